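"""Independent reference implementations used as test oracles.

Everything here is deliberately written without reusing package internals:
plain-Python dynamic programming and exhaustive enumeration, kept simple
and slow.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 10
GAP_EXTEND = 1
TERM_GAP = 1


def enumerate_identity(a: str, b: str) -> float:
    """Identity by exhaustive enumeration of every global alignment.

    Scores each alignment column by column (BLOSUM62; internal affine gaps
    open 10 / extend 1; leading and trailing gap runs cost 1 per residue
    and are excluded from the identity counts), then picks the alignment
    with maximal (score, matches, -columns). Exponential: only for tiny
    sequences.
    """
    best: list | None = None

    def walk(i: int, j: int, ops: list[str]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            key = _score_alignment(a, b, ops)
            if best is None or key > best:
                best = key
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, ops + ["M"])
        if i < len(a):
            walk(i + 1, j, ops + ["D"])  # gap in b
        if j < len(b):
            walk(i, j + 1, ops + ["I"])  # gap in a

    walk(0, 0, [])
    assert best is not None
    _, matches, neg_cols = best
    cols = -neg_cols
    return matches / cols if cols else 0.0


def _score_alignment(a: str, b: str, ops: list[str]) -> tuple[float, int, int]:
    # terminal gap runs: a contiguous run of ONE sequence's gaps touching an
    # alignment end (a mixed run, e.g. gap-in-a then gap-in-b, is internal
    # past the first op change)
    lead = 0
    while lead < len(ops) and ops[lead] != "M" and ops[lead] == ops[0]:
        lead += 1
    trail = 0
    while (
        trail < len(ops) - lead
        and ops[len(ops) - 1 - trail] != "M"
        and ops[len(ops) - 1 - trail] == ops[-1]
    ):
        trail += 1
    score = 0.0
    matches = 0
    cols = 0
    i = j = 0
    prev = None
    for k, op in enumerate(ops):
        terminal = k < lead or k >= len(ops) - trail
        if op == "M":
            score += float(_B62[a[i], b[j]])
            matches += a[i] == b[j]
            cols += 1
            i += 1
            j += 1
        else:
            if terminal:
                score -= TERM_GAP
            else:
                score -= GAP_EXTEND if prev == op else GAP_OPEN
                cols += 1
            if op == "D":
                i += 1
            else:
                j += 1
        prev = op if op != "M" else None
    return score, matches, -cols


def dp_identity(a: str, b: str) -> float:
    """Identity via a plain-Python affine-gap DP (tuple-valued cells).

    Same alignment model as :func:`enumerate_identity` but polynomial;
    used to cross-check the fast kernel on realistic lengths.
    """
    n, m = len(a), len(b)
    NEG = (float("-inf"), 0, 0)

    def mx(*cands):
        return max(cands)

    # states: 0 match, 1 gap-in-b (consume a), 2 gap-in-a (consume b)
    prev = [[NEG] * (m + 1) for _ in range(3)]
    prev[0][0] = (0.0, 0, 0)
    for j in range(1, m + 1):
        prev[2][j] = (-TERM_GAP * j, 0, 0)
    best = NEG
    rows = [[NEG] * (m + 1) for _ in range(3)]
    for i in range(1, n + 1):
        cur = [[NEG] * (m + 1) for _ in range(3)]
        cur[1][0] = (-TERM_GAP * i, 0, 0)
        for j in range(1, m + 1):
            s = float(_B62[a[i - 1], b[j - 1]])
            match = 1 if a[i - 1] == b[j - 1] else 0
            base = mx(prev[0][j - 1], prev[1][j - 1], prev[2][j - 1])
            if base[0] > float("-inf"):
                cur[0][j] = (base[0] + s, base[1] + match, base[2] - 1)
            c1 = mx(
                (prev[0][j][0] - GAP_OPEN, prev[0][j][1], prev[0][j][2] - 1),
                (prev[1][j][0] - GAP_EXTEND, prev[1][j][1], prev[1][j][2] - 1),
                (prev[2][j][0] - GAP_OPEN, prev[2][j][1], prev[2][j][2] - 1),
            )
            cur[1][j] = c1 if c1[0] > float("-inf") else NEG
            c2 = mx(
                (cur[0][j - 1][0] - GAP_OPEN, cur[0][j - 1][1], cur[0][j - 1][2] - 1),
                (cur[2][j - 1][0] - GAP_EXTEND, cur[2][j - 1][1], cur[2][j - 1][2] - 1),
                (cur[1][j - 1][0] - GAP_OPEN, cur[1][j - 1][1], cur[1][j - 1][2] - 1),
            )
            cur[2][j] = c2 if c2[0] > float("-inf") else NEG
        rem = TERM_GAP * (n - i)
        for st in range(3):
            v = cur[st][m]
            if v[0] > float("-inf"):
                best = mx(best, (v[0] - rem, v[1], v[2]))
        prev = cur
    for j in range(1, m + 1):
        rem = TERM_GAP * (m - j)
        for st in range(3):
            v = prev[st][j]
            if v[0] > float("-inf"):
                best = mx(best, (v[0] - rem, v[1], v[2]))
    cols = -best[2]
    return best[1] / cols if cols else 0.0


def six_frame_orfs(seq: str, min_nt: int):
    """Exhaustive six-frame ORF enumeration (independent of the package).

    For every start codon, walk to the first in-frame stop; per stop keep
    the longest ORF. Returns forward-strand 1-based (start, end, strand).
    """
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    rc = "".join(comp[c] for c in reversed(seq))
    found = {}
    for strand, s in (("+", seq), ("-", rc)):
        for start_pos in range(len(s) - 2):
            if s[start_pos : start_pos + 3] not in ("ATG", "GTG", "TTG"):
                continue
            p = start_pos
            while p + 3 <= len(s):
                codon = s[p : p + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    length = p + 3 - start_pos
                    if length >= min_nt:
                        key = (strand, p)  # one ORF per stop: keep earliest start
                        if key not in found or start_pos < found[key]:
                            found[key] = start_pos
                    break
                p += 3
    out = set()
    n = len(seq)
    for (strand, stop_pos), start_pos in found.items():
        s0, s1 = start_pos, stop_pos + 2
        if strand == "+":
            out.add((s0 + 1, s1 + 1, "+"))
        else:
            out.add((n - s1, n - s0, "-"))
    return out


def resolve_overlaps_bruteforce(hits, overlap_frac=0.5):
    """Order-free overlap resolution: admit hits best-e-value first, reject
    any hit conflicting with an already admitted one (naive O(n^2))."""

    def span(h):
        return h.ali_to - h.ali_from + 1

    def conflict(x, y):
        ov = min(x.ali_to, y.ali_to) - max(x.ali_from, y.ali_from) + 1
        return ov > 0 and ov > overlap_frac * min(span(x), span(y))

    ranked = sorted(hits, key=lambda h: (h.evalue, h.family, h.ali_from, h.ali_to))
    admitted = []
    for h in ranked:
        if all(not conflict(h, other) for other in admitted):
            admitted.append(h)
    return admitted
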