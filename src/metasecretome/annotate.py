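"""HMM-based functional annotation: CAZyme and orthologous-group filters.

Domain tables are standard HMMER3 ``--domtblout`` files in hmmscan
orientation (target = profile HMM, query = protein). CAZyme hits pass
through the dbCAN-style filter: overlapping hits on the same protein are
resolved in favour of the lower e-value whenever the overlap exceeds half
of the shorter alignment, then hits must cover at least 35% of the HMM at
an e-value of at most 1e-15. Orthologous-group (eggNOG-style) searches keep
the single best hit per protein at e-value <= 0.001.

Throughout, a tool's "minimum e-value" filter is interpreted as an upper
bound on the e-value, which is the standard meaning of those thresholds.
"""

from __future__ import annotations

import os
from collections import defaultdict
from importlib import resources

import pandas as pd

from .io import read_table, write_table
from .model import DomainHit, FunctionAnnotation, Mag

N_DOMTBL_FIELDS = 23  # fixed columns before the free-text description


def parse_domtblout(path: str | os.PathLike) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table (hmmscan orientation).

    Fields used: target name (family; a trailing ``.hmm`` is stripped),
    tlen (HMM length), query name (ORF id), i-Evalue (independent e-value
    of the domain) and hmm/ali coordinates.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < N_DOMTBL_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {N_DOMTBL_FIELDS} columns, got {len(f)}"
                )
            family = f[0]
            if family.endswith(".hmm"):
                family = family[: -len(".hmm")]
            hits.append(
                DomainHit(
                    orf_id=f[3],
                    family=family,
                    evalue=float(f[12]),
                    hmm_from=int(f[15]),
                    hmm_to=int(f[16]),
                    hmm_len=int(f[2]),
                    ali_from=int(f[17]),
                    ali_to=int(f[18]),
                )
            )
    return hits


def hmm_coverage(hit: DomainHit) -> float:
    """Fraction of the profile HMM covered by the aligned domain."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.hmm_len


def _overlap_conflict(a: DomainHit, b: DomainHit, overlap_frac: float) -> bool:
    overlap = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    if overlap <= 0:
        return False
    shorter = min(a.ali_to - a.ali_from + 1, b.ali_to - b.ali_from + 1)
    return overlap > overlap_frac * shorter


def filter_cazyme_hits(
    hits: list[DomainHit],
    min_cov: float = 0.35,
    max_eval: float = 1e-15,
    overlap_frac: float = 0.5,
) -> list[DomainHit]:
    """dbCAN-style CAZyme hit filter.

    Per protein, hits are admitted in order of increasing e-value (ties by
    family then query position); a hit overlapping an already-admitted hit
    by more than ``overlap_frac`` of the shorter alignment is discarded.
    Survivors must then satisfy coverage >= ``min_cov`` and e-value <=
    ``max_eval``. The outcome is independent of input order.
    """
    by_orf: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits:
        by_orf[hit.orf_id].append(hit)
    survivors: list[DomainHit] = []
    for orf_id in sorted(by_orf):
        ranked = sorted(
            by_orf[orf_id], key=lambda h: (h.evalue, h.family, h.ali_from, h.ali_to)
        )
        kept: list[DomainHit] = []
        for hit in ranked:
            if not any(_overlap_conflict(hit, other, overlap_frac) for other in kept):
                kept.append(hit)
        kept = [h for h in kept if hmm_coverage(h) >= min_cov and h.evalue <= max_eval]
        kept.sort(key=lambda h: (h.ali_from, h.ali_to, h.family))
        survivors.extend(kept)
    return survivors


def filter_eggnog_hits(hits: list[DomainHit], max_eval: float = 0.001) -> dict[str, str]:
    """Best orthologous-group hit per protein at e-value <= ``max_eval``.

    Ties on e-value are broken lexicographically by family id.
    """
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.evalue > max_eval:
            continue
        cur = best.get(hit.orf_id)
        if cur is None or (hit.evalue, hit.family) < (cur.evalue, cur.family):
            best[hit.orf_id] = hit
    return {orf_id: hit.family for orf_id, hit in best.items()}


def load_cazyme_reference(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Family -> representative EC and broad substrate classes (editable table)."""
    if path is None:
        ref = resources.files("metasecretome.data") / "cazyme_families.tsv"
        with resources.as_file(ref) as p:
            df = read_table(p)
    else:
        df = read_table(path)
    return df.fillna({"ec": "", "substrate_classes": ""})


def build_function_annotations(
    cazyme_hits: list[DomainHit],
    og_map: dict[str, str],
    og_reference: pd.DataFrame | None = None,
    cazyme_reference: pd.DataFrame | None = None,
) -> dict[str, FunctionAnnotation]:
    """Merge filtered CAZyme hits and OG assignments per ORF.

    ``og_reference`` maps og_id to COG category letters and optional EC
    numbers (columns og_id, cog_category, ec); ``cazyme_reference`` supplies
    family-level ECs. Lists are deduplicated and sorted.
    """
    if cazyme_reference is None:
        cazyme_reference = load_cazyme_reference()
    family_ec = {
        r.family: r.ec for r in cazyme_reference.itertuples() if getattr(r, "ec", "")
    }
    og_cog: dict[str, str] = {}
    og_ec: dict[str, str] = {}
    if og_reference is not None:
        for r in og_reference.itertuples():
            og_cog[r.og_id] = str(getattr(r, "cog_category", "") or "")
            ec = getattr(r, "ec", "")
            if isinstance(ec, str) and ec:
                og_ec[r.og_id] = ec

    out: dict[str, FunctionAnnotation] = {}
    fams_by_orf: dict[str, list[str]] = defaultdict(list)
    for hit in cazyme_hits:
        fams_by_orf[hit.orf_id].append(hit.family)
    for orf_id in sorted(set(fams_by_orf) | set(og_map)):
        families = sorted(set(fams_by_orf.get(orf_id, [])))
        og = og_map.get(orf_id)
        cogs = sorted(set(og_cog.get(og, ""))) if og else []
        ecs = {family_ec[f] for f in families if f in family_ec}
        if og and og in og_ec:
            ecs.add(og_ec[og])
        out[orf_id] = FunctionAnnotation(
            orf_id=orf_id,
            cazy_families=families,
            og_id=og,
            cog_categories=[c for c in cogs if c],
            ec_numbers=sorted(ecs),
        )
    return out


def avg_secreted_per_cog_per_phylum(
    annotations: dict[str, FunctionAnnotation],
    secretion_labels: dict[str, bool],
    mags: list[Mag],
) -> pd.DataFrame:
    """Mean number of secreted ORFs per MAG in each COG category, by phylum.

    MAGs lacking a category contribute zero to the phylum mean.
    """
    categories = sorted({c for a in annotations.values() for c in a.cog_categories})
    rows = []
    for mag in mags:
        counts = dict.fromkeys(categories, 0)
        for orf in mag.orfs:
            if not secretion_labels.get(orf.orf_id, False):
                continue
            ann = annotations.get(orf.orf_id)
            if ann is None:
                continue
            for c in ann.cog_categories:
                counts[c] += 1
        rows.append({"phylum": mag.phylum, **counts})
    if not rows:
        return pd.DataFrame(columns=categories)
    return pd.DataFrame(rows).groupby("phylum").mean()


def percent_secreted_cazymes_per_mag(
    cazyme_families: dict[str, list[str]],
    secretion_labels: dict[str, bool],
    orf_to_mag: dict[str, str],
) -> pd.Series:
    """Percent of each MAG's CAZyme ORFs that are secreted.

    MAGs with no CAZyme ORFs are absent from the result (the quantity is
    undefined for them).
    """
    totals: dict[str, int] = defaultdict(int)
    secreted: dict[str, int] = defaultdict(int)
    for orf_id, families in cazyme_families.items():
        if not families:
            continue
        mag = orf_to_mag[orf_id]
        totals[mag] += 1
        if secretion_labels.get(orf_id, False):
            secreted[mag] += 1
    return pd.Series(
        {mag: 100.0 * secreted[mag] / totals[mag] for mag in sorted(totals)},
        name="percent_secreted_cazymes",
        dtype=float,
    )


def write_annotation_table(
    annotations: dict[str, FunctionAnnotation],
    path: str | os.PathLike,
    meta: dict | None = None,
) -> None:
    rows = [
        {
            "orf_id": a.orf_id,
            "cazy_families": ",".join(a.cazy_families),
            "og_id": a.og_id or "",
            "cog_categories": ",".join(a.cog_categories),
            "ec_numbers": ",".join(a.ec_numbers),
        }
        for a in annotations.values()
    ]
    cols = ["orf_id", "cazy_families", "og_id", "cog_categories", "ec_numbers"]
    write_table(pd.DataFrame(rows, columns=cols), path, meta)


def read_annotation_table(path: str | os.PathLike) -> dict[str, FunctionAnnotation]:
    df = read_table(path).fillna("")
    out = {}
    for r in df.itertuples():
        out[r.orf_id] = FunctionAnnotation(
            orf_id=r.orf_id,
            cazy_families=[f for f in str(r.cazy_families).split(",") if f],
            og_id=str(r.og_id) or None,
            cog_categories=[c for c in str(r.cog_categories).split(",") if c],
            ec_numbers=[e for e in str(r.ec_numbers).split(",") if e],
        )
    return out
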