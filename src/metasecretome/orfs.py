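"""Minimal ORF calling and MAG-level quality filters.

The ORF caller reports, in all six reading frames, the maximal open reading
frame per stop codon: from the most upstream start codon (ATG/GTG/TTG)
following the previous in-frame stop through the first in-frame stop codon,
inclusive. The minimum-length threshold (default 15 nt, counted start
through stop) deliberately admits very short genes. Real gene-caller output
(e.g. Prodigal protein FASTA) is ingested directly via
:func:`metasecretome.io.parse_prodigal_header`; this caller exists so that
synthetic genomes can be processed end to end.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from .model import Mag, Orf

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def _frame_orfs(seq: str, frame: int, min_nt: int) -> list[tuple[int, int]]:
    """Maximal (start, stop) codon-index spans in one forward frame.

    Returns 0-based nucleotide offsets ``(orf_start, orf_end_inclusive)``
    covering start codon through stop codon.
    """
    spans: list[tuple[int, int]] = []
    first_start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if first_start is not None:
                length = pos + 3 - first_start
                if length >= min_nt:
                    spans.append((first_start, pos + 2))
            first_start = None
        elif first_start is None and codon in START_CODONS:
            first_start = pos
    return spans


def find_orfs(
    genome: str,
    min_nt: int = 15,
    mag_id: str = "",
    contig_id: str = "contig",
    on_ambiguous: str = "error",
) -> list[Orf]:
    """Call ORFs on both strands of a nucleotide sequence.

    Parameters
    ----------
    genome:
        Sequence over A/C/G/T (uppercased internally).
    min_nt:
        Minimum ORF length in nucleotides, start codon through stop codon
        inclusive.
    on_ambiguous:
        ``"error"`` rejects non-ACGT characters; ``"skip"`` returns no ORFs
        spanning them (frames containing ambiguity are dropped wholesale).

    Returns coordinates that are 1-based inclusive on the forward strand for
    both orientations; ``aa_seq`` excludes the stop codon.
    """
    seq = genome.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        if on_ambiguous == "error":
            raise ValueError(f"non-ACGT characters in genome: {sorted(bad)}")
        if on_ambiguous != "skip":
            raise ValueError(f"on_ambiguous must be 'error' or 'skip', got {on_ambiguous!r}")

    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for s0, s1 in _frame_orfs(s, frame, min_nt):
                nt = s[s0 : s1 + 1]
                if set(nt) - set("ACGT"):
                    continue  # on_ambiguous == "skip"
                if strand == "+":
                    start, end = s0 + 1, s1 + 1
                else:
                    start, end = n - s1, n - s0
                aa = str(Seq(nt[:-3]).translate(table=11))
                orfs.append(
                    Orf(
                        orf_id="",  # assigned below, in positional order
                        mag_id=mag_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        nt_seq=nt,
                        aa_seq=aa,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return [
        Orf(
            orf_id=f"{contig_id}_{i + 1}",
            mag_id=o.mag_id,
            contig_id=o.contig_id,
            start=o.start,
            end=o.end,
            strand=o.strand,
            nt_seq=o.nt_seq,
            aa_seq=o.aa_seq,
        )
        for i, o in enumerate(orfs)
    ]


def filter_mags_by_orf_count(mags: list[Mag], min_orfs: int = 482) -> list[Mag]:
    """Keep MAGs with at least ``min_orfs`` called genes (order preserved).

    The default matches the gene count of the smallest known bacterial
    genome, so bins below it are treated as too incomplete to analyse.
    """
    return [m for m in mags if len(m.orfs) >= min_orfs]


def select_representative_mags(mags: list[Mag], seed: int) -> list[Mag]:
    """Pick one MAG uniformly at random per species-level OTU.

    The choice depends only on the OTU membership and the seed, not on input
    order: OTUs are processed in sorted order and candidates sorted by
    mag_id before sampling. Returned in input order.
    """
    by_otu: dict[str, list[Mag]] = {}
    for mag in mags:
        if not mag.otu_id:
            raise ValueError(f"{mag.mag_id}: missing otu_id")
        by_otu.setdefault(mag.otu_id, []).append(mag)
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for otu in sorted(by_otu):
        candidates = sorted(by_otu[otu], key=lambda m: m.mag_id)
        chosen.add(candidates[int(rng.integers(len(candidates)))].mag_id)
    return [m for m in mags if m.mag_id in chosen]
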