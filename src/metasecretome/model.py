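"""Core domain types shared across the pipeline.

The objects here are deliberately thin: a called gene (:class:`Orf`), the
genome bin it came from (:class:`Mag`), a sequencing sample
(:class:`SampleMeta`), and the per-gene annotation records produced by the
secretion and function annotation stages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SpClass(enum.Enum):
    """Signal-peptide class of a protein N terminus.

    SEC_SPI  -- standard Sec pathway signal peptide (signal peptidase I)
    TAT      -- twin-arginine translocation signal peptide
    LIPO     -- lipoprotein signal peptide (signal peptidase II); the mature
                protein is lipid-anchored in the membrane, so it is not
                counted as extracellularly secreted
    OTHER    -- no signal peptide detected
    """

    SEC_SPI = "SEC_SPI"
    TAT = "TAT"
    LIPO = "LIPO"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Orf:
    """One called protein-coding gene.

    Coordinates are 1-based inclusive on the forward strand of the contig
    (the same convention Prodigal headers use); ``nt_seq`` is the coding
    sequence read in gene orientation, so ``len(nt_seq) == end - start + 1``
    and is divisible by three. ``aa_seq`` excludes the stop codon.
    """

    orf_id: str
    mag_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.orf_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be '+' or '-'")
        if self.nt_seq and len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(f"{self.orf_id}: nt_seq length disagrees with coordinates")
        if self.nt_seq and len(self.nt_seq) % 3:
            raise ValueError(f"{self.orf_id}: nt_seq length not divisible by 3")

    @property
    def aa_length(self) -> int:
        return len(self.aa_seq)

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Mag:
    """A metagenome-assembled genome with its taxonomy and called genes."""

    mag_id: str
    otu_id: str
    phylum: str
    family: str
    contigs: dict[str, str] = field(default_factory=dict)
    orfs: list[Orf] = field(default_factory=list)


@dataclass(frozen=True)
class SampleMeta:
    """A sequencing sample: its GI site, compartment and library size.

    ``compartment`` is one of ``lumen``, ``mucosa`` or ``stool``; stool
    samples carry no lumen/mucosa split and use ``stool`` for both fields'
    purposes. ``total_reads`` is the QC-passed read count of the library.
    """

    sample_id: str
    site: str
    compartment: str
    total_reads: int

    VALID_COMPARTMENTS = ("lumen", "mucosa", "stool")

    def __post_init__(self) -> None:
        if self.compartment not in self.VALID_COMPARTMENTS:
            raise ValueError(
                f"{self.sample_id}: compartment {self.compartment!r} not in "
                f"{self.VALID_COMPARTMENTS}"
            )
        if self.total_reads < 0:
            raise ValueError(f"{self.sample_id}: negative total_reads")


@dataclass(frozen=True)
class SecretionAnnotation:
    """Final secretion call for one ORF.

    An ORF is secreted iff it carries a Sec/SPI or Tat signal peptide and no
    predicted transmembrane helix.
    """

    orf_id: str
    sp_class: SpClass
    tm_helices: int
    secreted: bool

    def __post_init__(self) -> None:
        if self.tm_helices < 0:
            raise ValueError(f"{self.orf_id}: negative helix count")
        expected = self.sp_class in (SpClass.SEC_SPI, SpClass.TAT) and self.tm_helices == 0
        if self.secreted != expected:
            raise ValueError(
                f"{self.orf_id}: secreted flag inconsistent with "
                f"({self.sp_class.value}, {self.tm_helices})"
            )


@dataclass(frozen=True)
class OrfCluster:
    """A greedy identity cluster: centroid plus all members (incl. centroid)."""

    centroid_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError(f"centroid {self.centroid_id} missing from members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class DomainHit:
    """One HMM domain match from a domain table (hmmscan orientation)."""

    orf_id: str
    family: str
    evalue: float
    hmm_from: int
    hmm_to: int
    hmm_len: int
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_len):
            raise ValueError(
                f"{self.orf_id}/{self.family}: bad HMM coordinates "
                f"{self.hmm_from}-{self.hmm_to}/{self.hmm_len}"
            )
        if self.evalue <= 0:
            raise ValueError(f"{self.orf_id}/{self.family}: e-value must be > 0")


@dataclass
class FunctionAnnotation:
    """Aggregated functional labels for one ORF."""

    orf_id: str
    cazy_families: list[str] = field(default_factory=list)
    og_id: str | None = None
    cog_categories: list[str] = field(default_factory=list)
    ec_numbers: list[str] = field(default_factory=list)
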