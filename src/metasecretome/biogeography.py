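"""Spatial mapping of secreted functions along the gastrointestinal tract.

Reads assigned to secreted ORFs are counted per phylum and per EC function
and turned into a pseudo-RPKM: reads assigned to an EC divided by (mean
nucleotide ORF length of that EC, in kb) x (library size, in millions).
The mean length is computed once over all representative secreted ORFs
carrying the EC — not per sample — so the denominator reflects the gene
catalog rather than each library. Samples from the same (site, compartment)
are averaged, rows are kept only when some site exceeds a prevalence floor,
and two derived views are provided: per-row division by the row maximum
(so each EC attains 1.0 at its best site) and the mucosa/lumen ratio per
site.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .model import SampleMeta

logger = logging.getLogger(__name__)

STOOL = "stool"


def load_assignments(
    path: str | os.PathLike,
    sample_id: str | None = None,
    min_mapq: int = 10,
) -> pd.DataFrame:
    """Load read->ORF assignments from SAM or a 3-column TSV.

    SAM input (one file per sample; ``sample_id`` required) keeps primary
    alignments with MAPQ >= ``min_mapq``; secondary and supplementary
    records are ignored and reads with more than one primary target are
    discarded entirely ("unique reads"). TSV input has columns read_id,
    orf_id, sample_id and receives the same uniqueness filter per sample.
    """
    path = str(path)
    if path.endswith(".sam"):
        if sample_id is None:
            raise ValueError("sample_id is required for SAM input")
        rows = []
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                rows.append((rec.query_name, rec.reference_name, sample_id))
        df = pd.DataFrame(rows, columns=["read_id", "orf_id", "sample_id"])
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"read_id", "orf_id", "sample_id"}
        if missing := required - set(df.columns):
            raise ValueError(f"{path}: assignment table missing columns {sorted(missing)}")
        if df[list(required)].isna().any().any():
            bad = int(df[list(required)].isna().any(axis=1).idxmax()) + 2
            raise ValueError(f"{path}: malformed record near line {bad}")
    multi = df.duplicated(["read_id", "sample_id"], keep=False)
    if multi.any():
        logger.info("discarding %d multi-mapped read records", int(multi.sum()))
        df = df[~multi]
    return df.reset_index(drop=True)


def reads_per_phylum_secreted(
    assignments: pd.DataFrame,
    secretion_labels: dict[str, bool],
    orf_to_mag: dict[str, str],
    mag_to_phylum: dict[str, str],
) -> pd.DataFrame:
    """Unique-read counts to secreted ORFs per sample x phylum."""
    unknown = set(assignments["orf_id"]) - set(orf_to_mag)
    if unknown:
        raise ValueError(f"assignments reference unknown ORFs, e.g. {sorted(unknown)[:3]}")
    secreted_ids = {o for o, flag in secretion_labels.items() if flag}
    df = assignments[assignments["orf_id"].isin(secreted_ids)].copy()
    df["phylum"] = df["orf_id"].map(orf_to_mag).map(mag_to_phylum)
    table = df.groupby(["sample_id", "phylum"]).size().unstack(fill_value=0)
    return table.reindex(sorted(assignments["sample_id"].unique()), fill_value=0)


def pseudo_rpkm(reads_to_ec: float, mean_orf_len_nt: float, total_reads: int) -> float:
    """reads / ((mean ORF length / 1000) * (library size / 1e6))."""
    if mean_orf_len_nt <= 0:
        raise ValueError("mean ORF length must be positive")
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    return reads_to_ec / ((mean_orf_len_nt / 1000.0) * (total_reads / 1e6))


def mean_orf_length_per_ec(
    orf_lengths_nt: dict[str, int],
    orf_ecs: dict[str, list[str]],
    secretion_labels: dict[str, bool],
) -> pd.Series:
    """Mean nucleotide length over secreted representative ORFs per EC.

    ORFs carrying several ECs contribute their length to each of them.
    """
    acc: dict[str, list[int]] = {}
    for orf_id, ecs in orf_ecs.items():
        if not secretion_labels.get(orf_id, False):
            continue
        for ec in ecs:
            acc.setdefault(ec, []).append(orf_lengths_nt[orf_id])
    return pd.Series({ec: float(np.mean(v)) for ec, v in sorted(acc.items())}, dtype=float)


def ec_read_counts(
    assignments: pd.DataFrame,
    orf_ecs: dict[str, list[str]],
    secretion_labels: dict[str, bool],
) -> pd.DataFrame:
    """Unique reads to secreted ORFs per sample x EC.

    A read whose ORF carries several ECs is counted once per EC (the
    mean-length denominator is likewise computed per EC over its own ORFs).
    """
    secreted_ids = {o for o, flag in secretion_labels.items() if flag}
    df = assignments[assignments["orf_id"].isin(secreted_ids)]
    df = df.assign(ec=df["orf_id"].map(orf_ecs)).explode("ec").dropna(subset=["ec"])
    table = df.groupby(["sample_id", "ec"]).size().unstack(fill_value=0)
    return table.reindex(sorted(assignments["sample_id"].unique()), fill_value=0)


def rpkm_matrix(
    counts: pd.DataFrame,
    mean_lengths: pd.Series,
    sample_meta: list[SampleMeta],
    denominator: str = "qc",
) -> pd.DataFrame:
    """Pseudo-RPKM per sample x EC.

    ``denominator="qc"`` divides by the QC-passed library size recorded in
    the sample metadata (default); ``"mapped"`` divides by the number of
    unique mapped reads in the counts table instead.
    """
    meta = {s.sample_id: s for s in sample_meta}
    missing = set(counts.index) - set(meta)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    ecs = [ec for ec in counts.columns if ec in mean_lengths.index]
    dropped = set(counts.columns) - set(ecs)
    if dropped:
        logger.warning("%d EC columns lack a mean ORF length; dropped", len(dropped))
    out = pd.DataFrame(index=counts.index, columns=ecs, dtype=float)
    for sample in counts.index:
        if denominator == "qc":
            total = meta[sample].total_reads
        elif denominator == "mapped":
            total = int(counts.loc[sample].sum())
        else:
            raise ValueError("denominator must be 'qc' or 'mapped'")
        for ec in ecs:
            out.loc[sample, ec] = pseudo_rpkm(
                float(counts.loc[sample, ec]), float(mean_lengths[ec]), total
            )
    return out


def average_by_site(
    values: pd.DataFrame, sample_meta: list[SampleMeta]
) -> pd.DataFrame:
    """Average sample rows over (site, compartment); returns EC x (site, compartment).

    Stool samples appear as the ``(stool, stool)`` column.
    """
    meta = {s.sample_id: s for s in sample_meta}
    keys = pd.DataFrame(
        {
            "site": [meta[s].site for s in values.index],
            "compartment": [meta[s].compartment for s in values.index],
        },
        index=values.index,
    )
    grouped = values.groupby([keys["site"], keys["compartment"]]).mean()
    grouped.index.names = ["site", "compartment"]
    return grouped.T  # EC rows, (site, compartment) columns


def filter_prevalent_ecs(matrix: pd.DataFrame, min_rpkm: float = 50.0) -> pd.DataFrame:
    """Keep EC rows whose maximum over sites strictly exceeds ``min_rpkm``."""
    return matrix[matrix.max(axis=1) > min_rpkm]


def normalize_by_row_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each EC row by its maximum; every row attains exactly 1.0."""
    row_max = matrix.max(axis=1)
    if (row_max <= 0).any():
        bad = row_max.index[row_max <= 0][0]
        raise ValueError(f"row {bad!r} has non-positive maximum; filter first")
    return matrix.div(row_max, axis=0)


def zscore_by_row(matrix: pd.DataFrame) -> pd.DataFrame:
    """True per-row z-scores, provided as a clearly named alternative view."""
    mean = matrix.mean(axis=1)
    std = matrix.std(axis=1, ddof=0)
    if (std == 0).any():
        bad = std.index[std == 0][0]
        raise ValueError(f"row {bad!r} is constant; z-score undefined")
    return matrix.sub(mean, axis=0).div(std, axis=0)


def mucosa_lumen_ratio(matrix: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    """Mucosal / luminal pseudo-RPKM per EC and site.

    Only sites with both compartments are reported; a zero luminal value
    yields NaN (undefined) unless ``epsilon`` is set, in which case both
    numerator and denominator are stabilized by it.
    """
    sites = sorted(
        {
            site
            for site, comp in matrix.columns
            if comp == "mucosa" and (site, "lumen") in matrix.columns
        }
    )
    out = pd.DataFrame(index=matrix.index, columns=sites, dtype=float)
    for site in sites:
        mucosa = matrix[(site, "mucosa")] + epsilon
        lumen = matrix[(site, "lumen")] + epsilon
        ratio = mucosa / lumen
        if epsilon == 0:
            ratio = ratio.where(lumen > 0, np.nan)
        out[site] = ratio
    return out


@dataclass
class SiteFunctionMatrix:
    """Pseudo-RPKM per EC x (site, compartment), with derived views."""

    raw: pd.DataFrame
    min_rpkm: float = 50.0

    @property
    def filtered(self) -> pd.DataFrame:
        return filter_prevalent_ecs(self.raw, self.min_rpkm)

    @property
    def normalized(self) -> pd.DataFrame:
        return normalize_by_row_max(self.filtered)

    @property
    def ratio(self) -> pd.DataFrame:
        return mucosa_lumen_ratio(self.filtered)
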