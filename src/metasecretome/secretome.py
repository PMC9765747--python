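"""Secretion calling from signal-peptide and transmembrane predictions.

An ORF counts as extracellularly secreted when its predicted signal peptide
is Sec/SPI or Tat AND it carries no predicted transmembrane helix.
Lipoprotein signal peptides (Sec/SPII) are excluded because the mature
protein stays anchored in the membrane, and any predicted helix disqualifies
a protein even when the helix overlaps the signal peptide itself — the known
confound between signal peptides and N-terminal helices is deliberately not
corrected by default (see ``ignore_nterm_helices``).

Predictions are parsed from SignalP 5.0 summary files and TMHMM 2.0
short-format files; calls are made on cluster centroids and propagated to
all cluster members.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import read_table, write_table
from .model import Orf, Mag, OrfCluster, SecretionAnnotation, SpClass
from . import stats as _stats

logger = logging.getLogger(__name__)

_SIGNALP_CLASSES = {
    "SP(Sec/SPI)": SpClass.SEC_SPI,
    "TAT(Tat/SPI)": SpClass.TAT,
    "LIPO(Sec/SPII)": SpClass.LIPO,
    "OTHER": SpClass.OTHER,
}


def parse_signalp5(path: str | os.PathLike) -> dict[str, SpClass]:
    """Parse a SignalP 5.0 summary file into ``orf_id -> SpClass``."""
    out: dict[str, SpClass] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            orf_id, label = fields[0], fields[1]
            if label not in _SIGNALP_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown SignalP class {label!r}")
            if orf_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {orf_id!r}")
            out[orf_id] = _SIGNALP_CLASSES[label]
    return out


_PREDHEL = re.compile(r"PredHel=(\d+)")
_TOPOLOGY = re.compile(r"Topology=(\S+)")
_HELIX_SPAN = re.compile(r"(\d+)-(\d+)")


def parse_tmhmm(path: str | os.PathLike) -> dict[str, int]:
    """Parse a TMHMM 2.0 short-format file into ``orf_id -> helix count``."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            orf_id = line.split()[0]
            m = _PREDHEL.search(line)
            if not m:
                raise ValueError(f"{path}:{lineno}: missing PredHel field")
            if orf_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {orf_id!r}")
            out[orf_id] = int(m.group(1))
    return out


def parse_tmhmm_topology(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Parse helix spans from TMHMM short-format Topology strings."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            orf_id = line.split()[0]
            m = _TOPOLOGY.search(line)
            spans = (
                [(int(a), int(b)) for a, b in _HELIX_SPAN.findall(m.group(1))] if m else []
            )
            out[orf_id] = spans
    return out


def classify_secretion(sp_class: SpClass, tm_helices: int) -> bool:
    """Truth table for the secretion call.

    ``(SEC_SPI, 0)`` and ``(TAT, 0)`` are secreted; a lipoprotein signal
    peptide, no signal peptide, or any transmembrane helix is not.
    """
    if tm_helices < 0:
        raise ValueError("negative helix count")
    return sp_class in (SpClass.SEC_SPI, SpClass.TAT) and tm_helices == 0


def annotate_secretion(
    orf_ids: list[str],
    sp_map: dict[str, SpClass],
    tm_map: dict[str, int],
    tm_spans: dict[str, list[tuple[int, int]]] | None = None,
    ignore_nterm_helices: bool = False,
    nterm_window: int = 60,
) -> dict[str, SecretionAnnotation]:
    """Combine signal-peptide and helix predictions into final calls.

    ORFs absent from a prediction file default to OTHER / zero helices with
    a logged warning (robustness to partial tool output). With
    ``ignore_nterm_helices`` a helix fully inside the first ``nterm_window``
    residues is discounted, using topology spans when available.
    """
    missing_sp = missing_tm = 0
    out: dict[str, SecretionAnnotation] = {}
    for orf_id in orf_ids:
        sp = sp_map.get(orf_id)
        if sp is None:
            sp = SpClass.OTHER
            missing_sp += 1
        tm = tm_map.get(orf_id)
        if tm is None:
            tm = 0
            missing_tm += 1
        if ignore_nterm_helices and tm > 0 and tm_spans is not None:
            spans = tm_spans.get(orf_id, [])
            tm = sum(1 for a, b in spans if b > nterm_window) if spans else tm
        out[orf_id] = SecretionAnnotation(orf_id, sp, tm, classify_secretion(sp, tm))
    if missing_sp:
        logger.warning("%d ORFs missing from SignalP output; treated as OTHER", missing_sp)
    if missing_tm:
        logger.warning("%d ORFs missing from TMHMM output; treated as 0 helices", missing_tm)
    return out


def propagate_labels(
    clusters: list[OrfCluster], centroid_secreted: dict[str, bool]
) -> dict[str, bool]:
    """Assign every cluster member its centroid's secretion label."""
    out: dict[str, bool] = {}
    for cluster in clusters:
        if cluster.centroid_id not in centroid_secreted:
            raise ValueError(f"centroid {cluster.centroid_id!r} has no secretion label")
        label = centroid_secreted[cluster.centroid_id]
        for member in cluster.member_ids:
            out[member] = label
    return out


def percent_secreted_per_mag(
    orf_labels: dict[str, bool], mags: list[Mag]
) -> pd.Series:
    """Percent of each MAG's ORFs that are secreted (0-100)."""
    values = {}
    for mag in mags:
        if not mag.orfs:
            raise ValueError(f"{mag.mag_id}: MAG has no ORFs")
        labels = [orf_labels[o.orf_id] for o in mag.orfs]
        values[mag.mag_id] = 100.0 * sum(labels) / len(labels)
    return pd.Series(values, name="percent_secreted")


def percent_secreted_per_phylum(
    per_mag: pd.Series, mags: list[Mag], min_mags: int = 1
) -> pd.Series:
    """Mean per-MAG secreted percentage by phylum (phyla with >= min_mags MAGs)."""
    phyla = pd.Series({m.mag_id: m.phylum for m in mags})
    df = pd.DataFrame({"percent": per_mag, "phylum": phyla.reindex(per_mag.index)})
    grouped = df.groupby("phylum")["percent"]
    means = grouped.mean()
    counts = grouped.size()
    return means[counts >= min_mags].sort_values(ascending=False)


@dataclass(frozen=True)
class LengthSummary:
    mean_len_secreted: float
    mean_len_nonsecreted: float
    test: _stats.TestResult


def length_summary(orf_labels: dict[str, bool], orfs: list[Orf]) -> LengthSummary:
    """Mean amino-acid length of secreted vs nonsecreted proteins, with a
    two-sided Mann-Whitney U test of the difference."""
    sec = [o.aa_length for o in orfs if orf_labels[o.orf_id]]
    non = [o.aa_length for o in orfs if not orf_labels[o.orf_id]]
    if not sec or not non:
        raise ValueError("both secreted and nonsecreted groups must be non-empty")
    test = _stats.mann_whitney_u(sec, non)
    return LengthSummary(
        mean_len_secreted=sum(sec) / len(sec),
        mean_len_nonsecreted=sum(non) / len(non),
        test=test,
    )


def load_cost_table(path: str | os.PathLike | None = None) -> dict[str, float]:
    """Load a per-residue biosynthetic cost table (default: Akashi-Gojobori)."""
    if path is None:
        ref = resources.files("metasecretome.data") / "aa_costs.tsv"
        with resources.as_file(ref) as p:
            df = read_table(p)
    else:
        df = read_table(path)
    table = dict(zip(df["residue"], df["cost"].astype(float)))
    if len(table) < 20:
        raise ValueError("cost table must cover the 20 standard residues")
    if any(v <= 0 for v in table.values()):
        raise ValueError("costs must be positive")
    return table


def cost_per_residue(
    aa_seq: str, cost_table: dict[str, float], on_unknown: str = "skip"
) -> float:
    """Mean biosynthetic cost per residue of a protein.

    Residues absent from the table are skipped with a warning by default
    (``on_unknown="error"`` raises instead).
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    known = [c for c in aa_seq if c in cost_table]
    unknown = len(aa_seq) - len(known)
    if unknown:
        if on_unknown == "error":
            raise ValueError(f"{unknown} residues not in cost table")
        logger.warning("%d residues not in cost table; skipped", unknown)
    if not known:
        raise ValueError("no scoreable residues in sequence")
    return sum(cost_table[c] for c in known) / len(known)


def write_secretion_table(
    annotations: dict[str, SecretionAnnotation],
    path: str | os.PathLike,
    meta: dict | None = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "orf_id": a.orf_id,
                "sp_class": a.sp_class.value,
                "tm_helices": a.tm_helices,
                "secreted": a.secreted,
            }
            for a in annotations.values()
        ]
    )
    write_table(df, path, meta)


def read_secretion_table(path: str | os.PathLike) -> dict[str, SecretionAnnotation]:
    df = read_table(path)
    return {
        r.orf_id: SecretionAnnotation(
            r.orf_id, SpClass(r.sp_class), int(r.tm_helices), bool(r.secreted)
        )
        for r in df.itertuples()
    }
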