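"""FASTA and tabular I/O.

All tables are plain tab-separated text. Files written by the pipeline carry
provenance comment lines (``# key: value``) which :func:`read_table` skips
transparently.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import SampleMeta


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Raises ``ValueError`` on an empty file or content that precedes the
    first header.
    """
    path = Path(path)
    text_head = path.read_text()[:1] if path.exists() else ""
    if text_head == "":
        raise ValueError(f"{path}: empty FASTA file")
    if text_head != ">":
        raise ValueError(f"{path}: malformed FASTA (does not start with '>')")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-column wrapping)."""
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def parse_prodigal_header(header: str) -> tuple[str, int, int, str]:
    """Parse a Prodigal protein FASTA header.

    Headers look like ``"mag1_c1_3 # 310 # 846 # 1 # ID=..."``; the four
    leading fields are gene id, 1-based start, 1-based end and strand
    (``1``/``-1`` mapped to ``+``/``-``).
    """
    parts = [p.strip() for p in header.split("#")]
    if len(parts) < 4:
        raise ValueError(f"not a Prodigal header (expected '#'-separated fields): {header!r}")
    orf_id = parts[0].split()[0]
    try:
        start, end = int(parts[1]), int(parts[2])
        strand_code = int(parts[3])
    except ValueError as exc:
        raise ValueError(f"non-integer coordinate field in header {header!r}") from exc
    if strand_code not in (1, -1):
        raise ValueError(f"strand field must be 1 or -1, got {strand_code}")
    return orf_id, start, end, "+" if strand_code == 1 else "-"


def read_mag_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the MAG metadata table (mag_id, otu_id, phylum, family)."""
    df = read_table(path)
    required = {"mag_id", "otu_id", "phylum", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: MAG metadata missing columns {sorted(missing)}")
    if df["mag_id"].duplicated().any():
        dup = df.loc[df["mag_id"].duplicated(), "mag_id"].iloc[0]
        raise ValueError(f"{path}: duplicate mag_id {dup!r}")
    if (df["phylum"].astype(str).str.len() == 0).any() or df["phylum"].isna().any():
        raise ValueError(f"{path}: empty phylum entries")
    return df


def read_sample_metadata(path: str | os.PathLike) -> list[SampleMeta]:
    """Read the sample metadata table (sample_id, site, compartment, total_reads)."""
    df = read_table(path)
    required = {"sample_id", "site", "compartment", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample metadata missing columns {sorted(missing)}")
    return [
        SampleMeta(str(r.sample_id), str(r.site), str(r.compartment), int(r.total_reads))
        for r in df.itertuples()
    ]


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    meta: dict | None = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with optional ``# key: value`` provenance lines."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col: int | Sequence[int] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
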