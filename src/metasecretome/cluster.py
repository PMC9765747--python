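"""Greedy centroid clustering of proteins at high amino-acid identity.

Sequences are processed in order of decreasing length (ties broken
lexicographically by id). Each sequence joins the first existing centroid to
which its identity reaches the threshold, otherwise it founds a new cluster.
This reproduces the behaviour of greedy centroid clusterers such as
USEARCH's cluster_fast, minus their k-mer prefilters, and is fully
deterministic.
"""

from __future__ import annotations

import os

import pandas as pd

from ._align import encode, glocal_stats
from .io import write_table, read_table
from .model import OrfCluster


def pairwise_identity(a: str, b: str, gap_open: int = 10, gap_extend: int = 1) -> float:
    """Fraction of identical columns in the optimal glocal alignment of two proteins.

    Identity = matching columns / alignment columns excluding terminal-gap
    columns; internal gap columns count as mismatches. Symmetric in its
    arguments. Raises ``ValueError`` for empty sequences.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    _, matches, cols = glocal_stats(encode(a), encode(b), gap_open, gap_extend)
    return matches / cols if cols else 0.0


def greedy_cluster(
    seqs: list[tuple[str, str]], threshold: float = 0.95
) -> list[OrfCluster]:
    """Cluster ``(id, protein)`` pairs greedily at the given identity threshold.

    Returns clusters in centroid-founding order; members are listed in
    assignment order with the centroid first.
    """
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate sequence id {dup!r}")
    order = sorted(seqs, key=lambda rec: (-len(rec[1]), rec[0]))
    centroids: list[tuple[str, object]] = []  # (id, encoded seq)
    members: dict[str, list[str]] = {}
    for sid, seq in order:
        if not seq:
            raise ValueError(f"{sid}: empty sequence")
        enc = encode(seq)
        home = None
        for cid, cenc in centroids:
            _, matches, cols = glocal_stats(cenc, enc)
            if cols and matches / cols >= threshold:
                home = cid
                break
        if home is None:
            centroids.append((sid, enc))
            members[sid] = [sid]
        else:
            members[home].append(sid)
    return [OrfCluster(cid, tuple(members[cid])) for cid, _ in centroids]


def filter_clusters_by_size(
    clusters: list[OrfCluster], min_members: int = 5, strict: bool = False
) -> list[OrfCluster]:
    """Keep clusters with ``size >= min_members`` (``> min_members`` if strict)."""
    if strict:
        return [c for c in clusters if c.size > min_members]
    return [c for c in clusters if c.size >= min_members]


def write_cluster_table(
    clusters: list[OrfCluster], path: str | os.PathLike, meta: dict | None = None
) -> None:
    """Write clusters as a long table: cluster_id, centroid_id, member_id."""
    rows = [
        {"cluster_id": i, "centroid_id": c.centroid_id, "member_id": m}
        for i, c in enumerate(clusters)
        for m in c.member_ids
    ]
    write_table(pd.DataFrame(rows, columns=["cluster_id", "centroid_id", "member_id"]), path, meta)


def read_cluster_table(path: str | os.PathLike) -> list[OrfCluster]:
    df = read_table(path)
    clusters = []
    for _, grp in df.groupby("cluster_id", sort=True):
        centroid = grp["centroid_id"].iloc[0]
        clusters.append(OrfCluster(centroid, tuple(grp["member_id"])))
    return clusters
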