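"""Ordination of CAZyme repertoires across genomes.

The central object is a count matrix of ORFs per (CAZyme family, secretion
status) column per MAG: a family observed both secreted and nonsecreted
contributes two columns (``GH13__sec``, ``GH13__nonsec``), so secretion
status is part of the repertoire being compared. Distances between MAGs are
``1 - rho`` with Spearman's rank correlation of their count profiles, and
genomes are embedded by classical principal-coordinates analysis (Gower
double-centering followed by eigendecomposition). Negative eigenvalues —
possible because correlation distances need not be Euclidean — are reported
but their axes are dropped, without applying a Cailliez-type correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .model import FunctionAnnotation, Mag

SEC_SUFFIX = "__sec"
NONSEC_SUFFIX = "__nonsec"


def build_cazyme_matrix(
    annotations: dict[str, FunctionAnnotation],
    secretion_labels: dict[str, bool],
    mags: list[Mag],
    drop_singleton_families: bool = False,
) -> pd.DataFrame:
    """Count ORFs per (family, secretion status) column for each MAG.

    With ``drop_singleton_families`` a family (pooled over secretion status)
    present in only one MAG is removed, as done before heatmap ordering.
    All-zero columns never occur by construction.
    """
    counts: dict[str, dict[str, int]] = {m.mag_id: {} for m in mags}
    for mag in mags:
        row = counts[mag.mag_id]
        for orf in mag.orfs:
            ann = annotations.get(orf.orf_id)
            if ann is None or not ann.cazy_families:
                continue
            # ORFs outside the labelled secretome (e.g. in clusters below the
            # size floor) count as nonsecreted
            suffix = SEC_SUFFIX if secretion_labels.get(orf.orf_id, False) else NONSEC_SUFFIX
            for family in ann.cazy_families:
                col = family + suffix
                row[col] = row.get(col, 0) + 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "mag_id"
    if drop_singleton_families and not df.empty:
        base = df.T.groupby(
            df.columns.str.replace(f"{NONSEC_SUFFIX}$", "", regex=True).str.replace(
                f"{SEC_SUFFIX}$", "", regex=True
            )
        ).sum().T
        keep_fams = set(base.columns[(base > 0).sum(axis=0) > 1])
        keep = [
            c
            for c in df.columns
            if c.removesuffix(SEC_SUFFIX).removesuffix(NONSEC_SUFFIX) in keep_fams
        ]
        df = df[keep]
    return df


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance ``1 - rho`` (Spearman) between matrix rows.

    Ties receive average ranks. A constant row has no rank variance and no
    defined correlation; it is reported by name in the error.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    values = matrix.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, values)
    sd = ranks.std(axis=1)
    if (sd == 0).any():
        bad = matrix.index[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"row {bad!r} is constant; Spearman correlation undefined")
    rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class Embedding:
    """PCoA result: coordinates on positive-eigenvalue axes only."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over retained (positive) axes

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def pcoa(distance_matrix: pd.DataFrame, eps: float = 1e-9) -> Embedding:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-D**2/2``, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. Axes with eigenvalues
    <= ``eps`` relative to the largest are dropped; negative eigenvalues
    remain visible in ``eigenvalues``.
    """
    d = distance_matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = eps * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    k = int(positive.sum())
    axes = [f"PCo{i + 1}" for i in range(k)]
    pos_sum = eigval[positive].sum()
    prop = eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(k)
    return Embedding(
        coordinates=pd.DataFrame(coords, index=distance_matrix.index, columns=axes),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def single_linkage_order(matrix: pd.DataFrame, metric: str = "euclidean") -> list:
    """Leaf order of a single-linkage dendrogram over matrix rows.

    Rows are pre-sorted by index so that the result is independent of input
    row order (SciPy breaks merge ties by observation index).
    """
    if len(matrix) < 2:
        return list(matrix.index)
    ordered = matrix.sort_index()
    z = linkage(pdist(ordered.to_numpy(dtype=float), metric=metric), method="single")
    return [ordered.index[i] for i in leaves_list(z)]


def single_linkage_merge_heights(matrix: pd.DataFrame, metric: str = "euclidean") -> np.ndarray:
    """Sorted merge heights of the single-linkage dendrogram (for validation)."""
    z = linkage(pdist(matrix.to_numpy(dtype=float), metric=metric), method="single")
    return np.sort(z[:, 2])


def group_family_profile(
    percent_secreted: pd.DataFrame,
    group_mags: list[str],
    pseudovalue: float = -25.0,
) -> pd.Series:
    """Mean per-family secreted percentage over a group of MAGs.

    ``percent_secreted`` is MAG x family with values in [0, 100] and NaN
    where the MAG does not encode the family; absent families enter the
    mean at ``pseudovalue`` so that non-encoding genomes pull the group
    average down instead of being ignored.
    """
    if not group_mags:
        raise ValueError("empty MAG group")
    missing = set(group_mags) - set(percent_secreted.index)
    if missing:
        raise ValueError(f"MAGs not in table: {sorted(missing)}")
    sub = percent_secreted.loc[list(group_mags)].fillna(pseudovalue)
    return sub.mean(axis=0)
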