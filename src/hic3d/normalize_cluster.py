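"""Iterative-correction balancing and unsupervised sample clustering.

Balancing equalizes bin coverage by iteratively dividing counts by
row/column sums (ICE); clustering builds a feature table of balanced
intra-chromosomal bin-pair contacts at coarse resolution, keeps the
top-variance features, quantile-normalizes samples and applies Ward.D2
agglomeration on the Pearson distance (1 - r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.sparse import coo_matrix

from .core_io import ContactMatrix, ValidationError


def ice_balance(
    matrix: ContactMatrix, max_iter: int = 1000, tol: float = 1e-5
) -> ContactMatrix:
    """Iterative-correction (ICE) balancing of a raw contact matrix.

    Bin biases are updated until the maximum relative deviation of
    unmasked row sums is below ``tol`` (or ``max_iter`` is reached).
    Zero-coverage bins are masked (bias NaN).  Biases are rescaled so the
    balanced matrix total equals the raw total, keeping totals comparable
    across samples.
    """
    if matrix.count.sum() == 0:
        raise ValidationError("nothing to balance: matrix has no contacts")
    n = matrix.bin_table.n_bins
    # symmetric sparse with the diagonal counted once
    off = matrix.row != matrix.col
    sym = coo_matrix(
        (
            np.concatenate([matrix.count, matrix.count[off]]),
            (
                np.concatenate([matrix.row, matrix.col[off]]),
                np.concatenate([matrix.col, matrix.row[off]]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    coverage = np.asarray(sym.sum(axis=1)).ravel()
    unmasked = coverage > 0
    b = np.ones(n)
    inv = np.zeros(n)
    for _ in range(max_iter):
        inv[:] = 0.0
        inv[unmasked] = 1.0 / b[unmasked]
        s = (sym @ inv) * inv
        mean_s = s[unmasked].mean()
        dev = np.max(np.abs(s[unmasked] / mean_s - 1.0))
        if dev < tol:
            break
        b[unmasked] *= s[unmasked] / mean_s
    b = b / b[unmasked].mean()
    balanced = matrix.count / (b[matrix.row] * b[matrix.col])
    scale = matrix.count.sum() / balanced.sum()
    balanced = balanced * scale
    biases = np.where(unmasked, b / np.sqrt(scale), np.nan)
    return ContactMatrix(
        matrix.bin_table,
        matrix.row.copy(),
        matrix.col.copy(),
        balanced,
        balanced=True,
        biases=biases,
    )


@dataclass
class FeatureTable:
    """Bin-pair contact features (rows) by sample (columns)."""

    values: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("feature table contains missing values")


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise quantile normalization against the mean sorted profile.

    Ties receive the mean of the pooled reference quantiles at their
    (average) ranks, so all column distributions become identical.
    """
    ranks = df.rank(method="average").values  # 1-based average ranks
    ref = np.sort(df.values, axis=0).mean(axis=1)
    pos = np.arange(1, len(ref) + 1)
    out = np.empty_like(df.values, dtype=float)
    for j in range(df.shape[1]):
        out[:, j] = np.interp(ranks[:, j], pos, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def build_feature_table(
    samples: Mapping[str, ContactMatrix],
    top_k: int = 20_000,
    balance: bool = True,
) -> FeatureTable:
    """Balanced intra-chromosomal bin-pair features, top-k by variance.

    Features are upper-triangle cis bin pairs nonzero in at least one
    sample; samples must share a bin table.  After selecting the ``top_k``
    highest cross-sample-variance features (ties broken by feature order),
    samples are quantile normalized.
    """
    if len(samples) < 2:
        raise ValidationError("feature table needs at least 2 samples")
    names = sorted(samples)
    bt = samples[names[0]].bin_table
    for name in names[1:]:
        if samples[name].bin_table != bt:
            raise ValidationError("samples must share a bin table")
    columns = {}
    for name in names:
        m = samples[name]
        if balance and not m.balanced:
            m = ice_balance(m)
        cis = m.cis_mask()
        key = m.row[cis] * bt.n_bins + m.col[cis]
        columns[name] = pd.Series(m.count[cis], index=key)
    df = pd.DataFrame(columns).fillna(0.0)
    df = df.sort_index()
    var = df.var(axis=1, ddof=1).values
    order = np.argsort(-var, kind="stable")[: min(top_k, len(df))]
    kept = df.iloc[np.sort(order)]
    normed = quantile_normalize(kept)
    bins = kept.index.values
    feat_ids = [
        f"{bt.location(int(k // bt.n_bins)).chrom}:"
        f"{int(k // bt.n_bins)}-{int(k % bt.n_bins)}"
        for k in bins
    ]
    normed.index = feat_ids
    return FeatureTable(
        normed,
        provenance={
            "resolution": bt.resolution,
            "top_k": top_k,
            "n_candidate_features": int(len(df)),
            "normalization": "ICE + quantile",
        },
    )


@dataclass
class ClusterResult:
    """Ward.D2 dendrogram over samples with cut labels on demand."""

    linkage: np.ndarray
    samples: list[str]
    distances: pd.DataFrame

    def labels(self, k: int) -> pd.Series:
        lab = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(lab, index=self.samples)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(tree, tree.dist) + ";"


def hierarchical_cluster(features: FeatureTable) -> ClusterResult:
    """Cluster samples on 1 - Pearson correlation with Ward.D2 linkage."""
    df = features.values
    if df.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    stds = df.std(axis=0, ddof=0)
    zero = [s for s in df.columns if stds[s] == 0]
    if zero:
        raise ValidationError(
            f"zero-variance sample(s) {zero}: Pearson distance undefined"
        )
    corr = np.corrcoef(df.values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return ClusterResult(
        linkage=z,
        samples=list(df.columns),
        distances=pd.DataFrame(dist, index=df.columns, columns=df.columns),
    )
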