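"""Significant-contact (loop) calling against a distance-decay null.

The null model assigns every candidate bin pair a contact probability from
an equal-occupancy, isotonically smoothed distance-decay fit; observed
counts are then tested with a binomial tail over the matrix total, followed
by Benjamini-Hochberg correction.  Cross-sample merging keeps, for loops
sharing both anchors, the single call with the strongest evidence.
Differential testing between groups uses a conditional binomial on
normalized summed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .core_io import ContactMatrix, Loop, ValidationError


@dataclass
class DecayModel:
    """Expected per-pair contact probability as a function of cis distance.

    Probabilities are constant within equal-occupancy distance strata,
    non-increasing across strata after isotonic smoothing, and normalized
    so that summing p(d) over every candidate pair gives 1.
    """

    stratum_edges: np.ndarray  # distance (bins), len S+1, half-open strata
    stratum_midpoints: np.ndarray
    p_pair: np.ndarray  # per-pair probability per stratum
    n_pairs: np.ndarray  # candidate pairs per stratum
    total_count: float  # observed count within the candidate universe
    min_dist_bins: int
    max_dist_bins: int
    resolution: int

    def expected_p(self, d_bins: np.ndarray | int) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d_bins))
        idx = np.searchsorted(self.stratum_edges[1:-1], d, side="right")
        out = self.p_pair[idx]
        return out if np.ndim(d_bins) else float(out[0])

    @property
    def n_candidate_pairs(self) -> int:
        return int(self.n_pairs.sum())


def _cis_distances(matrix: ContactMatrix):
    """(distance in bins, count) for cis entries, plus per-chrom bin counts."""
    bt = matrix.bin_table
    ci_r = bt.chrom_index_of_bins(matrix.row)
    ci_c = bt.chrom_index_of_bins(matrix.col)
    cis = ci_r == ci_c
    d = (matrix.col - matrix.row)[cis]
    return d, matrix.count[cis], cis


def _pairs_per_distance(matrix: ContactMatrix, dmax: int) -> np.ndarray:
    """Number of candidate cis pairs at each distance 0..dmax."""
    bt = matrix.bin_table
    n_per = np.array([bt.n_bins_chrom(c) for c in bt.assembly.chrom_names])
    d = np.arange(dmax + 1)
    return np.maximum(n_per[:, None] - d[None, :], 0).sum(axis=0)


def fit_distance_decay(
    matrix: ContactMatrix,
    max_dist: float = 5e7,
    n_occupancy_bins: int = 100,
    min_dist_bins: int = 2,
) -> DecayModel:
    """Fit the distance-decay null on cis contacts within ``max_dist``.

    Pairs are stratified into (approximately) equal-occupancy distance
    strata; each stratum's per-pair probability is its count share divided
    by its candidate-pair count, smoothed to be non-increasing by isotonic
    regression and renormalized over the candidate universe.
    """
    res = matrix.bin_table.resolution
    max_dist_bins = int(max_dist // res)
    d, cnt, _ = _cis_distances(matrix)
    keep = (d >= min_dist_bins) & (d <= max_dist_bins)
    d, cnt = d[keep], cnt[keep]
    if d.size == 0:
        raise ValidationError("no cis entries within the distance range")
    cnt_per_d = np.bincount(d, weights=cnt, minlength=max_dist_bins + 1)
    total = cnt_per_d.sum()
    # equal-occupancy stratum edges over distances [min_dist_bins, max_dist_bins]
    dist_grid = np.arange(min_dist_bins, max_dist_bins + 1)
    cum = np.cumsum(cnt_per_d[min_dist_bins:])
    targets = total * np.arange(1, n_occupancy_bins) / n_occupancy_bins
    cut_idx = np.unique(np.searchsorted(cum, targets, side="left"))
    cut_idx = cut_idx[cut_idx < len(dist_grid) - 1]
    edges = np.concatenate(
        [[min_dist_bins], dist_grid[cut_idx + 1], [max_dist_bins + 1]]
    )
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValidationError("fewer than 2 occupancy strata; matrix too sparse")
    pairs_per_d = _pairs_per_distance(matrix, max_dist_bins)
    c_s = np.array(
        [cnt_per_d[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]
    )
    n_s = np.array(
        [pairs_per_d[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]
    )
    if (n_s == 0).any():
        keep_s = n_s > 0
        c_s, n_s = c_s[keep_s], n_s[keep_s]
        edges = np.concatenate([edges[:-1][keep_s], [edges[-1]]])
    if (c_s > 0).sum() < 2:
        raise ValidationError("fewer than 2 occupied strata; matrix too sparse")
    # representative distance: count-weighted mean distance per stratum
    dsum = np.cumsum(cnt_per_d * np.arange(len(cnt_per_d)))
    csum = np.cumsum(cnt_per_d)

    def seg(c, a, b):
        return c[b - 1] - (c[a - 1] if a > 0 else 0)

    mid = np.array(
        [
            seg(dsum, a, b) / seg(csum, a, b)
            if seg(csum, a, b) > 0
            else (a + b - 1) / 2.0
            for a, b in zip(edges[:-1], edges[1:])
        ]
    )
    p_raw = (c_s / total) / n_s
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    p_fit = iso.fit_transform(mid, p_raw, sample_weight=n_s)
    p_fit = np.maximum(p_fit, 1e-300)
    p_fit = p_fit / float(np.sum(p_fit * n_s))
    return DecayModel(
        stratum_edges=edges,
        stratum_midpoints=mid,
        p_pair=p_fit,
        n_pairs=n_s,
        total_count=float(total),
        min_dist_bins=min_dist_bins,
        max_dist_bins=max_dist_bins,
        resolution=res,
    )


def call_loops(
    matrix: ContactMatrix,
    decay: DecayModel,
    min_dist_bins: int = 2,
    alpha_q: float = 0.05,
    p_max: float = 0.01,
    sample_id: str = ".",
) -> list[Loop]:
    """Call loops: binomial tail of observed counts vs the decay null.

    For each candidate cis pair (observed count >= 1 within the decay
    model's distance range), p = P(X >= observed) with
    X ~ Binomial(N_total, p(d)).  Benjamini-Hochberg q-values are computed
    over all tested pairs; a loop must pass both the raw-p filter
    (``p_max``, default 0.01) and ``q <= alpha_q``.
    """
    if matrix.bin_table.resolution != decay.resolution:
        raise ValidationError("decay model fitted at a different resolution")
    bt = matrix.bin_table
    d_all, cnt_all, cis_mask = _cis_distances(matrix)
    keep = (
        (d_all >= max(min_dist_bins, decay.min_dist_bins))
        & (d_all <= decay.max_dist_bins)
        & (cnt_all >= 1)
    )
    rows = matrix.row[cis_mask][keep]
    cols = matrix.col[cis_mask][keep]
    obs = cnt_all[keep]
    d = d_all[keep]
    if obs.size == 0:
        return []
    n_total = int(round(decay.total_count))
    if (obs > n_total).any():
        raise ValidationError("observed count exceeds matrix total")
    p_d = decay.expected_p(d)
    pvals = stats.binom.sf(np.round(obs).astype(np.int64) - 1, n_total, p_d)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    sel = (pvals <= p_max) & (qvals <= alpha_q)
    loops = [
        Loop(
            bt.location(int(i)),
            bt.location(int(j)),
            observed=float(o),
            expected_p=float(ep),
            p_value=float(p),
            q_value=float(q),
            sample_id=sample_id,
        )
        for i, j, o, ep, p, q in zip(
            rows[sel], cols[sel], obs[sel], p_d[sel], pvals[sel], qvals[sel]
        )
    ]
    loops.sort(key=lambda lp: lp.anchor_key())
    return loops


def loop_pvalues(
    matrix: ContactMatrix, decay: DecayModel, min_dist_bins: int = 2
) -> pd.DataFrame:
    """Per-candidate-pair p-values (no thresholding) for diagnostics."""
    d_all, cnt_all, cis_mask = _cis_distances(matrix)
    keep = (
        (d_all >= max(min_dist_bins, decay.min_dist_bins))
        & (d_all <= decay.max_dist_bins)
        & (cnt_all >= 1)
    )
    obs = cnt_all[keep]
    d = d_all[keep]
    n_total = int(round(decay.total_count))
    p_d = decay.expected_p(d)
    pvals = np.clip(
        stats.binom.sf(np.round(obs).astype(np.int64) - 1, n_total, p_d), 0, 1
    )
    return pd.DataFrame(
        {
            "row": matrix.row[cis_mask][keep],
            "col": matrix.col[cis_mask][keep],
            "distance_bins": d,
            "observed": obs,
            "expected_p": p_d,
            "p_value": pvals,
        }
    )


def merge_group_loops(per_sample: Mapping[str, Sequence[Loop]]) -> list[Loop]:
    """Merge per-sample loop lists into one group list.

    Loops are identical iff both anchor bin pairs match exactly.  For a
    repeated loop only the call with the smallest p-value (ties broken by
    smallest sample id) represents the group; unique loops pass through
    unchanged.
    """
    widths = {
        len(lp.anchor1)
        for loops in per_sample.values()
        for lp in loops
    }
    if len(widths) > 1:
        raise ValidationError(f"mixed anchor resolutions: {sorted(widths)}")
    best: dict[tuple, Loop] = {}
    for sample in sorted(per_sample):
        for lp in per_sample[sample]:
            key = lp.anchor_key()
            cur = best.get(key)
            if cur is None or (lp.p_value, lp.sample_id) < (
                cur.p_value,
                cur.sample_id,
            ):
                best[key] = lp
    return sorted(best.values(), key=lambda lp: lp.anchor_key())


def differential_loops(
    group_a: Mapping[str, Mapping[tuple, float]],
    group_b: Mapping[str, Mapping[tuple, float]],
    totals: Mapping[str, float] | None = None,
    alpha_adj: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential test of loop strength.

    Per-sample counts at shared anchors are normalized by per-sample totals,
    summed within groups and compared with a conditional two-sided binomial
    test on the group split of the summed normalized counts; q-values are
    Benjamini-Hochberg adjusted and a loop is significant iff
    ``q <= alpha_adj``.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups need at least one sample")
    samples_a, samples_b = sorted(group_a), sorted(group_b)
    if totals is None:
        totals = {
            s: sum(cnts.values()) or 1.0
            for s, cnts in {**group_a, **group_b}.items()
        }
    ref = float(np.mean([totals[s] for s in samples_a + samples_b]))
    keys = sorted(
        {k for cnts in list(group_a.values()) + list(group_b.values()) for k in cnts}
    )
    rows = []
    for key in keys:
        ka = sum(
            group_a[s].get(key, 0.0) * ref / totals[s] for s in samples_a
        )
        kb = sum(
            group_b[s].get(key, 0.0) * ref / totals[s] for s in samples_b
        )
        if ka + kb == 0:
            warnings.warn(f"loop {key} absent from all samples; dropped")
            continue
        n = int(round(ka + kb))
        k = int(round(ka))
        pi = len(samples_a) / (len(samples_a) + len(samples_b))
        p = stats.binomtest(min(k, n), n, pi).pvalue if n > 0 else 1.0
        rate_a = ka / len(samples_a)
        rate_b = kb / len(samples_b)
        lfc = float(np.log2((rate_a + 0.5) / (rate_b + 0.5)))
        rows.append((key, ka, kb, lfc, p))
    if not rows:
        return pd.DataFrame(
            columns=["loop", "count_a", "count_b", "log2fc", "p_value",
                     "q_value", "direction", "significant"]
        ).set_index("loop")
    df = pd.DataFrame(
        rows, columns=["loop", "count_a", "count_b", "log2fc", "p_value"]
    ).set_index("loop")
    _, q, _, _ = multipletests(df["p_value"].values, method="fdr_bh")
    df["q_value"] = q
    df["direction"] = np.where(df["log2fc"] >= 0, "A", "B")
    df["significant"] = df["q_value"] <= alpha_adj
    return df
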