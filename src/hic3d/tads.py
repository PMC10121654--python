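"""TAD calling from the diamond (binSignal) statistic.

For each bin the mean contact frequency in the w x w diamond straddling it
(upstream window x downstream window) is computed; boundaries are smoothed
local minima of that track that pass a rank-sum comparison of the diamond
entries against the flanking within-window entries.  An insulation-score
track (log2 diamond mean over the chromosome-wide mean) is also provided
for structural-variant screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BinTable, ContactMatrix, GenomicInterval, TAD, ValidationError


@dataclass
class BinSignalTrack:
    """Per-bin diamond-mean values over the genome-wide bin index.

    Bins without at least one bin on each side (chromosome ends) are NaN.
    ``boundary_p`` holds adjusted boundary p-values at detected boundary
    bins (NaN elsewhere).
    """

    bin_table: BinTable
    values: np.ndarray
    w: int
    boundary_p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.boundary_p is None:
            self.boundary_p = np.full(self.bin_table.n_bins, np.nan)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bin_table.chrom_slice(chrom)]


def _diamond_bounds(i: int, n: int, w: int) -> tuple[int, int, int, int]:
    """Clipped upstream/downstream window bounds for the diamond at bin i."""
    u0 = max(0, i - w + 1)
    u1 = i + 1
    d0 = i + 1
    d1 = min(n, i + 1 + w)
    return u0, u1, d0, d1


def binsignal(matrix: ContactMatrix, w: int = 5) -> BinSignalTrack:
    """Mean contact frequency in the w x w diamond at every bin.

    The diamond at bin i covers pairs (u, d) with u in [i-w+1, i] and
    d in [i+1, i+w], clipped at chromosome ends; missing pairs count as 0.
    """
    if w < 1:
        raise ValidationError("window w must be >= 1")
    bt = matrix.bin_table
    values = np.full(bt.n_bins, np.nan)
    for chrom in bt.assembly.chrom_names:
        sl = bt.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n < 2:
            continue
        dense = matrix.cis_dense(chrom)
        # integral image for O(1) rectangle sums
        s = np.zeros((n + 1, n + 1))
        s[1:, 1:] = dense.cumsum(axis=0).cumsum(axis=1)
        for i in range(n - 1):
            u0, u1, d0, d1 = _diamond_bounds(i, n, w)
            total = s[u1, d1] - s[u0, d1] - s[u1, d0] + s[u0, d0]
            area = (u1 - u0) * (d1 - d0)
            values[sl.start + i] = total / area
    return BinSignalTrack(bt, values, w)


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Width-3 running mean with shrunken edge windows; NaN-aware."""
    out = np.full_like(x, np.nan, dtype=float)
    for i in range(len(x)):
        window = x[max(0, i - 1): i + 2]
        good = window[~np.isnan(window)]
        if good.size:
            out[i] = good.mean()
    return out


def _oe_normalize(dense: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean: removes the distance-decay trend
    so diamond-vs-flank comparisons are not biased by pair distance."""
    n = dense.shape[0]
    out = dense.astype(float).copy()
    for d in range(n):
        diag = np.diagonal(dense, offset=d)
        mean = diag.mean()
        if mean > 0:
            idx = np.arange(n - d)
            out[idx, idx + d] = dense[idx, idx + d] / mean
            out[idx + d, idx] = out[idx, idx + d]
    return out


def _flank_entries(dense: np.ndarray, i: int, n: int, w: int) -> np.ndarray:
    """Within-window upper-triangle entries on both sides of bin i."""
    u0, u1, d0, d1 = _diamond_bounds(i, n, w)
    vals = []
    for a, b in ((u0, u1), (d0, d1)):
        block = dense[a:b, a:b]
        iu = np.triu_indices(b - a, k=1)
        if iu[0].size:
            vals.append(block[iu])
    return np.concatenate(vals) if vals else np.array([])


def detect_boundaries(
    track: BinSignalTrack,
    matrix: ContactMatrix,
    alpha: float = 0.05,
) -> np.ndarray:
    """Detect TAD boundaries as filtered local minima of the diamond track.

    Candidates are local minima of the width-3 smoothed signal; each is
    tested by a one-sided rank-sum comparison of its diamond entries versus
    the pooled flanking within-window entries, after dividing every entry
    by its diagonal (distance) mean so the comparison is not confounded by
    distance decay.  Candidates with BH-adjusted p <= alpha are kept,
    enforcing a minimum spacing of w bins (the deeper minimum wins on
    conflict).

    Returns global bin indices of domain junctions: a boundary at index b
    means the split lies between bins b-1 and b.
    """
    bt = track.bin_table
    w = track.w
    cand_idx: list[int] = []
    cand_depth: list[float] = []
    pvals: list[float] = []
    for chrom in bt.assembly.chrom_names:
        sl = bt.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n < 3:
            continue
        sig = track.values[sl]
        smooth = _smooth3(sig)
        dense = _oe_normalize(matrix.cis_dense(chrom))
        for i in range(1, n - 1):
            if np.isnan(smooth[i - 1]) or np.isnan(smooth[i]) or np.isnan(smooth[i + 1]):
                continue
            if not (smooth[i] < smooth[i - 1] and smooth[i] <= smooth[i + 1]):
                continue
            u0, u1, d0, d1 = _diamond_bounds(i, n, w)
            diamond = dense[u0:u1, d0:d1].ravel()
            flank = _flank_entries(dense, i, n, w)
            if diamond.size == 0 or flank.size == 0:
                continue
            if np.ptp(np.concatenate([diamond, flank])) == 0:
                p = 1.0
            else:
                p = stats.mannwhitneyu(diamond, flank, alternative="less").pvalue
            cand_idx.append(sl.start + i)
            cand_depth.append(smooth[i])
            pvals.append(float(p))
    if not cand_idx:
        return np.array([], dtype=np.int64)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    keep = [
        (idx, depth, q)
        for idx, depth, q in zip(cand_idx, cand_depth, qvals)
        if q <= alpha
    ]
    # enforce minimum spacing of w bins; deeper (lower) minimum wins
    keep.sort(key=lambda t: (t[1], t[0]))
    chosen: list[tuple[int, float]] = []
    for idx, depth, q in keep:
        if all(abs(idx - c) >= w for c, _ in chosen):
            chosen.append((idx, q))
    chosen.sort()
    track.boundary_p[:] = np.nan
    for idx, q in chosen:
        track.boundary_p[idx] = q
    # report the junction (first bin of the downstream domain)
    return np.array([idx + 1 for idx, _ in chosen], dtype=np.int64)


def tads_from_boundaries(
    boundaries: np.ndarray, bin_table: BinTable, min_bins: int = 2
) -> list[TAD]:
    """Partition chromosomes into TADs at the given junction bin indices.

    Consecutive boundaries (and chromosome ends) delimit TADs; stretches
    shorter than ``min_bins`` bins are left unorganized (excluded).
    """
    boundaries = np.sort(np.asarray(boundaries, dtype=np.int64))
    out: list[TAD] = []
    for chrom in bin_table.assembly.chrom_names:
        sl = bin_table.chrom_slice(chrom)
        inner = boundaries[(boundaries > sl.start) & (boundaries < sl.stop)]
        edges = [sl.start, *inner.tolist(), sl.stop]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < min_bins:
                continue
            start = bin_table.location(a).start
            end = bin_table.location(b - 1).end
            out.append(TAD(GenomicInterval(chrom, start, end)))
    return out


def call_tads(
    matrix: ContactMatrix, w: int = 5, alpha: float = 0.05, min_bins: int = 2
) -> list[TAD]:
    """binSignal -> boundary detection -> TAD partition, in one call."""
    track = binsignal(matrix, w=w)
    boundaries = detect_boundaries(track, matrix, alpha=alpha)
    return tads_from_boundaries(boundaries, matrix.bin_table, min_bins=min_bins)


def insulation_score(matrix: ContactMatrix, window: int = 5) -> np.ndarray:
    """Per-bin log2 ratio of the diamond mean to its chromosome-wide mean.

    Minima mark insulating boundaries.  Invariant to global scaling of the
    matrix.  Bins undefined for the diamond statistic are NaN; zero diamond
    means map to -inf.
    """
    track = binsignal(matrix, w=window)
    bt = matrix.bin_table
    score = np.full(bt.n_bins, np.nan)
    for chrom in bt.assembly.chrom_names:
        sl = bt.chrom_slice(chrom)
        vals = track.values[sl]
        good = ~np.isnan(vals)
        if not good.any():
            continue
        mean = vals[good].mean()
        if mean == 0:
            raise ValidationError(f"zero chromosome-wide diamond mean on {chrom}")
        with np.errstate(divide="ignore"):
            score[sl.start: sl.stop][good] = np.log2(vals[good] / mean)
    return score
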