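"""Loop-mediated enhancer-gene association and insulator-dysfunction genes.

Genes (by TSS window) and enhancers (by overlap) are assigned to a 5 kb
bin grid and linked through significant loops; the expression advantage of
loop-connected genes is assessed with a bootstrap resampling test and
gene-enhancer pairs are filtered by expression/activity correlation.
Separately, differential CTCF occupancy is intersected with differentially
methylated regions to find insulators replaced by hypermethylation, and
candidate genes are emitted when such a site lies inside a loop that wires
a differentially expressed gene to an enhancer or super-enhancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    BinTable,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    Loop,
    MethylationProfile,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Bin assignment and loop linking
# ---------------------------------------------------------------------------

@dataclass
class BinAssignment:
    """Gene/enhancer membership per global bin index on a fixed grid."""

    bin_table: BinTable
    gene_bins: dict[int, list[str]]
    enhancer_bins: dict[int, list[str]]
    tss_window: int


def assign_bins(
    genes: Sequence[GeneAnnotation],
    enhancers: Mapping[str, GenomicInterval],
    bin_table: BinTable,
    tss_window: int = 2_500,
) -> BinAssignment:
    """Assign genes (TSS +/- window) and enhancers (overlap) to bins."""
    res = bin_table.resolution
    gene_bins: dict[int, list[str]] = {}
    enh_bins: dict[int, list[str]] = {}

    def bins_over(chrom: str, start: int, end: int) -> range:
        off = bin_table.chrom_offset(chrom)
        n = bin_table.n_bins_chrom(chrom)
        lo = max(start, 0) // res
        hi = min(-(-end // res), n)
        return range(off + lo, off + hi)

    for gene in genes:
        start = gene.tss - tss_window
        end = gene.tss + tss_window
        for b in bins_over(gene.chrom, start, end):
            gene_bins.setdefault(b, []).append(gene.gene_id)
    for eid in sorted(enhancers):
        iv = enhancers[eid]
        for b in bins_over(iv.chrom, iv.start, iv.end):
            enh_bins.setdefault(b, []).append(eid)
    return BinAssignment(bin_table, gene_bins, enh_bins, tss_window)


@dataclass(frozen=True)
class EAGRecord:
    """A gene linked to a partner (enhancer or gene) through a loop."""

    gene_id: str
    partner_id: str
    partner_type: str  # "enhancer" | "gene"
    loop: Loop
    supported_by_loop: bool = True
    r: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isnan(self.r) or -1.0 <= self.r <= 1.0):
            raise ValidationError("correlation r must lie in [-1, 1]")


def _features_at_anchor(
    assignment: BinAssignment, anchor: GenomicInterval
) -> tuple[list[str], list[str]]:
    """Genes/enhancers at the anchor bin, else at the nearest nonempty
    adjacent bin (+/- 1; both sides if both are nonempty)."""
    bt = assignment.bin_table
    mid = anchor.start + len(anchor) // 2
    b = bt.bin_index(anchor.chrom, mid)
    sl = bt.chrom_slice(anchor.chrom)

    def at(bb: int) -> tuple[list[str], list[str]]:
        return (
            assignment.gene_bins.get(bb, []),
            assignment.enhancer_bins.get(bb, []),
        )

    genes, enhs = at(b)
    if genes or enhs:
        return genes, enhs
    genes, enhs = [], []
    for bb in (b - 1, b + 1):
        if sl.start <= bb < sl.stop:
            g, e = at(bb)
            genes.extend(g)
            enhs.extend(e)
    return genes, enhs


def link_eags(
    merged_loops: Sequence[Loop], assignment: BinAssignment
) -> list[EAGRecord]:
    """Emit gene-enhancer and gene-gene records for loop anchor pairs.

    A record is emitted when one anchor carries a gene TSS and the other a
    partner feature; empty anchor bins fall back to the nearest nonempty
    adjacent bin.
    """
    res = assignment.bin_table.resolution
    records: dict[tuple, EAGRecord] = {}
    for lp in merged_loops:
        if len(lp.anchor1) > res or len(lp.anchor2) > res:
            raise ValidationError("loop anchors are wider than the bin grid")
        g1, e1 = _features_at_anchor(assignment, lp.anchor1)
        g2, e2 = _features_at_anchor(assignment, lp.anchor2)
        for ga, partners in ((g1, (g2, e2)), (g2, (g1, e1))):
            for gene in ga:
                for pid in partners[1]:
                    key = (gene, pid, "enhancer", lp.anchor_key())
                    records.setdefault(
                        key, EAGRecord(gene, pid, "enhancer", lp)
                    )
                for pid in partners[0]:
                    if pid == gene:
                        continue
                    key = (gene, pid, "gene", lp.anchor_key())
                    records.setdefault(key, EAGRecord(gene, pid, "gene", lp))
    return [records[k] for k in sorted(records)]


# ---------------------------------------------------------------------------
# Bootstrap expression test and correlation filter
# ---------------------------------------------------------------------------

def bootstrap_expression_test(
    expr: ExpressionMatrix,
    connected_genes: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Are loop-connected genes expressed higher than unconnected ones?

    The observed statistic is the difference of mean expression,
    connected minus unconnected.  Each bootstrap draws a random
    unconnected gene set of the same size and computes its mean difference
    against the remaining unconnected genes; the one-sided empirical p is
    (1 + #{boot >= observed}) / (n_boot + 1).
    """
    connected = sorted(set(connected_genes))
    all_genes = list(expr.values.index)
    if not connected:
        raise ValidationError("connected gene set is empty")
    unknown = set(connected) - set(all_genes)
    if unknown:
        raise ValidationError(f"unknown connected genes: {sorted(unknown)}")
    unconnected = [g for g in all_genes if g not in set(connected)]
    if not unconnected:
        raise ValidationError("connected set covers all genes")
    per_gene = expr.values.mean(axis=1)
    observed = float(per_gene[connected].mean() - per_gene[unconnected].mean())
    rng = np.random.default_rng(seed)
    pool = per_gene[unconnected].values
    m = len(connected)
    stats_boot = np.empty(n_boot)
    total = pool.sum()
    npool = len(pool)
    for b in range(n_boot):
        idx = rng.choice(npool, size=m, replace=False)
        s = pool[idx].sum()
        rest_mean = (total - s) / (npool - m) if npool > m else np.nan
        stats_boot[b] = s / m - rest_mean
    p = (1.0 + np.sum(stats_boot >= observed)) / (n_boot + 1.0)
    return observed, float(p)


def correlation_filter(
    records: Sequence[EAGRecord],
    expr: ExpressionMatrix,
    enhancer_activity: pd.DataFrame,
    min_r: float = 0.5,
) -> tuple[list[EAGRecord], list[tuple[EAGRecord, str]]]:
    """Keep records whose gene/partner Pearson correlation is >= min_r.

    Correlations are computed over the samples shared by the expression
    matrix and the activity table (>= 3 required).  Zero-variance vectors
    drop the record with a reason.  Returns (kept, dropped-with-reason).
    """
    shared = [s for s in expr.values.columns if s in enhancer_activity.columns]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples for correlation")
    kept: list[EAGRecord] = []
    dropped: list[tuple[EAGRecord, str]] = []
    for rec in records:
        if rec.gene_id not in expr.values.index:
            dropped.append((rec, "gene missing from expression"))
            continue
        x = expr.values.loc[rec.gene_id, shared].values.astype(float)
        if rec.partner_type == "enhancer":
            if rec.partner_id not in enhancer_activity.index:
                dropped.append((rec, "enhancer missing from activity"))
                continue
            y = enhancer_activity.loc[rec.partner_id, shared].values.astype(float)
        else:
            if rec.partner_id not in expr.values.index:
                dropped.append((rec, "partner gene missing from expression"))
                continue
            y = expr.values.loc[rec.partner_id, shared].values.astype(float)
        if x.std() == 0 or y.std() == 0:
            dropped.append((rec, "zero-variance vector"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r >= min_r:
            kept.append(replace(rec, r=r))
        else:
            dropped.append((replace(rec, r=r), f"r={r:.3f} < {min_r}"))
    return kept, dropped


# ---------------------------------------------------------------------------
# Differential CTCF occupancy and DMRs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialSite:
    """A consensus site with group contrast of signal and/or methylation."""

    interval: GenomicInterval
    log2fc: float  # group A minus group B, log2 normalized counts
    p_value: float
    q_value: float
    is_differential: bool
    delta_beta: float = float("nan")
    meth_q: float = float("nan")
    classification: str = "unchanged"  # hyper_lost_A | hyper_lost_B | unchanged


def differential_ctcf_sites(
    sites: Sequence[GenomicInterval],
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    p_max: float = 0.1,
    lfc_min: float = 0.5,
) -> list[DifferentialSite]:
    """Differential CTCF occupancy between two groups.

    Library-size-normalized log2 counts are compared per site with a
    two-sample (Welch) t test; a site is differential iff p <= p_max and
    |log2FC| >= lfc_min.  Sites with zero counts in every sample are
    dropped.
    """
    sa = [s for s in counts.columns if groups[s] == group_a]
    sb = [s for s in counts.columns if groups[s] == group_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("need >= 2 samples per group")
    libsize = counts.sum(axis=0)
    norm = counts * libsize.mean() / libsize
    log = np.log2(norm + 1.0)
    keep_rows = counts.sum(axis=1).values > 0
    pvals, lfcs, rows = [], [], []
    for i, site in enumerate(sites):
        if not keep_rows[i]:
            warnings.warn(f"site {i} has no counts in any sample; dropped")
            continue
        xa = log.iloc[i][sa].values
        xb = log.iloc[i][sb].values
        lfc = float(xa.mean() - xb.mean())
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            p = 1.0 if lfc == 0 else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        pvals.append(p)
        lfcs.append(lfc)
        rows.append(site)
    if not rows:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        DifferentialSite(
            interval=site,
            log2fc=lfc,
            p_value=p,
            q_value=float(q),
            is_differential=(p <= p_max and abs(lfc) >= lfc_min),
        )
        for site, lfc, p, q in zip(rows, lfcs, pvals, qvals)
    ]


@dataclass(frozen=True)
class DMR:
    """Differentially methylated region over consecutive CpGs."""

    interval: GenomicInterval
    delta_beta: float  # group A minus group B mean beta
    n_cpgs: int
    p_value: float
    q_value: float


def _group_mean_betas(profiles: Sequence[MethylationProfile]) -> pd.Series:
    frames = [
        p.data.set_index(["chrom", "pos"])["beta"] for p in profiles
    ]
    return pd.concat(frames, axis=1).mean(axis=1)


def call_dmrs(
    group_a: Sequence[MethylationProfile],
    group_b: Sequence[MethylationProfile],
    min_cpgs: int = 10,
    min_diff: float = 0.1,
    q_max: float = 0.05,
) -> list[DMR]:
    """Sliding-segment DMR detection between two sample groups.

    Maximal runs of >= min_cpgs consecutive shared CpGs whose per-CpG
    group-mean difference keeps one sign and magnitude >= min_diff form
    candidate segments; each is tested with a signed-rank test of the
    per-CpG differences, BH-adjusted, and emitted when q <= q_max.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups need at least one profile")
    mean_a = _group_mean_betas(group_a)
    mean_b = _group_mean_betas(group_b)
    shared = mean_a.index.intersection(mean_b.index)
    if shared.empty:
        raise ValidationError("no shared CpGs between groups")
    delta = (mean_a[shared] - mean_b[shared]).reset_index()
    delta.columns = ["chrom", "pos", "delta"]
    delta = delta.sort_values(["chrom", "pos"]).reset_index(drop=True)
    segments: list[tuple[str, np.ndarray, np.ndarray]] = []
    for chrom, grp in delta.groupby("chrom", sort=True):
        d = grp["delta"].values
        pos = grp["pos"].values
        sign = np.sign(d) * (np.abs(d) >= min_diff)
        start = 0
        for i in range(1, len(d) + 1):
            if i == len(d) or sign[i] != sign[start] or sign[i] == 0:
                if sign[start] != 0 and i - start >= min_cpgs:
                    segments.append((chrom, pos[start:i], d[start:i]))
                start = i
    if not segments:
        return []
    pvals = []
    for _, _, d in segments:
        try:
            pvals.append(float(stats.wilcoxon(d, alternative="two-sided").pvalue))
        except ValueError:
            pvals.append(1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        DMR(
            GenomicInterval(chrom, int(pos[0]), int(pos[-1]) + 1),
            delta_beta=float(d.mean()),
            n_cpgs=len(d),
            p_value=p,
            q_value=float(q),
        )
        for (chrom, pos, d), p, q in zip(segments, pvals, qvals)
        if q <= q_max
    ]
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def overlap_dmr_ctcf(
    dmrs: Sequence[DMR], ctcf_sites: Sequence[DifferentialSite]
) -> tuple[list[tuple[DMR, DifferentialSite, str]], dict[str, int]]:
    """Intersect DMRs with differential CTCF sites (>= 1 bp overlap).

    Each overlapping pair is classified: ``hyper_lost_A`` when group A is
    hypermethylated (delta beta > 0) and has lower CTCF occupancy
    (log2FC < 0); ``hyper_lost_B`` symmetrically; ``unchanged`` otherwise.
    Returns the pair list and per-class counts.
    """
    pairs: list[tuple[DMR, DifferentialSite, str]] = []
    counts = {"hyper_lost_A": 0, "hyper_lost_B": 0, "unchanged": 0}
    for dmr in dmrs:
        for site in ctcf_sites:
            if not site.is_differential:
                continue
            if dmr.interval.overlap_len(site.interval) < 1:
                continue
            if dmr.delta_beta > 0 and site.log2fc < 0:
                cls = "hyper_lost_A"
            elif dmr.delta_beta < 0 and site.log2fc > 0:
                cls = "hyper_lost_B"
            else:
                cls = "unchanged"
            counts[cls] += 1
            pairs.append((dmr, site, cls))
    return pairs, counts


# ---------------------------------------------------------------------------
# Candidate-gene selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateGene:
    """A gene implicated by insulator loss inside one of its loops."""

    gene_id: str
    route: str  # "eag_loop" | "super_enhancer"
    site: GenomicInterval
    loop: Loop
    flags: tuple[tuple[str, bool], ...]

    @property
    def all_flags_true(self) -> bool:
        return all(v for _, v in self.flags)


def _loop_span(loop: Loop) -> GenomicInterval:
    return GenomicInterval(
        loop.anchor1.chrom,
        min(loop.anchor1.start, loop.anchor2.start),
        max(loop.anchor1.end, loop.anchor2.end),
    )


def _de_table(
    expr: ExpressionMatrix, target_group: str
) -> pd.DataFrame:
    """Per-gene Welch t test of log2 expression, target group vs rest."""
    target = expr.samples_in_group(target_group)
    rest = [s for s in expr.values.columns if s not in target]
    if len(target) < 2 or len(rest) < 2:
        raise ValidationError("need >= 2 samples per side for the DE test")
    log = np.log2(expr.values + 1.0)
    xa = log[target].values
    xb = log[rest].values
    t = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2fc": diff,
            "p_value": pvals,
            "q_value": qvals,
            "target_mean_expr": expr.values[target].mean(axis=1).values,
        },
        index=expr.values.index,
    )


def insulator_candidates(
    pairs: Sequence[tuple[DMR, DifferentialSite, str]],
    merged_loops: Sequence[Loop],
    eag_records: Sequence[EAGRecord],
    super_enhancers: Sequence[GenomicInterval],
    assignment: BinAssignment,
    expr: ExpressionMatrix,
    target_group: str,
    target_class: str = "hyper_lost_A",
    de_q_max: float = 0.05,
    min_expr: float = 1.0,
    include_rejected: bool = False,
) -> list[CandidateGene] | tuple[list[CandidateGene], list[CandidateGene]]:
    """Genes whose loops span an insulator lost to hypermethylation.

    Route ``eag_loop``: a hyper-lost site lies within the span of a loop
    backing an enhancer-gene record, and the gene is group-specifically
    upregulated (q <= de_q_max, higher mean in the target group) with mean
    target-group expression >= min_expr.  Route ``super_enhancer``: one
    loop anchor overlaps a super-enhancer, the span covers a hyper-lost
    site, and the other anchor carries a gene TSS passing the same DE
    filter.
    """
    lost_sites = [site.interval for _, site, cls in pairs if cls == target_class]
    de = _de_table(expr, target_group)

    def gene_flags(gene_id: str) -> tuple[tuple[str, bool], ...]:
        if gene_id not in de.index:
            return (("known_gene", False),)
        row = de.loc[gene_id]
        return (
            ("de_specific", bool(row.q_value <= de_q_max and row.log2fc > 0)),
            ("min_expr", bool(row.target_mean_expr >= min_expr)),
        )

    emitted: dict[tuple[str, str], CandidateGene] = {}
    rejected: list[CandidateGene] = []

    def consider(gene_id: str, route: str, site: GenomicInterval, loop: Loop):
        flags = gene_flags(gene_id)
        cand = CandidateGene(gene_id, route, site, loop, flags)
        if cand.all_flags_true:
            emitted.setdefault((gene_id, route), cand)
        else:
            rejected.append(cand)

    # route 1: previously detected enhancer-associated genes
    for rec in eag_records:
        if rec.partner_type != "enhancer" or not rec.supported_by_loop:
            continue
        span = _loop_span(rec.loop)
        for site in lost_sites:
            if site.overlap_len(span) >= 1:
                consider(rec.gene_id, "eag_loop", site, rec.loop)
                break
    # route 2: super-enhancer loops over lost sites
    for lp in merged_loops:
        span = _loop_span(lp)
        covered = [s for s in lost_sites if s.overlap_len(span) >= 1]
        if not covered:
            continue
        for se_anchor, gene_anchor in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            if not any(se.overlap_len(se_anchor) >= 1 for se in super_enhancers):
                continue
            genes, _ = _features_at_anchor(assignment, gene_anchor)
            for gid in genes:
                consider(gid, "super_enhancer", covered[0], lp)
    out = sorted(emitted.values(), key=lambda c: (c.gene_id, c.route))
    if include_rejected:
        return out, rejected
    return out
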