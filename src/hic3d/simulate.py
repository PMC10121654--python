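"""Synthetic Hi-C, methylation/CTCF and expression data with planted truth.

Contact maps are Poisson draws around a power-law distance-decay
expectation with block-diagonal TAD enrichment, focal loop enrichment and
a uniform trans background; a planted structural variant mixes the
reference-allele expectation with the derivative-allele expectation
(projected back to reference coordinates) at the somatic allele fraction.
Companion generators emulate CpG methylation anticorrelated with CTCF
occupancy at planted "lost" insulator sites, and gene expression coupled
to enhancer activity at a target correlation.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BinTable,
    ContactMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    GenomeAssembly,
    GenomicInterval,
    Loop,
    MethylationProfile,
    SignalTrack,
    StructuralVariant,
    ValidationError,
)
from .sv_neotad import CoordinateMap, reconstruct_genome


@dataclass
class SimulationConfig:
    """Parameters of the contact-map generator.

    ``depth`` is the expected total cis contact count; the decay follows
    P(d) ~ (d + d0)^(-alpha) in bin units.  TADs multiply within-domain
    pairs by ``tad_fold``; loops multiply their anchor pixel by
    ``loop_fold``; weights are renormalized so the expected cis total
    equals ``depth``.  The trans background rate is a fraction of the mean
    cis per-pair rate.  At most one structural variant may be planted; its
    allele fraction controls the reference/derivative expectation mixture.
    """

    assembly: GenomeAssembly
    resolution: int
    depth: float = 1e6
    alpha: float = 1.0
    d0: float = 1.0
    tads: Sequence[GenomicInterval] = ()
    tad_fold: float = 3.0
    loops: Sequence[tuple[GenomicInterval, GenomicInterval]] = ()
    loop_fold: float = 8.0
    svs: Sequence[StructuralVariant] = ()
    sv_window: GenomicInterval | None = None
    derivative_tads: Sequence[tuple[int, int]] = ()  # bp intervals on derivative
    trans_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("decay exponent alpha must be > 0")
        if self.tad_fold < 1 or self.loop_fold < 1:
            raise ValidationError("enrichment folds must be >= 1")
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if len(self.svs) > 1:
            raise ValidationError("the generator plants at most one SV per map")


@dataclass
class GroundTruth:
    """Planted structure for recovery tests; never re-derived by tests."""

    tad_boundaries: list[int] = field(default_factory=list)  # junction bin idx
    loop_pixels: list[tuple[int, int]] = field(default_factory=list)
    svs: list[StructuralVariant] = field(default_factory=list)
    coordinate_map: CoordinateMap | None = None
    derivative_tads: list[tuple[int, int]] = field(default_factory=list)
    lost_sites: list[GenomicInterval] = field(default_factory=list)
    gene_enhancer_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = []
        for b in self.tad_boundaries:
            rows.append(("tad_boundary", b, "", ""))
        for i, j in self.loop_pixels:
            rows.append(("loop_pixel", i, j, ""))
        for sv in self.svs:
            rows.append(
                (
                    "sv",
                    f"{sv.bp_a[0]}:{sv.bp_a[1]}",
                    f"{sv.bp_b[0]}:{sv.bp_b[1]}",
                    f"{sv.sv_type}:{sv.allele_fraction}",
                )
            )
        for site in self.lost_sites:
            rows.append(("lost_site", site.chrom, site.start, site.end))
        for g, e, r in self.gene_enhancer_pairs:
            rows.append(("gene_enhancer", g, e, r))
        pd.DataFrame(rows, columns=["kind", "a", "b", "c"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Contact-map expectation
# ---------------------------------------------------------------------------

def _base_weight(d_bins: np.ndarray, alpha: float, d0: float) -> np.ndarray:
    return np.power(d_bins + d0, -alpha)


def _tad_ids(config: SimulationConfig, bt: BinTable, chrom: str) -> np.ndarray:
    """Planted-TAD membership id per bin (-1 outside), by bin midpoint."""
    sl = bt.chrom_slice(chrom)
    n = sl.stop - sl.start
    ids = np.full(n, -1)
    res = bt.resolution
    for t, tad in enumerate(config.tads):
        if tad.chrom != chrom:
            continue
        mids = np.arange(n) * res + res // 2
        ids[(mids >= tad.start) & (mids < tad.end)] = t
    return ids


def _ref_components(
    config: SimulationConfig, bt: BinTable, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(base decay, planted-TAD ids, loop multiplier, upper-tri ref weight)."""
    sl = bt.chrom_slice(chrom)
    n = sl.stop - sl.start
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    base = _base_weight(d.astype(float), config.alpha, config.d0)
    ids = _tad_ids(config, bt, chrom)
    loop_mult = np.ones((n, n))
    for a1, a2 in config.loops:
        if a1.chrom != chrom or a2.chrom != chrom:
            continue
        b1 = (a1.start + len(a1) // 2) // bt.resolution
        b2 = (a2.start + len(a2) // 2) // bt.resolution
        loop_mult[b1, b2] *= config.loop_fold
        loop_mult[b2, b1] *= config.loop_fold
    w = base * loop_mult
    same = (ids[:, None] == ids[None, :]) & (ids[:, None] >= 0)
    w[same] *= config.tad_fold
    return base, ids, loop_mult, np.triu(w)


def _der_positions(
    cmap: CoordinateMap, bt: BinTable, chrom: str
) -> np.ndarray:
    """Padded (n, 2) derivative positions of bin midpoints; NaN if absent."""
    sl = bt.chrom_slice(chrom)
    n = sl.stop - sl.start
    res = bt.resolution
    out = np.full((n, 2), np.nan)
    for b in range(n):
        loc = bt.location(sl.start + b)
        mid = min(loc.start + res // 2, loc.end - 1)
        pos = cmap.to_derivative(chrom, mid)
        for k, p in enumerate(pos[:2]):
            out[b, k] = p
    return out


def _der_domain_ids(
    pos: np.ndarray,
    ref_ids: np.ndarray,
    der_tads: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Domain id for each (bin, copy) on the derivative allele.

    Planted derivative-space TADs override the mapped reference TADs; -1
    marks positions outside any domain (or unmapped).
    """
    ids = np.where(ref_ids[:, None] >= 0, 1000 + ref_ids[:, None], -1.0)
    ids = np.broadcast_to(ids, pos.shape).copy()
    for t, (s, e) in enumerate(der_tads):
        ids[(pos >= s) & (pos < e)] = t
    ids[np.isnan(pos)] = -1.0
    return ids


def _der_weight_block(
    pos_r: np.ndarray,
    pos_c: np.ndarray,
    config: SimulationConfig,
    res: int,
    ref_ids_r: np.ndarray,
    ref_ids_c: np.ndarray,
    loop_mult: np.ndarray,
) -> np.ndarray:
    """Derivative-allele weights: sum over copy pairs of decay at the
    derivative distance.  Domain (TAD) enrichment is evaluated in
    derivative space -- planted derivative TADs override mapped reference
    TADs -- and reference loop pixels keep their focal multiplier."""
    tid_r = _der_domain_ids(pos_r, ref_ids_r, config.derivative_tads)
    tid_c = _der_domain_ids(pos_c, ref_ids_c, config.derivative_tads)
    w = np.zeros((pos_r.shape[0], pos_c.shape[0]))
    for a in range(2):
        for b in range(2):
            pr = pos_r[:, a][:, None]
            pc = pos_c[:, b][None, :]
            valid = ~np.isnan(pr) & ~np.isnan(pc)
            d = np.abs(pr - pc) / res
            wb = _base_weight(np.where(valid, d, 1.0), config.alpha, config.d0)
            same = (
                (tid_r[:, a][:, None] == tid_c[:, b][None, :])
                & (tid_r[:, a][:, None] >= 0)
            )
            wb = np.where(same, wb * config.tad_fold, wb)
            w += np.where(valid, wb, 0.0)
    return w * loop_mult


def expected_contacts(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], np.ndarray], BinTable]:
    """Closed-form expectation of the generator.

    Returns per-chromosome upper-triangle cis expectations, per-pair trans
    block expectations (rows = first chromosome), and the bin table.
    """
    bt = BinTable(config.assembly, config.resolution)
    comps = {c: _ref_components(config, bt, c) for c in config.assembly.chrom_names}
    ref_w = {c: comps[c][3] for c in comps}
    z_cis = sum(w.sum() for w in ref_w.values())
    n_cis_pairs = sum(
        n * (n + 1) // 2
        for n in (bt.n_bins_chrom(c) for c in bt.assembly.chrom_names)
    )
    bg = config.trans_rate * config.depth / n_cis_pairs
    chroms = config.assembly.chrom_names
    cis_mu: dict[str, np.ndarray] = {}
    trans_mu: dict[tuple[str, str], np.ndarray] = {}
    if not config.svs:
        for chrom in chroms:
            cis_mu[chrom] = config.depth * ref_w[chrom] / z_cis
        for ca, cb in itertools.combinations(chroms, 2):
            trans_mu[(ca, cb)] = np.full(
                (bt.n_bins_chrom(ca), bt.n_bins_chrom(cb)), bg
            )
        return cis_mu, trans_mu, bt
    sv = config.svs[0]
    f = sv.allele_fraction
    if sv.sv_type == "translocation":
        cmap = reconstruct_genome(config.assembly, [sv])
        affected = {sv.bp_a[0], sv.bp_b[0]}
    else:
        window = config.sv_window or GenomicInterval(
            sv.bp_a[0], 0, config.assembly.length(sv.bp_a[0])
        )
        cmap = reconstruct_genome(config.assembly, [sv], window=window)
        affected = {sv.bp_a[0]}
    pos = {c: _der_positions(cmap, bt, c) for c in affected}
    der_w_cis: dict[str, np.ndarray] = {}
    for chrom in chroms:
        if chrom in affected:
            _, ids, loop_mult, _ = comps[chrom]
            der_w_cis[chrom] = np.triu(
                _der_weight_block(
                    pos[chrom], pos[chrom], config, bt.resolution,
                    ids, ids, loop_mult,
                )
            )
        else:
            der_w_cis[chrom] = ref_w[chrom]
    der_w_trans: dict[tuple[str, str], np.ndarray] = {}
    for ca, cb in itertools.combinations(chroms, 2):
        if ca in affected and cb in affected:
            der_w_trans[(ca, cb)] = _der_weight_block(
                pos[ca], pos[cb], config, bt.resolution,
                comps[ca][1], comps[cb][1],
                np.ones((bt.n_bins_chrom(ca), bt.n_bins_chrom(cb))),
            )
    z_der = sum(w.sum() for w in der_w_cis.values()) + sum(
        w.sum() for w in der_w_trans.values()
    )
    for chrom in chroms:
        cis_mu[chrom] = config.depth * (
            (1 - f) * ref_w[chrom] / z_cis + f * der_w_cis[chrom] / z_der
        )
    for ca, cb in itertools.combinations(chroms, 2):
        mu = np.full((bt.n_bins_chrom(ca), bt.n_bins_chrom(cb)), (1 - f) * bg + f * bg)
        if (ca, cb) in der_w_trans:
            mu = (1 - f) * bg + f * (
                bg + config.depth * der_w_trans[(ca, cb)] / z_der
            )
        trans_mu[(ca, cb)] = mu
    return cis_mu, trans_mu, bt


def simulate_contacts(config: SimulationConfig) -> tuple[ContactMatrix, GroundTruth]:
    """Draw a contact matrix from the generator's Poisson expectation."""
    if config.depth == 0 and (config.tads or config.loops or config.svs):
        warnings.warn("depth 0 with planted structure: empty matrix")
    cis_mu, trans_mu, bt = expected_contacts(config)
    rng = np.random.default_rng(config.seed)
    rows, cols, counts = [], [], []
    for chrom in config.assembly.chrom_names:
        off = bt.chrom_offset(chrom)
        draws = rng.poisson(cis_mu[chrom])
        r, c = np.nonzero(draws)
        rows.append(r + off)
        cols.append(c + off)
        counts.append(draws[r, c])
    for ca, cb in itertools.combinations(config.assembly.chrom_names, 2):
        draws = rng.poisson(trans_mu[(ca, cb)])
        r, c = np.nonzero(draws)
        rows.append(r + bt.chrom_offset(ca))
        cols.append(c + bt.chrom_offset(cb))
        counts.append(draws[r, c])
    matrix = ContactMatrix(
        bt,
        np.concatenate(rows) if rows else np.array([], dtype=np.int64),
        np.concatenate(cols) if cols else np.array([], dtype=np.int64),
        np.concatenate(counts).astype(float) if counts else np.array([]),
    )
    truth = GroundTruth(svs=list(config.svs))
    res = bt.resolution
    boundaries = set()
    for tad in config.tads:
        off = bt.chrom_offset(tad.chrom)
        n = bt.n_bins_chrom(tad.chrom)
        for pos_bp in (tad.start, tad.end):
            b = pos_bp // res
            if 0 < b < n:
                boundaries.add(off + b)
    truth.tad_boundaries = sorted(boundaries)
    for a1, a2 in config.loops:
        b1 = bt.chrom_offset(a1.chrom) + (a1.start + len(a1) // 2) // res
        b2 = bt.chrom_offset(a2.chrom) + (a2.start + len(a2) // 2) // res
        truth.loop_pixels.append((min(b1, b2), max(b1, b2)))
    if config.svs:
        sv = config.svs[0]
        if sv.sv_type == "translocation":
            truth.coordinate_map = reconstruct_genome(config.assembly, [sv])
        else:
            window = config.sv_window or GenomicInterval(
                sv.bp_a[0], 0, config.assembly.length(sv.bp_a[0])
            )
            truth.coordinate_map = reconstruct_genome(
                config.assembly, [sv], window=window
            )
        truth.derivative_tads = list(config.derivative_tads)
    return matrix, truth


# ---------------------------------------------------------------------------
# Methylation / CTCF generator
# ---------------------------------------------------------------------------

def simulate_methylation_ctcf(
    sites: Sequence[GenomicInterval],
    groups: Mapping[str, str],
    effect: float,
    n_cpg_per_site: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    lost_mask: Sequence[bool] | None = None,
    lost_group: str | None = None,
    base_beta: float = 0.3,
    base_signal: float = 10.0,
    kappa: float = 1.0,
) -> tuple[list[MethylationProfile], list[SignalTrack], GroundTruth]:
    """CpG methylation anticorrelated with CTCF occupancy at lost sites.

    At sites flagged lost in ``lost_group``, that group's CpG betas rise by
    ``effect`` while its CTCF signal is scaled by (1 - effect * kappa);
    elsewhere the groups are identical in expectation.  CpGs are evenly
    placed within each site.
    """
    if not (0.0 <= effect <= 1.0):
        raise ValidationError("effect (delta beta) must lie in [0, 1]")
    if lost_mask is None:
        lost_mask = [True] * len(sites)
    if len(lost_mask) != len(sites):
        raise ValidationError("lost_mask length mismatch")
    if lost_group is None:
        lost_group = sorted(set(groups.values()))[0]
    rng = np.random.default_rng(seed)
    cpg_pos: list[tuple[str, int, int]] = []  # chrom, pos, site index
    for si, site in enumerate(sites):
        span = len(site)
        step = max(span // n_cpg_per_site, 1)
        for k in range(n_cpg_per_site):
            cpg_pos.append((site.chrom, site.start + min(k * step, span - 1), si))
    profiles: list[MethylationProfile] = []
    tracks: list[SignalTrack] = []
    for sample in sorted(groups):
        in_lost_group = groups[sample] == lost_group
        betas, chroms, poss = [], [], []
        for chrom, p, si in cpg_pos:
            mean = base_beta + (
                effect if (lost_mask[si] and in_lost_group) else 0.0
            )
            betas.append(np.clip(mean + rng.normal(0.0, noise_sd), 0.0, 1.0))
            chroms.append(chrom)
            poss.append(p)
        profiles.append(
            MethylationProfile(
                pd.DataFrame(
                    {
                        "chrom": chroms,
                        "pos": poss,
                        "beta": betas,
                        "coverage": np.full(len(poss), 30),
                    }
                ),
                sample_id=sample,
                group=groups[sample],
            )
        )
        values = []
        for si, site in enumerate(sites):
            level = base_signal * (
                1.0 - effect * kappa
                if (lost_mask[si] and in_lost_group)
                else 1.0
            )
            values.append(max(level * (1.0 + rng.normal(0.0, noise_sd)), 0.0))
        tracks.append(
            SignalTrack(
                pd.DataFrame(
                    {
                        "chrom": [s.chrom for s in sites],
                        "start": [s.start for s in sites],
                        "end": [s.end for s in sites],
                        "value": values,
                    }
                ),
                sample_id=sample,
            )
        )
    truth = GroundTruth(
        lost_sites=[s for s, m in zip(sites, lost_mask) if m]
    )
    return profiles, tracks, truth


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: Sequence[GeneAnnotation],
    pairs: Sequence[tuple[str, str, float]],  # gene_id, enhancer_id, r*
    enhancer_activity: Mapping[str, np.ndarray] | None = None,
    noise_sd: float = 1.0,
    n_samples: int = 25,
    seed: int = 0,
    sample_groups: Mapping[str, str] | None = None,
    base: float = 10.0,
    scale: float = 2.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression coupled to enhancer activity at a target correlation.

    For a paired gene, raw expression is r* . z(activity) +
    sqrt(1 - r*^2) . noise (noise sd 1 by default, so the sample
    correlation converges to r*); unpaired genes are pure noise.  Values
    are affinely shifted per gene to be strictly positive, which leaves
    correlations unchanged.  Returns the expression matrix and the
    per-enhancer activity actually used.
    """
    for _, _, r in pairs:
        if not (-1.0 <= r <= 1.0):
            raise ValidationError("target correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    if sample_groups is not None:
        samples = sorted(sample_groups)
        n_samples = len(samples)
    pair_of_gene: dict[str, tuple[str, float]] = {}
    for g, e, r in pairs:
        pair_of_gene.setdefault(g, (e, r))
    activity: dict[str, np.ndarray] = {}
    for _, e, _ in pairs:
        if e not in activity:
            if enhancer_activity is not None and e in enhancer_activity:
                activity[e] = np.asarray(enhancer_activity[e], dtype=float)
            else:
                activity[e] = rng.standard_normal(n_samples)
    values = {}
    for gene in genes:
        eps = rng.standard_normal(n_samples) * noise_sd
        if gene.gene_id in pair_of_gene:
            e, r = pair_of_gene[gene.gene_id]
            act = activity[e]
            sd = act.std()
            z = (act - act.mean()) / sd if sd > 0 else np.zeros_like(act)
            raw = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * eps
        else:
            raw = eps
        x = base + scale * raw
        if x.min() <= 0:
            x = x - x.min() + 0.5
        values[gene.gene_id] = x
    groups = (
        pd.Series({s: "all" for s in samples})
        if sample_groups is None
        else pd.Series(dict(sample_groups))
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=samples).T[samples], groups
    )
    act_df = pd.DataFrame(activity, index=samples).T
    return expr, act_df


# ---------------------------------------------------------------------------
# End-to-end insulator-dysfunction scenario
# ---------------------------------------------------------------------------

@dataclass
class InsulatorScenario:
    """A fully synthetic cohort for the insulator-dysfunction pipeline."""

    genes: list[GeneAnnotation]
    enhancers: dict[str, GenomicInterval]
    sites: list[GenomicInterval]
    ctcf_counts: pd.DataFrame  # sites x samples
    groups: pd.Series
    methylation: list[MethylationProfile]
    loops: list[Loop]
    expression: ExpressionMatrix
    activity: pd.DataFrame
    super_enhancers: list[GenomicInterval]
    bin_table: BinTable
    planted_genes: list[str]
    truth: GroundTruth


def simulate_insulator_scenario(
    n_genes: int = 200,
    n_planted: int = 10,
    n_samples_per_group: int = 12,
    delta_beta: float = 0.4,
    noise_beta: float = 0.05,
    activity_shift: float = 3.0,
    r_star: float = 0.85,
    ctcf_kappa: float = 1.875,
    target_group: str = "PFA",
    other_group: str = "ZFTA",
    seed: int = 0,
) -> InsulatorScenario:
    """Plant insulator-dysfunction genes among decoys.

    Each gene owns an enhancer 30 kb downstream of its TSS and a CTCF site
    between them.  Planted genes carry a gene-enhancer loop, lose their
    CTCF site to hypermethylation in the target group and follow
    target-shifted enhancer activity; decoys are missing exactly one
    ingredient each (no lost site, or lost site without differential
    expression, or no loop, or differential expression without a loop).
    A replaced insulator loses most of its occupancy: with the default
    ``ctcf_kappa`` the CTCF signal at lost sites drops 4-fold
    (1 - delta_beta * kappa = 0.25).
    """
    spacing = 100_000
    chrom = "chrS"
    assembly = GenomeAssembly((chrom,), (spacing * n_genes,))
    bt = BinTable(assembly, 5_000)
    planted_idx = set(
        i * (n_genes // n_planted) for i in range(n_planted)
    )
    genes, enhancers, sites = [], {}, []
    loops_out: list[Loop] = []
    lost_mask: list[bool] = []
    shifted: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    super_enhancers: list[GenomicInterval] = []
    decoy_rank = 0
    for g in range(n_genes):
        gid = f"G{g:03d}"
        eid = f"E{g:03d}"
        tss = spacing * g + 50_000
        genes.append(
            GeneAnnotation(
                gid, chrom, tss, "+", GenomicInterval(chrom, tss - 1_000, tss + 9_000)
            )
        )
        enh = GenomicInterval(chrom, tss + 30_000, tss + 32_000)
        enhancers[eid] = enh
        sites.append(GenomicInterval(chrom, tss + 15_000, tss + 16_000))
        if g in planted_idx:
            role = "planted"
        else:
            role = ("loop_no_site", "loop_site_no_de", "no_loop", "de_no_loop")[
                decoy_rank % 4
            ]
            decoy_rank += 1
        has_loop = role in ("planted", "loop_no_site", "loop_site_no_de")
        lost_mask.append(role in ("planted", "loop_site_no_de"))
        if role in ("planted", "de_no_loop"):
            shifted.add(eid)
        if role != "no_loop":
            pairs.append((gid, eid, r_star))
        if has_loop:
            tss_bin = bt.location(bt.bin_index(chrom, tss))
            enh_bin = bt.location(bt.bin_index(chrom, enh.start + len(enh) // 2))
            loops_out.append(
                Loop(
                    tss_bin,
                    enh_bin,
                    observed=50.0,
                    expected_p=1e-8,
                    p_value=1e-6,
                    q_value=1e-4,
                    sample_id=target_group,
                )
            )
    # a few planted enhancers double as super-enhancers (second route)
    for g in sorted(planted_idx)[:3]:
        super_enhancers.append(enhancers[f"E{g:03d}"])
    groups = {}
    for i in range(n_samples_per_group):
        groups[f"T{i:02d}"] = target_group
        groups[f"Z{i:02d}"] = other_group
    rng = np.random.default_rng(seed + 1)
    samples = sorted(groups)
    activity_in = {}
    for eid in sorted({e for _, e, _ in pairs}):
        act = rng.standard_normal(len(samples))
        if eid in shifted:
            act = act + activity_shift * np.array(
                [1.0 if groups[s] == target_group else 0.0 for s in samples]
            )
        activity_in[eid] = act
    expr, act_df = simulate_expression(
        genes,
        pairs,
        enhancer_activity=activity_in,
        n_samples=len(samples),
        seed=seed + 2,
        sample_groups=groups,
    )
    profiles, tracks, meth_truth = simulate_methylation_ctcf(
        sites,
        groups,
        effect=delta_beta,
        n_cpg_per_site=20,
        noise_sd=noise_beta,
        seed=seed + 3,
        lost_mask=lost_mask,
        lost_group=target_group,
        kappa=ctcf_kappa,
    )
    ctcf_counts = pd.DataFrame(
        {t.sample_id: t.data["value"].values for t in tracks}
    )
    planted_genes = sorted(f"G{g:03d}" for g in planted_idx)
    truth = GroundTruth(
        lost_sites=meth_truth.lost_sites,
        gene_enhancer_pairs=[
            (g, e, r) for g, e, r in pairs if g in planted_genes
        ],
    )
    return InsulatorScenario(
        genes=genes,
        enhancers=enhancers,
        sites=sites,
        ctcf_counts=ctcf_counts,
        groups=pd.Series(groups),
        methylation=profiles,
        loops=loops_out,
        expression=expr,
        activity=act_df,
        super_enhancers=super_enhancers,
        bin_table=bt,
        planted_genes=planted_genes,
        truth=truth,
    )
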