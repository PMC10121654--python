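# Methods

This note documents the statistical models behind each stage, the
parameters that matter, the synthetic-data generator's scope, and the
numerical and design choices that were genuinely open. Coordinates are
0-based half-open throughout; contact matrices are upper-triangle sparse
triplets over a genome-wide bin index.

## Contact-map generator

The generator draws each bin-pair count independently as
`Poisson(mu_ij)`. For a cis pair at distance `d` bins,

```
w_ij = (d + d0)^(-alpha) * tad_fold^[same planted TAD] * loop_fold^[loop pixel]
mu_ij = depth * w_ij / sum(w)
```

so the expected cis total equals `depth` exactly while planted loops and
TADs keep their fold enrichment relative to decay-matched background (the
global renormalization affects all pairs equally). Trans pairs receive a
uniform background, `trans_rate` times the mean cis per-pair rate.

With a planted structural variant of allele fraction `f`, the map is the
mixture `(1-f) * mu_ref + f * mu_der`, where the derivative-allele
expectation `mu_der` is computed by mapping bin midpoints through the
derivative coordinate map and summing the decay weight over all copy
pairs (a duplicated bin has two derivative positions). Domain enrichment
on the derivative allele is evaluated in derivative space: planted
derivative-space TADs override mapped reference TADs, so a fused
neo-domain is a single domain rather than a product of overlapping folds.
Positions absent from the derivative (deleted, or beyond a translocation
junction) contribute nothing to `mu_der`, which produces the diagonal
depletion that unbalanced rearrangements show in real maps; positions
joined by the junction produce the off-diagonal/trans blocks.

Defaults: `alpha = 1.0`, `d0 = 1` bin, `tad_fold = 3`, `loop_fold = 8`,
`trans_rate = 0.01`. These make planted structure clearly but not
trivially detectable at a depth of 1e6 contacts per ~200–1000-bin
chromosome, the scale used throughout the tests, and keep every fixture
generatable in well under a second. One SV is planted per map (the
mixture composes one reference and one derivative allele); the
reconstruction code itself composes multiple non-overlapping cis SVs.

What the generator does **not** emulate: restriction-fragment geometry
and ligation artifacts, coverage waves from genome-wide copy-number
profiles, compartment (A/B) structure, overdispersion beyond Poisson, and
mappability/blacklist artifacts. Passing recovery tests therefore shows
that the statistics are implemented correctly and calibrated under their
own model assumptions — not that thresholds transfer unchanged to tissue
Hi-C, where all of the above inflate the background.

Companion generators: CpG methylation at insulator sites
(`beta = base + effect` in the hypermethylated group at lost sites, CTCF
signal scaled by `1 - effect*kappa`, so methylation gain and occupancy
loss are anticorrelated across sites) and expression coupled to enhancer
activity (`x = r* z(act) + sqrt(1 - r*^2) eps`, affinely shifted
positive, so the sample correlation converges to `r*`).

## Balancing and clustering

ICE iterates `b_i <- b_i * s_i / mean(s)` on unmasked bins until the
maximum relative row-sum deviation is below `tol = 1e-5`, then rescales
so the balanced total equals the raw total (biases are folded so
`c_ij / (b_i b_j)` reproduces the balanced counts). Convergence of the
plain multiplicative update is linear; a 2,000-bin genome needs roughly
230 iterations, hence `max_iter = 1000` (each iteration is one sparse
mat-vec). Zero-coverage bins are masked with bias NaN; an all-zero matrix
is an error.

Clustering features are intra-chromosomal upper-triangle bin pairs
nonzero in at least one sample, valued from balanced matrices. The
spec of "feature" in published clusterings is ambiguous; this definition
is recorded in the table's provenance. The `top_k = 20000`
highest-variance features are kept (ties broken by feature id, stable
sort), columns are quantile normalized against the mean sorted profile
(ties get the mean of pooled quantiles — with ties the column
distributions are identical up to that convention), and samples are
clustered by Ward.D2 on `1 - Pearson r`. A zero-variance sample makes the
distance undefined and raises an error naming the sample.

## Loop calling

Candidate pairs are cis pairs with at least one observed contact within
`[min_dist, max_dist]` (defaults: 2 bins, 50 Mb). Distances are cut into
`n_occupancy_bins = 100` equal-occupancy strata; the per-pair probability
of stratum `s` is `(C_s / C_total) / N_s` with `C_s` the observed count
and `N_s` the number of candidate pairs. The stratum's representative
distance is its count-weighted mean distance (for an exact power law this
makes probability vs representative distance exact; an arithmetic
midpoint biases wide far strata). Probabilities are made non-increasing
by weighted isotonic regression and renormalized to sum to one over
candidates. At least two *occupied* strata are required.

Significance: `p = P(X >= k)` with `X ~ Binomial(N_total, p(d))`;
BH q-values over all tested pairs; calls need raw `p <= 0.01` **and**
`q <= 0.05` (both exposed — published pipelines are ambiguous about which
scale the 0.01 filter uses). The binomial-over-isotonic-decay null is a
deliberate, documented simplification of spline-based count models; on
generator nulls its p-values are near-uniform with one-sided conservatism
from count discreteness.

Merging identifies loops by exact anchor-bin equality and keeps the
smallest p (ties: smallest sample id). Differential testing normalizes
per-sample counts by totals, sums within groups and applies a two-sided
conditional binomial on the group split (null split proportional to group
sample counts) with BH at 0.05 — exact at small n, replacing
regression-based count models.

## TAD calling

`binsignal(i)` is the mean contact frequency in the `w x w` diamond
(upstream window x downstream window, clipped at chromosome ends, missing
pairs = 0); `w = 5` follows the common default at 50 kb since no single
value is canonical. Boundary candidates are local minima of the width-3
running mean. Each candidate's diamond entries are compared to the pooled
flanking within-window entries by one-sided Mann-Whitney **after dividing
every entry by its diagonal (distance) mean**: without that step the
comparison is confounded by decay (flank pairs are systematically
shorter-range and larger) and noise minima inside domains pass. This
normalization plus BH (`alpha = 0.05`) and a minimum boundary spacing of
`w` bins (deeper minimum wins) replaces the piecewise-linear extremum
refinement of the original diamond method. Boundaries are reported as
junction indices (first bin of the downstream domain); segments shorter
than 2 bins are left unorganized. The insulation score is
`log2(diamond_i / chromosome mean diamond)` — scale-invariant, with
`-inf` marking zero-coverage bins.

## SV detection

*Trans.* Row- and column-sum profiles of a chromosome-pair block are
segmented by binary segmentation (SSE gain must exceed
`3 * sigma^2 * log n`, sigma from the MAD of first differences — a
conservative BIC-flavored stop; over-segmentation is harmless because
blocks are filtered afterwards). Grid blocks need mean count
`>= fold_min = 8` times the genome-wide trans background and a BH-adjusted
Poisson block test at 0.05; adjacent significant blocks merge, and the
breakpoint estimate is the merged block's corner nearest the maximum
pixel. The published abrupt-shift threshold (t = 0.6) belongs to a
different statistic and is not portable; the fold-over-background default
replaces it and is configurable.

*Cis.* Pixels with observed/expected `>= oe_min = 4` (expected from the
decay model), distance `>= 1 Mb` and at least 3 reads are
density-clustered (DBSCAN, Chebyshev radius `eps = 2` bins,
`min_pts = 4`). A cluster becomes a candidate only if the insulation
score between its anchor projections *shifts* from the flanking level by
`>= 0.5` (log2). The shift is taken in magnitude, not drop-only:
unbalanced losses depress interior insulation by `log2(1/(1-f))`, copy
gains raise it by `log2(1+f)`, and focal loops leave it unchanged — which
is the gate's purpose. `-inf` interior insulation (a fully deleted
segment) counts as an infinite drop. Consequence of the default gate:
copy gains with `f < 2^0.5 - 1 ~ 0.41` are below the detection limit;
tests therefore exercise duplications at `f >= 0.5` (the ZFTA-RELA-type
event is a 50:50 mixture) and losses/translocations down to `f = 0.3`.
Breakpoints are reported at the cluster's enrichment-maximum pixel.

## Derivative genomes and neo-TADs

Reconstruction is exact segment bookkeeping: a tandem duplication of
`[s, e)` inside window `[W0, W1)` yields segments `[W0, e) + [s, W1)`
(duplicated length appears twice); deletions skip `[s, e)`; inversions
insert `[s, e)` reversed; a translocation joins the retained side of each
chromosome per the junction orientation. The map is bidirectional;
reference → derivative is multi-valued inside duplications.

Remapping re-addresses each triplet by bin midpoint. An end inside a
duplicated segment goes to the copy minimizing derivative distance to its
partner (ties split equally), which is what makes breakpoint-spanning
contacts short-range across the junction. Contacts joining different
source segments are scaled by `1 / w_somatic` (default: the allele
fraction; for a 50:50 locus junction counts double), approximating the
somatic-allele-only map; with `f = 1` remapping conserves totals exactly.

A derivative TAD is *neo* iff it contains a segment junction strictly
inside and its reverse-mapped footprint has reciprocal overlap `>= 0.8`
with no reference TAD.

## Regulatory integration

Genes are assigned to 5 kb bins via a TSS window of ±2,500 bp (a phrase
in the source literature reads "2500 Kbp", which would be a 5 Mb window —
implausible on a 5 kb grid; 2,500 bp matches the grid and is the default,
with the literal reading available as an override), enhancers by overlap.
Loop anchors pick up features from their own bin, else from the nearest
nonempty adjacent bin (both neighbors if both are nonempty, being equally
near). The bootstrap expression test compares the mean expression of
loop-connected genes to unconnected genes against 1000 same-size random
unconnected draws, `p = (1 + #{boot >= obs}) / (n_boot + 1)`, one-sided.
Gene–partner correlations use the samples shared between expression and
activity tables (>= 3) and keep `r >= 0.5`.

Differential CTCF sites: library-size-normalized `log2(x+1)` counts,
Welch t per site, differential iff `p <= 0.1` and `|log2FC| >= 0.5`
(strict: exactly 0.4 never passes). DMRs: maximal runs of >= 10
consecutive shared CpGs whose group-mean difference keeps one sign with
`|delta| >= 0.1`, tested by signed-rank on the per-CpG differences, BH
`q <= 0.05`. These are deliberate, simpler surrogates for dedicated
count-model and segmentation tools, faithful in thresholds and logic but
not in estimator details. DMR x differential-site overlaps (>= 1 bp) are
classified `hyper_lost_A/B` when methylation gain and occupancy loss
point the same way. Candidate genes: a hyper-lost site inside the span of
a loop backing a gene–enhancer record (`eag_loop` route) or of a loop
with one anchor on a super-enhancer and a gene at the other
(`super_enhancer` route), with the gene group-specifically upregulated
(Welch + BH `q <= 0.05`, higher mean in the target group) and expressed
(mean `>= 1` in target samples). Whether the published specificity
filters used raw or adjusted p is not fully stated; adjusted is the
default and both are parameters. Super-enhancer identification itself is
taken as an input list.

The end-to-end insulator scenario plants 10 dysfunction genes among 190
decoys, each decoy missing exactly one ingredient. Its cohort has 12
samples per group (24 total, mirroring the n = 25 expression cohort such
analyses typically use), and CTCF occupancy at replaced insulators drops
4-fold (`kappa = 1.875` at `delta_beta = 0.4`) — complete insulator loss,
matching the planted-loss convention used for the differential-CTCF
operation's own tests.

## Problem sizes and determinism

Test and acceptance fixtures use 3–10 Mb chromosomes at 5 or 50 kb with
1e6–2e6 contacts, 200-gene cohorts, and 500-replicate calibration loops —
sizes chosen so each recovery question is answered by a simulation a
laptop runs in seconds while keeping planted effects at realistic
magnitudes. All generators consume a single integer seed through
`numpy.random.default_rng`; same seed, same bytes, on any platform.

## Known limitations

- The binomial/isotonic loop null is conservative for discrete counts and
  ignores local (TAD-corner) enrichment structure; donut-style local
  backgrounds are out of scope.
- TAD calling is single-scale (one `w`); nested domain hierarchies are
  not modeled.
- The cis SV detector's insulation gate implies the `f ~ 0.41` copy-gain
  detection floor noted above; sub-clonal gains need a lower gate at the
  cost of loop false positives.
- Derivative reconstruction supports one translocation or multiple
  non-overlapping cis SVs per derivative; chromothripsis-scale
  reconstructions are out of scope.
- QC keeps samples below the valid-pair threshold (default 1e8) available
  to SV detection only, reflecting that large rearrangements survive low
  depth while loop calling does not.
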