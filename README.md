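# hic3d

Analysis of 3D tumor genomes from binned Hi-C contact maps: matrix
balancing and unsupervised sample clustering, chromatin-loop calling
against a distance-decay null, TAD calling, structural-variant (SV)
detection from contact anomalies, reconstruction of derivative (rearranged)
chromosomes with **neo-TAD** discovery, and integration with CTCF
occupancy, DNA methylation and expression to nominate genes activated by
*insulator dysfunction* or enhancer rewiring.

The package is aimed at cancer-genomics analysts who have binned contact
matrices (HiC-Pro triplet dialect), ChIP-seq signal tracks, WGBS
methylation tables and expression matrices, and want a reproducible,
tested implementation of the 3D-genome computations these studies
typically stitch together from one-off scripts. Because patient Hi-C data
are usually access-controlled, every stage ships with a synthetic-data
generator that plants known TADs, loops, SVs, methylation/CTCF structure
and enhancer-driven expression, so the whole pipeline is testable end to
end against ground truth.

## Models at a glance

- **Balancing (ICE).** Iterative correction finds per-bin biases `b_i`
  such that the normalized counts `c_ij / (b_i b_j)` have equal row sums;
  zero-coverage bins are masked, and the balanced total is rescaled to the
  raw total so depths stay comparable across samples.
- **Sample clustering.** Balanced intra-chromosomal bin-pair contacts at
  500 kb form features; the 20,000 highest-variance features are quantile
  normalized and samples are clustered with Ward.D2 linkage on the Pearson
  distance `d = 1 − r`.
- **Loops.** The null assigns each cis bin pair a contact probability
  `p(d)` from an equal-occupancy, isotonically-smoothed distance-decay
  fit (probabilities sum to 1 over candidate pairs). A pair with observed
  count `k` is tested with `P(X ≥ k)`, `X ~ Binomial(N, p(d))`, BH-adjusted;
  calls require raw `p ≤ 0.01` and `q ≤ 0.05`. Per-sample calls sharing
  both anchors merge to the single strongest call; group differences use a
  conditional binomial on normalized summed counts.
- **TADs.** The diamond statistic `signal(i)` is the mean contact
  frequency in the `w × w` window straddling bin `i` (default `w = 5` at
  50 kb). Boundaries are smoothed local minima that pass a rank-sum
  comparison of diamond vs flanking within-window entries (after dividing
  entries by their distance mean). An insulation track
  `log2(diamond_i / mean diamond)` feeds SV detection.
- **SVs.** Trans rearrangements appear as rectangular contact blocks:
  binary-segmentation changepoints of the trans sub-matrix margins
  delimit blocks, filtered by fold over the trans background and a
  Poisson block test. Cis rearrangements are density-clustered
  observed/expected-enriched long-range pixels whose bracketed region
  shows an anomalous insulation shift (losses depress it, copy gains
  raise it by `log2(1+f)`; focal loops leave it unchanged).
- **Derivative genomes and neo-TADs.** Breakpoints define an ordered list
  of reference segments; contacts are re-addressed to derivative
  coordinates (duplicated ends go to the copy nearest their partner) and
  junction-spanning counts are scaled by the inverse somatic junction
  support (e.g. doubled for a 50:50 somatic:normal locus), approximating
  the somatic-allele map. TADs re-called on that map are flagged *neo*
  when they span a junction and their reverse-mapped footprint matches no
  reference TAD.
- **Regulatory integration.** Genes (TSS ± 2.5 kb) and enhancers
  (overlap) are assigned to a 5 kb grid and linked through merged loops;
  a bootstrap test (1000 resamples) asks whether loop-connected genes are
  expressed above unconnected ones; gene–enhancer pairs are kept at
  Pearson `r ≥ 0.5`. Differential CTCF occupancy (Welch t on normalized
  log2 counts, `p ≤ 0.1`, `|log2FC| ≥ 0.5`) intersected with DMRs
  (sliding runs of ≥ 10 CpGs, `|Δβ| ≥ 0.1`, signed-rank + BH `q ≤ 0.05`)
  yields hypermethylation-replaced insulators; candidate genes are
  emitted when such a site lies inside a loop wiring a group-specific,
  expressed gene (≥ 1 RPKM-like) to an enhancer or super-enhancer.

## Worked example: from contact anomaly to neo-TAD

```python
import hic3d as h

# a 9 Mb locus carrying a tandem duplication on half of the alleles
assembly = h.GenomeAssembly(("chrW",), (9_000_000,))
sv = h.StructuralVariant("tandem_duplication",
                         ("chrW", 3_500_000), ("chrW", 5_500_000),
                         allele_fraction=0.5)
config = h.SimulationConfig(
    assembly, resolution=50_000, depth=2e6, seed=11,
    tads=[h.GenomicInterval("chrW", i * 1_500_000, (i + 1) * 1_500_000)
          for i in range(6)],
    svs=[sv], derivative_tads=[(4_500_000, 6_500_000)], trans_rate=0.0,
)
matrix, truth = h.simulate_contacts(config)

# 1. find the rearrangement from the contact map alone
candidate = h.detect_cis_sv(matrix)[0]
print(f"SV candidate: {candidate.chrom_a}:{candidate.bp_a}-{candidate.bp_b} "
      f"(O/E {candidate.enrichment:.1f}, p = {candidate.p_value:.2e})")

# 2. rebuild the derivative chromosome and remap the contacts (50:50 alleles)
cmap = truth.coordinate_map
derivative = h.remap_contacts(matrix, cmap, allele_fraction=0.5)
print(f"derivative length: {cmap.derivative_length:,} bp, "
      f"junction at {cmap.junctions()[0]:,}")

# 3. re-call TADs on the derivative and flag neo-TADs
reference_map, _ = h.simulate_contacts(h.SimulationConfig(
    assembly, resolution=50_000, depth=2e6, seed=12,
    tads=config.tads, trans_rate=0.0))
reference_tads = h.call_tads(reference_map)
for tad in h.call_neotads(derivative, cmap, reference_tads):
    tag = "  <-- neo-TAD (spans the breakpoint)" if tad.neo else ""
    print(f"TAD {tad.interval.start:>9,} - {tad.interval.end:>9,}{tag}")
```

Output:

```
SV candidate: chrW:3500000-5500000 (O/E 23.7, p = 0.00e+00)
derivative length: 11,000,000 bp, junction at 5,500,000
TAD         0 - 1,500,000
TAD 1,500,000 - 3,000,000
TAD 3,000,000 - 4,500,000
TAD 4,500,000 - 6,500,000  <-- neo-TAD (spans the breakpoint)
TAD 6,500,000 - 8,000,000
TAD 8,000,000 - 9,500,000
TAD 9,500,000 - 11,000,000
```

The detector brackets the duplication exactly (3.5–5.5 Mb; enrichment 23.7
times expected); the derivative chromosome carries the 2 Mb duplicated
segment twice (9 + 2 = 11 Mb) with the copy–copy junction at 5.5 Mb; and
TAD re-calling on the remapped contacts reports one domain that crosses
the junction and exists in no reference TAD — the neo-TAD, the
configuration that can place a gene under control of enhancers it never
touched in the reference genome.

A command-line interface mirrors the main steps
(`hic3d simulate / qc / balance / cluster / call-loops / merge-loops /
call-tads / find-sv / reconstruct`); run `hic3d --help`.

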