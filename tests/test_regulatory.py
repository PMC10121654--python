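"""EAG linking, bootstrap test, correlation filter, CTCF/DMR pipeline."""

import numpy as np
import pandas as pd
import pytest

import hic3d as h


def grid_5kb(length=1_000_000, chrom="chr1"):
    return h.BinTable(h.GenomeAssembly((chrom,), (length,)), 5_000)


class TestAssignBins:
    def test_tss_window_interval_arithmetic(self):
        bt = grid_5kb()
        gene = h.GeneAnnotation(
            "g", "chr1", 12_345, "+", h.GenomicInterval("chr1", 12_000, 20_000)
        )
        assignment = h.assign_bins([gene], {}, bt, tss_window=2_500)
        # window [9845, 14845) overlaps bins 1 and 2 of the 5 kb grid
        assert sorted(b for b, gs in assignment.gene_bins.items() if "g" in gs) == [1, 2]

    def test_enhancer_single_bin(self):
        bt = grid_5kb()
        assignment = h.assign_bins(
            [], {"e": h.GenomicInterval("chr1", 40_000, 45_000)}, bt
        )
        assert list(assignment.enhancer_bins) == [8]

    def test_matches_brute_force_overlap(self):
        bt = grid_5kb(2_000_000)
        rng = np.random.default_rng(9)
        genes, enhancers = [], {}
        for i in range(50):
            tss = int(rng.integers(5_000, 1_990_000))
            genes.append(
                h.GeneAnnotation(
                    f"g{i}", "chr1", tss, "+",
                    h.GenomicInterval("chr1", tss - 500, tss + 5_000),
                )
            )
            s = int(rng.integers(0, 1_990_000))
            enhancers[f"e{i}"] = h.GenomicInterval("chr1", s, s + int(rng.integers(500, 9_000)))
        assignment = h.assign_bins(genes, enhancers, bt, tss_window=2_500)
        for b in range(bt.n_bins):
            lo, hi = b * 5_000, (b + 1) * 5_000
            exp_genes = sorted(
                g.gene_id for g in genes
                if g.tss - 2_500 < hi and g.tss + 2_500 > lo
            )
            exp_enh = sorted(
                e for e, iv in enhancers.items() if iv.start < hi and iv.end > lo
            )
            assert sorted(assignment.gene_bins.get(b, [])) == exp_genes
            assert sorted(assignment.enhancer_bins.get(b, [])) == exp_enh


def loop_between_bins(bt, b1, b2, sample="s"):
    return h.Loop(
        bt.location(b1), bt.location(b2),
        observed=20.0, expected_p=1e-7, p_value=1e-5, q_value=1e-3,
        sample_id=sample,
    )


class TestLinkEags:
    def setup_assignment(self):
        bt = grid_5kb()
        gene = h.GeneAnnotation(
            "g", "chr1", 52_500, "+", h.GenomicInterval("chr1", 50_000, 60_000)
        )
        enh = {"e": h.GenomicInterval("chr1", 100_000, 105_000)}
        return bt, h.assign_bins([gene], enh, bt)

    def test_gene_enhancer_record(self):
        bt, assignment = self.setup_assignment()
        records = h.link_eags([loop_between_bins(bt, 10, 20)], assignment)
        assert len(records) == 1
        rec = records[0]
        assert rec.gene_id == "g" and rec.partner_id == "e"
        assert rec.supported_by_loop

    def test_adjacent_bin_fallback(self):
        bt, assignment = self.setup_assignment()
        # anchor on bin 21 (empty); enhancer lives in adjacent bin 20
        records = h.link_eags([loop_between_bins(bt, 10, 21)], assignment)
        assert len(records) == 1 and records[0].partner_id == "e"

    def test_matches_brute_force_enumeration(self):
        bt = grid_5kb(2_000_000)
        rng = np.random.default_rng(3)
        genes = []
        enhancers = {}
        for i in range(30):
            tss = int(rng.integers(5_000, 1_990_000))
            genes.append(
                h.GeneAnnotation(
                    f"g{i}", "chr1", tss, "+",
                    h.GenomicInterval("chr1", tss - 100, tss + 1_000),
                )
            )
            s = int(rng.integers(0, 1_990_000))
            enhancers[f"e{i}"] = h.GenomicInterval("chr1", s, s + 4_000)
        assignment = h.assign_bins(genes, enhancers, bt)
        loops = [
            loop_between_bins(
                bt, int(rng.integers(0, 200)), int(rng.integers(200, 399))
            )
            for _ in range(25)
        ]
        records = h.link_eags(loops, assignment)

        def feats(b):
            g = assignment.gene_bins.get(b, [])
            e = assignment.enhancer_bins.get(b, [])
            if g or e:
                return g, e
            g2, e2 = [], []
            for bb in (b - 1, b + 1):
                if 0 <= bb < bt.n_bins:
                    g2 += assignment.gene_bins.get(bb, [])
                    e2 += assignment.enhancer_bins.get(bb, [])
            return g2, e2

        expected = set()
        for lp in loops:
            b1 = lp.anchor1.start // 5_000
            b2 = lp.anchor2.start // 5_000
            (ga, ea), (gb, eb) = feats(b1), feats(b2)
            for gene in ga:
                expected |= {(gene, p, "enhancer") for p in eb}
                expected |= {(gene, p, "gene") for p in gb if p != gene}
            for gene in gb:
                expected |= {(gene, p, "enhancer") for p in ea}
                expected |= {(gene, p, "gene") for p in ga if p != gene}
        got = {(r.gene_id, r.partner_id, r.partner_type) for r in records}
        assert got == expected


class TestBootstrap:
    def make_expr(self, vals):
        genes = [f"g{i}" for i in range(len(vals))]
        samples = ["s0", "s1"]
        df = pd.DataFrame({s: vals for s in samples}, index=genes)
        return h.ExpressionMatrix(df, pd.Series({s: "x" for s in samples}))

    def test_identical_expression_p_near_one(self):
        expr = self.make_expr(np.full(100, 5.0))
        obs, p = h.bootstrap_expression_test(expr, [f"g{i}" for i in range(10)])
        assert obs == 0.0 and p > 0.9

    def test_power_for_two_sd_shift(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            vals = np.maximum(rng.normal(10, 2, size=200), 0.1)
            vals[:20] += 4.0  # +2 SD for the 10% connected set
            expr = self.make_expr(vals)
            _, p = h.bootstrap_expression_test(
                expr, [f"g{i}" for i in range(20)], seed=seed
            )
            hits += p < 0.01
        assert hits >= 95

    def test_connected_covering_all_genes_rejected(self):
        expr = self.make_expr(np.arange(10.0) + 1)
        with pytest.raises(h.ValidationError):
            h.bootstrap_expression_test(expr, [f"g{i}" for i in range(10)])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        expr = self.make_expr(rng.normal(10, 2, size=100))
        r1 = h.bootstrap_expression_test(expr, ["g1", "g5", "g7"], seed=42)
        r2 = h.bootstrap_expression_test(expr, ["g1", "g5", "g7"], seed=42)
        assert r1 == r2


class TestCorrelationFilter:
    def record(self, gene="g0", partner="e0"):
        bt = grid_5kb()
        return h.EAGRecord(gene, partner, "enhancer", loop_between_bins(bt, 1, 5))

    def expr_and_activity(self, gene_vec, act_vec):
        samples = [f"s{i}" for i in range(len(gene_vec))]
        expr = h.ExpressionMatrix(
            pd.DataFrame([gene_vec], index=["g0"], columns=samples),
            pd.Series({s: "x" for s in samples}),
        )
        act = pd.DataFrame([act_vec], index=["e0"], columns=samples)
        return expr, act

    def test_identical_vectors_kept_with_r_one(self):
        v = [1.0, 2, 3, 4, 5]
        expr, act = self.expr_and_activity(v, v)
        kept, dropped = h.correlation_filter([self.record()], expr, act)
        assert len(kept) == 1 and kept[0].r == pytest.approx(1.0)

    def test_anticorrelated_dropped(self):
        expr, act = self.expr_and_activity([1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1])
        kept, dropped = h.correlation_filter([self.record()], expr, act)
        assert kept == [] and len(dropped) == 1

    def test_zero_variance_dropped_with_reason(self):
        expr, act = self.expr_and_activity([2.0, 2, 2, 2, 2], [1.0, 2, 3, 4, 5])
        kept, dropped = h.correlation_filter([self.record()], expr, act)
        assert kept == [] and "zero-variance" in dropped[0][1]

    def test_monte_carlo_true_pairs_kept_decoys_rejected(self):
        true_kept = decoy_kept = 0
        for seed in range(100):
            genes = [
                h.GeneAnnotation(
                    g, "chr1", 10_000, "+", h.GenomicInterval("chr1", 5_000, 15_000)
                )
                for g in ("gt", "gd")
            ]
            expr, act = h.simulate_expression(
                genes, [("gt", "et", 0.7), ("gd", "ed", 0.0)],
                n_samples=25, seed=seed,
            )
            bt = grid_5kb()
            recs = [
                h.EAGRecord("gt", "et", "enhancer", loop_between_bins(bt, 1, 5)),
                h.EAGRecord("gd", "ed", "enhancer", loop_between_bins(bt, 1, 6)),
            ]
            kept, _ = h.correlation_filter(recs, expr, act)
            names = {r.gene_id for r in kept}
            true_kept += "gt" in names
            decoy_kept += "gd" in names
        assert true_kept >= 80
        assert decoy_kept <= 10


class TestDifferentialCtcf:
    def sites(self, n):
        return [
            h.GenomicInterval("chr1", 10_000 * i, 10_000 * i + 1_000)
            for i in range(n)
        ]

    def groups(self):
        return {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}

    def test_equal_means_not_differential(self):
        counts = pd.DataFrame(
            {s: [100.0, 50.0] for s in self.groups()}, index=[0, 1]
        )
        out = h.differential_ctcf_sites(
            self.sites(2), counts, self.groups(), "A", "B"
        )
        assert not any(d.is_differential for d in out)

    def test_planted_fourfold_loss_flagged(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            base = 100.0
            a = base / 4 if i < 5 else base
            rows.append(
                [a * (1 + rng.normal(0, 0.05)) for _ in range(3)]
                + [base * (1 + rng.normal(0, 0.05)) for _ in range(3)]
            )
        counts = pd.DataFrame(rows, columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        out = h.differential_ctcf_sites(
            self.sites(40), counts, self.groups(), "A", "B"
        )
        assert all(out[i].is_differential and out[i].log2fc < 0 for i in range(5))
        assert not any(d.is_differential for d in out[5:])

    def test_lfc_below_threshold_not_flagged(self):
        # |log2FC| = 0.4 exactly: below the strict 0.5 threshold at any p
        xb = 100.0
        xa = (xb + 1) * 2**-0.4 - 1
        pad_a = 50 + (xb - xa)  # equalize library sizes across columns
        counts = pd.DataFrame(
            {
                "a1": [xa, pad_a], "a2": [xa, pad_a], "a3": [xa, pad_a],
                "b1": [xb, 50.0], "b2": [xb, 50.0], "b3": [xb, 50.0],
            }
        )
        out = h.differential_ctcf_sites(
            self.sites(2), counts, self.groups(), "A", "B"
        )
        assert abs(out[0].log2fc) == pytest.approx(0.4, abs=1e-6)
        assert not out[0].is_differential


class TestDmrs:
    def profile(self, sample, group, betas, start=1000, spacing=50):
        return h.MethylationProfile(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": start + spacing * np.arange(len(betas)),
                    "beta": betas,
                    "coverage": 30,
                }
            ),
            sample_id=sample, group=group,
        )

    def test_identical_groups_no_dmrs(self):
        rng = np.random.default_rng(0)
        base = np.clip(rng.normal(0.3, 0.05, 200), 0, 1)
        ga = [self.profile(f"a{i}", "A", base) for i in range(3)]
        gb = [self.profile(f"b{i}", "B", base) for i in range(3)]
        assert h.call_dmrs(ga, gb) == []

    def test_planted_region_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        ga, gb = [], []
        for i in range(3):
            a = np.clip(rng.normal(0.3, 0.05, n), 0, 1)
            a[100:120] += 0.4
            ga.append(self.profile(f"a{i}", "A", np.clip(a, 0, 1)))
            gb.append(self.profile(f"b{i}", "B",
                                   np.clip(rng.normal(0.3, 0.05, n), 0, 1)))
        dmrs = h.call_dmrs(ga, gb)
        assert len(dmrs) == 1
        start_cpg = (dmrs[0].interval.start - 1000) // 50
        end_cpg = (dmrs[0].interval.end - 1000) // 50
        assert abs(start_cpg - 100) <= 2 and abs(end_cpg - 120) <= 2
        assert dmrs[0].delta_beta == pytest.approx(0.4, abs=0.05)

    def test_small_difference_below_min_diff(self):
        base = np.full(100, 0.3)
        ga = [self.profile("a0", "A", base + 0.05)]
        gb = [self.profile("b0", "B", base)]
        assert h.call_dmrs(ga, gb) == []

    def test_disjoint_cpgs_rejected(self):
        ga = [self.profile("a0", "A", [0.5] * 20, start=0)]
        gb = [self.profile("b0", "B", [0.5] * 20, start=100_000)]
        with pytest.raises(h.ValidationError):
            h.call_dmrs(ga, gb)


class TestOverlapDmrCtcf:
    def dmr(self, start, end, delta=0.4):
        return h.DMR(
            h.GenomicInterval("chr1", start, end), delta_beta=delta,
            n_cpgs=20, p_value=1e-4, q_value=1e-3,
        )

    def site(self, start, end, lfc=-1.0):
        return h.DifferentialSite(
            h.GenomicInterval("chr1", start, end), log2fc=lfc,
            p_value=1e-3, q_value=1e-2, is_differential=True,
        )

    def test_disjoint_sets_no_pairs(self):
        pairs, counts = h.overlap_dmr_ctcf(
            [self.dmr(0, 100)], [self.site(200, 300)]
        )
        assert pairs == [] and sum(counts.values()) == 0

    def test_toy_fixture_matches_brute_force(self):
        dmrs = [self.dmr(i * 100, i * 100 + 80) for i in range(5)]
        sites = [self.site(50 + i * 120, 130 + i * 120) for i in range(4)]
        pairs, _ = h.overlap_dmr_ctcf(dmrs, sites)
        expected = {
            (d.interval.start, s.interval.start)
            for d in dmrs
            for s in sites
            if d.interval.overlap_len(s.interval) >= 1
        }
        got = {(d.interval.start, s.interval.start) for d, s, _ in pairs}
        assert got == expected

    def test_dmr_overlapping_two_sites_two_pairs(self):
        pairs, counts = h.overlap_dmr_ctcf(
            [self.dmr(0, 500)], [self.site(10, 50), self.site(100, 150)]
        )
        assert len(pairs) == 2
        assert counts["hyper_lost_A"] == 2

    def test_classification_sides(self):
        pairs, counts = h.overlap_dmr_ctcf(
            [self.dmr(0, 100, delta=-0.4)], [self.site(50, 150, lfc=+1.0)]
        )
        assert counts["hyper_lost_B"] == 1


class TestInsulatorCandidates:
    def test_end_to_end_scenario_recall_and_precision(self, insulator_scenario):
        sc = insulator_scenario
        diff = h.differential_ctcf_sites(
            sc.sites, sc.ctcf_counts, sc.groups.to_dict(), "PFA", "ZFTA"
        )
        ga = [p for p in sc.methylation if p.group == "PFA"]
        gb = [p for p in sc.methylation if p.group == "ZFTA"]
        dmrs = h.call_dmrs(ga, gb)
        pairs, counts = h.overlap_dmr_ctcf(dmrs, diff)
        assert counts["hyper_lost_A"] > 0 and counts["hyper_lost_B"] == 0
        assignment = h.assign_bins(sc.genes, sc.enhancers, sc.bin_table)
        records = h.link_eags(sc.loops, assignment)
        kept, _ = h.correlation_filter(records, sc.expression, sc.activity)
        cands = h.insulator_candidates(
            pairs, sc.loops, kept, sc.super_enhancers, assignment,
            sc.expression, "PFA",
        )
        found = {c.gene_id for c in cands}
        planted = set(sc.planted_genes)
        tp = len(found & planted)
        assert tp / len(planted) >= 0.8
        assert tp / max(len(found), 1) >= 0.8
        # all emitted candidates satisfy every recorded flag
        assert all(c.all_flags_true for c in cands)

    def test_site_outside_span_not_emitted(self, insulator_scenario):
        sc = insulator_scenario
        assignment = h.assign_bins(sc.genes, sc.enhancers, sc.bin_table)
        records = h.link_eags(sc.loops, assignment)
        kept, _ = h.correlation_filter(records, sc.expression, sc.activity)
        # fake pair whose site lies far outside every loop span
        far_site = h.DifferentialSite(
            h.GenomicInterval("chrS", 19_990_000, 19_991_000),
            log2fc=-2.0, p_value=1e-6, q_value=1e-5, is_differential=True,
        )
        far_dmr = h.DMR(
            h.GenomicInterval("chrS", 19_990_000, 19_991_000),
            delta_beta=0.4, n_cpgs=20, p_value=1e-5, q_value=1e-4,
        )
        cands = h.insulator_candidates(
            [(far_dmr, far_site, "hyper_lost_A")],
            sc.loops, kept, sc.super_enhancers, assignment,
            sc.expression, "PFA",
        )
        assert cands == []

    def test_min_expr_failure_recorded(self, insulator_scenario):
        sc = insulator_scenario
        diff = h.differential_ctcf_sites(
            sc.sites, sc.ctcf_counts, sc.groups.to_dict(), "PFA", "ZFTA"
        )
        ga = [p for p in sc.methylation if p.group == "PFA"]
        gb = [p for p in sc.methylation if p.group == "ZFTA"]
        dmrs = h.call_dmrs(ga, gb)
        pairs, _ = h.overlap_dmr_ctcf(dmrs, diff)
        assignment = h.assign_bins(sc.genes, sc.enhancers, sc.bin_table)
        records = h.link_eags(sc.loops, assignment)
        kept, _ = h.correlation_filter(records, sc.expression, sc.activity)
        cands, rejected = h.insulator_candidates(
            pairs, sc.loops, kept, sc.super_enhancers, assignment,
            sc.expression, "PFA", min_expr=1e9, include_rejected=True,
        )
        assert cands == []
        assert any(
            dict(c.flags).get("min_expr") is False for c in rejected
        )
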