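import numpy as np
import pandas as pd
import pytest

from idcgwas import lddecay, qtl

from conftest import make_genotypes


def _ld_chain_panel():
    """Four markers at 100/200/300/400 kb: 1-2 and 2-3 in strong LD, 3-4 unlinked."""
    rng = np.random.default_rng(0)
    n = 60
    x1 = 2.0 * (rng.random(n) < 0.5)
    x2 = x1.copy()
    flip = rng.choice(n, 3, replace=False)
    x2[flip] = 2.0 - x2[flip]
    x3 = x2.copy()
    flip = rng.choice(n, 3, replace=False)
    x3[flip] = 2.0 - x3[flip]
    x4 = 2.0 * (rng.random(n) < 0.5)
    d = np.column_stack([x1, x2, x3, x4])
    g = make_genotypes(d, positions=[100_000, 200_000, 300_000, 400_000], chrom="Gm03")
    r12 = lddecay.partial_r2(x1, x2)
    r23 = lddecay.partial_r2(x2, x3)
    r34 = lddecay.partial_r2(x3, x4)
    assert r12 > 0.6 and r23 > 0.6 and r34 <= 0.6  # fixture sanity
    return g


class TestStepwise:
    def test_single_significant_candidate_selected(self):
        rng = np.random.default_rng(1)
        x = 2.0 * (rng.random(50) < 0.5)
        y = 2.7 + 0.2 * x + rng.normal(0, 0.3, 50)
        res = qtl.stepwise_select(y, x[:, None], ["m1"])
        assert res.selected == ["m1"]
        # multiple R^2 equals the single-marker R^2
        r = np.corrcoef(x, y)[0, 1]
        np.testing.assert_allclose(res.multiple_r2_pct, 100 * r * r, rtol=1e-9)

    def test_duplicated_marker_selected_once(self):
        rng = np.random.default_rng(2)
        x = 2.0 * (rng.random(50) < 0.5)
        y = 2.7 + 0.3 * x + rng.normal(0, 0.3, 50)
        res = qtl.stepwise_select(y, np.column_stack([x, x]), ["m1", "m1_dup"])
        assert len(res.selected) == 1

    def test_no_qualifying_candidate_gives_empty_result(self):
        rng = np.random.default_rng(3)
        X = 2.0 * (rng.random((60, 4)) < 0.5)
        y = rng.normal(size=60)
        res = qtl.stepwise_select(y, X, list("abcd"))
        assert not res and res.selected == []

    def test_true_predictors_recovered_over_nulls(self):
        """Three orthogonal real effects are always retained over five nulls.

        With a 0.05 entry threshold and five null candidates, a null marker
        sneaks in with probability ~1-0.95^5 per extra step, so exact recovery
        is bounded near 77%; the reliable properties are superset recovery and
        a low false-inclusion count.
        """
        n_seeds = 20
        supersets, false_inclusions = 0, 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            X = 2.0 * (rng.random((n, 8)) < 0.5)
            y = 2.7 + 0.3 * X[:, 0] - 0.25 * X[:, 1] + 0.3 * X[:, 2]
            y = y + rng.normal(0, 0.4, n)
            ids = [f"m{i}" for i in range(8)]
            res = qtl.stepwise_select(y, X, ids)
            supersets += {"m0", "m1", "m2"} <= set(res.selected)
            false_inclusions += len(set(res.selected) - {"m0", "m1", "m2"})
        assert supersets == n_seeds
        assert false_inclusions <= n_seeds  # on average at most one stray null

    def test_retained_markers_significant_in_joint_model(self, breeding_panel):
        g = breeding_panel["genotypes"]
        y = breeding_panel["phenotypes"].table["adjusted"].to_numpy()
        X = g.dosage[:, :30]
        res = qtl.stepwise_select(y, X, g.markers["id"].tolist()[:30])
        for p in res.final_p.values():
            assert p <= 0.05

    def test_multiple_r2_at_least_best_single(self):
        rng = np.random.default_rng(5)
        X = 2.0 * (rng.random((100, 5)) < 0.5)
        y = 2.7 + 0.3 * X[:, 0] + 0.2 * X[:, 1] + rng.normal(0, 0.3, 100)
        res = qtl.stepwise_select(y, X, [f"m{i}" for i in range(5)])
        singles = [
            100 * np.corrcoef(X[:, i], y)[0, 1] ** 2
            for i, mid in enumerate([f"m{i}" for i in range(5)])
            if mid in res.selected
        ]
        assert res.multiple_r2_pct >= max(singles) - 1e-9


class TestDelineateRegion:
    def test_chain_extends_through_ld_and_stops(self):
        g = _ld_chain_panel()
        region = qtl.delineate_region("Gm03_200000", g)
        assert (region.start, region.end) == (100_000, 300_000)
        assert region.member_ids == ["Gm03_100000", "Gm03_200000", "Gm03_300000"]

    def test_isolated_lead_gives_point_region(self):
        g = _ld_chain_panel()
        region = qtl.delineate_region("Gm03_400000", g)
        assert region.start == region.end == 400_000
        assert region.member_ids == ["Gm03_400000"]

    def test_threshold_one_always_point_region(self):
        g = _ld_chain_panel()
        region = qtl.delineate_region("Gm03_200000", g, r2_threshold=1.0)
        assert region.start == region.end == 200_000

    def test_invariant_to_other_chromosomes(self):
        g = _ld_chain_panel()
        rng = np.random.default_rng(9)
        extra = make_genotypes(
            2.0 * (rng.random((60, 3)) < 0.5),
            positions=[50_000, 60_000, 70_000],
            chrom="Gm09",
        )
        combined = make_genotypes(
            np.hstack([g.dosage, extra.dosage]),
            positions=list(g.markers["pos"]) + list(extra.markers["pos"]),
            chrom=list(g.markers["chrom"]) + list(extra.markers["chrom"]),
        )
        a = qtl.delineate_region("Gm03_200000", g)
        b = qtl.delineate_region("Gm03_200000", combined)
        assert (a.start, a.end, a.member_ids) == (b.start, b.end, b.member_ids)

    def test_missing_lead_rejected(self):
        with pytest.raises(KeyError):
            qtl.delineate_region("nope", _ld_chain_panel())


def _merge_panel(gap_bp, n_between, correlated_between=False):
    """Two 2-marker LD blocks separated by `gap_bp` with `n_between` markers between."""
    rng = np.random.default_rng(4)
    n = 80
    a = 2.0 * (rng.random(n) < 0.5)
    a2 = a.copy()
    flip = rng.choice(n, 2, replace=False)
    a2[flip] = 2.0 - a2[flip]
    b = 2.0 * (rng.random(n) < 0.5)
    b2 = b.copy()
    flip = rng.choice(n, 2, replace=False)
    b2[flip] = 2.0 - b2[flip]
    between = [
        (a if correlated_between else 2.0 * (rng.random(n) < 0.5))
        for _ in range(n_between)
    ]
    start2 = 200_000 + gap_bp
    pos = (
        [100_000, 200_000]
        + [200_000 + (i + 1) * gap_bp // (n_between + 1) for i in range(n_between)]
        + [start2, start2 + 100_000]
    )
    d = np.column_stack([a, a2] + between + [b, b2])
    g = make_genotypes(d, positions=pos, chrom="Gm05")
    ids = g.markers["id"].tolist()
    blocks = [
        qtl.QTLRegion("Gm05", 100_000, 200_000, ids[0], ids[:2]),
        qtl.QTLRegion("Gm05", start2, start2 + 100_000, ids[-2], ids[-2:]),
    ]
    return g, blocks


class TestMergeBlocks:
    def test_short_gap_few_nonld_markers_merged(self):
        g, blocks = _merge_panel(gap_bp=5_000, n_between=2)
        merged = qtl.merge_blocks(blocks, g)
        assert len(merged) == 1
        assert merged[0].start == 100_000 and merged[0].end == 305_000
        assert len(merged[0].member_ids) == 6  # both blocks plus intervening markers

    def test_wide_gap_not_merged(self):
        g, blocks = _merge_panel(gap_bp=50_000, n_between=2)
        assert len(qtl.merge_blocks(blocks, g)) == 2

    def test_too_many_nonld_markers_not_merged(self):
        g, blocks = _merge_panel(gap_bp=5_000, n_between=5)
        assert len(qtl.merge_blocks(blocks, g)) == 2

    def test_or_rule_merges_on_count_alone(self):
        g, blocks = _merge_panel(gap_bp=50_000, n_between=2)
        assert len(qtl.merge_blocks(blocks, g, rule="or")) == 1

    def test_idempotent_and_length_non_decreasing(self):
        g, blocks = _merge_panel(gap_bp=5_000, n_between=2)
        before = sum(b.length_bp for b in blocks)
        once = qtl.merge_blocks(blocks, g)
        twice = qtl.merge_blocks(once, g)
        assert [(r.start, r.end) for r in once] == [(r.start, r.end) for r in twice]
        assert sum(r.length_bp for r in once) >= before


class TestOverlapGenes:
    GENES = pd.DataFrame(
        {
            "gene_id": ["inside", "before", "fre1_like"],
            "chrom": ["Gm03"] * 3,
            "start": [45_000_000, 44_700_000, 44_925_730],
            "end": [45_001_000, 44_797_999, 44_930_360],
        }
    )

    def _region(self):
        return qtl.QTLRegion("Gm03", 44_798_000, 47_140_000, "lead", ["lead"])

    def test_gene_inside_region_reported(self):
        hits = qtl.overlap_genes(self._region(), self.GENES)
        assert "inside" in hits

    def test_gene_ending_one_bp_before_not_reported(self):
        assert "before" not in qtl.overlap_genes(self._region(), self.GENES)

    def test_candidate_iron_gene_interval_inside_major_region(self):
        # a ferric-reductase-like gene at 44,925,730-44,930,360 falls in the
        # Gm03 44.798-47.140 Mbp region
        assert "fre1_like" in qtl.overlap_genes(self._region(), self.GENES)


class TestEpistasis:
    def test_two_markers_one_pair(self):
        rng = np.random.default_rng(0)
        X = 2.0 * (rng.random((50, 2)) < 0.5)
        res = qtl.epistasis_scan(rng.normal(size=50), X, ["a", "b"])
        assert len(res) == 1

    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(1)
        k = 12
        X = 2.0 * (rng.random((60, k)) < 0.5)
        res = qtl.epistasis_scan(rng.normal(size=60), X, [f"m{i}" for i in range(k)])
        assert len(res) == k * (k - 1) // 2
        pairs = {(r.marker_a, r.marker_b) for r in res}
        assert len(pairs) == len(res)

    def test_collinear_pair_degenerate(self):
        rng = np.random.default_rng(2)
        x = 2.0 * (rng.random(40) < 0.5)
        res = qtl.epistasis_scan(rng.normal(size=40), np.column_stack([x, x]), ["a", "b"])
        assert res[0].degenerate and res[0].p_value == 1.0

    def test_planted_interaction_detected(self):
        """Interaction effect 0.4 at n = 270 is detected at 1e-3 in >= 80% of seeds;
        null pairs are flagged in <= 0.5% of tests."""
        detected, false_flags, null_tests = 0, 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 270
            X = 2.0 * (rng.random((n, 6)) < 0.5)
            xa, xb = X[:, 0] - 1.0, X[:, 1] - 1.0
            y = 2.7 + 0.4 * xa * xb + rng.normal(0, 0.3, n)
            res = qtl.epistasis_scan(y, X, [f"m{i}" for i in range(6)])
            for r in res:
                if {r.marker_a, r.marker_b} == {"m0", "m1"}:
                    detected += r.significant
                else:
                    null_tests += 1
                    false_flags += r.significant
        assert detected >= 0.8 * n_seeds
        assert false_flags / null_tests <= 0.005


class TestAlleleCombos:
    def _two_sample_panel(self, scores, dosages):
        d = np.asarray(dosages, dtype=float)
        return make_genotypes(d, ref="C", alt="T"), np.asarray(scores, dtype=float)

    def test_two_member_statistics(self):
        # members {2.18, 2.34} -> mean 2.26, SD 0.11 at two decimals
        g, y = self._two_sample_panel([2.18, 2.34], [[2.0], [2.0]])
        combos, _ = qtl.allele_combos(g, ["Gm01_1000"], y)
        c = combos[0]
        assert round(c.mean, 2) == 2.26 and round(c.sd, 2) == 0.11
        assert c.n == 2 and c.min == 2.18 and c.max == 2.34

    def test_single_member_sd_absent(self):
        g, y = self._two_sample_panel([2.4, 3.9], [[0.0], [2.0]])
        combos, _ = qtl.allele_combos(g, ["Gm01_1000"], y)
        tolerant = [c for c in combos if c.mean == 2.4][0]
        assert tolerant.sd is None and tolerant.n == 1

    def test_boundary_mean_is_tolerant(self):
        g, y = self._two_sample_panel([2.5, 3.5], [[0.0], [2.0]])
        combos, _ = qtl.allele_combos(g, ["Gm01_1000"], y)
        by_mean = {c.mean: c.tolerance_class for c in combos}
        assert by_mean[2.5] == "tolerant" and by_mean[3.5] == "susceptible"

    def test_het_and_missing_samples_excluded(self):
        d = np.array([[0.0, 0.0], [1.0, 0.0], [np.nan, 2.0], [2.0, 2.0]])
        g = make_genotypes(d)
        combos, excluded = qtl.allele_combos(g, ["Gm01_1000", "Gm01_2000"],
                                             np.array([2.0, 2.1, 2.2, 3.9]))
        assert excluded == 2
        assert sum(c.n for c in combos) == 2

    def test_combination_string_uses_carried_alleles_in_order(self):
        d = np.array([[0.0, 2.0]])
        g = make_genotypes(d, ref=["A", "C"], alt=["G", "T"])
        combos, _ = qtl.allele_combos(g, ["Gm01_1000", "Gm01_2000"], np.array([2.0]))
        assert combos[0].combination == "AT"

    def test_classification_soundness(self, breeding_panel):
        g = breeding_panel["genotypes"]
        y = breeding_panel["phenotypes"].table["idc_score"].to_numpy()
        ids = g.markers["id"].tolist()[:4]
        combos, _ = qtl.allele_combos(g, ids, y)
        for c in combos:
            if c.tolerance_class == "tolerant":
                assert c.mean <= 2.5
            elif c.tolerance_class == "susceptible":
                assert c.mean >= 3.5
            else:
                assert 2.5 < c.mean < 3.5
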