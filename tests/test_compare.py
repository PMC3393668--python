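import numpy as np
import pandas as pd
import pytest

from exp_helpers import count_inversion_false_positives

from f2linkage import compare as cp, mapbuild as mb, simulate as sim
from f2linkage.genodata import MarkerGenotypeMatrix


def matrix_from_counts(n_aa, n_h, n_bb, marker="m1"):
    calls = np.concatenate(
        [np.zeros(n_aa), np.ones(n_h), np.full(n_bb, 2)]
    ).astype(np.int8)[:, None]
    ids = [f"i{k}" for k in range(len(calls))]
    return MarkerGenotypeMatrix(ids, [marker], calls)


class TestDistortionScan:
    def test_exact_ratio_not_distorted(self):
        scan = cp.distortion_chisq_scan(matrix_from_counts(40, 80, 40))
        row = scan.iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert not row["distorted"]

    def test_worked_chi2_value(self):
        """Counts 30/80/50 against 40/80/40: chi2 = 5, p = exp(-2.5)."""
        scan = cp.distortion_chisq_scan(matrix_from_counts(30, 80, 50))
        row = scan.iloc[0]
        assert row["chi2"] == pytest.approx(5.0, abs=1e-9)
        assert row["p"] == pytest.approx(np.exp(-2.5), abs=1e-9)

    def test_sparse_marker_untestable(self):
        scan = cp.distortion_chisq_scan(matrix_from_counts(2, 3, 2))
        assert not scan.iloc[0]["testable"]
        assert not scan.iloc[0]["distorted"]

    def test_viability_selected_locus_flagged(self):
        ch = sim.SimChromosome("c", ["sel"], np.zeros(1))
        cfg = sim.SimConfig(
            n_individuals=500, chromosomes=[ch], viability={"sel": (1.0, 1.0, 0.25)}, seed=4
        )
        m, _ = sim.simulate_f2_population(cfg)
        scan = cp.distortion_chisq_scan(m, alpha=0.05)
        assert scan.iloc[0]["distorted"]


class TestDistortionRegression:
    def test_exact_line(self):
        slope, r2, p = cp.distortion_expansion_regression(
            [0.1, 0.2, 0.3], [1.0, 1.1, 1.2]
        )
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        slope, r2, _ = cp.distortion_expansion_regression([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictor_errors(self):
        with pytest.raises(cp.CompareError, match="zero variance"):
            cp.distortion_expansion_regression([0.2, 0.2, 0.2], [1.0, 1.1, 1.2])


def single_group_map(positions, ids=None):
    positions = np.asarray(positions, dtype=float)
    ids = ids or [f"m{k}" for k in range(len(positions))]
    bins = np.concatenate([[0], np.cumsum(np.diff(positions) > 0)]).astype(int)
    return mb.LinkageMap([mb.LinkageGroup("LG1", ids, positions, bins)])


class TestSpacedSubset:
    def test_exactly_spaced_bins_all_retainable(self):
        lmap = single_group_map([0.0, 5.0, 10.0])
        subset = cp.select_spaced_subset(lmap, min_spacing=5.0, rng=0)
        assert len(subset) == 3

    def test_close_bins_keep_one(self):
        lmap = single_group_map([0.0, 1.0])
        subset = cp.select_spaced_subset(lmap, min_spacing=5.0, rng=0)
        assert len(subset) == 1

    def test_subset_respects_spacing(self):
        rng = np.random.default_rng(0)
        positions = np.sort(rng.uniform(0, 150, size=120))
        positions[0] = 0.0
        lmap = single_group_map(positions)
        pos = dict(zip(lmap.groups[0].marker_ids, lmap.groups[0].positions))
        for seed in range(5):
            subset = cp.select_spaced_subset(lmap, min_spacing=5.0, rng=seed)
            kept = np.sort([pos[mk] for mk in subset])
            assert (np.diff(kept) >= 5.0 - 1e-9).all()

    def test_anchor_varies_with_seed(self):
        positions = np.concatenate([[0.0], np.arange(1.0, 100.0, 1.0)])
        lmap = single_group_map(positions)
        subsets = {tuple(cp.select_spaced_subset(lmap, 5.0, rng=s)) for s in range(10)}
        assert len(subsets) > 1


@pytest.fixture(scope="module")
def clean_population():
    # gamma-renewal interference so the Kosambi positions are calibrated
    # to the generative process even at 5 cM subset spacing
    ch = sim.uniform_chromosome("c", 60, 100.0)
    cfg = sim.SimConfig(
        n_individuals=200, chromosomes=[ch], interference_model="gamma", seed=77
    )
    m, _ = sim.simulate_f2_population(cfg)
    lmap = mb.build_map(m, seed=0)
    return m, lmap


class TestResampling:

    def test_deterministic_given_seed(self, clean_population):
        m, lmap = clean_population
        r1 = cp.resampled_length_distribution(m, lmap, iterations=5, seed=11)
        r2 = cp.resampled_length_distribution(m, lmap, iterations=5, seed=11)
        pd.testing.assert_frame_equal(r1.lengths, r2.lengths)
        assert r1.subset_sizes == r2.subset_sizes

    def test_error_free_resampled_length_near_full(self, clean_population):
        """Clean data: spaced-subset maps average close to the full map."""
        m, lmap = clean_population
        res = cp.resampled_length_distribution(m, lmap, iterations=20, seed=5)
        assert res.total_lengths.mean() == pytest.approx(lmap.total_length_cm(), rel=0.05)


class TestAnova:
    def test_worked_example(self):
        f, (d1, d2), p = cp.anova_compare({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert f == pytest.approx(1.5, abs=1e-9)
        assert (d1, d2) == (1, 4)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_groups_f_zero(self):
        f, _, p = cp.anova_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_flagged_infinite(self):
        f, _, p = cp.anova_compare({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert np.isinf(f)
        assert p == 0.0

    def test_separated_populations_significant(self):
        rng = np.random.default_rng(1)
        a = 1150 + rng.normal(0, 8, size=60)
        b = 1050 + rng.normal(0, 8, size=60)
        f, _, p = cp.anova_compare({"expen": a, "expim": b})
        assert p < 0.001


class TestColinearity:
    def test_identical_orders_r2_one(self):
        lmap = single_group_map(np.arange(10.0))
        res = cp.colinearity_r2(lmap, lmap, "LG1", "LG1")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.inverted_blocks == []

    def test_worked_rank_example(self):
        """Ranks (1,2,3,4) vs (2,1,3,4): R^2 = (4/5)^2 = 0.64."""
        a = single_group_map([0.0, 1.0, 2.0, 3.0], ids=["w", "x", "y", "z"])
        b = single_group_map([0.0, 1.0, 2.0, 3.0], ids=["x", "w", "y", "z"])
        res = cp.colinearity_r2(a, b, "LG1", "LG1")
        assert res.r_squared == pytest.approx(0.64, abs=1e-12)

    def test_reversed_order_perfect_negative(self):
        a = single_group_map(np.arange(8.0))
        b = single_group_map(np.arange(8.0), ids=[f"m{k}" for k in range(7, -1, -1)])
        res = cp.colinearity_r2(a, b, "LG1", "LG1")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope_sign == -1
        # orientation, not disorder: no inverted blocks after normalization
        assert cp.detect_inverted_blocks(res.ranks_a, res.ranks_b) == []

    def test_symmetry(self):
        a = single_group_map([0.0, 1.0, 2.0, 3.0, 4.0], ids=list("abcde"))
        b = single_group_map([0.0, 1.0, 2.0, 3.0, 4.0], ids=list("acbed"))
        r_ab = cp.colinearity_r2(a, b, "LG1", "LG1").r_squared
        r_ba = cp.colinearity_r2(b, a, "LG1", "LG1").r_squared
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_too_few_common_markers(self):
        a = single_group_map([0.0, 1.0], ids=["a", "b"])
        with pytest.raises(cp.CompareError, match="common markers"):
            cp.colinearity_r2(a, a, "LG1", "LG1", min_common=3)


class TestInvertedBlocks:
    def test_constructed_permutation(self):
        """Indices 8-12 reversed out of 20: exactly that block is reported."""
        a = np.arange(20.0)
        b = a.copy()
        b[8:13] = b[8:13][::-1]
        blocks = cp.detect_inverted_blocks(a, b, min_block=4, slope_threshold=0.8)
        assert len(blocks) == 1
        s, e, rho = blocks[0]
        assert (s, e) == (8, 12)
        assert rho == pytest.approx(-1.0, abs=1e-9)

    def test_colinear_no_blocks(self):
        a = np.arange(30.0)
        assert cp.detect_inverted_blocks(a, a) == []

    def test_no_false_positives_on_mapped_colinear_pairs(self):
        """Independently mapped populations of the same cross layout never
        trigger inversion calls (20 pairs here; the wider sweep runs in the
        acceptance suite)."""
        assert count_inversion_false_positives(n_pairs=20, seed0=9000) == 0

    def test_end_to_end_inversion_detection(self):
        """A 6-marker inversion between two simulated crosses is localized."""
        ch1 = sim.uniform_chromosome("cA", 30, 60.0)
        ch2 = sim.uniform_chromosome("cB", 30, 60.0)
        m_a, _ = sim.simulate_f2_population(
            sim.SimConfig(n_individuals=150, chromosomes=[ch1, ch2], seed=11)
        )
        lo = ch2.cm_positions[10] - 0.1
        hi = ch2.cm_positions[15] + 0.1
        ch2_inv = sim.reverse_segment(ch2, lo, hi)
        m_b, _ = sim.simulate_f2_population(
            sim.SimConfig(n_individuals=150, chromosomes=[ch1, ch2_inv], seed=12)
        )
        map_a = mb.build_map(m_a, seed=0)
        map_b = mb.build_map(m_b, seed=0)
        results = cp.compare_maps(map_a, map_b)
        assert len(results) == 2
        by_chrom = {
            ("cB" if any(mk.startswith("cB") for mk in res.common_markers) else "cA"): res
            for res in results
        }
        assert by_chrom["cA"].inverted_blocks == []
        blocks = by_chrom["cB"].inverted_blocks
        assert len(blocks) == 1
        s, e, _ = blocks[0]
        assert (s, e) == (10, 15)


class TestPrintedRatios:
    def test_percent_longer(self):
        assert cp.percent_longer(150.0, 100.0) == pytest.approx(50.0)

    def test_percent_reduction(self):
        assert cp.percent_reduction(200.0, 150.0) == pytest.approx(25.0)

    def test_invalid_reference(self):
        with pytest.raises(cp.CompareError):
            cp.percent_longer(1.0, 0.0)
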