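"""Overlap curves, scrambled baselines, informative size, final lists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordkit.listsize import (
    DEFAULT_K,
    OverlapCurve,
    _differences,
    estimate_informative_size,
    final_list,
    method_ratio_histogram,
    overlap_curve,
    percent_overlap,
    scrambled_baseline,
)
from cordkit.synth import two_phase_rank_lists


def symbols(n, tag="G"):
    return [f"{tag}{i:05d}" for i in range(n)]


class TestPercentOverlap:
    def test_identical_disjoint_and_partial(self):
        a = symbols(20, "A")
        assert percent_overlap(a, list(a), 7) == 100.0
        assert percent_overlap(a, symbols(20, "B"), 10) == 0.0
        b = a[:4] + symbols(16, "B")  # top-10 share exactly 4
        assert percent_overlap(a, b, 10) == 40.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        g = symbols(50)
        a = list(rng.permutation(g))
        b = list(rng.permutation(g))
        for n in (1, 10, 50):
            assert percent_overlap(a, b, n) == percent_overlap(b, a, n)

    def test_errors(self):
        a = symbols(5)
        with pytest.raises(ValueError, match="exceeds"):
            percent_overlap(a, a, 6)
        with pytest.raises(ValueError, match="duplicate"):
            percent_overlap(["x", "x", "y"], a[:3], 2)
        with pytest.raises(ValueError):
            percent_overlap(a, a, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_matches_set_intersection_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        g = symbols(40)
        a = list(rng.permutation(g))
        b = list(rng.permutation(g))
        expected = 100.0 * len(set(a[:n]) & set(b[:n])) / n
        assert percent_overlap(a, b, n) == expected


class TestOverlapCurve:
    def test_identical_lists_are_flat_at_100(self):
        a = symbols(1000)
        curve = overlap_curve(a, list(a))
        assert np.all(curve.overlap_pct == 100.0)
        assert np.allclose(curve.d1, 0.0, atol=1e-12)

    def test_random_lists_match_chance_expectation(self):
        rng = np.random.default_rng(1)
        g = symbols(5000)
        a = list(rng.permutation(g))
        b = list(rng.permutation(g))
        curve = overlap_curve(a, b, n_min=100, n_max=1000, step=100)
        expected = 100.0 * curve.n_values / 5000.0
        # sampling error shrinks with n; generous envelope
        assert np.all(np.abs(curve.overlap_pct - expected) < 3.0)

    def test_short_lists_truncate_the_grid(self):
        a = symbols(150)
        curve = overlap_curve(a, list(a), n_min=10, n_max=1000, step=10)
        assert curve.n_values[-1] == 150

    def test_two_phase_lists_plateau_after_breakpoint(self):
        a, b = two_phase_rank_lists(breakpoint=200, plateau_pct=50.0)
        curve = overlap_curve(a, b)
        after = curve.overlap_pct[curve.n_values >= 250]
        assert np.allclose(after, 50.0, atol=1.0)
        early = curve.overlap_pct[curve.n_values <= 100]
        assert np.all(early < 45.0)


class TestScrambledBaseline:
    def test_same_seed_is_identical(self):
        rng = np.random.default_rng(2)
        g = symbols(500)
        a, b = list(rng.permutation(g)), list(rng.permutation(g))
        c1 = scrambled_baseline(a, b, n_max=500, n_reps=5, seed=99)
        c2 = scrambled_baseline(a, b, n_max=500, n_reps=5, seed=99)
        np.testing.assert_array_equal(c1.overlap_pct, c2.overlap_pct)

    def test_matches_hypergeometric_expectation(self):
        g = symbols(2000)
        base = scrambled_baseline(g, list(g), n_max=2000, step=200, n_reps=50, seed=3)
        expected = 100.0 * base.n_values / 2000.0
        assert np.all(np.abs(base.overlap_pct - expected) < 1.0)

    def test_full_length_overlap_is_total(self):
        g = symbols(300)
        base = scrambled_baseline(g, list(g), n_min=300, n_max=300, n_reps=3, seed=0)
        assert base.overlap_pct[-1] == 100.0


class TestInformativeSize:
    def baseline_for(self, a, b, seed=0):
        return scrambled_baseline(a, b, n_max=min(len(a), len(b)), n_reps=20, seed=seed)

    def test_two_phase_breakpoint_recovered(self):
        a, b = two_phase_rank_lists(breakpoint=300, plateau_pct=50.0)
        curve = overlap_curve(a, b)
        k = estimate_informative_size(curve, self.baseline_for(a, b))
        assert 250 <= k <= 350

    def test_linear_from_start_returns_grid_minimum(self):
        # exactly one shared symbol per rank block: flat 10% overlap
        a, b = [], []
        for j in range(100):
            a += [f"S{j}"] + [f"A{j}_{i}" for i in range(9)]
            b += [f"S{j}"] + [f"B{j}_{i}" for i in range(9)]
        curve = overlap_curve(a, b)
        k = estimate_informative_size(curve, self.baseline_for(a, b))
        assert k == 10

    def test_pathological_curve_falls_back_to_default(self):
        n = np.arange(10, 1001, 10)
        pct = 50.0 + 40.0 * np.sin(n / 25.0)  # never settles
        d1, d2 = _differences(pct)
        curve = OverlapCurve(n, pct, d1, d2)
        flat = OverlapCurve(n, np.full_like(pct, 10.0), np.zeros_like(pct), np.zeros_like(pct))
        assert estimate_informative_size(curve, flat) == DEFAULT_K

    def test_mismatched_grids_rejected(self):
        a, b = two_phase_rank_lists()
        curve = overlap_curve(a, b)
        base = scrambled_baseline(a, b, n_max=500, n_reps=2, seed=0)
        with pytest.raises(ValueError, match="grid"):
            estimate_informative_size(curve, base)

    def test_stable_under_grid_refinement(self):
        a5, b5 = two_phase_rank_lists(breakpoint=300, step=5)
        k5 = estimate_informative_size(
            overlap_curve(a5, b5, step=5),
            scrambled_baseline(a5, b5, step=5, n_reps=20, seed=1),
        )
        a10, b10 = two_phase_rank_lists(breakpoint=300, step=10)
        k10 = estimate_informative_size(
            overlap_curve(a10, b10, step=10),
            scrambled_baseline(a10, b10, step=10, n_reps=20, seed=1),
        )
        assert abs(k5 - k10) <= 50  # one smoothing window


def recs(pairs):
    df = pd.DataFrame(pairs, columns=["gene", "r"])
    df["n_shared"] = 10
    return df


class TestMethodRatioHistogram:
    def test_identical_records_center_at_zero(self):
        r = recs([("A", 0.9), ("B", 0.5), ("C", 0.1)])
        mc = method_ratio_histogram(r, r.copy())
        assert np.allclose(mc.ratios, 0.0)
        assert mc.median == 0.0

    def test_doubled_grouped_correlations_center_at_minus_one(self):
        ind = recs([("A", 0.4), ("B", 0.3), ("C", 0.2)])
        grp = recs([("A", 0.8), ("B", 0.6), ("C", 0.4)])
        mc = method_ratio_histogram(ind, grp)
        assert mc.median == pytest.approx(-1.0)

    def test_known_scaling_recovered_within_tolerance(self):
        rng = np.random.default_rng(4)
        genes = symbols(200)
        r_ind = rng.uniform(0.05, 0.7, 200)
        scale = 2 ** 0.42  # grouped stronger by 0.42 log2 units
        r_grp = np.clip(r_ind * scale * rng.lognormal(0, 0.05, 200), 1e-6, 0.999)
        mc = method_ratio_histogram(
            recs(list(zip(genes, r_ind))), recs(list(zip(genes, r_grp)))
        )
        assert abs(mc.median - (-0.42)) < 0.1
        assert mc.counts.sum() == 200

    def test_negative_correlations_are_excluded(self):
        ind = recs([("A", 0.5), ("B", -0.5)])
        grp = recs([("A", 0.5), ("B", 0.5)])
        mc = method_ratio_histogram(ind, grp)
        assert list(mc.ratios.index) == ["A"]


class TestFinalList:
    def test_identical_rankings_keep_top_k_in_grouped_order(self):
        rng = np.random.default_rng(5)
        genes = symbols(600)
        r = np.sort(rng.uniform(-1, 1, 600))[::-1]
        records = recs(list(zip(genes, r)))
        lists = final_list(records, records.copy(), k=400)
        positive = records[records["r"] > 0]
        expected = positive.head(400)
        assert list(lists.similar["gene"]) == list(expected["gene"])
        assert (lists.similar["r_grouped"].diff().dropna() <= 0).all()
        assert (lists.dissimilar["r_grouped"].diff().dropna() >= 0).all()

    def test_disjoint_top_k_yields_empty(self):
        a = recs([(f"A{i}", 0.9 - i * 0.01) for i in range(10)])
        b = recs([(f"B{i}", 0.9 - i * 0.01) for i in range(10)])
        lists = final_list(a, b, k=5)
        assert lists.similar.empty
        assert lists.dissimilar.empty

    def test_small_fixture_matches_set_oracle(self):
        ind = recs(
            [("A", 0.9), ("B", 0.8), ("C", 0.7), ("D", 0.6), ("E", -0.2),
             ("F", -0.5), ("G", -0.9), ("H", 0.1), ("I", 0.05), ("J", -0.05)]
        )
        grp = recs(
            [("B", 0.95), ("A", 0.85), ("D", 0.75), ("H", 0.65), ("E", -0.3),
             ("G", -0.8), ("F", -0.4), ("C", 0.02), ("I", -0.1), ("J", 0.3)]
        )
        k = 4
        top_ind = set(ind.nlargest(k, "r")["gene"])
        top_grp = set(grp.nlargest(k, "r")["gene"])
        lists = final_list(ind, grp, k=k)
        assert set(lists.similar["gene"]) == top_ind & top_grp == {"A", "B", "D"}
        assert list(lists.similar["gene"]) == ["B", "A", "D"]  # grouped order
        bot_ind = set(ind.nsmallest(k, "r")["gene"])
        bot_grp = set(grp.nsmallest(k, "r")["gene"])
        # sign-mixed genes are excluded even when they intersect
        expected_dis = {
            g for g in bot_ind & bot_grp
            if ind.set_index("gene").loc[g, "r"] < 0
            and grp.set_index("gene").loc[g, "r"] < 0
        }
        assert set(lists.dissimilar["gene"]) == expected_dis == {"E", "F", "G"}
        assert list(lists.dissimilar["gene"]) == ["G", "F", "E"]

    def test_lists_are_subsets_of_both_top_k(self):
        rng = np.random.default_rng(6)
        genes = symbols(500)
        ind = recs(list(zip(genes, rng.uniform(-1, 1, 500))))
        grp = recs(list(zip(genes, rng.uniform(-1, 1, 500))))
        k = 100
        lists = final_list(ind, grp, k=k)
        assert len(lists.similar) <= k
        assert set(lists.similar["gene"]) <= set(ind.nlargest(k, "r")["gene"])
        assert set(lists.similar["gene"]) <= set(grp.nlargest(k, "r")["gene"])
        assert not (set(lists.similar["gene"]) & set(lists.dissimilar["gene"]))
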