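import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_stepup
from hybridexpr import (
    CountMatrix,
    NormalizedMatrix,
    SimConfig,
    bh_adjust,
    by_adjust,
    classify_gene,
    filter_candidates,
    mid_parent_value,
    normalize_cpm,
    run_pattern_analysis,
    simulate_cross,
)
from hybridexpr.patterns import test_vs_mpv as one_sample_mpv_test
from hybridexpr.patterns import CATEGORIES, classify_matrix


def _tissue_cm(expressed_in):
    """18-sample single-tissue matrix; gene gX has count>0 in `expressed_in`
    samples, gene g_all everywhere."""
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(18)],
            "group": ["P1"] * 6 + ["P2"] * 6 + ["F1"] * 6,
            "tissue": ["liver"] * 18,
            "sex": ["unknown"] * 18,
        }
    ).set_index("sample_id")
    row = np.zeros(18, dtype=int)
    row[:expressed_in] = 5
    counts = pd.DataFrame(
        [row, np.full(18, 3)], index=["gX", "g_all"], columns=meta.index
    )
    return CountMatrix(counts, meta)


class TestFilter:
    def test_expressed_in_half_is_kept(self):
        assert "gX" in filter_candidates(_tissue_cm(9), "liver")

    def test_below_half_is_dropped(self):
        assert "gX" not in filter_candidates(_tissue_cm(8), "liver")

    def test_expressed_everywhere_is_kept(self):
        assert filter_candidates(_tissue_cm(18), "liver") == ["gX", "g_all"]

    def test_unknown_tissue_errors(self):
        with pytest.raises(ValueError, match="muscle"):
            filter_candidates(_tissue_cm(9), "muscle")


class TestMPV:
    def _norm(self, p1, p2):
        meta = pd.DataFrame(
            {
                "sample_id": [f"a{i}" for i in range(len(p1))]
                + [f"b{i}" for i in range(len(p2))],
                "group": ["P1"] * len(p1) + ["P2"] * len(p2),
                "tissue": ["t"] * (len(p1) + len(p2)),
                "sex": ["unknown"] * (len(p1) + len(p2)),
            }
        ).set_index("sample_id")
        values = pd.DataFrame([list(p1) + list(p2)], index=["g"], columns=meta.index)
        return NormalizedMatrix(values, meta, "cpm")

    def test_symmetric_parents(self):
        assert mid_parent_value(self._norm([5.0, 5.0], [5.0, 5.0]), "g") == 5.0

    def test_forced_by_definition(self):
        assert mid_parent_value(self._norm([0.0, 0.0], [8.0, 8.0]), "g") == 4.0

    def test_direct_arithmetic(self):
        assert mid_parent_value(self._norm([2.0, 4.0, 6.0], [10.0, 10.0, 10.0]), "g") == 7.0


class TestBY:
    def test_single_p_identity(self):
        assert by_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_harmonic_factor(self):
        # c(3) = 1 + 1/2 + 1/3 = 11/6; all step-up values collapse to 0.055
        np.testing.assert_allclose(
            by_adjust([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055], atol=1e-12
        )

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_oracle_and_dominates_bh(self, p):
        by = by_adjust(p)
        np.testing.assert_allclose(by, brute_force_stepup(p, by=True), atol=1e-12)
        assert (by >= bh_adjust(p) - 1e-15).all()


class TestVsMPV:
    def test_constant_equal_to_mpv(self):
        assert one_sample_mpv_test([7.0, 7.0, 7.0], 7.0) == (0.0, 1.0)

    def test_mean_equal_to_mpv_gives_t_zero(self):
        t, p = one_sample_mpv_test([10.0, 11.0, 12.0, 9.0, 10.0, 11.0], 10.5)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_tiny_spread(self):
        _, p = one_sample_mpv_test([100.0, 100.001, 99.999, 100.0], 10.0)
        assert p < 1e-6

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            one_sample_mpv_test([1.0], 1.0)


class TestClassifyGene:
    def test_nonsignificant_mpv_is_additive(self):
        assert classify_gene(0.40, 0.001, 0.001, 5, 8, 2) == "additive"

    def test_over_dominance(self):
        assert classify_gene(0.001, 0.002, 0.9, 10, 8, 2) == "over_dominance"

    def test_under_dominance(self):
        assert classify_gene(0.001, 0.9, 0.002, 1, 8, 2) == "under_dominance"

    def test_enhancing_dominance(self):
        assert classify_gene(0.001, 0.50, 0.003, 7, 8, 2) == "enhancing_dominance"

    def test_suppressing_dominance(self):
        assert classify_gene(0.001, 0.003, 0.50, 3, 8, 2) == "suppressing_dominance"

    def test_unnamed_combination_falls_through(self):
        # significant vs both parents but F1 strictly between them
        assert (
            classify_gene(0.001, 0.003, 0.004, 5, 8, 2)
            == "unclassified_nonadditive"
        )

    def test_parental_tie_blocks_dominance_calls(self):
        assert classify_gene(0.001, 0.001, 0.001, 9, 5, 5, high_parent="tie") == (
            "unclassified_nonadditive"
        )
        assert classify_gene(0.40, 0.001, 0.001, 9, 5, 5, high_parent="tie") == (
            "additive"
        )

    def test_missing_q_is_not_testable(self):
        assert classify_gene(np.nan, 0.5, 0.5, 5, 8, 2) == "not_testable"

    def test_every_combination_gets_exactly_one_category(self):
        # enumerate significance patterns x F1 position relative to parents
        mean_high, mean_low = 8.0, 2.0
        for q_mpv, q_high, q_low, mean_f1 in itertools.product(
            (0.001, 0.5), (0.001, 0.5), (0.001, 0.5), (1.0, 5.0, 9.0)
        ):
            cat = classify_gene(q_mpv, q_high, q_low, mean_f1, mean_high, mean_low)
            assert cat in CATEGORIES
            if q_mpv >= 0.05:
                assert cat == "additive"
            else:
                assert cat != "additive"
                if cat == "over_dominance":
                    assert q_high < 0.05 and mean_f1 > mean_high
                if cat == "under_dominance":
                    assert q_low < 0.05 and mean_f1 < mean_low


@pytest.fixture(scope="module")
def strong_records(strong_sim):
    cm, truth = strong_sim
    records = run_pattern_analysis(cm, "breast_muscle")
    return records, truth


class TestRunPatternAnalysis:
    def test_partition_every_candidate_classified_once(self, strong_records):
        records, truth = strong_records
        assert len(records) == len(truth)  # all simulated genes pass the filter
        assert records["category"].isin(CATEGORIES).all()
        assert records["gene_id"].is_unique

    def test_mpv_is_parental_mean_exactly(self, strong_records):
        records, _ = strong_records
        np.testing.assert_array_equal(
            records["mpv"], (records["mean_p1"] + records["mean_p2"]) / 2.0
        )

    def test_truth_recovery_on_strong_signal(self, strong_records):
        records, truth = strong_records
        mode = truth.set_index("gene_id").loc[records["gene_id"], "mode"].to_numpy()
        cat = records["category"].to_numpy()
        for m in np.unique(mode):
            target = "additive" if m == "null_equal" else m
            assert (cat[mode == m] == target).mean() >= 0.9, m

    def test_parent_label_swap_leaves_categories_unchanged(self, strong_sim):
        cm, _ = strong_sim
        swapped_meta = cm.meta.copy()
        swapped_meta["group"] = swapped_meta["group"].map(
            {"P1": "P2", "P2": "P1", "F1": "F1"}
        )
        swapped = CountMatrix(cm.counts.copy(), swapped_meta)
        a = run_pattern_analysis(cm, "breast_muscle")
        b = run_pattern_analysis(swapped, "breast_muscle")
        assert list(a["category"]) == list(b["category"])
        np.testing.assert_allclose(a["mean_p1"], b["mean_p2"], rtol=1e-12)

    def test_null_simulation_calls_few_nonadditive(self):
        cm, _ = simulate_cross(
            SimConfig(n_genes_per_mode={"null_equal": 1000}, seed=31)
        )
        records = run_pattern_analysis(cm, "breast_muscle")
        assert (records["category"] != "additive").mean() <= 0.05

    def test_empty_candidate_list(self):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "group": ["P1", "P1", "P2", "P2", "F1", "F1"],
                "tissue": ["t"] * 6,
                "sex": ["unknown"] * 6,
            }
        ).set_index("sample_id")
        counts = pd.DataFrame(
            [[3, 4, 2, 5, 3, 4], [0, 0, 1, 0, 0, 0]],
            index=["keep", "dropme"], columns=meta.index,
        )
        records = run_pattern_analysis(CountMatrix(counts, meta), "t")
        assert list(records["gene_id"]) == ["keep"]
        empty = counts.copy()
        empty.loc[:] = 0
        empty.iloc[0, 0] = 1  # still below the >=50% threshold, nonzero library
        records = run_pattern_analysis(CountMatrix(empty, meta), "t")
        assert records.empty

    def test_missing_group_errors(self, strong_sim):
        cm, _ = strong_sim
        no_f1 = cm.subset_samples(
            list(cm.meta.index[cm.meta["group"] != "F1"])
        )
        with pytest.raises(ValueError, match="F1"):
            run_pattern_analysis(no_f1, "breast_muscle")

    def test_scale_invariance_on_linear_path(self, strong_sim):
        cm, _ = strong_sim
        norm = normalize_cpm(cm)
        a = classify_matrix(norm, scale="linear", align=False)
        scaled = NormalizedMatrix(norm.values * 37.5, norm.meta, norm.method_tag)
        b = classify_matrix(scaled, scale="linear", align=False)
        assert list(a["category"]) == list(b["category"])
        np.testing.assert_allclose(a["p_mpv"], b["p_mpv"], rtol=1e-9)

    def test_two_sample_mpv_variant_agrees_on_strong_signal(self, strong_sim):
        cm, truth = strong_sim
        records = run_pattern_analysis(cm, "breast_muscle", mpv_test="two-sample")
        mode = truth.set_index("gene_id").loc[records["gene_id"], "mode"].to_numpy()
        cat = records["category"].to_numpy()
        sel = mode == "over_dominance"
        assert (cat[sel] == "over_dominance").mean() >= 0.9
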