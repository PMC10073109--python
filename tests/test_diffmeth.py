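"""One-way ANOVA, BH adjustment, and the delta/FDR informative gate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from methrev.datatypes import BetaMatrix, SampleSheet
from methrev.diffmeth import (
    DifferentialTable,
    anova_f_test,
    bh_adjust,
    call_differential,
)
from methrev.errors import ConfigurationError, ValidationError
from oracles import bh_naive_oracle


class TestAnovaF:
    def test_hand_computed_two_group_example(self):
        # SSB = 0.49, SSW = 0.01, df = (1, 2) -> F = 98
        f, p = anova_f_test([0.1, 0.2, 0.8, 0.9], ["a", "a", "b", "b"])
        assert f == pytest.approx(98.0, rel=1e-12)
        assert 0 < p < 0.05

    def test_identical_group_means_with_spread_give_zero_f(self):
        f, _ = anova_f_test([0.1, 0.3, 0.1, 0.3], ["a", "a", "b", "b"])
        assert f == pytest.approx(0.0, abs=1e-15)

    def test_zero_within_variance_different_means_is_infinite(self):
        f, p = anova_f_test([0.2, 0.2, 0.8, 0.8], ["a", "a", "b", "b"])
        assert math.isinf(f) and p == 0.0

    def test_all_identical_values_give_f_zero_p_one(self):
        f, p = anova_f_test([0.5, 0.5, 0.5, 0.5], ["a", "a", "b", "b"])
        assert (f, p) == (0.0, 1.0)

    def test_small_group_flagged_missing_not_raised(self):
        f, p = anova_f_test([0.1, 0.8, 0.9], ["a", "b", "b"])
        assert math.isnan(f) and math.isnan(p)

    def test_missing_values_dropped_pairwise(self):
        f1, p1 = anova_f_test([0.1, 0.2, np.nan, 0.8, 0.9],
                              ["a", "a", "a", "b", "b"])
        f2, p2 = anova_f_test([0.1, 0.2, 0.8, 0.9], ["a", "a", "b", "b"])
        assert f1 == f2 and p1 == p2

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 10, size=2)
            x = rng.random(n1)
            y = rng.random(n2)
            f, p = anova_f_test(np.concatenate([x, y]),
                                ["a"] * n1 + ["b"] * n2)
            t, pt = sps.ttest_ind(x, y, equal_var=True)
            assert f == pytest.approx(t ** 2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-8)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),  # single p: q = p
        ],
    )
    def test_hand_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    def test_missing_entries_pass_through(self):
        q = bh_adjust([0.005, np.nan, 0.5])
        assert np.isnan(q[1])
        # m counts only the 2 non-missing entries
        assert q[0] == pytest.approx(0.01) and q[2] == pytest.approx(0.5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(bh_naive_oracle(p), rel=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_q_dominates_p_and_is_monotone_in_sorted_order(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.random(200)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(q_ref, rel=1e-12)


def _beta_from(values, samples):
    return BetaMatrix(pd.DataFrame(values, columns=samples,
                                   index=[f"cg{i}" for i in range(len(values))]))


def _sheet(groups):
    return SampleSheet(pd.DataFrame(
        {"group": list(groups.values()), "study": "s"},
        index=pd.Index(list(groups), name="sample_id")))


class TestCallDifferential:
    def test_boundary_delta_is_inclusive(self):
        # |delta| exactly 0.66 with a tiny q must be informative
        samples = [f"s{i}" for i in range(8)]
        rows = [[0.90, 0.92, 0.91, 0.89, 0.25, 0.24, 0.26, 0.25],
                [0.50, 0.52, 0.51, 0.49, 0.50, 0.49, 0.51, 0.50]]
        rows[0] = [0.91, 0.91, 0.91, 0.91, 0.25, 0.25, 0.25, 0.25]
        beta = _beta_from(rows, samples)
        sheet = _sheet({s: ("g1" if i < 4 else "g2")
                        for i, s in enumerate(samples)})
        dm = call_differential(beta, sheet, "g1", "g2",
                               delta_min=0.66, q_max=0.01)
        row = dm.table.loc["cg0"]
        assert row["delta_beta"] == pytest.approx(-0.66, abs=1e-12)
        assert bool(row["informative"])
        assert row["direction"] == "hyper"  # group1 mean is higher

    def test_below_threshold_never_informative(self):
        samples = [f"s{i}" for i in range(8)]
        beta = _beta_from([[0.75, 0.75, 0.75, 0.75, 0.25, 0.25, 0.25, 0.25]],
                          samples)
        sheet = _sheet({s: ("g1" if i < 4 else "g2")
                        for i, s in enumerate(samples)})
        dm = call_differential(beta, sheet, "g1", "g2",
                               delta_min=0.66, q_max=0.01)
        # |delta| = 0.5 < 0.66: not informative regardless of q
        assert dm.table["q_value"].iloc[0] <= 0.01
        assert not bool(dm.table["informative"].iloc[0])
        assert dm.table["direction"].iloc[0] == "none"

    def test_unknown_group_label_raises(self, small_beta, two_group_sheet):
        with pytest.raises(ConfigurationError):
            call_differential(small_beta, two_group_sheet, "tumor", "nope",
                              0.2, 0.05)

    def test_invariant_to_row_and_column_order(self, default_sim, default_config):
        sim = default_sim
        beta = sim.beta_a
        sheet = sim.sheet
        dm1 = call_differential(beta, sheet, "NCC", "melanocyte", 0.66, 0.01)
        rng = np.random.default_rng(0)
        rows = rng.permutation(len(beta.probe_ids))
        cols = rng.permutation(len(beta.sample_ids))
        shuffled = BetaMatrix(beta.values.iloc[rows, cols])
        dm2 = call_differential(shuffled, sheet, "NCC", "melanocyte", 0.66, 0.01)
        joined = dm2.table.loc[dm1.table.index]
        pd.testing.assert_frame_equal(dm1.table, joined)

    def test_matches_scalar_anova_per_probe(self, small_beta, two_group_sheet):
        dm = call_differential(small_beta, two_group_sheet, "tumor", "normal",
                               0.2, 0.05)
        labels = two_group_sheet.table.loc[list(small_beta.sample_ids), "group"]
        for probe in small_beta.probe_ids:
            f, p = anova_f_test(small_beta.values.loc[probe].to_numpy(),
                                labels.to_numpy())
            row = dm.table.loc[probe]
            assert row["f_statistic"] == pytest.approx(f, rel=1e-10,
                                                       nan_ok=True)
            assert row["p_value"] == pytest.approx(p, rel=1e-10, nan_ok=True)

    def test_planted_probe_called_with_correct_direction(self, default_sim,
                                                         default_config):
        dm = call_differential(default_sim.beta_a, default_sim.sheet,
                               "NCC", "melanocyte",
                               default_config.delta_min_a, default_config.q_max)
        truth = default_sim.truth
        for direction in ("hyper", "hypo"):
            called = dm.probes_with_direction(direction)
            planted = truth.planted_with_direction(direction)
            assert len(called & planted) / len(planted) >= 0.95

    def test_probes_below_min_samples_kept_with_missing_stats(self):
        samples = ["s1", "s2", "s3", "s4"]
        beta = _beta_from([[0.1, np.nan, 0.8, 0.9]], samples)
        sheet = _sheet({"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"})
        dm = call_differential(beta, sheet, "g1", "g2", 0.2, 0.05)
        row = dm.table.iloc[0]
        assert math.isnan(row["p_value"]) and not bool(row["informative"])
        assert len(dm.table) == 1  # accounted for, not dropped

    def test_tsv_round_trip(self, tmp_path, small_beta, two_group_sheet):
        dm = call_differential(small_beta, two_group_sheet, "tumor", "normal",
                               0.2, 0.05)
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        back = DifferentialTable.from_tsv(path)
        assert back.group1 == "tumor" and back.q_max == 0.05
        pd.testing.assert_frame_equal(
            back.table, dm.table, check_dtype=False, check_exact=False,
            rtol=1e-12)
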