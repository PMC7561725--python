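"""Histology scoring and survival analysis against closed forms and lifelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncscreen.clinical import (
    composite_score,
    four_group_split,
    km_estimate,
    localization_summary,
    logrank_test,
    survival_by_expression_groups,
)
from lncscreen.synthetic import generate_stains, generate_survival


class TestCompositeScore:
    @pytest.mark.parametrize(
        "intensity,proportion,expected",
        [(0.5, 60, 30.0), (0.0, 80, 0.0), (1.0, 100, 100.0)],
    )
    def test_products(self, intensity, proportion, expected):
        assert composite_score(intensity, proportion) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 50)
        with pytest.raises(ValueError):
            composite_score(0.5, 101)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 100))
    def test_bounded_and_bilinear(self, i, p):
        s = composite_score(i, p)
        assert 0 <= s <= 100
        assert np.isclose(composite_score(i / 2, p), s / 2)


class TestLocalization:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "compartment", "intensity", "proportion", "tissue_class"]
        )

    def test_single_sample_split(self):
        df = self._frame(
            [("s1", "nuclear", 1.0, 30.0, "tumour"), ("s1", "cytoplasmic", 1.0, 10.0, "tumour")]
        )
        out = localization_summary(df)
        assert np.isclose(out.loc["tumour", "pct_cytoplasmic"], 25.0)

    def test_all_nuclear_cohort(self):
        df = self._frame(
            [(f"s{i}", c, 0.8, 50.0 if c == "nuclear" else 0.0, "benign")
             for i in range(5) for c in ("nuclear", "cytoplasmic")]
        )
        out = localization_summary(df)
        assert out.loc["benign", "pct_cytoplasmic"] == 0.0

    def test_zero_signal_sample_excluded(self):
        df = self._frame(
            [("s1", "nuclear", 0.0, 0.0, "t"), ("s1", "cytoplasmic", 0.0, 0.0, "t"),
             ("s2", "nuclear", 1.0, 50.0, "t"), ("s2", "cytoplasmic", 1.0, 50.0, "t")]
        )
        out = localization_summary(df)
        assert out.loc["t", "n"] == 1

    def test_recovers_planted_split(self):
        stains = generate_stains(
            n_per_class=200,
            class_effects={"tumour": dict(intensity_a=5, intensity_b=2,
                                          proportion_mean=60, proportion_sd=10)},
            compartment_shift={"tumour": 0.7},
            seed=21,
        )
        out = localization_summary(stains)
        assert abs(out.loc["tumour", "pct_cytoplasmic"] - 70.0) <= 5.0


class TestFourGroupSplit:
    def test_hand_evaluated_median_rule(self):
        # medians 2.5 / 2.5: (1,4)->3, (2,3)->3, (3,2)->2, (4,1)->2
        records = pd.DataFrame({"expr_pcg": [1, 2, 3, 4], "expr_lnc": [4, 3, 2, 1]})
        assert four_group_split(records).tolist() == [3, 3, 2, 2]

    def test_value_at_median_counts_as_low(self):
        records = pd.DataFrame({"expr_pcg": [1, 2, 3, 4, 5], "expr_lnc": [5, 4, 3, 2, 1]})
        # middle sample sits exactly at both medians -> both low -> group 4
        assert four_group_split(records).tolist()[2] == 4

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame(
            {"expr_pcg": rng.normal(size=20), "expr_lnc": rng.normal(size=20)}
        )
        base = four_group_split(records)
        perm = rng.permutation(20)
        shuffled = four_group_split(records.iloc[perm].reset_index(drop=True))
        assert shuffled.tolist() == base.iloc[perm].tolist()

    def test_every_record_gets_exactly_one_group(self):
        rng = np.random.default_rng(1)
        records = pd.DataFrame(
            {"expr_pcg": rng.normal(size=101), "expr_lnc": rng.normal(size=101)}
        )
        groups = four_group_split(records)
        assert set(groups.unique()) <= {1, 2, 3, 4} and len(groups) == 101

    def test_constant_column_rejected(self):
        records = pd.DataFrame({"expr_pcg": [1.0] * 5, "expr_lnc": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="constant"):
            four_group_split(records)


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5.0, size=80)
        curve = km_estimate(t, np.ones(80, dtype=int))
        for x in np.quantile(t, [0.1, 0.5, 0.9]):
            assert np.isclose(curve.survival_at(x), np.mean(t > x))

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        t = rng.exponential(5.0, size=120)
        e = (rng.uniform(size=120) < 0.7).astype(int)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for i, ti in enumerate(curve.event_times):
            assert np.isclose(curve.survival[i], kmf.survival_function_at_times(ti).iloc[0])

    def test_exponential_median_closed_form(self):
        lam = 0.1
        cohort = generate_survival(500, {"g": lam}, censor_rate=0.0, seed=5)
        curve = km_estimate(cohort["time"], cohort["event"])
        assert abs(curve.median - np.log(2) / lam) / (np.log(2) / lam) < 0.10


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = logrank_test([(t, e), (t, e)])
        assert np.isclose(res.chi_square, 0.0, atol=1e-12) and res.p == 1.0

    def test_no_events_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test([([1.0], [0]), ([2.0], [0])])
        assert res.p == 1.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        groups = [
            (rng.exponential(5, 40), np.ones(40, dtype=int)),
            (rng.exponential(3, 40), np.ones(40, dtype=int)),
            (rng.exponential(8, 40), np.ones(40, dtype=int)),
        ]
        a = logrank_test(groups)
        b = logrank_test(groups[::-1])
        assert np.isclose(a.chi_square, b.chi_square)

    def test_two_group_statistic_squares_standardized_oe(self):
        """For K=2 the statistic equals ((O1-E1)/sqrt(V11))^2 of either group."""
        rng = np.random.default_rng(7)
        g1 = (rng.exponential(5, 30), np.ones(30, dtype=int))
        g2 = (rng.exponential(2, 30), np.ones(30, dtype=int))
        res = logrank_test([g1, g2])
        swapped = logrank_test([g2, g1])
        assert np.isclose(res.chi_square, swapped.chi_square)
        assert res.df == 1

    def test_matches_lifelines_multigroup(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(s, 50) for s in (5.0, 4.0, 2.0, 6.0)])
        e = (rng.uniform(size=200) < 0.8).astype(int)
        lab = np.repeat([0, 1, 2, 3], 50)
        ours = logrank_test([(t[lab == k], e[lab == k]) for k in range(4)])
        ref = multivariate_logrank_test(t, lab, e)
        assert np.isclose(ours.chi_square, ref.test_statistic)
        assert np.isclose(ours.p, ref.p_value)


class TestFourGroupSurvival:
    def test_end_to_end_recovers_group_hazards(self):
        records = generate_survival(
            60, {1: 0.4, 2: 0.2, 3: 0.1, 4: 0.05}, censor_rate=0.1, seed=9,
            with_expression=True,
        )
        res = survival_by_expression_groups(records)
        # well-separated expression -> median split recovers the planted groups
        assert (res["groups"].to_numpy() == records["group"].to_numpy()).mean() > 0.95
        assert res["logrank"].p < 1e-6
        med1 = res["curves"][1].median
        med4 = res["curves"][4].median
        assert med1 < med4  # higher hazard, shorter survival
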