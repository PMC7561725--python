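"""Statistical engine: quantile normalization, moderated t, BH-FDR, thresholds."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from lncscreen.destats import (
    Contrast,
    ModerationPrior,
    ThresholdRule,
    apply_thresholds,
    bh_fdr,
    estimate_prior,
    fit_de,
    log2_transform,
    quantile_normalize,
)
from lncscreen.io_formats import ExpressionMatrix


def _expr(values: np.ndarray, n1: int, n2: int) -> ExpressionMatrix:
    n = values.shape[1]
    assert n == n1 + n2
    cols = [f"s{i}" for i in range(n)]
    design = pd.Series(["g1"] * n1 + ["g2"] * n2, index=cols)
    genes = [f"gene{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=cols), design=design)


CONTRAST = Contrast("g1_over_g2", "g1", "g2")


class TestQuantileNormalize:
    def test_two_column_example(self):
        expr = _expr(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]).reshape(3, 2), 1, 1)
        # per-rank means of [1,2,3] and [4,5,6]
        out = quantile_normalize(expr).values
        assert out.iloc[:, 0].tolist() == [2.5, 3.5, 4.5]
        assert out.iloc[:, 1].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        expr = _expr(np.column_stack([col, col, col]), 2, 1)
        out = quantile_normalize(expr).values.to_numpy()
        assert np.allclose(out, np.column_stack([col, col, col]))

    def test_ties_get_mean_of_reference_span(self):
        # column A = [1,1,2], column B = [3,4,5]; ref = [2, 2.5, 3.5];
        # A's tie at ranks 1-2 -> mean(2, 2.5) = 2.25
        expr = _expr(np.array([[1.0, 3.0], [1.0, 4.0], [2.0, 5.0]]), 1, 1)
        out = quantile_normalize(expr).values
        assert out.iloc[:, 0].tolist() == [2.25, 2.25, 3.5]
        assert out.iloc[:, 1].tolist() == [2.0, 2.5, 3.5]

    def test_single_sample_rejected(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"s0": [1.0, 2.0]}, index=["a", "b"]),
            design=pd.Series({"s0": "g"}),
        )
        with pytest.raises(ValueError, match="at least 2 samples"):
            quantile_normalize(expr)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arrays(
            float, (7, 4),
            elements=st.floats(0, 1e6, allow_nan=False, allow_infinity=False, width=32),
            unique=True,  # tie-averaging makes exact idempotence a tie-free property
        )
    )
    def test_idempotent_and_equal_column_distributions(self, values):
        expr = _expr(values.astype(float), 2, 2)
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values)
        sorted_cols = np.sort(once.values.to_numpy(), axis=0)
        for j in range(1, 4):
            # ties may perturb individual columns; column means always agree
            assert np.isclose(sorted_cols[:, j].mean(), sorted_cols[:, 0].mean())


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert bh_fdr([1.0]).tolist() == [1.0]

    def test_range_validated(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_permutation_equivariance_and_rank_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200) ** 2
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)


class TestFitDe:
    def test_no_difference_ordinary(self):
        values = np.array([[5.0, 5.0, 5.0, 5.0]])
        res = fit_de(_expr(values, 2, 2), CONTRAST, method="ordinary")
        assert res["log2fc"].iloc[0] == 0 and res["p"].iloc[0] == 1

    def test_group_too_small_rejected(self):
        values = np.ones((2, 3))
        expr = _expr(np.column_stack([values, values[:, :1]]), 1, 3)
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_de(expr, CONTRAST)

    def test_infinite_d0_limit(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(20, 6))
        prior = ModerationPrior(d0=math.inf, s0_sq=2.0)
        res = fit_de(_expr(values, 3, 3), CONTRAST, prior=prior)
        lfc = values[:, :3].mean(axis=1) - values[:, 3:].mean(axis=1)
        expected = lfc / (math.sqrt(2.0) * math.sqrt(1 / 3 + 1 / 3))
        assert np.allclose(res["t_mod"], expected)

    def test_scalar_oracle_single_gene(self):
        """t_mod from fit_de equals a direct scalar evaluation of the formulas."""
        x1 = np.array([8.0, 9.0, 7.5])
        x2 = np.array([6.0, 5.5, 6.5])
        prior = ModerationPrior(d0=4.0, s0_sq=0.5)
        res = fit_de(_expr(np.array([np.r_[x1, x2]]), 3, 3), CONTRAST, prior=prior)
        lfc = x1.mean() - x2.mean()
        s2 = (x1.var(ddof=1) * 2 + x2.var(ddof=1) * 2) / 4
        s2_post = (4.0 * 0.5 + 4 * s2) / (4.0 + 4)
        t = lfc / math.sqrt(s2_post * (2 / 3))
        p = 2 * stats.t.sf(abs(t), df=8)
        assert np.isclose(res["t_mod"].iloc[0], t)
        assert np.isclose(res["p"].iloc[0], p)
        assert res["df_total"].iloc[0] == 8

    def test_small_d0_approaches_ordinary(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(30, 6))
        expr = _expr(values, 3, 3)
        tiny = fit_de(expr, CONTRAST, prior=ModerationPrior(d0=1e-9, s0_sq=1.0))
        ordinary = fit_de(expr, CONTRAST, method="ordinary")
        assert np.allclose(tiny["t_mod"], ordinary["t_mod"], rtol=1e-4)

    def test_zero_variance_gene_moderated(self):
        values = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0], [3.0, 4.0, 5.0, 3.5, 4.5, 5.5]])
        res = fit_de(_expr(values, 3, 3), CONTRAST)
        assert np.isfinite(res["t_mod"]).all()

    def test_all_constant_matrix_degrades_gracefully(self):
        values = np.full((5, 6), 7.0)
        res = fit_de(_expr(values, 3, 3), CONTRAST)
        assert (res["p"] == 1).all()

    def test_prior_estimate_recovers_known_hyperparameters(self):
        """Moment-matching inverts the scaled-F model it assumes: simulate
        s2 ~ s0^2 * F(df, d0) at large m and recover (d0, s0^2)."""
        rng = np.random.default_rng(4)
        d0_true, s0_true, df = 6.0, 0.8, 4
        m = 60_000
        s2 = s0_true * (rng.chisquare(df, m) / df) / (rng.chisquare(d0_true, m) / d0_true)
        prior = estimate_prior(s2, df)
        assert abs(prior.d0 - d0_true) / d0_true < 0.1
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.05

    def test_matches_limma(self, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation in R."""
        rng = np.random.default_rng(8)
        values = rng.normal(8, 1, size=(80, 6)) + rng.normal(0, 0.5, size=(80, 1))
        expr = _expr(values, 3, 3)
        res = fit_de(expr, CONTRAST, method="moderated")
        mat = tmp_path / "m.tsv"
        expr.values.to_csv(mat, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("%s", row.names = 1))
            design <- cbind(Intercept = 1, g1 = c(1, 1, 1, 0, 0, 0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "g1"], p = fit$p.value[, "g1"],
                              d0 = fit$df.prior, s0 = fit$s2.prior)
            write.table(out, "%s", sep = "\t", quote = FALSE)
        """ % (mat, tmp_path / "out.tsv")))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert np.allclose(res["t_mod"], ref["t"], rtol=1e-5)
        assert np.allclose(res["p"], ref["p"], rtol=1e-5)

    def test_power_on_planted_negative_binomial_shifts(self):
        """Moderated selection at (1.5x, FDR 0.1) recovers nearly all planted
        two-fold-change genes at n = 3 vs 3, NB dispersion 0.1."""
        rng = np.random.default_rng(9)
        n_genes, n_planted = 2000, 100
        base = np.exp(rng.normal(np.log(300), 0.8, n_genes))  # realistic mean spread
        base[:n_planted] = 300.0
        mu = np.tile(base[:, None], (1, 6))
        signs = rng.choice([-1, 1], size=n_planted)
        mu[:n_planted, 3:] *= 2.0 ** (2.0 * signs[:, None])
        size = 1 / 0.1
        counts = rng.negative_binomial(size, size / (size + mu))
        expr = quantile_normalize(log2_transform(_expr(counts.astype(float), 3, 3)))
        res = fit_de(expr, CONTRAST)
        selected = apply_thresholds(res, ThresholdRule(1.5, 0.1, "fdr"))
        planted_ids = {f"gene{i}" for i in range(n_planted)}
        recall = len(planted_ids & set(selected.index)) / n_planted
        assert recall >= 0.9


class TestThresholds:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_fdr_rule_selects_up(self):
        res = self._frame([{"log2fc": 0.60, "p": 0.001, "q": 0.05}])
        out = apply_thresholds(res, ThresholdRule(1.5, 0.1, "fdr"))
        assert list(out.index) == ["g0"] and out["direction"].iloc[0] == "up"

    def test_fold_change_floor(self):
        res = self._frame([{"log2fc": -0.50, "p": 0.001, "q": 0.01}])
        assert apply_thresholds(res, ThresholdRule(1.5, 0.1, "fdr")).empty

    def test_raw_p_scale(self):
        res = self._frame([{"log2fc": 2.0, "p": 0.04, "q": 0.2}])
        out = apply_thresholds(res, ThresholdRule(1.5, 0.05, "raw_p"))
        assert list(out.index) == ["g0"]

    def test_strict_boundary_flag(self):
        res = self._frame([{"log2fc": math.log2(1.5), "p": 0.001, "q": 0.01}])
        assert len(apply_thresholds(res, ThresholdRule(1.5, 0.1, "fdr"))) == 1
        assert apply_thresholds(res, ThresholdRule(1.5, 0.1, "fdr", fc_boundary="strict")).empty

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ThresholdRule(0.5, 0.1, "fdr")
        with pytest.raises(ValueError):
            ThresholdRule(1.5, 0.0, "fdr")
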