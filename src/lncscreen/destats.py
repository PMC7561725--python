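"""Expression statistics: quantile normalization, moderated two-group
differential expression, Benjamini–Hochberg FDR and threshold rules.

The differential test is the empirical-Bayes moderated t-statistic for a
two-group comparison.  Per gene g with pooled within-group variance s²_g on
d_g = n₁ + n₂ − 2 degrees of freedom, the variance is shrunk toward a prior:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

with the prior (d₀, s₀²) estimated once across all genes by moment matching
of log s²_g against its scaled-F sampling distribution (trigamma inversion by
Newton's method; d₀ = ∞ when the spread of log s²_g does not exceed its
expected chi-square sampling spread).  The statistic

    t_g = (x̄₁ − x̄₂) / (s̃_g · sqrt(1/n₁ + 1/n₂))

is referred to a t distribution on d_g + d₀ degrees of freedom (standard
normal when d₀ = ∞).  Expression is expected on a log2 scale; upstream
pipelines transform counts with log2(x + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison: numerator over denominator."""

    name: str
    group_numerator: str
    group_denominator: str

    def validate(self, expr: ExpressionMatrix) -> None:
        for g in (self.group_numerator, self.group_denominator):
            if g not in set(expr.design):
                raise ValueError(f"contrast {self.name!r}: group {g!r} not in design")
        if self.group_numerator == self.group_denominator:
            raise ValueError(f"contrast {self.name!r}: groups must differ")


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes prior: d0 degrees of freedom (possibly inf), s0² variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


@dataclass(frozen=True)
class ThresholdRule:
    """Fold-change + significance selection rule for one contrast.

    ``alpha`` applies to BH-adjusted q-values when ``alpha_scale='fdr'``, to
    raw p-values when ``'raw_p'``.  The fold-change boundary is inclusive
    (|log2FC| >= log2(min_fold_change)) unless ``fc_boundary='strict'``.
    """

    min_fold_change: float = 1.5
    alpha: float = 0.1
    alpha_scale: Literal["fdr", "raw_p"] = "fdr"
    fc_boundary: Literal["inclusive", "strict"] = "inclusive"

    def __post_init__(self):
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.alpha_scale not in ("fdr", "raw_p"):
            raise ValueError(f"unknown alpha_scale {self.alpha_scale!r}")
        if self.fc_boundary not in ("inclusive", "strict"):
            raise ValueError(f"unknown fc_boundary {self.fc_boundary!r}")


@dataclass(frozen=True)
class DEResult:
    """Row schema of the differential-expression table for one gene."""

    gene_id: str
    log2fc: float
    s2: float
    t_mod: float
    df_total: float
    p: float
    q: float


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto one shared empirical distribution.

    The reference distribution is the across-sample mean at each rank of the
    column-sorted values.  Within a column, tied values all receive the mean
    of the reference values over their tied rank span.
    """
    X = expr.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = X.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col_sorted = arr[order, j]
        assigned = ref.copy()
        # average the reference over each run of tied input values
        start = 0
        for k in range(1, len(col_sorted) + 1):
            if k == len(col_sorted) or col_sorted[k] != col_sorted[start]:
                if k - start > 1:
                    assigned[start:k] = ref[start:k].mean()
                start = k
        out[order, j] = assigned
    return expr.with_values(pd.DataFrame(out, index=X.index, columns=X.columns))


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 75) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Moment-matching estimate of (d0, s0²) from per-gene variances.

    Under the hierarchical model, s²_g ~ s0²·F(d_g, d0), so
    e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean
    log s0² − ψ(d0/2) + log(d0/2) and excess variance ψ′(d0/2) beyond the
    sampling term ψ′(d_g/2).  Genes with zero variance carry no information
    about the prior and are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("need at least one gene with positive variance to estimate the prior")
    if pos.size == 1:
        # no spread information: complete shrinkage to the single observed variance
        return ModerationPrior(d0=math.inf, s0_sq=float(pos[0]))
    e = np.log(pos) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond chi-square sampling: complete shrinkage, and
        # the moment estimate of s0² is the plain mean of the variances
        d0 = math.inf
        s0_sq = float(np.mean(s2))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def fit_de(
    expr: ExpressionMatrix,
    contrast: Contrast,
    method: Literal["moderated", "ordinary"] = "moderated",
    prior: ModerationPrior | None = None,
) -> pd.DataFrame:
    """Two-group differential expression for one contrast.

    Returns a DataFrame indexed by gene id with columns
    ``log2fc, s2, t_mod, df_total, p, q`` (the :class:`DEResult` schema);
    ``q`` is Benjamini–Hochberg adjusted over all genes of this contrast.
    Expression values are taken as already log2-scale.
    """
    contrast.validate(expr)
    if method not in ("moderated", "ordinary"):
        raise ValueError(f"unknown method {method!r}")
    num_samples = expr.group_samples(contrast.group_numerator)
    den_samples = expr.group_samples(contrast.group_denominator)
    n1, n2 = len(num_samples), len(den_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: each group needs >= 2 samples (got {n1}, {n2})"
        )
    X1 = expr.values[num_samples].to_numpy(dtype=float)
    X2 = expr.values[den_samples].to_numpy(dtype=float)
    log2fc = X1.mean(axis=1) - X2.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * X1.var(axis=1, ddof=1) + (n2 - 1) * X2.var(axis=1, ddof=1)) / df_resid
    s2 = np.maximum(s2, 0.0)  # guard tiny negative rounding
    scale = 1.0 / n1 + 1.0 / n2

    if method == "moderated" and prior is None and not np.any(s2 > 0):
        # degenerate input (every gene constant within groups): no prior can be
        # estimated; the ordinary path handles zero variances explicitly
        method = "ordinary"
    if method == "moderated":
        estimated_here = prior is None
        if prior is None:
            prior = estimate_prior(s2, df_resid)
        if math.isinf(prior.d0):
            s2_post = np.full_like(s2, prior.s0_sq)
        else:
            s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid
        if estimated_here:
            # an internally estimated prior cannot carry more information than
            # the data it came from: cap at the pooled residual df over genes
            df_total = min(df_total, len(s2) * df_resid)
        t = log2fc / np.sqrt(s2_post * scale)
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    else:
        s2_post = s2
        df_total = float(df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post * scale)
        # zero-variance genes: t undefined; no change -> p=1, any change -> p=0
        zero = s2_post == 0
        t = np.where(zero & (log2fc == 0), 0.0, t)
        t = np.where(zero & (log2fc != 0), np.sign(log2fc) * np.inf, t)
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where(zero & (log2fc == 0), 1.0, p)

    q = bh_fdr(np.clip(p, 0.0, 1.0))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "t_mod": t,
            "df_total": df_total,
            "p": np.clip(p, 0.0, 1.0),
            "q": q,
        },
        index=pd.Index(expr.values.index, name="gene_id"),
    )


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order.

    q_(i) = min_{j >= i} p_(j)·m/j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_thresholds(results: pd.DataFrame, rule: ThresholdRule) -> pd.DataFrame:
    """Select genes passing the fold-change and significance cut-offs.

    Returns the selected subset of ``results`` with an added ``direction``
    column ('up'/'down' from the sign of log2fc).
    """
    lfc_cut = math.log2(rule.min_fold_change)
    abs_lfc = results["log2fc"].abs()
    fc_ok = abs_lfc >= lfc_cut if rule.fc_boundary == "inclusive" else abs_lfc > lfc_cut
    sig = results["q"] < rule.alpha if rule.alpha_scale == "fdr" else results["p"] < rule.alpha
    selected = results[fc_ok & sig].copy()
    selected["direction"] = np.where(selected["log2fc"] >= 0, "up", "down")
    return selected


def iter_results(frame: pd.DataFrame):
    """Yield :class:`DEResult` records from a fit_de frame."""
    for gene_id, row in frame.iterrows():
        yield DEResult(
            gene_id=str(gene_id),
            log2fc=float(row["log2fc"]),
            s2=float(row["s2"]),
            t_mod=float(row["t_mod"]),
            df_total=float(row["df_total"]),
            p=float(row["p"]),
            q=float(row["q"]),
        )


def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform for count matrices, done before normalization/DE."""
    return expr.with_values(np.log2(expr.values + 1.0))
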