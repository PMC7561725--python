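"""Histology composite scoring and expression-stratified survival analysis.

Composite stain score
    A tissue core stained by ISH or IHC is summarised by two image-analysis
    measurements: signal intensity (continuous, 0–1) and proportion of
    positive tissue (continuous, 0–100%).  The composite score is their
    product, bounded in [0, 100].

Four-group stratification
    For a protein-coding gene (PCG) / lncRNA combination, samples are split
    at each RNA's cohort median ("high" means strictly greater than the
    median) and combined into four groups: 1 = both high; 2 = PCG high,
    lncRNA low; 3 = PCG low, lncRNA high; 4 = both low.

Survival machinery
    The Kaplan–Meier product-limit estimator S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) and
    the K-group log-rank test (hypergeometric variance, chi-square on K−1
    degrees of freedom, generalized inverse for degenerate groups) are
    implemented here from first principles; at tied times events precede
    censorings, the usual convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._util import logger

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"


def composite_score(intensity, proportion):
    """Composite stain score: intensity (0–1) times percent positive (0–100).

    Accepts scalars or arrays; the result lies in [0, 100].
    """
    intensity = np.asarray(intensity, dtype=float)
    proportion = np.asarray(proportion, dtype=float)
    if np.any((intensity < 0) | (intensity > 1)):
        raise ValueError("intensity must lie in [0, 1]")
    if np.any((proportion < 0) | (proportion > 100)):
        raise ValueError("proportion must lie in [0, 100]")
    out = intensity * proportion
    return float(out) if out.ndim == 0 else out


def localization_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Percent cytoplasmic vs nuclear signal per tissue class.

    ``measurements`` needs columns sample_id, compartment ('nuclear' or
    'cytoplasmic'), intensity, proportion and tissue_class.  Per sample the
    cytoplasmic percentage is 100·cyt/(cyt+nuc) of the composite scores; the
    summary averages over samples within each tissue class.  Samples with
    zero total signal are excluded with a warning.
    """
    df = measurements.copy()
    df["score"] = composite_score(df["intensity"].to_numpy(), df["proportion"].to_numpy())
    wide = df.pivot_table(
        index=["tissue_class", "sample_id"], columns="compartment", values="score", aggfunc="sum"
    ).reindex(columns=[NUCLEAR, CYTOPLASMIC], fill_value=0.0).fillna(0.0)
    total = wide[NUCLEAR] + wide[CYTOPLASMIC]
    zero = total == 0
    if zero.any():
        logger.warning("%d samples with zero total stain signal excluded", int(zero.sum()))
        wide = wide[~zero]
        total = total[~zero]
    pct_cyt = 100.0 * wide[CYTOPLASMIC] / total
    out = pct_cyt.groupby(level="tissue_class").agg(["mean", "size"])
    out.columns = ["pct_cytoplasmic", "n"]
    out["pct_nuclear"] = 100.0 - out["pct_cytoplasmic"]
    return out[["pct_cytoplasmic", "pct_nuclear", "n"]]


def four_group_split(records: pd.DataFrame) -> pd.Series:
    """Assign each sample to one of four PCG×lncRNA median-split groups.

    ``records`` needs columns ``expr_pcg`` and ``expr_lnc``.  "High" means
    strictly greater than the cohort median of that RNA (values exactly at
    the median count as low).  Groups: 1 both high; 2 PCG high only;
    3 lncRNA high only; 4 both low.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records for a four-group split")
    for col in ("expr_pcg", "expr_lnc"):
        if records[col].nunique() < 2:
            raise ValueError(f"{col} is constant; no median split possible")
    pcg_high = records["expr_pcg"] > records["expr_pcg"].median()
    lnc_high = records["expr_lnc"] > records["expr_lnc"].median()
    group = np.select(
        [pcg_high & lnc_high, pcg_high & ~lnc_high, ~pcg_high & lnc_high],
        [1, 2, 3],
        default=4,
    )
    return pd.Series(group, index=records.index, name="group")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: survival after each distinct event time."""

    event_times: np.ndarray  # increasing distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n_i at each event time
    events: np.ndarray  # d_i at each event time

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function (S = 1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("inf")


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan–Meier estimate from follow-up times and event indicators.

    Censored subjects leave the risk set after their censoring time; at tied
    times, events are processed before censorings.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    order = np.lexsort((1 - event, time))  # time ascending, events before censorings
    time, event = time[order], event[order]
    uniq_event_times = np.unique(time[event == 1])
    surv, at_risk, d_list = [], [], []
    s = 1.0
    n_total = time.size
    for t in uniq_event_times:
        n_i = int(np.sum(time >= t))  # events at t count as still at risk at t
        d_i = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_list.append(d_i)
    return KMCurve(
        event_times=uniq_event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(d_list, dtype=int),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    df: int
    p: float


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> LogrankResult:
    """K-group log-rank test from (time, event) pairs per group.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the statistic
    is (O−E)ᵀ V⁻ (O−E) over the first K−1 groups (generalized inverse), with
    a chi-square reference on K−1 degrees of freedom.
    """
    K = len(groups)
    if K < 2:
        raise ValueError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    time = np.concatenate(times)
    event = np.concatenate(events)
    label = np.concatenate(labels)

    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        warnings.warn("no events in any group; log-rank undefined, returning p = 1")
        return LogrankResult(chi_square=0.0, df=K - 1, p=1.0)

    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int(np.sum((time == t) & (event == 1)))
        n_i = np.array([np.sum(at_risk & (label == i)) for i in range(K)], dtype=float)
        d_i = np.array(
            [np.sum((time == t) & (event == 1) & (label == i)) for i in range(K)], dtype=float
        )
        O += d_i
        E += d * n_i / n
        if n > 1:
            frac = n_i / n
            hyper = d * (n - d) / (n - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    u = (O - E)[: K - 1]
    v = V[: K - 1, : K - 1]
    chi = float(u @ linalg.pinvh(v) @ u)
    p = float(stats.chi2.sf(chi, df=K - 1))
    return LogrankResult(chi_square=chi, df=K - 1, p=p)


def survival_by_expression_groups(records: pd.DataFrame) -> dict:
    """Four-group median-split survival analysis in one call.

    ``records`` needs columns time, event, expr_pcg, expr_lnc.  Returns the
    group labels, one KM curve per non-empty group, and the log-rank test
    over the groups.
    """
    labels = four_group_split(records)
    curves: dict[int, KMCurve] = {}
    group_data = []
    for g in (1, 2, 3, 4):
        sub = records[labels == g]
        if len(sub):
            curves[g] = km_estimate(sub["time"], sub["event"])
            group_data.append((sub["time"].to_numpy(), sub["event"].to_numpy()))
    test = logrank_test(group_data) if len(group_data) >= 2 else None
    return {"groups": labels, "curves": curves, "logrank": test}


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_time": curve.event_times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
        }
    )
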