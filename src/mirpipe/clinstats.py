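"""Biomarker and bench-quantification statistics.

ROC/AUC with a DeLong confidence interval, median-split Kaplan–Meier with
the log-rank test and an O/E hazard ratio, 2^-ddCt relative qPCR
quantification, ChIP percent-of-input, and the caliper tumor-volume
formula V = length x width^2 / 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ROCResult:
    points: pd.DataFrame  # threshold, fpr, tpr
    auc: float
    ci_low: float
    ci_high: float


@dataclass
class KMGroup:
    name: str
    times: np.ndarray  # event/censor times in ascending order of the step grid
    survival: np.ndarray  # product-limit estimate after each time
    n: int
    observed: float
    expected: float


@dataclass
class LogrankResult:
    groups: list[KMGroup]
    chi2: float
    p_value: float
    hazard_ratio: float | None  # high vs low expression; None when undefined


@dataclass
class QPCRMeasurement:
    """Replicated Ct quartet for one target against an endogenous control."""

    ct_target_treated: list[float]
    ct_control_treated: list[float]
    ct_target_reference: list[float]
    ct_control_reference: list[float]

    def __post_init__(self):
        for name in ("ct_target_treated", "ct_control_treated", "ct_target_reference", "ct_control_reference"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"missing Ct values for {name}")
            if any(v <= 0 for v in vals):
                raise ValueError("Ct values must be positive")


@dataclass
class DDCTResult:
    ddct: float
    fold_change: float
    fold_sem: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve, trapezoidal AUC, and a DeLong 95% confidence interval.

    The AUC equals the Mann–Whitney statistic with half-credit for tied
    scores; the CI uses the DeLong placement-value variance, clipped to
    [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    # placements: per case, fraction of controls scoring below (+ half ties)
    order = np.sort(controls)
    v10 = (np.searchsorted(order, cases, side="left")
           + 0.5 * (np.searchsorted(order, cases, side="right") - np.searchsorted(order, cases, side="left"))) / n
    order_c = np.sort(cases)
    v01 = (np.searchsorted(order_c, controls, side="left")
           + 0.5 * (np.searchsorted(order_c, controls, side="right") - np.searchsorted(order_c, controls, side="left"))) / m
    v01 = 1.0 - v01  # per control, fraction of cases scoring above (+ half ties)
    auc = float(v10.mean())

    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * math.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(cases >= t).mean() if np.isfinite(t) else 0.0 for t in thresholds]
    fpr = [(controls >= t).mean() if np.isfinite(t) else 0.0 for t in thresholds]
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return ROCResult(points, auc, ci_low, ci_high)


def km_curve(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate: distinct event times and S(t) after each."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return event_times, np.array(surv)


def km_logrank_median_split(records: pd.DataFrame) -> LogrankResult:
    """Median-split survival comparison with the log-rank test.

    Samples at or below the median expression form the low group (ties to
    low).  The log-rank chi-square sums observed-minus-expected events over
    distinct event times with the usual hypergeometric variance; the hazard
    ratio is (O_high/E_high)/(O_low/E_low).  With no events at all the
    comparison is vacuous: p = 1 and the HR is undefined.
    """
    expr = records["expression"].to_numpy(dtype=float)
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    median = np.median(expr)
    high = expr > median
    groups_idx = {"low": ~high, "high": high}
    if min(high.sum(), (~high).sum()) < 2:
        raise ValueError("need at least two records per group after the median split")

    event_times = np.unique(times[events == 1])
    o = {g: 0.0 for g in groups_idx}
    e = {g: 0.0 for g in groups_idx}
    var = 0.0
    for t in event_times:
        n_at = {g: np.sum(times[idx] >= t) for g, idx in groups_idx.items()}
        d_at = {g: np.sum((times[idx] == t) & (events[idx] == 1)) for g, idx in groups_idx.items()}
        n_tot = sum(n_at.values())
        d_tot = sum(d_at.values())
        for g in groups_idx:
            o[g] += d_at[g]
            e[g] += d_tot * n_at[g] / n_tot
        if n_tot > 1:
            var += (
                d_tot
                * (n_at["high"] / n_tot)
                * (n_at["low"] / n_tot)
                * (n_tot - d_tot)
                / (n_tot - 1)
            )

    groups = []
    for g, idx in groups_idx.items():
        et, sv = km_curve(times[idx], events[idx])
        groups.append(KMGroup(g, et, sv, int(idx.sum()), o[g], e[g]))

    if len(event_times) == 0 or var == 0:
        warnings.warn("no events (all records censored); log-rank comparison is vacuous")
        return LogrankResult(groups, 0.0, 1.0, None)
    chi2 = (o["high"] - e["high"]) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    hr = None
    if o["low"] > 0 and e["low"] > 0 and e["high"] > 0:
        hr = float((o["high"] / e["high"]) / (o["low"] / e["low"]))
    return LogrankResult(groups, float(chi2), p, hr)


def ddct(m: QPCRMeasurement) -> DDCTResult:
    """Relative expression by 2^-ddCt.

    dCt = Ct_target − Ct_control per condition (replicate means), ddCt =
    dCt_treated − dCt_reference, fold = 2^−ddCt.  The SEM of ddCt is
    propagated from the four replicate SEMs and mapped to the fold scale by
    the delta method.
    """
    def mean_sem(vals):
        arr = np.asarray(vals, dtype=float)
        sem = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        return arr.mean(), sem

    mt_t, se_tt = mean_sem(m.ct_target_treated)
    mc_t, se_ct = mean_sem(m.ct_control_treated)
    mt_r, se_tr = mean_sem(m.ct_target_reference)
    mc_r, se_cr = mean_sem(m.ct_control_reference)
    ddct_val = (mt_t - mc_t) - (mt_r - mc_r)
    se = math.sqrt(se_tt**2 + se_ct**2 + se_tr**2 + se_cr**2)
    fold = 2.0 ** (-ddct_val)
    return DDCTResult(float(ddct_val), float(fold), float(fold * math.log(2) * se))


def chip_percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP enrichment as a percentage of input chromatin.

    The input Ct is first adjusted down by log2(1/fraction) to represent
    100% of chromatin; percent input = 100 × 2^(adjusted input Ct − IP Ct).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input fraction must lie in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume V = length × width² / 2 (mm³)."""
    if length < 0 or width < 0:
        raise ValueError("dimensions must be nonnegative")
    if width > length:
        warnings.warn("width exceeds length; arguments may be swapped")
    return length * width**2 / 2.0
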