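"""Two-group differential expression for count matrices.

Re-implements the classic count-based DE stack from first principles:
trimmed-mean-of-M-values (TMM) between-library normalization, a pooled
method-of-moments common-dispersion estimate, the two-group
negative-binomial exact test on equalized pseudo-counts, and
Benjamini–Hochberg FDR.  The dispersion estimator is deliberately the
transparent method-of-moments pool rather than conditional maximum
likelihood; at the replicate numbers this package targets (2–3 per group)
the difference is within the noise of either estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

_TIE_REL_TOL = 1e-7  # relative tolerance when comparing conditional masses


@dataclass
class CountMatrix:
    """Features × samples integer counts with two-group labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: list[str]
    lib_sizes: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("group labels must cover all samples")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
            if np.any(self.lib_sizes <= 0):
                raise ValueError("a sample has zero total counts; provide explicit library sizes")
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if np.any(self.lib_sizes <= 0):
                raise ValueError("library sizes must be positive")

    @property
    def group_names(self) -> list[str]:
        # lexicographic order: group 1 is the alphabetically first label,
        # so logFC is group2-vs-group1 regardless of column arrangement
        return sorted(set(self.groups))

    def group_columns(self) -> tuple[np.ndarray, np.ndarray]:
        names = self.group_names
        if len(names) != 2:
            raise ValueError("exactly two groups are required for testing")
        g = np.asarray(self.groups)
        return np.flatnonzero(g == names[0]), np.flatnonzero(g == names[1])


@dataclass
class NormalizationFactors:
    factors: np.ndarray
    reference_sample: str
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError("factors must have geometric mean 1")


def tmm_factors(matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose 75th-percentile count-per-million
    lies closest to the mean of those percentiles.  For each sample,
    per-feature log2 proportion ratios (M) and mean log2 abundances (A)
    against the reference are doubly trimmed — the most extreme ``trim_m``
    fraction by M (split across both tails) and ``trim_a`` by A — and the
    factor is 2 to the precision-weighted mean of the surviving M values,
    with binomial delta-method weights.  Factors are rescaled to geometric
    mean 1.
    """
    counts = matrix.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    lib = matrix.lib_sizes

    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    pr = counts[:, ref] / lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ps = counts[:, j] / lib[j]
        ok = (ps > 0) & (pr > 0)
        if not ok.any():
            warnings.warn(
                f"sample {matrix.sample_ids[j]} shares no nonzero feature with the reference; factor set to 1"
            )
            continue
        m = np.log2(ps[ok] / pr[ok])
        a = 0.5 * np.log2(ps[ok] * pr[ok])
        # binomial delta-method variance on the proportion scale; depth-free
        # so factors are exactly invariant to uniform scaling of any library
        w = (1.0 - ps[ok]) / ps[ok] + (1.0 - pr[ok]) / pr[ok]
        lo_m, hi_m = np.quantile(m, [trim_m / 2, 1 - trim_m / 2])
        lo_a, hi_a = np.quantile(a, [trim_a / 2, 1 - trim_a / 2])
        trimmed = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a) & (w > 0)
        if not trimmed.any():
            continue
        factors[j] = 2.0 ** (np.sum(m[trimmed] / w[trimmed]) / np.sum(1.0 / w[trimmed]))
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(factors, matrix.sample_ids[ref], list(matrix.sample_ids))


def effective_lib_sizes(matrix: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    return matrix.lib_sizes * factors.factors


def estimate_common_dispersion(matrix: CountMatrix, factors: NormalizationFactors) -> float:
    """Pooled method-of-moments common NB dispersion.

    Counts are put on the common effective library size; per feature and
    replicated group the raw moment estimate (s² − m)/m² is formed, averaged
    across groups, clamped at zero, and the median over features with grand
    within-group mean > 5 is returned.  Falls back to 0 (Poisson) with a
    warning when no group has replicates.
    """
    eff = effective_lib_sizes(matrix, factors)
    common = np.exp(np.mean(np.log(eff)))
    z = matrix.counts / eff * common
    idx1, idx2 = matrix.group_columns()
    replicated = [idx for idx in (idx1, idx2) if len(idx) >= 2]
    if not replicated:
        warnings.warn("no replicated group; falling back to Poisson (dispersion 0)")
        return 0.0
    per_group = []
    for idx in replicated:
        m = z[:, idx].mean(axis=1)
        v = z[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_group.append(np.where(m > 0, (v - m) / m**2, np.nan))
    raw = np.nanmean(np.column_stack(per_group), axis=1)
    grand_mean = z[:, np.concatenate(replicated)].mean(axis=1)
    usable = (grand_mean > 5) & np.isfinite(raw)
    if not usable.any():
        return 0.0
    return float(max(0.0, np.median(np.maximum(raw[usable], 0.0))))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def pseudo_counts(matrix: CountMatrix, factors: NormalizationFactors) -> tuple[np.ndarray, float]:
    """Counts scaled to the geometric-mean effective library size, rounded half-up."""
    eff = effective_lib_sizes(matrix, factors)
    common = np.exp(np.mean(np.log(eff)))
    return _round_half_up(matrix.counts * (common / eff)), common


def _exact_test_pvalue(s1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB test p-value by the minimum-likelihood rule.

    Conditional on the total ``t``, the first group's sum is compared
    against its null distribution: Binomial(t, n1/(n1+n2)) when phi = 0
    (the Poisson limit), otherwise the distribution induced by modelling
    each group sum as NB with mean proportional to its replicate number and
    dispersion phi divided by the replicate number.
    """
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 1e-12:
        logp = stats.binom.logpmf(k, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        lp1 = stats.nbinom.logpmf(k, r1, r1 / (r1 + m1))
        lp2 = stats.nbinom.logpmf(t - k, r2, r2 / (r2 + m2))
        logp = lp1 + lp2
        logp -= logsumexp(logp)
    obs = logp[s1]
    keep = logp <= obs + np.log1p(_TIE_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def nb_exact_test(
    matrix: CountMatrix, factors: NormalizationFactors, dispersion: float
) -> pd.DataFrame:
    """Per-feature two-group NB exact test on equalized pseudo-counts.

    Returns a frame with ``feature_id``, ``logFC`` (group 2 vs group 1, with
    a 0.5 prior count on each group mean) and ``PValue``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    pseudo, _ = pseudo_counts(matrix, factors)
    idx1, idx2 = matrix.group_columns()
    n1, n2 = len(idx1), len(idx2)
    s1 = pseudo[:, idx1].sum(axis=1)
    s2 = pseudo[:, idx2].sum(axis=1)
    mean1 = pseudo[:, idx1].mean(axis=1)
    mean2 = pseudo[:, idx2].mean(axis=1)
    lfc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    pvals = np.array(
        [_exact_test_pvalue(int(a), int(a + b), n1, n2, dispersion) for a, b in zip(s1, s2)]
    )
    return pd.DataFrame({"feature_id": matrix.feature_ids, "logFC": lfc, "PValue": pvals})


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, fdr_threshold: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Label features up/down/ns at a strict FDR threshold.

    ``up``/``down`` require FDR strictly below the threshold and a positive/
    negative logFC; everything else (including FDR exactly at the threshold)
    is ``ns``.  Returns the augmented frame and a summary dict.
    """
    out = results.copy()
    if "FDR" not in out.columns:
        out["FDR"] = bh_fdr(out["PValue"].to_numpy())
    sig = out["FDR"] < fdr_threshold
    out["call"] = np.where(
        sig & (out["logFC"] > 0), "up", np.where(sig & (out["logFC"] < 0), "down", "ns")
    )
    summary = {
        "total": int((out["call"] != "ns").sum()),
        "up": int((out["call"] == "up").sum()),
        "down": int((out["call"] == "down").sum()),
    }
    return out, summary


def de_pipeline(matrix: CountMatrix, fdr_threshold: float = 0.05, dispersion: float | None = None):
    """TMM → dispersion → exact test → BH → calls, in one step."""
    factors = tmm_factors(matrix)
    phi = estimate_common_dispersion(matrix, factors) if dispersion is None else dispersion
    results = nb_exact_test(matrix, factors, phi)
    results["FDR"] = bh_fdr(results["PValue"].to_numpy())
    results, summary = call_de(results, fdr_threshold)
    return results, summary, factors, phi
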