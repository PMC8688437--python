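"""Target-gene CDF-shift analysis and set-overlap statistics.

A miRNA that falls after knockdown releases repression of its targets, so
the log2 fold changes (LFCs) of its target genes should shift positive
relative to non-target background genes.  The shift is scored by the
two-sample Kolmogorov–Smirnov statistic between the target-set LFC
distribution and the background LFC distribution, with background defined
as all expressed genes excluding the cognate miRNA's targets.

The module also carries the cross-cell-line statistics: one-sided
hypergeometric overlap of DE feature sets, Pearson concordance of paired
LFCs, and generic Fisher-exact set enrichment with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffexpr import bh_fdr


@dataclass
class ShiftResult:
    mirna_id: str
    n_targets_expressed: int
    n_background: int
    ks_statistic: float
    p_value: float
    signed_shift: float
    direction_consistent: bool | None
    underpowered: bool


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p_value: float

    def __post_init__(self):
        if not self.n_overlap <= min(self.n_a, self.n_b) <= self.universe:
            raise ValueError("inconsistent overlap sizes")


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic with the asymptotic Kolmogorov p-value.

    D is the supremum absolute difference of the two empirical CDFs
    (standard step construction, ties included); p is the Kolmogorov
    survival function at sqrt(mn/(m+n))·D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / m
    cdf_y = np.searchsorted(y, pooled, side="right") / n
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(m * n / (m + n))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return d, p


def target_shift_test(
    mirna_id: str,
    target_map: dict[str, set[str]],
    lfc_table: pd.Series | dict,
    mirna_lfc: float,
    min_targets: int = 10,
) -> ShiftResult:
    """KS comparison of target-gene LFCs against the non-target background.

    ``lfc_table`` maps expressed genes to their LFC; targets are intersected
    with it and every remaining expressed gene forms the background, so the
    two samples strictly partition the expressed genes.  ``signed_shift`` is
    median(target LFC) − median(background LFC); the direction is consistent
    with repression release when its sign opposes the miRNA's own LFC.
    Results from fewer than ``min_targets`` expressed targets are flagged
    underpowered but still computed.
    """
    lfc = pd.Series(lfc_table, dtype=float)
    targets = set(target_map.get(mirna_id, set())) & set(lfc.index)
    background = [g for g in lfc.index if g not in targets]
    n_t, n_b = len(targets), len(background)
    if n_t == 0 or n_b == 0:
        return ShiftResult(mirna_id, n_t, n_b, np.nan, np.nan, np.nan, None, True)
    t_vals = lfc[sorted(targets)].to_numpy()
    b_vals = lfc[background].to_numpy()
    d, p = ks_two_sample(t_vals, b_vals)
    shift = float(np.median(t_vals) - np.median(b_vals))
    consistent: bool | None
    if shift == 0 or mirna_lfc == 0:
        consistent = None
    else:
        consistent = bool(np.sign(shift) == -np.sign(mirna_lfc))
    return ShiftResult(mirna_id, n_t, n_b, d, p, shift, consistent, n_t < min_targets)


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        special.gammaln(K + 1)
        - special.gammaln(k + 1)
        - special.gammaln(K - k + 1)
        + special.gammaln(N - K + 1)
        - special.gammaln(n - k + 1)
        - special.gammaln(N - K - n + k + 1)
        - (special.gammaln(N + 1) - special.gammaln(n + 1) - special.gammaln(N - n + 1))
    )


def concordant_de_overlap(set_a, set_b, universe_size: int) -> OverlapResult:
    """One-sided hypergeometric test of set overlap.

    P(X ≥ |A∩B|) for X hypergeometric with the given universe, computed by
    log-space summation of the upper tail; identical to a one-sided Fisher
    exact test on the 2×2 table.
    """
    a, b = set(set_a), set(set_b)
    n_a, n_b, k_obs = len(a), len(b), len(a & b)
    if max(n_a, n_b) > universe_size:
        raise ValueError("set larger than universe")
    k_max = min(n_a, n_b)
    k = np.arange(k_obs, k_max + 1)
    k = k[(k >= max(0, n_a + n_b - universe_size))]
    if len(k) == 0:
        p = 1.0 if k_obs <= max(0, n_a + n_b - universe_size) else 0.0
    else:
        p = float(min(1.0, np.exp(special.logsumexp(_log_hypergeom_pmf(k, universe_size, n_a, n_b)))))
    return OverlapResult(n_a, n_b, k_obs, universe_size, p)


def pearson_lfc_concordance(paired_lfcs) -> tuple[float, float]:
    """Pearson r between paired per-miRNA LFCs from two cell lines.

    p comes from the t distribution with n − 2 degrees of freedom; with
    zero variance in either coordinate the correlation is undefined and
    (nan, nan) is returned.
    """
    arr = np.asarray(paired_lfcs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def set_enrichment(query_set, annotation_sets: dict, universe) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query set against annotation sets.

    Each annotation set is tested for overlap with the query within the
    universe; BH adjustment runs across all sets.  Output is sorted by
    (FDR, p, name) so the ranking is invariant to input ordering.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set) & universe
    rows = []
    for name in annotation_sets:
        ann = set(annotation_sets[name]) & universe
        res = concordant_de_overlap(query, ann, len(universe))
        rows.append({"set_name": name, "n_set": len(ann), "n_overlap": res.n_overlap, "p": res.p_value})
    frame = pd.DataFrame(rows, columns=["set_name", "n_set", "n_overlap", "p"])
    frame["fdr"] = bh_fdr(frame["p"].to_numpy()) if len(frame) else []
    return frame.sort_values(["fdr", "p", "set_name"], kind="mergesort").reset_index(drop=True)
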