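"""Cross-group nonparametric statistics.

Wilcoxon rank-sum (Mann-Whitney) comparisons with exact small-sample
p-values, log10 fold-changes of group medians, Spearman age-trend
correlation, and a batch comparison driver producing the star notation
(* p<0.05 ** p<0.01 *** p<0.001 **** p<0.0001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_PAIR_LIMIT = 400  # exact Wilcoxon null when nA*nB <= this and no ties


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Rank-sum test: (U, two-sided p).

    U counts (x_i, y_j) pairs with x_i > y_j, ties contributing 1/2.  The
    exact null distribution is used for small tie-free samples
    (nA*nB <= 400); otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # fully tied: no evidence of a shift
        return x.size * y.size / 2.0, 1.0
    method = "exact" if (x.size * y.size <= EXACT_PAIR_LIMIT and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def median_log10_fold_change(x, y) -> float:
    """log10(median(x) / median(y)); inf / nan flag degenerate medians."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    mx, my = float(np.median(x)), float(np.median(y))
    if my == 0:
        return math.inf if mx > 0 else math.nan
    if mx == 0:
        return -math.inf
    return math.log10(mx / my)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    n = xr.size
    perms = np.array(list(permutations(range(n))))
    yp = yr[perms]                       # (n!, n) permuted y-ranks
    xc = xr - xr.mean()
    yc = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    rho = (yc @ xc) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def age_trend(ages, freqs) -> tuple[float, float]:
    """Spearman rank correlation between age and a frequency.

    Average ranks for ties; exact permutation p for n <= 9, t-approximation
    otherwise.  Constant input yields (nan, nan).
    """
    ages = np.asarray(ages, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if ages.size != freqs.size or ages.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(ages) == 0 or np.ptp(freqs) == 0:
        return math.nan, math.nan
    if ages.size <= 9:
        xr = sps.rankdata(ages)
        yr = sps.rankdata(freqs)
        rho = float(np.corrcoef(xr, yr)[0, 1])
        return rho, _exact_spearman_p(xr, yr, rho)
    res = sps.spearmanr(ages, freqs)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    log10_fc: float
    U: float
    p: float
    stars: str


def compare_groups(values: pd.DataFrame, feature: str,
                   comparisons: list[tuple[str, str]],
                   bh: bool = False) -> pd.DataFrame:
    """One Wilcoxon comparison row per requested (group A, group B) pair.

    ``values`` must hold columns ``group`` and ``value`` (one row per donor),
    e.g. from :func:`csfcyto.metrics.donor_values` or a scores table.  Raw
    p-values by default; ``bh=True`` appends a Benjamini-Hochberg column over
    the requested comparisons.
    """
    for col in ("group", "value"):
        if col not in values.columns:
            raise ValueError(f"values frame must have a {col!r} column")
    present = set(values["group"])
    rows = []
    for a, b in comparisons:
        for g in (a, b):
            if g not in present:
                raise ValueError(f"group {g!r} has no donors in the values frame")
        va = values.loc[values["group"] == a, "value"].to_numpy(dtype=float)
        vb = values.loc[values["group"] == b, "value"].to_numpy(dtype=float)
        u, p = wilcoxon_rank_sum(va, vb)
        rows.append(ComparisonResult(
            feature=feature, group_a=a, group_b=b, n_a=va.size, n_b=vb.size,
            median_a=float(np.median(va)), median_b=float(np.median(vb)),
            log10_fc=median_log10_fold_change(va, vb),
            U=u, p=p, stars=significance_stars(p)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh and not out.empty:
        out["p_bh"] = sps.false_discovery_control(out["p"], method="bh")
    return out
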