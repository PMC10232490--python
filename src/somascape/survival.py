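"""Survival stratification and the study's statistical toolkit.

Stratification rules (signature presence at >= 15% exposure; tertile
low/high split with ties to the lower group), the Kaplan-Meier
product-limit estimator, the k-group log-rank test with optional
subject weights, inverse-probability weights from categorical
stage x treatment strata, Benjamini-Hochberg adjustment, the exact
two-sided binomial enrichment test and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "stratify_presence",
    "stratify_tertiles",
    "km_curve",
    "SurvivalResult",
    "logrank_test",
    "ipw_weights",
    "bh_adjust",
    "binomial_enrichment_test",
    "pearson_correlation",
]


def stratify_presence(
    exposures: pd.Series, cutoff: float = 0.15
) -> pd.Series:
    """Label samples 'present' (exposure >= cutoff) or 'absent'."""
    return pd.Series(
        np.where(exposures.to_numpy(dtype=float) >= cutoff, "present", "absent"),
        index=exposures.index,
        name="presence",
    )


def stratify_tertiles(values: pd.Series) -> pd.Series:
    """Split a continuous feature into low / mid / high tertiles.

    Cut points are the 1/3 and 2/3 empirical quantiles; ties go to the
    lower group (low: v <= q1; mid: q1 < v <= q2; high: v > q2). The
    mid group is excluded from two-group tests by the caller.
    """
    x = values.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate strata: all values identical")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    labels = np.where(x <= q1, "low", np.where(x <= q2, "mid", "high"))
    return pd.Series(labels, index=values.index, name="tertile")


def km_curve(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame of (time, at_risk, events, survival) rows at the
    distinct event times, starting from S(0) = 1. Censored-only data
    yields the constant curve S = 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [(0.0, len(t), 0, 1.0)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / at_risk
        rows.append((float(ti), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


@dataclass
class SurvivalResult:
    statistic: float
    p: float
    df: int
    group_sizes: dict
    weighting: str = "none"
    q: Optional[float] = None


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
    weights: Optional[Sequence[float]] = None,
) -> SurvivalResult:
    """K-group log-rank chi-square test, optionally subject-weighted.

    The statistic is z' V^{-1} z over the first g-1 groups, where z
    accumulates observed-minus-expected events at each distinct event
    time and V the hypergeometric covariance. With subject weights
    (e.g. inverse-probability weights), every subject's contribution to
    the at-risk, observed and covariance terms is multiplied by its
    weight.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    k = len(levels)
    gi = np.searchsorted(np.sort(levels.astype(str)), g.astype(str))
    # remap to the sorted-level index
    level_order = np.argsort(levels.astype(str))
    sizes = {str(levels[level_order[i]]): int(np.sum(gi == i)) for i in range(k)}

    z = np.zeros(k)
    V = np.zeros((k, k))
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n_g = np.array([w[at & (gi == i)].sum() for i in range(k)])
        n_tot = n_g.sum()
        if n_tot <= 0:
            continue
        died = (t == ti) & (e == 1)
        d_g = np.array([w[died & (gi == i)].sum() for i in range(k)])
        d_tot = d_g.sum()
        if d_tot == 0:
            continue
        expected = d_tot * n_g / n_tot
        z += d_g - expected
        if n_tot > 1:
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            for a in range(k):
                for b in range(k):
                    if a == b:
                        V[a, b] += factor * n_g[a] * (n_tot - n_g[a]) / n_tot**2
                    else:
                        V[a, b] -= factor * n_g[a] * n_g[b] / n_tot**2
    z_r = z[:-1]
    V_r = V[:-1, :-1]
    if np.allclose(V_r, 0):
        stat = 0.0
    else:
        stat = float(z_r @ np.linalg.pinv(V_r) @ z_r)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=k - 1))
    return SurvivalResult(
        stat, p, k - 1, sizes, "none" if weights is None else "IPW"
    )


def ipw_weights(
    groups: Sequence, strata: Sequence, smoothing: float = 0.5
) -> np.ndarray:
    """Inverse-probability weights from categorical covariate strata.

    The propensity P(group | stratum) comes from the group x stratum
    cross-tabulation; strata missing a group are smoothed by adding
    ``smoothing`` to every cell of that stratum, so the weight is
    always finite. Weights are normalized to mean 1 within each group.
    """
    g = pd.Series(list(groups)).astype(str)
    s = pd.Series(list(strata)).astype(str)
    tab = pd.crosstab(s, g)
    raw = np.empty(len(g))
    for stratum, row in tab.iterrows():
        cells = row.to_numpy(dtype=float)
        if (cells == 0).any():
            cells = cells + smoothing
        probs = cells / cells.sum()
        for gi, level in enumerate(row.index):
            mask = (s == stratum) & (g == level)
            raw[mask.to_numpy()] = 1.0 / probs[gi]
    out = raw.copy()
    for level in g.unique():
        mask = (g == level).to_numpy()
        out[mask] = raw[mask] / raw[mask].mean()
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_enrichment_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test of k successes in n at rate p0.

    Two-sided by summing the probabilities of all outcomes at most as
    likely as the observed one.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 <= 1:
        raise ValueError("p0 must lie in (0, 1]")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
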