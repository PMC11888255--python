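"""Statistical decision layer.

Three procedures cover the pipeline's group comparisons: Mann-Whitney U
(exact by full enumeration for small samples, tie-corrected normal
approximation otherwise), Pearson chi-square on 2x2 transition tables, and
a linear-mixed-model group effect with a random intercept per cluster
(neuron or culture), judged significant at a given level when the
corresponding confidence interval excludes zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

CI_LEVELS = (95.0, 99.0, 99.5, 99.9, 99.95, 99.99)


@dataclass
class EffectReport:
    """Group-effect estimate with a ladder of confidence intervals.

    ``ci`` maps confidence level (percent) to (lower, upper); ``significant``
    maps level to whether that CI excludes zero.  CI widths are monotone
    non-decreasing in level by construction.
    """

    estimate: float
    se: float
    ci: dict[float, tuple[float, float]]
    significant: dict[float, bool]
    test: str
    n_per_group: dict

    def summary(self) -> str:
        lines = [f"{self.test}: estimate = {self.estimate:.4g} (SE {self.se:.3g})"]
        for lev in sorted(self.ci):
            lo, hi = self.ci[lev]
            star = "significant" if self.significant[lev] else "ns"
            lines.append(f"  {lev:g}% CI [{lo:.4g}, {hi:.4g}] -> {star}")
        return "\n".join(lines)


def _exact_u_distribution(pooled: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the rank-sum of a size-n1 subset.

    Midranks handle ties; doubled midranks are integers, enabling a
    dynamic-programming count over (subset size, doubled rank sum).
    Returns (possible doubled rank sums, counts).
    """
    r2 = np.rint(2 * sstats.rankdata(pooled)).astype(int)
    max_sum = int(r2.sum())
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in r2:
        for c in range(n1, 0, -1):  # descending: row c-1 still pre-update
            table[c, r:] += table[c - 1, :-r]
    counts = table[n1]
    sums = np.flatnonzero(counts)
    return sums, counts[sums]


def mann_whitney_u(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    For combined n <= ``exact_max_n`` the p-value is exact over all
    C(n, n1) group labelings of the pooled values (midranks make the
    enumeration tie-correct); the null U distribution is symmetric about
    n1*n2/2, and the two-sided p is the probability of a U at least as far
    from that center as observed.  Larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_max_n:
        sums2, counts = _exact_u_distribution(pooled, n1)
        u_all = sums2 / 2.0 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        p = counts[np.abs(u_all - mu) >= dev - 1e-9].sum() / comb(n1 + n2, n1)
        return u_obs, float(min(1.0, p))
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    Continuity (Yates) correction is off by default, matching the plain
    chi-square convention; enable via ``correction=True``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("cells must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    stat, p, _, _ = sstats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def lmm_group_effect(data: pd.DataFrame, value: str = "value",
                     group: str = "group", cluster: str = "cluster",
                     levels=CI_LEVELS) -> EffectReport:
    """Group effect from a linear mixed model with random cluster intercepts.

    ``data`` holds one row per observation; observations cluster within
    neurons or cultures.  The fixed effect is the indicator of the second
    group (sorted order).  Wald confidence intervals are reported at every
    level in ``levels``; an effect is significant at a level iff that CI
    excludes zero.  With fewer than 2 clusters per group the model is
    unidentifiable and an ordinary least-squares interval is reported with a
    logged caveat.
    """
    df = data[[value, group, cluster]].dropna().copy()
    groups = sorted(df[group].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    n_per_group = df.groupby(group, observed=True)[value].size().to_dict()
    y = df[value].to_numpy(dtype=float)
    x = (df[group] == groups[1]).to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(x), x])

    if np.ptp(y) == 0:
        ci = {float(l): (0.0, 0.0) for l in levels}
        sig = {float(l): False for l in levels}
        return EffectReport(0.0, 0.0, ci, sig, "LMM (degenerate: constant data)",
                            n_per_group)

    clusters_per_group = df.groupby(group, observed=True)[cluster].nunique()
    test_name = "LMM random-intercept"
    if (clusters_per_group < 2).any():
        logger.warning("fewer than 2 clusters in a group; falling back to OLS "
                       "interval (clustering not estimable)")
        fit = sm.OLS(y, exog).fit()
        est, se = float(fit.params[1]), float(fit.bse[1])
        dist = sstats.t(df=fit.df_resid)
        test_name = "OLS fallback (single cluster)"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=df[cluster].to_numpy())
            fit = model.fit(reml=True)
        est, se = float(fit.params[1]), float(fit.bse[1])
        # group is a cluster-level covariate: between-within t reference
        # (df = clusters - 2), the standard small-sample correction for
        # Wald intervals on mixed-model fixed effects
        n_clusters = int(df[cluster].nunique())
        dist = sstats.t(df=max(n_clusters - 2, 1))
        if not np.isfinite(se):
            logger.warning("non-finite LMM standard error; reporting OLS interval")
            fit = sm.OLS(y, exog).fit()
            est, se = float(fit.params[1]), float(fit.bse[1])
            dist = sstats.t(df=fit.df_resid)
            test_name = "OLS fallback (LMM SE not finite)"
    ci, sig = {}, {}
    for lev in levels:
        z = float(dist.ppf(1 - (1 - lev / 100.0) / 2.0))
        lo, hi = est - z * se, est + z * se
        ci[float(lev)] = (lo, hi)
        sig[float(lev)] = bool(lo > 0 or hi < 0)
    return EffectReport(est, se, ci, sig, test_name, n_per_group)
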