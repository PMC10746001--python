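"""Group-comparison decision tree for scalar endpoints.

Each endpoint is routed by per-group Shapiro-Wilk normality at alpha: all
groups Gaussian -> one-way ANOVA with Tukey's HSD; otherwise Kruskal-Wallis
with Dunn's post-hoc test (Bonferroni family over all pairs by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import bh_fdr, kw_test


@dataclass
class ComparisonReport:
    endpoint: str
    normality_p: dict
    path: str                 # 'parametric' | 'nonparametric'
    omnibus_stat: float
    omnibus_p: float
    posthoc: pd.DataFrame     # group_1, group_2, statistic, p_raw, p_adjusted


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return bh_fdr(p)
    if method == "none":
        return p
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after a Kruskal-Wallis omnibus.

    z for a pair (i, j) uses pooled average ranks with tie correction:
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided normal p,
    adjusted over all pairs by `adjust`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("Dunn's test needs at least two groups")
    n = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int((groups == g).sum()) for g in uniq}
    rows = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            g1, g2 = uniq[i], uniq[j]
            se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_1": g1, "group_2": g2, "statistic": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = _adjust(out["p_raw"].to_numpy(), adjust)
    return out


def _tukey(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    uniq = np.unique(groups)
    samples = [values[groups == g] for g in uniq]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            rows.append(
                {
                    "group_1": uniq[i],
                    "group_2": uniq[j],
                    "statistic": float(res.statistic[i, j]),
                    "p_raw": float(res.pvalue[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),  # Tukey is jointly adjusted
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    values,
    groups,
    alpha: float = 0.05,
    endpoint: str = "endpoint",
    force_path: str | None = None,
    dunn_adjust: str = "bonferroni",
) -> ComparisonReport:
    """Route an endpoint through the normality decision tree and compare groups.

    Shapiro-Wilk is run per group; the parametric path (one-way ANOVA +
    Tukey HSD) is taken iff every group's normality p > alpha.  Groups with
    fewer than 3 observations, or with identical values (degenerate for
    Shapiro-Wilk), force the nonparametric path (Kruskal-Wallis + Dunn)
    with a warning.  `force_path` overrides the routing.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in uniq}

    normality_p: dict = {}
    forced = False
    for g, x in samples.items():
        if x.size < 3:
            warnings.warn(
                f"group {g!r} has n={x.size} < 3: normality untestable, "
                "nonparametric path forced",
                stacklevel=2,
            )
            normality_p[g] = np.nan
            forced = True
        elif np.ptp(x) == 0:
            warnings.warn(
                f"group {g!r} has identical values: Shapiro-Wilk degenerate, "
                "nonparametric path forced",
                stacklevel=2,
            )
            normality_p[g] = np.nan
            forced = True
        else:
            normality_p[g] = float(stats.shapiro(x).pvalue)

    if force_path is not None:
        path = force_path
    elif forced:
        path = "nonparametric"
    else:
        path = (
            "parametric"
            if all(p > alpha for p in normality_p.values())
            else "nonparametric"
        )

    if path == "parametric":
        stat, p = stats.f_oneway(*samples.values())
        posthoc = _tukey(values, groups)
    elif path == "nonparametric":
        stat, p = kw_test(values, groups)
        posthoc = dunn_posthoc(values, groups, adjust=dunn_adjust)
    else:
        raise ValueError(f"unknown path {path!r}")

    return ComparisonReport(
        endpoint=endpoint,
        normality_p=normality_p,
        path=path,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        posthoc=posthoc,
    )
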