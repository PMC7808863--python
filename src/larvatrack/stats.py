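"""Two-group comparison by the Wilcoxon-Mann-Whitney rank-sum test.

For the small per-experiment group sizes typical of dish assays (n <= 6 per
group) the exact null distribution of the Mann-Whitney U statistic is
obtained by complete enumeration of all C(n1+n2, n1) group assignments of
the observed (mid-)ranks, which remains exact under ties.  Larger samples
fall back to the tie-corrected normal approximation.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

#: largest combined sample size for which the exact enumeration is used
EXACT_ENUMERATION_MAX_N = 16

_EPS = 1e-9


@dataclass(frozen=True)
class RankSumResult:
    U_statistic: float
    p_two_sided: float
    method: str  # exact_enumeration | exact_with_ties | normal_approx
    n1: int
    n2: int


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon-Mann-Whitney test of samples ``a`` vs ``b``.

    U is the Mann-Whitney statistic of the first sample (number of pairs
    won, ties counted half).  With ``n1 + n2 <= 16`` the p-value is exact:
    every assignment of the pooled mid-ranks to the two groups is
    enumerated and ``p = min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_ENUMERATION_MAX_N:
        u_null = np.array(
            [sum(ranks[list(c)]) for c in combinations(range(n1 + n2), n1)]
        ) - n1 * (n1 + 1) / 2.0
        p_le = float(np.mean(u_null <= u_obs + _EPS))
        p_ge = float(np.mean(u_null >= u_obs - _EPS))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact_with_ties" if has_ties else "exact_enumeration"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approx"
    return RankSumResult(
        U_statistic=u_obs, p_two_sided=p, method=method, n1=n1, n2=n2
    )


METRIC_COLUMNS = (
    "total_distance_px",
    "median_speed_px_per_interval",
    "median_bout_duration_windows",
    "bout_count",
)


def compare_groups(
    metrics: pd.DataFrame,
    group_a: str = "mock",
    group_b: str = "infected",
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Rank-sum comparison of each locomotion metric between two groups.

    One test per metric, per experiment and pooled across experiments.
    NaN metric values (e.g. median speed of a larva that never moved) are
    dropped from that test.  Returns a table
    ``metric,experiment,n1,n2,U,p_two_sided,sig_0.05,sig_0.01``.
    """
    missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    for g in (group_a, group_b):
        if not (metrics["group"] == g).any():
            raise ValueError(f"no larvae with group label {g!r}")

    scopes = [("pooled", metrics)]
    if "experiment" in metrics.columns:
        for exp, sub in metrics.groupby("experiment", sort=True):
            scopes.append((str(exp), sub))

    rows = []
    for metric in METRIC_COLUMNS:
        for scope_name, sub in scopes:
            va = sub.loc[sub["group"] == group_a, metric].dropna().to_numpy()
            vb = sub.loc[sub["group"] == group_b, metric].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                continue
            res = rank_sum_test(va, vb)
            rows.append(
                {
                    "metric": metric,
                    "experiment": scope_name,
                    "n1": res.n1,
                    "n2": res.n2,
                    "U": res.U_statistic,
                    "p_two_sided": res.p_two_sided,
                    f"sig_{alpha_levels[0]}": res.p_two_sided < alpha_levels[0],
                    f"sig_{alpha_levels[1]}": res.p_two_sided < alpha_levels[1],
                }
            )
    return pd.DataFrame(rows)
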