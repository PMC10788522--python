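"""Group comparison helpers for connectivity values.

The default is a two-sample permutation test on the mean difference
(exact enumeration when feasible, Monte Carlo otherwise); Welch's t is
available as an alternative.  ``compare_profiles`` applies the test per
network and direction with Bonferroni correction across the 14
comparisons.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["regress_out", "compare_groups", "compare_profiles"]


def regress_out(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residualise connectivity values against a nuisance covariate.

    ``covariate`` may be numeric or categorical (e.g. medication class);
    categories are dummy-coded.  Returns the residuals of an ordinary
    least-squares fit with intercept, preserving the overall mean.
    """
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covariate)
    if cov.shape[0] != values.shape[0]:
        raise ValueError("covariate length must match number of subjects")
    if cov.dtype.kind in "OUS":  # categorical -> dummy columns
        levels = np.unique(cov)
        design = np.column_stack([(cov == lv).astype(float) for lv in levels[1:]])
    else:
        design = cov.reshape(cov.shape[0], -1).astype(float)
    X = np.column_stack([np.ones(values.shape[0]), design])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return resid + values.mean(axis=0)


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple:
    """Two-sample test; returns ``(statistic, p)``.

    The permutation statistic is the mean difference; the two-sided p
    uses |difference|.  When the number of distinct group-A assignments
    is at most ``n_perm`` the null is enumerated exactly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    stat = float(a.mean() - b.mean())
    if method == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    if comb(n, na) <= n_perm:
        count = total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            count += abs(diff) >= abs(stat) - 1e-12
            total += 1
        return stat, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:na].mean() - perm[na:].mean()
        count += abs(diff) >= abs(stat) - 1e-12
    return stat, (count + 1) / (n_perm + 1)


def compare_profiles(
    profiles_a: list,
    profiles_b: list,
    method: str = "permutation",
    n_perm: int = 10_000,
    bonferroni: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-network, per-direction group comparison of connectivity profiles.

    Bonferroni-corrects across the 14 network x direction tests by
    default.
    """
    networks = list(profiles_a[0].forward)
    n_tests = 2 * len(networks)
    rows = []
    for direction in ("forward", "backward"):
        for net in networks:
            va = np.array([getattr(p, direction)[net] for p in profiles_a])
            vb = np.array([getattr(p, direction)[net] for p in profiles_b])
            stat, p = compare_groups(va, vb, method=method, n_perm=n_perm, seed=seed)
            p_corr = min(1.0, p * n_tests) if bonferroni else p
            rows.append(
                {
                    "network": net,
                    "direction": direction,
                    "statistic": stat,
                    "p": p,
                    "p_corrected": p_corr,
                }
            )
    return pd.DataFrame(rows)
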