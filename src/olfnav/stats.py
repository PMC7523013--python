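"""Rank-correlation association between homing indices and air-mass covariates.

Spearman's rank correlation is computed from first principles (average ranks
for ties, Pearson correlation of the ranks) so that infinite covariate
values — sea/land residence ratios with zero land hours — participate
naturally via their ranks instead of being capped or dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AssociationResult", "spearman_rho", "orientation_association", "EmptyJoinError"]


class EmptyJoinError(ValueError):
    """No complete, consistent observations survive the join/filter."""


@dataclass(frozen=True)
class AssociationResult:
    n: int
    rho: float
    p_value: float
    method: str = "t"

    def as_row(self) -> dict:
        return {"n": self.n, "rho": self.rho, "p_value": self.p_value, "method": self.method}


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties averaged; +inf ranks above every finite value."""
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("NaN values are not rankable; filter them first")
    n = v.size
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sv = v[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(
    x,
    y,
    method: str = "t",
    n_permutations: int = 9999,
    rng: Optional[np.random.Generator] = None,
) -> AssociationResult:
    """Spearman rank correlation with a two-sided p-value.

    ``method="t"`` uses the t-approximation t = rho*sqrt((n-2)/(1-rho^2))
    on n-2 degrees of freedom (adequate at the cohort sizes this package
    targets); ``method="permutation"`` draws seeded permutations of the
    ranks for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if method == "t":
        if abs(rho) == 1.0:
            p = float(np.finfo(float).tiny)
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
            p = max(p, float(np.finfo(float).tiny))
    elif method == "permutation":
        rng = rng or np.random.default_rng()
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1.0) / (n_permutations + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(n=n, rho=rho, p_value=p, method=method)


def orientation_association(
    indices: pd.DataFrame,
    covariates: pd.DataFrame,
    index_field: str = "deviation_from_west_abs",
    covariate_field: str = "ratio_sea_land",
    key: str = "bird_id",
    method: str = "t",
    rng: Optional[np.random.Generator] = None,
) -> AssociationResult:
    """Spearman association between a homing index and an air-mass covariate.

    Joins the per-bird indices table with the residence-counts table on
    ``key``, drops birds flagged inconsistent (initial mean vector r below
    threshold) and rows with missing values, then correlates. Infinite
    ratios are retained and ranked.
    """
    joined = indices.merge(covariates, on=key, how="inner")
    if "consistent" in joined.columns:
        joined = joined[joined["consistent"].astype(bool)]
    joined = joined.dropna(subset=[index_field, covariate_field])
    if joined.empty:
        raise EmptyJoinError("no complete consistent birds after join/filter")
    return spearman_rho(
        joined[covariate_field].to_numpy(dtype=float),
        joined[index_field].to_numpy(dtype=float),
        method=method,
        rng=rng,
    )
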