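"""Pearson / Spearman correlation with P-values and strength classes.

The cross-system comparisons in this package involve very few systems
(typically nine), where the usual t-transform P-value is only asymptotic;
for n <= 9 an exact permutation P-value (all n! orderings) is therefore
computed as well and reported alongside.  Strength classes follow the
conventional absolute-value bands: |rho| >= 0.5 strong, 0.3-0.49 moderate,
below 0.3 weak, ~0 none.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

PERMUTATION_MAX_N = 9


def _validate(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return x, y


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def permutation_pvalue(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation P: share of the n! orderings of y whose
    |r| >= |r_obs| (the identity ordering included)."""
    n = len(x)
    if n > PERMUTATION_MAX_N:
        raise ValueError(f"exact permutation limited to n <= {PERMUTATION_MAX_N}")
    xc = x - x.mean()
    sx = np.sqrt(xc @ xc)
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    perms = np.array(list(permutations(range(n))))
    rs = (yc[perms] @ xc) / (sx * sy)
    return float(np.count_nonzero(np.abs(rs) >= np.abs(r_obs) - 1e-12)
                 / factorial(n))


def pearson(x, y, method: str = "auto") -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided P-value.

    ``method``: 't' (n-2 df t-transform), 'permutation' (exact, n <= 9), or
    'auto' (permutation when feasible, else t).
    """
    x, y = _validate(x, y)
    r = _pearson_r(x, y)
    if method == "auto":
        method = "permutation" if len(x) <= PERMUTATION_MAX_N else "t"
    if method == "permutation":
        return r, permutation_pvalue(x, y, r)
    if method == "t":
        return r, float(stats.pearsonr(x, y).pvalue)
    raise ValueError(f"unknown method {method!r}")


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with a two-sided P-value."""
    x, y = _validate(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    return pearson(rx, ry, method=method)


def classify_strength(coefficient: float, strong: float = 0.5,
                      moderate: float = 0.3, none: float = 0.05) -> str:
    """Strength band of a correlation coefficient (absolute-value rule)."""
    a = abs(float(coefficient))
    if a > 1 + 1e-9:
        raise ValueError("|coefficient| must be <= 1")
    if a >= strong:
        return "strong"
    if a >= moderate:
        return "moderate"
    if a < none:
        return "none"
    return "weak"


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    n: int
    pearson_r: float
    pearson_p: float
    pearson_p_t: float
    spearman_r: float
    spearman_p: float
    spearman_p_t: float
    pearson_class: str
    spearman_class: str

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Both coefficients with permutation (when n <= 9) and t P-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= PERMUTATION_MAX_N
    r, p_perm = pearson(x, y, method="permutation" if small else "t")
    _, p_t = pearson(x, y, method="t")
    rs, ps_perm = spearman(x, y, method="permutation" if small else "t")
    _, ps_t = spearman(x, y, method="t")
    return CorrelationResult(
        x=x_name, y=y_name, n=len(x),
        pearson_r=r, pearson_p=p_perm, pearson_p_t=p_t,
        spearman_r=rs, spearman_p=ps_perm, spearman_p_t=ps_t,
        pearson_class=classify_strength(r),
        spearman_class=classify_strength(rs))


def correlate_observables(table: pd.DataFrame,
                          pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """One CorrelationResult row per named column pair of the system table."""
    rows = []
    for a, b in pairs:
        for col in (a, b):
            if col not in table.columns:
                raise KeyError(f"unknown observable column {col!r}")
        sub = table[[a, b]]
        if sub.isna().any().any():
            raise ValueError(f"missing cells in columns {a!r}/{b!r}")
        rows.append(correlate(sub[a].to_numpy(), sub[b].to_numpy(),
                              x_name=a, y_name=b).as_dict())
    return pd.DataFrame(rows)
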