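"""Spearman rank correlation with exact small-sample permutation p-values.

Single source of truth for every rank-correlation computation in the
package (taxon-taxon network edges and taxon-behavior associations), so
the two stages can never disagree on a shared pair.

Ranks use midranks for ties.  For n <= EXACT_MAX_N samples the two-sided
p-value is obtained by full enumeration of all n! permutations of one
vector; beyond that the usual t approximation with n-2 degrees of freedom
is used.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = ["spearman", "EXACT_MAX_N"]

EXACT_MAX_N = 9


@lru_cache(maxsize=None)
def _perm_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n), one per row (n <= 9 kept tractable)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@lru_cache(maxsize=None)
def _tie_free_null(n: int) -> np.ndarray:
    """Sorted |rho| over all permutations when both vectors are tie-free ranks."""
    r = np.arange(1, n + 1, dtype=float)
    rc = r - r.mean()
    denom = rc @ rc
    perms = _perm_indices(n)
    rhos = (rc[perms] * rc).sum(axis=1) / denom
    return np.sort(np.abs(rhos))


def _rho_from_ranks(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _exact_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided permutation p = #{perm: |rho_perm| >= |rho|} / n!."""
    n = len(xr)
    tol = 1e-12
    tie_free = len(set(xr)) == n and len(set(yr)) == n
    if tie_free:
        null = _tie_free_null(n)
        k = null.size - np.searchsorted(null, abs(rho) - tol, side="left")
        return float(k) / null.size
    perms = _perm_indices(n)
    yc = yr - yr.mean()
    xc = xr - xr.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    rhos = (yc[perms] @ xc) / (sx * sy)
    return float(np.mean(np.abs(rhos) >= abs(rho) - tol))


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rho (midranks) and two-sided p-value.

    method: "auto" (exact when n <= 9), "exact", or "approx" (t with n-2 df).
    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 paired samples")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _rho_from_ranks(xr, yr)
    if np.isnan(rho):
        return np.nan, np.nan
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method: {method!r}")
    exact = method == "exact" or (method == "auto" and n <= EXACT_MAX_N)
    if exact:
        if n > 10:
            raise ValueError("exact enumeration is limited to n <= 10")
        return rho, _exact_p(xr, yr, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))
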