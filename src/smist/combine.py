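"""Combine the independent mediation and variance-component p-values.

The two component statistics are independent by construction (the
variance-component statistic conditions out the mediator directions), so
classical combiners for independent p-values apply directly:

* Fisher: −2(ln p₁ + ln p₂) ~ χ²₄,
* minP (Tippett): 1 − (1 − min p)²,
* weighted: a grid search over T(ρ) = −2[ρ·ln p₁ + (1−ρ)·ln p₂], each
  grid point referred to the exact law of ρχ²₂ + (1−ρ)χ²₂, with the
  minimum-over-grid calibrated by seeded Monte Carlo under the joint null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CombinedResult", "fisher_combine", "minp_combine", "weighted_combine",
           "DEFAULT_GRID"]

DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))
_PMIN = 1e-300


@dataclass
class CombinedResult:
    p_fisher: float
    p_minp: float
    p_weighted: float
    weight_grid: tuple
    rho_selected: float
    mc_draws: int


def _clip_p(p: float, name: str) -> float:
    if not (0.0 <= p <= 1.0) and not np.isnan(p):
        raise ValueError(f"{name} must lie in [0, 1]")
    if p <= 0.0:
        warnings.warn(f"{name} <= 0 clipped to {_PMIN}")
        return _PMIN
    return p


def fisher_combine(p_med: float, p_vc: float) -> float:
    """Fisher's product combination: χ²₄ upper tail of −2(ln p₁ + ln p₂)."""
    p1, p2 = _clip_p(p_med, "p_med"), _clip_p(p_vc, "p_vc")
    t = -2.0 * (math.log(p1) + math.log(p2))
    return float(stats.chi2.sf(t, df=4))


def minp_combine(p_med: float, p_vc: float) -> float:
    """Tippett's minimum-p combination for two independent components."""
    p1, p2 = _clip_p(p_med, "p_med"), _clip_p(p_vc, "p_vc")
    return float(1.0 - (1.0 - min(p1, p2)) ** 2)


def _weighted_chi2_pair_sf(t, a: float, b: float):
    """Exact survival function of a·χ²₂ + b·χ²₂ (independent), a, b ≥ 0."""
    t = np.asarray(t, float)
    if a < b:  # symmetric; canonical order for the closed form
        a, b = b, a
    if b == 0.0:
        return np.exp(-t / (2.0 * a))
    if abs(a - b) < 1e-12:
        x = t / (2.0 * a)
        return (1.0 + x) * np.exp(-x)
    return (a * np.exp(-t / (2.0 * a)) - b * np.exp(-t / (2.0 * b))) / (a - b)


def _grid_min_p(logp1, logp2, grid: np.ndarray):
    """min over ρ of the per-ρ p-value of T(ρ), plus the argmin index.

    Inputs are natural logs of the component p-values; vectorized over
    replicate axes.  Ties go to the smallest ρ (grid sorted ascending).
    """
    logp1 = np.asarray(logp1, float)
    logp2 = np.asarray(logp2, float)
    pmat = np.empty((len(grid),) + logp1.shape)
    for i, rho in enumerate(grid):
        t = -2.0 * (rho * logp1 + (1.0 - rho) * logp2)
        pmat[i] = _weighted_chi2_pair_sf(t, rho, 1.0 - rho)
    imin = np.argmin(pmat, axis=0)  # first minimum → smallest ρ
    return np.min(pmat, axis=0), imin


_NULL_CACHE: dict = {}


def _null_min_p_table(grid: tuple, mc_draws: int, seed: int) -> np.ndarray:
    key = (grid, mc_draws, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=(2, mc_draws))
        mins, _ = _grid_min_p(np.log(u[0]), np.log(u[1]), np.asarray(grid))
        _NULL_CACHE[key] = np.sort(mins)
    return _NULL_CACHE[key]


def weighted_combine(p_med: float, p_vc: float, grid=DEFAULT_GRID,
                     mc_draws: int = 100_000, seed: int = 0):
    """Grid-search weighted Fisher combination with Monte-Carlo calibration.

    Returns (overall p, rho_selected).  The null distribution of the
    minimum per-ρ p-value is simulated once per (grid, mc_draws, seed) and
    cached, so repeated calls (a genome scan) reuse the same table.
    """
    grid = tuple(sorted(float(g) for g in grid))
    if len(grid) == 0:
        raise ValueError("weight grid must be non-empty")
    if grid[0] < 0.0 or grid[-1] > 1.0:
        raise ValueError("weight grid must lie in [0, 1]")
    p1, p2 = _clip_p(p_med, "p_med"), _clip_p(p_vc, "p_vc")
    garr = np.asarray(grid)
    obs_min, imin = _grid_min_p(math.log(p1), math.log(p2), garr)
    rho_selected = float(garr[int(imin)])
    null = _null_min_p_table(grid, mc_draws, seed)
    count = int(np.searchsorted(null, obs_min, side="right"))
    p = (1.0 + count) / (mc_draws + 1.0)
    return float(p), rho_selected


def combine_all(p_med: float, p_vc: float, grid=DEFAULT_GRID,
                mc_draws: int = 100_000, seed: int = 0) -> CombinedResult:
    pw, rho = weighted_combine(p_med, p_vc, grid, mc_draws, seed)
    return CombinedResult(fisher_combine(p_med, p_vc), minp_combine(p_med, p_vc),
                          pw, tuple(sorted(float(g) for g in grid)), rho, mc_draws)
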