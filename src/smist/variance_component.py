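"""Variance-component (direct-effect) test from summary statistics.

After conditioning the per-variant marginal statistics on the genetically
predicted mediators, the residual per-variant effects α̂*_p are squared and
summed into U_τ² = Σ_p (α̂*_p / var(α̂*_p))².  Under the null this statistic
follows a mixture Σ_j w_j χ²₁ whose weights are the eigenvalues of
D_α R* D_α, with D_α = diag(1/se(α̂*)) and R* the correlation of α̂*.
Because the conditioning projects out the mediator directions, U_τ² is
independent of the mediation statistic, which is what later makes the
p-value combination valid.

The module also owns the ridge regularization of the LD correlation matrix
(cor + λI) that stabilizes near-singular reference panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

from .summary_io import HarmonizedGene, LDPanel

__all__ = [
    "RegularizedPanel",
    "VCResult",
    "regularize",
    "default_lambda",
    "conditioning_row",
    "conditioning_matrix",
    "vc_test",
    "mixture_chisq_sf",
]

# relative variance below which a variant counts as fully absorbed by the
# mediators (its conditioned statistic is 0/0) and is excluded from U_τ²
_ABSORBED_RTOL = 1e-10
_EIG_RTOL = 1e-8


def default_lambda(n_ref: int) -> float:
    """Ridge penalty λ = 1/sqrt(n_ref·ln n_ref); vanishes as the reference
    panel grows, so the regularized test is consistent."""
    if n_ref is None or n_ref <= 1:
        raise ValueError("n_ref must exceed 1 to set the default ridge penalty")
    return 1.0 / math.sqrt(n_ref * math.log(n_ref))


@dataclass
class RegularizedPanel:
    """LD panel with the correlation matrix ridge-shifted by λI.

    cor_reg = cor + λI (diagonal left at 1 + λ) and
    cov_reg = diag(√d)·cor_reg·diag(√d).
    """

    base: LDPanel
    lam: float

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def variant_ids(self):
        return self.base.variant_ids

    @property
    def n_ref(self):
        return self.base.n_ref

    @property
    def d(self) -> np.ndarray:
        return self.base.d * (1.0 + self.lam)

    @property
    def cor(self) -> np.ndarray:
        c = self.base.cor.copy()
        c[np.diag_indices_from(c)] += self.lam
        return c

    @property
    def cov(self) -> np.ndarray:
        s = np.sqrt(self.base.d)
        return self.cor * np.outer(s, s)


def regularize(panel: LDPanel, lambda_override: float | None = None) -> RegularizedPanel:
    """Apply the ridge penalty; λ defaults to 1/sqrt(n_ref·ln n_ref)."""
    lam = default_lambda(panel.n_ref) if lambda_override is None else float(lambda_override)
    return RegularizedPanel(panel, lam)


@dataclass
class VCResult:
    alpha_star: np.ndarray
    cov_alpha: np.ndarray
    u_tau2: float
    eigen_weights: np.ndarray
    p_vc: float
    method_used: str
    absorbed: np.ndarray = field(default=None)  # variants excluded as fully conditioned out
    degenerate: bool = False


def _panel_arrays(hg: HarmonizedGene, panel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    panel = panel if panel is not None else hg.panel
    if isinstance(panel, RegularizedPanel):
        return panel.cov, panel.cor, panel.d
    return panel.cov, panel.cor, panel.d


def effective_inputs(hg: HarmonizedGene, panel=None):
    """(beta, se, cov, cor, d) with the dialect resolved.

    The standardized dialect replaces β̂ by z and se by 1 and moves the panel
    onto the correlation scale (unit diagonal).
    """
    beta, se = hg.stats.effective_wald()
    cov, cor, d = _panel_arrays(hg, panel)
    if hg.stats.dialect == "standardized":
        cov, d = cor, np.ones_like(d)
    return beta, se, cov, cor, d


def _solve_psd(mat: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve mat @ x = rhs for symmetric PSD mat, pseudo-inverting when
    numerically singular.  Returns (solution, used_pinv)."""
    try:
        c, low = None, None
        sol = np.linalg.solve(mat, rhs)
        if np.all(np.isfinite(sol)):
            return sol, False
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(mat, hermitian=True) @ rhs, True


def conditioning_matrix(hg: HarmonizedGene, panel=None) -> tuple[np.ndarray, np.ndarray]:
    """Stack the per-variant conditioning rows a_p into A_full (P×P) so that
    α̂* = A_full·β̂*.

    Row p folds the block system C = [[WᵀΣW, WᵀΣe_p·d-col], [·, D_p]] into a
    single row over β̂*: the Schur complement s_p = D_p − c_pᵀM⁻¹c_p of the
    shared K×K block M = WᵀΣW gives
    a_p = (D_p e_pᵀ − c_pᵀ M⁻¹ WᵀD) / s_p.
    Returns (A_full, s) where s_p ≤ 0 marks a variant fully absorbed by the
    mediators (its row is zeroed).
    """
    beta, se, cov, cor, d = effective_inputs(hg, panel)
    P, K = hg.P, hg.K
    W = hg.W
    if K == 0:
        return np.eye(P), d.copy()
    M = W.T @ cov @ W
    SW = cov @ W  # P×K, row p = cov(G)_{p·} W
    Minv_SW_T, _ = _solve_psd(M, SW.T)  # K×P
    WD = W.T * d  # K×P  (WᵀD)
    Minv_WD, _ = _solve_psd(M, WD)
    s = d - np.einsum("pk,kp->p", SW, Minv_SW_T)
    A = np.diag(d) - SW @ Minv_WD
    tol = _ABSORBED_RTOL * max(np.max(np.abs(d)), 1.0)
    absorbed = s <= tol
    s_safe = np.where(absorbed, 1.0, s)
    A = A / s_safe[:, None]
    A[absorbed] = 0.0
    return A, np.where(absorbed, 0.0, s)


def conditioning_row(hg: HarmonizedGene, p_index: int, panel=None) -> np.ndarray:
    """Row vector a_p with α̂*_p = a_p·β̂* (variant ``p_index`` conditioned on
    all mediators).  With no mediators a_p = e_p."""
    A, _ = conditioning_matrix(hg, panel)
    return A[p_index]


def vc_test(hg: HarmonizedGene, panel=None) -> VCResult:
    """Variance-component score test of the residual per-variant effects."""
    beta, se, cov, cor, d = effective_inputs(hg, panel)
    A, s = conditioning_matrix(hg, panel)
    alpha = A @ beta
    cov_beta = cor * np.outer(se, se)
    cov_alpha = A @ cov_beta @ A.T
    var_alpha = np.diag(cov_alpha).copy()

    absorbed = s <= 0
    valid = ~absorbed & (var_alpha > _ABSORBED_RTOL * max(var_alpha.max(initial=0.0), 1e-300))
    if not valid.any():
        return VCResult(alpha, cov_alpha, 0.0, np.zeros(0), 1.0, "exact",
                        absorbed=absorbed, degenerate=True)

    v = var_alpha[valid]
    u_vec = alpha[valid] / v
    u_tau2 = float(u_vec @ u_vec)
    # null covariance of u_vec is diag(1/var)·cov_alpha·diag(1/var); its
    # eigenvalues equal those of D_α R* D_α
    Wmat = cov_alpha[np.ix_(valid, valid)] / np.outer(v, v)
    eig = np.linalg.eigvalsh((Wmat + Wmat.T) / 2.0)
    eig = eig[eig > _EIG_RTOL * max(eig.max(initial=0.0), 0.0)]
    if eig.size == 0:
        return VCResult(alpha, cov_alpha, u_tau2, np.zeros(0), 1.0, "exact",
                        absorbed=absorbed, degenerate=True)
    p, method = mixture_chisq_sf(u_tau2, eig, return_method=True)
    return VCResult(alpha, cov_alpha, u_tau2, eig, p, method, absorbed=absorbed)


# ---------------------------------------------------------------------------
# Tail probability of Σ_j w_j χ²₁ (Davies-type evaluation by numerical
# characteristic-function inversion, with saddlepoint and moment-matching
# fallbacks for extreme tails).
# ---------------------------------------------------------------------------


def _imhof_sf(q: float, w: np.ndarray) -> tuple[float, float]:
    """Imhof (1961) inversion: P(Q>q) = 1/2 + (1/π)∫ sinθ(u)/(u·ρ(u)) du."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
        return math.sin(theta) / (u * rho)

    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=2_000,
                                      epsabs=1e-12, epsrel=1e-10)
    return 0.5 + val / math.pi, err / math.pi


def _saddlepoint_sf(q: float, w: np.ndarray) -> float:
    """Kuonen (1999) saddlepoint survival probability; accurate relative
    error deep in the tail where quadrature loses precision."""
    mu = w.sum()
    if q <= 0 or abs(q - mu) / max(mu, 1e-300) < 1e-8:
        return 0.5

    wmax = w.max()

    def kprime(z):
        return np.sum(w / (1.0 - 2.0 * z * w))

    hi = 1.0 / (2.0 * wmax)
    try:
        if q > mu:
            zhat = optimize.brentq(lambda z: kprime(z) - q, 0.0, hi * (1 - 1e-12),
                                   xtol=1e-14, maxiter=200)
        else:
            zhat = optimize.brentq(lambda z: kprime(z) - q, -1e6, 0.0,
                                   xtol=1e-14, maxiter=200)
    except ValueError:
        return np.nan
    k0 = -0.5 * np.sum(np.log1p(-2.0 * zhat * w))
    k2 = 2.0 * np.sum(w ** 2 / (1.0 - 2.0 * zhat * w) ** 2)
    if k2 <= 0:
        return np.nan
    wstat = np.sign(zhat) * math.sqrt(max(2.0 * (zhat * q - k0), 0.0))
    vstat = zhat * math.sqrt(k2)
    if wstat == 0.0:
        return 0.5
    z = wstat + math.log(vstat / wstat) / wstat
    return float(stats.norm.sf(z))


def _liu_sf(q: float, w: np.ndarray) -> float:
    """Liu–Tang–Zhang 4-moment chi-square approximation."""
    c = [np.sum(w ** k) for k in (1, 2, 3, 4)]
    s1 = c[2] / c[1] ** 1.5
    s2 = c[3] / c[1] ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2.0 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2 if s2 > 0 else 1.0
        a = math.sqrt(dof)
    mu_q, sigma_q = c[0], math.sqrt(2.0 * c[1])
    t = (q - mu_q) / sigma_q
    x = t * math.sqrt(2.0) * math.sqrt(dof + 2.0 * delta) + dof + delta
    return float(stats.ncx2.sf(x, dof, delta)) if delta > 0 else float(stats.chi2.sf(x, dof))


def mixture_chisq_sf(q: float, weights, return_method: bool = False):
    """Upper-tail probability of Σ_j w_j χ²₁ at q.

    Equal weights collapse to a scaled central chi-square (exact).  Otherwise
    the tail is evaluated by numerical inversion of the characteristic
    function, switching to a saddlepoint approximation when the inversion
    cannot resolve the tail, and to a 4-moment match as a last resort.
    The result is clipped to [1e-300, 1].
    """
    w = np.asarray(weights, float)
    w = w[w > 0]
    if q < 0:
        raise ValueError("quadratic form statistic must be non-negative")
    if w.size == 0 or q == 0.0:
        out = (1.0, "exact")
        return out if return_method else out[0]
    if np.allclose(w, w[0], rtol=1e-12):
        p = float(stats.chi2.sf(q / w[0], df=w.size))
        out = (min(max(p, 1e-300), 1.0), "exact")
        return out if return_method else out[0]

    # the saddlepoint is cheap and has uniform relative accuracy deep in the
    # tail, where double-precision quadrature cannot resolve the integral;
    # the inversion is preferred in the central region where it is near-exact
    sp = _saddlepoint_sf(q, w)
    if np.isfinite(sp) and 0.0 < sp < 5e-4:
        p, method = sp, "saddlepoint"
    else:
        p, err = _imhof_sf(q, w)
        method = "imhof"
        if not np.isfinite(p) or p <= max(1e-12, 10 * err) or p > 1.0:
            if np.isfinite(sp) and 0.0 < sp <= 1.0:
                p, method = sp, "saddlepoint"
            else:
                p, method = _liu_sf(q, w), "moment_match"
    p = float(min(max(p, 1e-300), 1.0))
    return (p, method) if return_method else p
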