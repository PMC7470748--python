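"""Individual-level mixed-effects score test — the gold standard.

Given outcome, confounders, genotypes and weights on the same individuals,
the mediation component is the K-df score test of the predicted mediators
M̂ = GW in the generalized linear model fitted under the confounder-only
null, and the variance-component statistic is the squared score of the
genotypes after projecting out (X, M̂) under the fitted null model, referred
to the same mixture-of-chi-squares law as the summary version.  The
summary-statistics test is validated by its agreement with these p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .variance_component import _solve_psd, mixture_chisq_sf

__all__ = ["IndividualData", "OracleResult", "oracle_fit"]


@dataclass
class IndividualData:
    """Individual-level bundle: outcome y (binary or continuous), confounder
    matrix x (must include the intercept column), dosages g (n×P), and
    variant→mediator weights w (P×K)."""

    y: np.ndarray
    x: np.ndarray
    g: np.ndarray
    w: np.ndarray
    link: str = "logit"  # "logit" or "identity"

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.x = np.atleast_2d(np.asarray(self.x, float))
        if self.x.shape[0] != self.y.shape[0]:
            self.x = self.x.T
        self.g = np.asarray(self.g, float)
        self.w = np.atleast_2d(np.asarray(self.w, float))
        if self.w.shape[0] != self.g.shape[1]:
            self.w = self.w.T
        if self.link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")

    @property
    def m_hat(self) -> np.ndarray:
        return self.g @ self.w


@dataclass
class OracleResult:
    p_mediation: float
    p_vc: float
    gamma_hat: np.ndarray
    u_gamma: float
    u_tau2: float
    eigen_weights: np.ndarray
    converged: bool = True


def _fit_null(y, design, link):
    """Fit the null GLM, returning (mu, working weights, score scale, ok).

    Gaussian scores carry the 1/σ̂² dispersion factor; binomial scores use
    the fitted variance μ(1−μ) with unit dispersion.
    """
    if link == "identity":
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        mu = design @ coef
        dof = max(len(y) - design.shape[1], 1)
        sigma2 = float((y - mu) @ (y - mu)) / dof
        return mu, np.full_like(y, 1.0 / sigma2), 1.0 / sigma2, True
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
        converged = bool(res.converged)
    except Exception:
        return None, None, None, False
    mu = np.clip(res.fittedvalues, 1e-10, 1 - 1e-10)
    return mu, mu * (1.0 - mu), 1.0, converged


def _projected_score(y, mu, wts, scale, design, test_cols):
    """Score vector of ``test_cols`` and its covariance under the null fit,
    with the fitted design projected out (the standard GLM score test)."""
    r = y - mu
    if np.ndim(test_cols) == 1:
        test_cols = test_cols[:, None]
    U = scale * (test_cols.T @ r)
    tw = test_cols * wts[:, None]
    V = test_cols.T @ tw - (tw.T @ design) @ np.linalg.solve(
        design.T @ (design * wts[:, None]), design.T @ tw)
    return U, (V + V.T) / 2.0


def oracle_fit(data: IndividualData) -> OracleResult:
    """Component p-values from individual-level data.

    Returns the K-df mediation score test (predicted mediators, confounders
    projected out), the variance-component statistic U_τ² = SᵀS with S the
    genotype scores under the (X, M̂) null fit, its eigenvalue mixture
    p-value, and the fitted mediator effects γ̂.
    """
    y, x, g = data.y, data.x, data.g
    m_hat = data.m_hat
    n = len(y)
    if n <= x.shape[1] + data.w.shape[1] + 10:
        raise ValueError("sample too small relative to the model dimension")

    # mediation: score test of gamma under the confounder-only null
    mu0, w0, s0, ok0 = _fit_null(y, x, data.link)
    if not ok0:
        return OracleResult(np.nan, np.nan, np.full(data.w.shape[1], np.nan),
                            np.nan, np.nan, np.zeros(0), converged=False)
    U, V = _projected_score(y, mu0, w0, s0, x, m_hat)
    sol, _ = _solve_psd(V, U)
    u_gamma = float(U @ sol)
    p_med = float(stats.chi2.sf(u_gamma, df=m_hat.shape[1]))

    # variance component: genotype scores under the (X, M_hat) null fit
    design1 = np.column_stack([x, m_hat])
    mu1, w1, s1, ok1 = _fit_null(y, design1, data.link)
    if not ok1:
        return OracleResult(p_med, np.nan, np.full(data.w.shape[1], np.nan),
                            u_gamma, np.nan, np.zeros(0), converged=False)
    if data.link == "identity":
        coef, *_ = np.linalg.lstsq(design1, y, rcond=None)
        gamma_hat = coef[x.shape[1]:]
    else:
        gamma_hat = sm.GLM(y, design1, family=sm.families.Binomial()) \
            .fit(maxiter=100, tol=1e-8).params[x.shape[1]:]
    S, Vg = _projected_score(y, mu1, w1, s1, design1, g)
    u_tau2 = float(S @ S)
    eig = np.linalg.eigvalsh(Vg)
    eig = eig[eig > 1e-8 * max(eig.max(initial=0.0), 0.0)]
    p_vc = mixture_chisq_sf(u_tau2, eig) if eig.size else 1.0
    return OracleResult(p_med, p_vc, np.asarray(gamma_hat, float), u_gamma,
                        u_tau2, eig, converged=True)
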