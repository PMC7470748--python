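"""Fixed-effect (mediation) test of the genetically predicted mediators.

From marginal per-variant statistics β̂*, their LD-induced covariance
cov(β̂*) = diag(se)·cor(G)·diag(se), and the variant→mediator weights W, the
mediator effects on the outcome scale are

    γ̂ = {Wᵀcov(G)W}⁻¹ Wᵀ D β̂*,        D = diag(cov(G)),

with sandwich covariance and the K-df quadratic form U_γ = γ̂ᵀcov(γ̂)⁻¹γ̂,
which is χ²_K under the null of no mediator effect and no direct effects.
With a single mediator γ̂ coincides with the S-PrediXcan estimator.  Each
mediator also gets a joint (conditional-on-the-others) normal test from the
diagonal of cov(γ̂).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_io import HarmonizedGene
from .variance_component import effective_inputs, _solve_psd

__all__ = ["MediationResult", "wald_from_score", "standardized_inputs", "mediation_test"]


@dataclass
class MediationResult:
    gamma_hat: np.ndarray
    cov_gamma: np.ndarray
    u_gamma: float
    df: int
    p_mediation: float
    per_mediator: list  # (mediator_id, gamma_k, se_k, z_k, p_k)
    condition_number: float = np.nan
    used_pinv: bool = False


def wald_from_score(score_u, score_v):
    """Convert score statistics to the Wald scale: β̂ = U/V, se = V^{-1/2}.

    Score statistics are computed under the null, which keeps them stable
    for rare variants where Wald estimates degrade.
    """
    u = np.asarray(score_u, float)
    v = np.asarray(score_v, float)
    if np.any(v <= 0):
        raise ValueError("score_v must be positive")
    return u / v, 1.0 / np.sqrt(v)


def standardized_inputs(z_vector, panel):
    """Inputs for the standardized-score dialect: pseudo-β = z (which carries
    the effect direction), pseudo-se = 1, and the panel on the correlation
    scale (unit diagonal)."""
    z = np.asarray(z_vector, float)
    return z, np.ones_like(z), panel.cor if hasattr(panel, "cor") else np.asarray(panel)


def mediation_test(hg: HarmonizedGene, panel=None) -> MediationResult:
    """K-df test of the predicted-mediator effects, plus per-mediator tests.

    ``panel`` may be a :class:`~smist.variance_component.RegularizedPanel`;
    by default the gene's own harmonized panel is used unregularized.
    """
    if hg.K == 0:
        raise ValueError("no mediators: use the variance-component test alone")
    beta, se, cov, cor, d = effective_inputs(hg, panel)
    W = hg.W
    M = W.T @ cov @ W
    cond = float(np.linalg.cond(M))
    WD = W.T * d  # K×P = WᵀD
    rhs = WD @ beta
    gamma, pinv1 = _solve_psd(M, rhs)

    cov_beta = cor * np.outer(se, se)
    B = WD @ cov_beta @ WD.T
    Minv_B, pinv2 = _solve_psd(M, B)
    cov_gamma, _ = _solve_psd(M, Minv_B.T)
    cov_gamma = (cov_gamma + cov_gamma.T) / 2.0

    sol, pinv3 = _solve_psd(cov_gamma, gamma)
    u_gamma = float(gamma @ sol)
    u_gamma = max(u_gamma, 0.0)
    p = float(stats.chi2.sf(u_gamma, df=hg.K))

    se_g = np.sqrt(np.clip(np.diag(cov_gamma), 0.0, None))
    per = []
    for k, mid in enumerate(hg.mediator_ids):
        zk = gamma[k] / se_g[k] if se_g[k] > 0 else np.nan
        pk = float(2.0 * stats.norm.sf(abs(zk))) if np.isfinite(zk) else np.nan
        per.append((mid, float(gamma[k]), float(se_g[k]), float(zk), pk))

    return MediationResult(gamma, cov_gamma, u_gamma, hg.K, p, per,
                           condition_number=cond,
                           used_pinv=pinv1 or pinv2 or pinv3)
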