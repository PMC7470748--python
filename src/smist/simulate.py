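"""Synthetic case-control studies with a genetically predicted mediator.

The generator emulates the validation conditions for a summary-statistics
gene test: block-LD genotypes (clusters of highly correlated variants next
to weakly correlated ones), a mediator M = cB + ε with B = Σ_p w_p G_p and
(c, σ²) solved so that genotypes explain a target share R² of var(M) = 1.5,
a mediator effect γ = log 2 on the logit scale, sparse direct variant
effects δ_p ~ N(0, 0.05) orthogonalized against B, intercept −3 (≈5%
baseline disease probability), and 1000 cases / 1000 controls collected by
rejection sampling from the population model.  Replicate drivers produce
per-replicate p-values for type-I error, power, and oracle-agreement
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats as sps

from .combine import fisher_combine, minp_combine, weighted_combine
from .mediation import mediation_test
from .oracle import IndividualData, oracle_fit
from .summary_io import harmonized_from_arrays, ld_from_genotypes
from .variance_component import RegularizedPanel, vc_test

__all__ = [
    "SimulationConfig", "SimulatedStudy",
    "simulate_genotypes", "simulate_phenotype", "make_confounder",
    "simulate_dataset", "score_summary_stats", "wald_summary_stats",
    "smist_from_study", "run_replicates", "summarize_replicates",
]

_MAX_DRAWS = 100_000_000


@dataclass
class SimulationConfig:
    """Generative settings for one study condition.

    ``ld_spec`` is a list of (block_size, within_block_correlation) pairs,
    the string "near_singular" (12 variants at r = 0.999), or an explicit
    correlation matrix.  ``confounder`` is None or (target_correlation,
    effect_size).  ``weights`` / ``mafs`` are drawn once (see
    :meth:`realize`) when not given, so replicates share one gene
    structure.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    P: int = 40
    ld_spec: object = None
    mafs: np.ndarray | None = None
    weights: np.ndarray | None = None
    nonzero_weight_frac: float = 0.5
    r2_med: float = 0.05
    var_m: float = 1.5
    gamma: float = math.log(2.0)
    tau_var: float = 0.05
    prop_direct: float = 1.0
    intercept: float = -3.0
    confounder: tuple | None = None
    link_true: str = "linear"  # mediator model: "linear" or "log"
    inconsistent: bool = False
    seed: int | None = None

    def realize(self, rng: np.random.Generator) -> "SimulationConfig":
        """Fill in per-gene structure (MAFs, eQTL weights, LD blocks) that
        should stay fixed across replicates of one condition."""
        cfg = self
        if cfg.ld_spec is None:
            cfg = replace(cfg, ld_spec=_default_blocks(cfg.P))
        elif cfg.ld_spec == "near_singular":
            # one block of 12 variants with a shared MAF; the latent
            # correlation is set so the thresholded dosages end up pairwise
            # r ≈ 0.999, the regime where a 1000-sample reference panel is
            # frequently rank-deficient (exact duplicate columns)
            cfg = replace(cfg, P=12, ld_spec=[(12, 0.99999)],
                          mafs=cfg.mafs if cfg.mafs is not None else np.full(12, 0.3))
        if cfg.mafs is None:
            cfg = replace(cfg, mafs=rng.uniform(0.05, 0.5, size=cfg.P))
        if cfg.weights is None:
            w = np.zeros(cfg.P)
            nz = rng.choice(cfg.P, size=max(1, int(round(cfg.nonzero_weight_frac * cfg.P))),
                            replace=False)
            w[nz] = rng.normal(0.0, 1.0, size=nz.size)
            cfg = replace(cfg, weights=w)
        return cfg


def _default_blocks(P: int):
    """Clusters from near-perfect to absent correlation, padded with
    independent variants."""
    sizes = [max(P // 4, 1)] * 3
    blocks = list(zip(sizes, (0.95, 0.6, 0.3)))
    left = P - sum(s for s, _ in blocks)
    if left > 0:
        blocks.append((left, 0.0))
    return blocks


def _block_correlation(ld_spec, P: int) -> np.ndarray:
    if isinstance(ld_spec, np.ndarray):
        C = np.asarray(ld_spec, float)
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            import warnings

            warnings.warn("LD spec not positive semi-definite; repaired by eigenvalue clipping")
            vals, vecs = np.linalg.eigh(C)
            C = (vecs * np.clip(vals, 1e-10, None)) @ vecs.T
            s = np.sqrt(np.diag(C))
            C = C / np.outer(s, s)
        return C
    C = np.eye(P)
    at = 0
    for size, rho in ld_spec:
        if not 0.0 <= rho < 1.0 + 1e-12:
            raise ValueError("within-block correlation must lie in [0, 1)")
        C[at:at + size, at:at + size] = rho
        at += size
    np.fill_diagonal(C, 1.0)
    return C


def simulate_genotypes(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n×P dosages: a latent MVN with block correlation thresholded to
    {0, 1, 2} at Hardy–Weinberg cutpoints matching each variant's MAF."""
    C = _block_correlation(cfg.ld_spec, cfg.P)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(cfg.P))
    z = rng.standard_normal((n, cfg.P)) @ L.T
    q = np.asarray(cfg.mafs, float)
    c1 = sps.norm.ppf((1.0 - q) ** 2)  # below: 0 copies
    c2 = sps.norm.ppf((1.0 - q) ** 2 + 2.0 * q * (1.0 - q))
    return (z > c1).astype(np.int8) + (z > c2).astype(np.int8)


@dataclass
class _PhenotypeModel:
    """Frozen generative parameters, calibrated once per study so fresh
    rejection-sampling batches come from the same population."""

    cfg: SimulationConfig
    c: float
    sigma: float
    delta: np.ndarray  # per-variant direct effects (already masked)
    resid_coef: tuple  # (a0, a1): projection of the direct term on B
    b_mean: float
    conf_model: object = None  # (anchor weights over indep draws) or None

    def linear_scores(self, g, rng):
        cfg = self.cfg
        b = g @ cfg.weights
        if cfg.link_true == "log":
            bb = np.exp((b - self.b_mean) / max(self.sigma_b, 1e-12))
        else:
            bb = b
        m = self.c * (bb - self.e_mean) + rng.normal(0.0, self.sigma, size=len(b))
        raw = g @ self.delta
        direct = raw - self.resid_coef[0] - self.resid_coef[1] * b
        conf = None
        lp = cfg.intercept + cfg.gamma * m + direct
        if self.conf_model is not None:
            w_anchor, n_extra, beta_c = self.conf_model
            extra = rng.binomial(2, 0.3, size=(len(b), n_extra)) if n_extra else 0.0
            conf = g @ w_anchor
            if n_extra:
                conf = conf + extra @ self.conf_extra_w
            conf = (conf - self.conf_mean) / self.conf_sd
            lp = lp + beta_c * conf
        return lp, m, conf

    # populated during calibration
    sigma_b: float = 1.0
    e_mean: float = 0.0
    conf_extra_w: np.ndarray | None = None
    conf_mean: float = 0.0
    conf_sd: float = 1.0


def _calibrate_model(cfg: SimulationConfig, rng: np.random.Generator,
                     n_cal: int = 20_000, g_cal: np.ndarray | None = None) -> _PhenotypeModel:
    g = simulate_genotypes(cfg, n_cal, rng) if g_cal is None else np.asarray(g_cal, float)
    b = g @ cfg.weights
    var_target = cfg.r2_med * cfg.var_m
    sigma = math.sqrt(max(cfg.var_m - var_target, 1e-12))

    model = _PhenotypeModel(cfg, c=1.0, sigma=sigma, delta=np.zeros(cfg.P),
                            resid_coef=(0.0, 0.0), b_mean=float(b.mean()))
    model.sigma_b = float(b.std()) or 1.0
    if cfg.link_true == "log":
        e = np.exp((b - model.b_mean) / model.sigma_b)
    else:
        e = b
    model.e_mean = float(e.mean())
    ve = float(e.var())
    model.c = math.sqrt(var_target / ve) if ve > 0 else 0.0

    # sparse direct effects, orthogonalized against the predicted mediator
    n_direct = int(round(cfg.prop_direct * cfg.P))
    delta = np.zeros(cfg.P)
    if n_direct > 0 and cfg.tau_var > 0:
        which = rng.choice(cfg.P, size=n_direct, replace=False)
        delta[which] = rng.normal(0.0, math.sqrt(cfg.tau_var), size=n_direct)
        if cfg.inconsistent:
            # direct effects oppose the mediated direction γ·w_p
            sgn = np.sign(cfg.gamma if cfg.gamma != 0 else 1.0) * np.sign(cfg.weights)
            flip = (sgn[which] != 0)
            delta[which] = np.where(flip, -sgn[which] * np.abs(delta[which]), delta[which])
    model.delta = delta
    raw = g @ delta
    vb = float(b.var())
    a1 = float(np.cov(raw, b, ddof=1)[0, 1] / vb) if vb > 0 else 0.0
    a0 = float(raw.mean() - a1 * b.mean())
    model.resid_coef = (a0, a1)

    if cfg.confounder is not None:
        target_r, beta_c = cfg.confounder
        w_anchor, n_extra, extra_w, cm, cs = _fit_confounder(g, b, cfg, target_r, rng)
        model.conf_model = (w_anchor, n_extra, beta_c)
        model.conf_extra_w = extra_w
        model.conf_mean, model.conf_sd = cm, cs
    return model


def _fit_confounder(g, b, cfg, target_r, rng, tol: float = 0.02, max_extra: int = 400):
    """Anchor on the variant most correlated with the predicted mediator and
    dilute with independent variants until corr(confounder, B) hits the
    target (±tol); returns the closest achieved construction."""
    if target_r == 0.0:
        w_anchor = np.zeros(cfg.P)
        return w_anchor, 8, rng.normal(0.0, 1.0, size=8), 0.0, 1.0
    cors = np.array([abs(np.corrcoef(g[:, p], b)[0, 1]) if g[:, p].std() > 0 else 0.0
                     for p in range(cfg.P)])
    anchor = int(np.argmax(cors))
    w_anchor = np.zeros(cfg.P)
    w_anchor[anchor] = 1.0
    base = g[:, anchor].astype(float)
    extra_w = np.zeros(0)
    best = (abs(cors[anchor] - target_r), 0, extra_w)
    u = base.copy()
    draws = rng.binomial(2, 0.3, size=(len(b), max_extra)).astype(float)
    wts = rng.normal(0.0, 1.0, size=max_extra) * base.std() * 0.35
    for j in range(max_extra):
        u = u + draws[:, j] * wts[j]
        r = abs(np.corrcoef(u, b)[0, 1])
        gap = abs(r - target_r)
        if gap < best[0]:
            best = (gap, j + 1, wts[:j + 1].copy())
        if r < target_r - tol:
            break
    if best[0] > tol:
        import warnings

        warnings.warn(f"confounder correlation target {target_r} not reached; "
                      f"closest gap {best[0]:.3f}")
    n_extra = best[1]
    conf = base + (draws[:, :n_extra] @ best[2] if n_extra else 0.0)
    return w_anchor, n_extra, best[2], float(conf.mean()), float(conf.std()) or 1.0


def simulate_phenotype(g: np.ndarray, weights: np.ndarray, cfg: SimulationConfig,
                       rng: np.random.Generator):
    """Population phenotype model on given dosages.

    Returns (y, m, truth): binary outcomes, realized mediators, and the
    generating parameters (c, σ, δ, residualization coefficients) for
    parameter-recovery checks.
    """
    cfg = replace(cfg, weights=np.asarray(weights, float), P=g.shape[1],
                  mafs=cfg.mafs if cfg.mafs is not None else np.full(g.shape[1], 0.3))
    model = _calibrate_model(cfg, rng, g_cal=g)
    lp, m, conf = model.linear_scores(g, rng)
    y = rng.uniform(size=len(lp)) < expit(lp)
    truth = {"c": model.c, "sigma": model.sigma, "delta": model.delta,
             "resid_coef": model.resid_coef, "weights": cfg.weights,
             "confounder": conf, "linear_predictor": lp}
    return y.astype(float), m, truth


def make_confounder(g: np.ndarray, b_pred: np.ndarray, target_r: float,
                    rng: np.random.Generator):
    """Confounder column with corr(confounder, predicted mediator) ≈ target_r,
    built from an anchor variant plus independent diluting variants."""
    cfg = SimulationConfig(P=g.shape[1])
    w_anchor, n_extra, extra_w, cm, cs = _fit_confounder(
        g.astype(float), np.asarray(b_pred, float), cfg, target_r, rng)
    conf = g @ w_anchor
    if n_extra:
        conf = conf + rng.binomial(2, 0.3, size=(g.shape[0], n_extra)) @ extra_w
    return (conf - conf.mean()) / (conf.std() or 1.0)


@dataclass
class SimulatedStudy:
    y: np.ndarray
    g: np.ndarray
    m: np.ndarray
    confounder: np.ndarray | None
    cfg: SimulationConfig
    truth: dict


def simulate_dataset(cfg: SimulationConfig, rng: np.random.Generator) -> SimulatedStudy:
    """Case-control study meeting the configured quotas by rejection
    sampling over fresh individuals from the population model."""
    cfg = cfg.realize(rng)
    model = _calibrate_model(cfg, rng)
    need_ca, need_co = cfg.n_cases, cfg.n_controls
    cases, controls = [], []
    drawn = 0
    batch = max(4 * (need_ca + need_co), 2000)
    while need_ca > 0 or need_co > 0:
        if drawn > _MAX_DRAWS:
            raise RuntimeError("case/control quota unreachable; check the configuration "
                               "(baseline probability or effect sizes pathological)")
        g = simulate_genotypes(cfg, batch, rng)
        lp, m, conf = model.linear_scores(g, rng)
        y = rng.uniform(size=batch) < expit(lp)
        drawn += batch
        rows = np.column_stack([g, m, conf if conf is not None else np.zeros(batch)])
        if need_ca > 0:
            take = rows[y][:need_ca]
            cases.append(take)
            need_ca -= len(take)
        if need_co > 0:
            take = rows[~y][:need_co]
            controls.append(take)
            need_co -= len(take)
        batch = min(max(batch, 2000), 200_000)
    data = np.vstack(cases + controls)
    y = np.concatenate([np.ones(cfg.n_cases), np.zeros(cfg.n_controls)])
    P = cfg.P
    truth = {"c": model.c, "sigma": model.sigma, "delta": model.delta,
             "weights": cfg.weights, "resid_coef": model.resid_coef}
    conf = data[:, P + 1] if cfg.confounder is not None else None
    return SimulatedStudy(y, data[:, :P], data[:, P], conf, cfg, truth)


# ---------------------------------------------------------------------------
# summary statistics from individual-level data (the simulator's GWAS step)
# ---------------------------------------------------------------------------


def score_summary_stats(y, g, x=None):
    """Per-variant score statistics (U_p, V_p) under the covariate-only null
    of a logistic model — the numerically stable GWAS dialect."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    x = np.column_stack([np.ones(n)]) if x is None else np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != n:
        x = x.T
    from .oracle import _fit_null

    mu, w, scale, ok = _fit_null(y, x, "logit")
    if not ok:
        raise RuntimeError("null model for score statistics did not converge")
    u = g.T @ (y - mu)
    gw = g * w[:, None]
    xtwx_inv = np.linalg.inv(x.T @ (x * w[:, None]))
    B = gw.T @ x  # P×C
    v = np.einsum("np,np->p", g, gw) - np.einsum("pc,cd,pd->p", B, xtwx_inv, B)
    return u, v


def wald_summary_stats(y, g, x=None, max_iter: int = 50, tol: float = 1e-8):
    """Per-variant marginal logistic (beta, se) — the Wald GWAS dialect."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n, P = g.shape
    x = np.column_stack([np.ones(n)]) if x is None else np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != n:
        x = x.T
    beta = np.empty(P)
    se = np.empty(P)
    for p in range(P):
        design = np.column_stack([x, g[:, p]])
        theta = np.zeros(design.shape[1])
        for _ in range(max_iter):
            mu = expit(design @ theta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            info = design.T @ (design * w[:, None])
            step = np.linalg.solve(info, design.T @ (y - mu))
            theta += step
            if np.max(np.abs(step)) < tol:
                break
        mu = expit(design @ theta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        cov = np.linalg.inv(design.T @ (design * w[:, None]))
        beta[p] = theta[-1]
        se[p] = math.sqrt(cov[-1, -1])
    return beta, se


# ---------------------------------------------------------------------------
# replicate drivers
# ---------------------------------------------------------------------------


def smist_from_study(study: SimulatedStudy, dialect: str = "score",
                     lam: float = 0.0, panel=None):
    """Run the summary-statistics pipeline on one simulated study using its
    exact in-sample LD (or a supplied external panel)."""
    x = None if study.confounder is None else np.column_stack(
        [np.ones(len(study.y)), study.confounder])
    ids = [f"v{p}" for p in range(study.g.shape[1])]
    if panel is None:
        panel = ld_from_genotypes(study.g, ids)
    if dialect == "score":
        u, v = score_summary_stats(study.y, study.g, x)
        hg = harmonized_from_arrays("sim", ids, study.truth["weights"],
                                    score_u=u, score_v=v, panel=panel)
    elif dialect == "wald":
        beta, se = wald_summary_stats(study.y, study.g, x)
        hg = harmonized_from_arrays("sim", ids, study.truth["weights"],
                                    beta=beta, se=se, panel=panel)
    elif dialect == "standardized":
        u, v = score_summary_stats(study.y, study.g, x)
        hg = harmonized_from_arrays("sim", ids, study.truth["weights"],
                                    z=u / np.sqrt(v), panel=panel)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    use_panel = RegularizedPanel(hg.panel, lam) if lam > 0 else None
    med = mediation_test(hg, panel=use_panel)
    vc = vc_test(hg, panel=use_panel)
    return med, vc


def run_replicates(cfg: SimulationConfig, n_reps: int, seed: int = 0,
                   dialect: str = "score", lam: float = 0.0,
                   with_oracle: bool = False, combine_seed: int | None = None,
                   mc_draws: int = 100_000) -> pd.DataFrame:
    """Replicate table: component statistics, combined p-values, and (when
    requested) the individual-level oracle, one row per simulated study.

    Deterministic for a fixed seed; the weighted combiner's calibration
    table is seeded separately so every replicate shares it.
    """
    master = np.random.default_rng(seed)
    cfg = cfg.realize(master)
    combine_seed = seed if combine_seed is None else combine_seed
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(master.integers(2 ** 31 - 1))
        study = simulate_dataset(cfg, rng)
        med, vc = smist_from_study(study, dialect=dialect, lam=lam)
        pw, rho = weighted_combine(med.p_mediation, vc.p_vc, seed=combine_seed,
                                   mc_draws=mc_draws)
        row = {"rep": rep, "p_med": med.p_mediation, "p_vc": vc.p_vc,
               "u_gamma": med.u_gamma, "u_tau2": vc.u_tau2,
               "p_fisher": fisher_combine(med.p_mediation, vc.p_vc),
               "p_minp": minp_combine(med.p_mediation, vc.p_vc),
               "p_weighted": pw, "rho_selected": rho}
        if with_oracle:
            x = np.ones((len(study.y), 1)) if study.confounder is None else \
                np.column_stack([np.ones(len(study.y)), study.confounder])
            orc = oracle_fit(IndividualData(study.y, x, study.g,
                                            study.truth["weights"][:, None]))
            row.update({"oracle_p_med": orc.p_mediation, "oracle_p_vc": orc.p_vc,
                        "oracle_converged": orc.converged})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Empirical rejection rates with 95% binomial (Wilson) intervals."""
    from statsmodels.stats.proportion import proportion_confint

    out = {}
    for col in ("p_med", "p_vc", "p_fisher", "p_minp", "p_weighted"):
        if col in df:
            k = int((df[col] < alpha).sum())
            lo, hi = proportion_confint(k, len(df), method="wilson")
            out[col] = {"rate": k / len(df), "ci": (float(lo), float(hi)), "n": len(df)}
    return out
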