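"""Conditional testing against known loci, and sequential variant selection.

A known risk variant is adjusted for by treating it as an extra "mediator":
the weight matrix is augmented with an indicator column (1 at the known
locus row, 0 elsewhere), the variant set with the known locus itself, and
the LD panel with the joint covariance.  The mediation test on the
augmented gene then yields, for the gene-expression columns, effects
conditional on the known loci; the variance-component test conditions out
known loci and mediators alike.  Sequential selection repeats this with the
most significant conditioned variant added to the conditioning set until
neither component p-value is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mediation import MediationResult, mediation_test
from .summary_io import (HarmonizedGene, HarmonizePolicy, LDPanel,
                         SummaryStatSet, WeightSet, harmonize)
from .variance_component import VCResult, _solve_psd, vc_test

__all__ = ["AugmentedGene", "ConditionalResult", "augment_known_loci",
           "conditional_test", "sequential_scan"]

_LOCUS_PREFIX = "locus:"


@dataclass
class AugmentedGene:
    """Harmonized bundle over the union of known-locus and gene variants,
    with indicator "mediator" columns for the Q known loci followed by the
    K gene-mediator weight columns."""

    base: HarmonizedGene
    known_ids: list
    gene_mediators: list

    @property
    def Q(self) -> int:
        return len(self.known_ids)

    @property
    def K(self) -> int:
        return len(self.gene_mediators)

    def gene_mediator_indices(self) -> np.ndarray:
        return np.asarray([self.base.mediator_ids.index(m) for m in self.gene_mediators])


@dataclass
class ConditionalResult:
    mediation: MediationResult  # full (Q+K)-mediator fit
    vc: VCResult
    u_adjusted: float
    p_mediation_adjusted: float  # joint test of the K gene mediators given the Q loci
    p_vc: float
    per_mediator_adjusted: list


def _weightset_from_harmonized(hg: HarmonizedGene) -> pd.DataFrame:
    stab = hg.stats.table
    rows = []
    for p, v in enumerate(hg.variant_ids):
        for k, m in enumerate(hg.mediator_ids):
            if hg.W[p, k] != 0.0:
                rows.append((v, m, hg.W[p, k],
                             stab.loc[p, "effect_allele"], stab.loc[p, "other_allele"]))
    return pd.DataFrame(rows, columns=["variant_id", "mediator_id", "weight",
                                       "effect_allele", "other_allele"])


def augment_known_loci(hg: HarmonizedGene, known_stats: SummaryStatSet | None,
                       joint_panel: LDPanel | None) -> AugmentedGene:
    """Build the augmented gene for conditional analysis.

    ``known_stats`` holds marginal statistics for the Q known loci in the
    same dialect as the gene's; ``joint_panel`` must cover the union of gene
    and known-locus variants.  Known loci absent from the panel are dropped
    with a warning; a known locus that is itself one of the gene's variants
    is represented once (its row carries both the indicator and any gene
    weight, avoiding exact collinearity).  With Q = 0 the augmented gene is
    the input gene unchanged.
    """
    if known_stats is None or len(known_stats) == 0:
        return AugmentedGene(hg, [], list(hg.mediator_ids))
    if known_stats.dialect != hg.stats.dialect:
        raise ValueError("known-locus statistics must share the gene's dialect")
    if joint_panel is None:
        raise ValueError("conditional analysis needs a joint LD panel over gene + known loci")

    ktab = known_stats.table.copy()
    in_panel = ktab["variant_id"].isin(set(joint_panel.variant_ids))
    for v in ktab.loc[~in_panel, "variant_id"]:
        warnings.warn(f"known locus {v} missing from joint panel; dropped")
    ktab = ktab[in_panel]
    known_ids = list(dict.fromkeys(ktab["variant_id"]))  # preserve order, collapse dups

    gene_vars = set(hg.variant_ids)
    stat_parts = [hg.stats.table]
    extra = ktab[~ktab["variant_id"].isin(gene_vars)]
    if len(extra):
        stat_parts.append(extra[hg.stats.table.columns.intersection(extra.columns)])
    combined_stats = SummaryStatSet(
        pd.concat(stat_parts, ignore_index=True), hg.stats.dialect)

    wrows = []
    for v in known_ids:
        if v in gene_vars:
            p = hg.variant_ids.index(v)
            ea = hg.stats.table.loc[p, "effect_allele"]
            oa = hg.stats.table.loc[p, "other_allele"]
        else:
            r = ktab[ktab["variant_id"] == v].iloc[0]
            ea, oa = r["effect_allele"], r["other_allele"]
        wrows.append((v, _LOCUS_PREFIX + v, 1.0, ea, oa))
    wtab = pd.concat([pd.DataFrame(wrows, columns=["variant_id", "mediator_id", "weight",
                                                   "effect_allele", "other_allele"]),
                      _weightset_from_harmonized(hg)], ignore_index=True)
    aug_weights = WeightSet(hg.gene_id, wtab)

    policy = HarmonizePolicy(drop_ambiguous=False, restrict_to_weights=False)
    base = harmonize(combined_stats, aug_weights, joint_panel, policy)
    return AugmentedGene(base, known_ids, list(hg.mediator_ids))


def conditional_test(hg: HarmonizedGene, known_stats=None, joint_panel=None,
                     panel=None, aug: AugmentedGene | None = None,
                     lam: float = 0.0) -> ConditionalResult:
    """Mediation and variance-component tests adjusted for known loci.

    The adjusted mediation p-value is the joint chi-square test of the gene
    mediators' effects from the (Q+K)-mediator fit; the variance-component
    test automatically conditions on all Q+K columns.  ``panel`` optionally
    supplies a (possibly regularized) panel aligned with the augmented
    gene; alternatively ``lam`` > 0 ridge-shifts the augmented panel.
    """
    aug = aug or augment_known_loci(hg, known_stats, joint_panel)
    if panel is None and lam > 0.0:
        from .variance_component import RegularizedPanel

        panel = RegularizedPanel(aug.base.panel, lam)
    med = mediation_test(aug.base, panel=panel)
    vc = vc_test(aug.base, panel=panel)

    idx = aug.gene_mediator_indices()
    g = med.gamma_hat[idx]
    cg = med.cov_gamma[np.ix_(idx, idx)]
    sol, _ = _solve_psd(cg, g)
    u_adj = max(float(g @ sol), 0.0)
    p_adj = float(sps.chi2.sf(u_adj, df=len(idx)))
    per_adj = [med.per_mediator[i] for i in idx]
    return ConditionalResult(med, vc, u_adj, p_adj, vc.p_vc, per_adj)


def sequential_scan(hg: HarmonizedGene, known_stats=None, joint_panel=None,
                    alpha_stop: float = 0.05, max_steps: int | None = None,
                    lam: float = 0.0):
    """Sequential variant selection under growing conditional adjustment.

    Starting from the known-locus conditioning set, repeatedly: test the
    gene conditionally; stop when both the adjusted mediation p-value and
    the variance-component p-value are ≥ ``alpha_stop``; otherwise add the
    variant with the largest conditioned |α̂*_p|/se(α̂*_p) (ties go to the
    lower variant index) to the conditioning set and repeat.  Returns the
    ordered list of (variant_id, p_mediation_adjusted, p_vc) at each
    selection step.
    """
    joint_panel = joint_panel if joint_panel is not None else hg.panel
    if known_stats is not None and len(known_stats):
        cond_stats = known_stats.table.copy()
    else:
        cond_stats = hg.stats.table.iloc[0:0].copy()
    selected: list[tuple[str, float, float]] = []
    max_steps = max_steps if max_steps is not None else hg.P

    stab = hg.stats.table.set_index("variant_id", drop=False)
    while len(selected) < max_steps:
        ks = SummaryStatSet(cond_stats.reset_index(drop=True), hg.stats.dialect) \
            if len(cond_stats) else None
        aug = augment_known_loci(hg, ks, joint_panel)
        res = conditional_test(hg, aug=aug, lam=lam)
        if res.p_mediation_adjusted >= alpha_stop and res.p_vc >= alpha_stop:
            break
        base = aug.base
        var_alpha = np.diag(res.vc.cov_alpha)
        tstat = np.zeros(base.P)
        ok = (var_alpha > 0) & ~res.vc.absorbed
        tstat[ok] = np.abs(res.vc.alpha_star[ok]) / np.sqrt(var_alpha[ok])
        already = set(cond_stats["variant_id"]) if len(cond_stats) else set()
        candidates = [(p, v) for p, v in enumerate(base.variant_ids)
                      if v in set(hg.variant_ids) and v not in already]
        if not candidates:
            break
        best_p, best_v = max(candidates, key=lambda pv: (tstat[pv[0]], -pv[0]))
        if tstat[best_p] == 0.0:
            break
        selected.append((best_v, res.p_mediation_adjusted, res.p_vc))
        cond_stats = pd.concat([cond_stats, stab.loc[[best_v]]], ignore_index=True)
    return selected
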