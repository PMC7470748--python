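"""Readers and harmonization for GWAS summary statistics, eQTL weights, and LD references.

Every downstream test consumes a :class:`HarmonizedGene`: an allele-aligned,
variant-intersected bundle of per-variant association statistics, a P×K
variant→mediator weight matrix, and the genotype covariance of the same
variants.  All effects are re-expressed per copy of the panel's counted
allele (dosage 0–2) so that sign conventions cannot leak into the tests.
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatSet",
    "WeightSet",
    "LDPanel",
    "HarmonizedGene",
    "HarmonizePolicy",
    "load_summary_stats",
    "load_weights",
    "load_ld_matrix",
    "ld_from_genotypes",
    "harmonize",
]

DIALECTS = ("wald", "score", "standardized")

_REQUIRED_BY_DIALECT = {
    "wald": ("beta", "se"),
    "score": ("score_u", "score_v"),
    "standardized": ("z",),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatSet:
    """Per-variant marginal association statistics in one dialect.

    ``table`` holds one row per variant with columns ``variant_id``,
    ``effect_allele``, ``other_allele`` plus the dialect's statistic columns
    (``beta``/``se``, ``score_u``/``score_v``, or ``z``) and an optional
    ``n``.  ``rejected`` records (line_number, reason) for malformed rows.
    """

    table: pd.DataFrame
    dialect: str
    rejected: list = field(default_factory=list)

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r} in summary statistics")

    def __len__(self) -> int:
        return len(self.table)

    def effective_wald(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (beta, se) on the marginal-regression scale for any dialect.

        Score statistics convert via beta = U/V, se = V^{-1/2}; standardized
        z statistics are used as pseudo-betas with unit standard error (the
        panel must then be used on the correlation scale).
        """
        t = self.table
        if self.dialect == "wald":
            return t["beta"].to_numpy(float), t["se"].to_numpy(float)
        if self.dialect == "score":
            from .mediation import wald_from_score

            return wald_from_score(
                t["score_u"].to_numpy(float), t["score_v"].to_numpy(float)
            )
        z = t["z"].to_numpy(float)
        return z, np.ones_like(z)


@dataclass
class WeightSet:
    """Variant→mediator weights for one gene (the P×K matrix W).

    ``table`` columns: variant_id, mediator_id, weight, effect_allele,
    other_allele.  Zero weights are dropped at load time; a (variant,
    mediator) pair may appear at most once.
    """

    gene_id: str
    table: pd.DataFrame
    r2: float | None = None

    def __post_init__(self):
        if self.table.duplicated(["variant_id", "mediator_id"]).any():
            raise ValueError(
                f"duplicate (variant, mediator) entry in weights for {self.gene_id}"
            )
        if len(self.table) == 0:
            raise ValueError(f"gene {self.gene_id} has no nonzero weights")

    @property
    def mediator_ids(self) -> list:
        return list(pd.unique(self.table["mediator_id"]))

    @property
    def variant_ids(self) -> list:
        return list(pd.unique(self.table["variant_id"]))


@dataclass
class LDPanel:
    """Genotype covariance for an ordered variant set, from n_ref samples.

    ``cov`` is the P×P covariance of dosages (ddof=1); ``cor`` and the
    diagonal ``d`` derive from it.  Allele columns are optional — when
    present they define the counted allele each dosage column measures.
    """

    variant_ids: list
    cov: np.ndarray
    n_ref: int
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    monomorphic: list = field(default_factory=list)

    def __post_init__(self):
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (len(self.variant_ids),) * 2:
            raise ValueError("cov shape does not match variant list")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("cov must be symmetric")

    @property
    def d(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    @property
    def cor(self) -> np.ndarray:
        s = np.sqrt(self.d)
        s[s == 0] = 1.0
        c = self.cov / np.outer(s, s)
        np.fill_diagonal(c, 1.0)
        return c

    def subset(self, idx: np.ndarray) -> "LDPanel":
        idx = np.asarray(idx)
        return LDPanel(
            variant_ids=[self.variant_ids[i] for i in idx],
            cov=self.cov[np.ix_(idx, idx)],
            n_ref=self.n_ref,
            effect_allele=None if self.effect_allele is None else self.effect_allele[idx],
            other_allele=None if self.other_allele is None else self.other_allele[idx],
            monomorphic=[v for v in self.monomorphic if v in {self.variant_ids[i] for i in idx}],
        )


@dataclass
class HarmonizedGene:
    """Allele-aligned bundle ready for testing: stats, W, and LD share one
    variant ordering of length P; signs follow the panel's counted allele."""

    gene_id: str
    variant_ids: list
    W: np.ndarray  # P×K
    mediator_ids: list
    stats: SummaryStatSet  # aligned, P rows
    panel: LDPanel  # aligned, P×P
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        P = len(self.variant_ids)
        self.W = np.atleast_2d(np.asarray(self.W, float))
        if self.W.shape[0] != P:
            raise ValueError("W row count must equal number of variants")
        if P < 1:
            raise ValueError("harmonized gene must retain at least one variant")
        if len(self.stats.table) != P or len(self.panel.variant_ids) != P:
            raise ValueError("stats/panel not aligned with variant list")

    @property
    def P(self) -> int:
        return len(self.variant_ids)

    @property
    def K(self) -> int:
        return self.W.shape[1]


@dataclass
class HarmonizePolicy:
    drop_ambiguous: bool = True  # drop strand-ambiguous (A/T, C/G) variants
    restrict_to_weights: bool = False  # keep stats∩panel variants with weight 0
    drop_monomorphic: bool = True


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", dtype={0: str})


def load_summary_stats(path, dialect: str, column_map: dict | None = None) -> SummaryStatSet:
    """Load per-variant summary statistics from delimited text.

    ``column_map`` maps canonical names (variant_id, effect_allele,
    other_allele, beta, se, score_u, score_v, z, n) to the file's column
    names; identity by default.  Rows with non-positive se/score_v or
    missing statistics are rejected with their line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = _read_table(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)

    needed = ("variant_id", "effect_allele", "other_allele") + _REQUIRED_BY_DIALECT[dialect]
    for col in needed:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r} for dialect {dialect!r}")

    keep_cols = [c for c in
                 ("variant_id", "effect_allele", "other_allele", "beta", "se",
                  "score_u", "score_v", "z", "n") if c in raw.columns]
    raw = raw[keep_cols].copy()
    raw["variant_id"] = raw["variant_id"].astype(str)
    for al in ("effect_allele", "other_allele"):
        raw[al] = raw[al].astype(str).str.upper()

    rejected = []
    ok = np.ones(len(raw), bool)
    stat_cols = _REQUIRED_BY_DIALECT[dialect]
    for i, (_, row) in enumerate(raw.iterrows()):
        line = i + 2  # header is line 1
        if any(pd.isna(row[c]) for c in stat_cols):
            ok[i] = False
            rejected.append((line, "missing statistic"))
        elif dialect == "wald" and row["se"] <= 0:
            ok[i] = False
            rejected.append((line, "non-positive se"))
        elif dialect == "score" and row["score_v"] <= 0:
            ok[i] = False
            rejected.append((line, "non-positive score_v"))
    return SummaryStatSet(raw[ok].reset_index(drop=True), dialect, rejected)


def load_weights(path, mediator_id: str = "expression") -> dict[str, WeightSet]:
    """Load eQTL weights, either tab-delimited or a PredictDB SQLite database.

    Tabular columns: gene_id, variant_id, mediator_id (optional), weight,
    effect_allele, other_allele.  Zero-weight rows are dropped; a gene whose
    weights are all zero is excluded with a warning.
    """
    path = str(path)
    if path.endswith((".db", ".sqlite", ".sqlite3")):
        tab = _read_predictdb(path, mediator_id)
        r2_map = tab.attrs.get("r2", {})
    else:
        tab = _read_table(path)
        if "mediator_id" not in tab.columns:
            tab["mediator_id"] = mediator_id
        r2_map = {}
    for col in ("gene_id", "variant_id", "weight", "effect_allele", "other_allele"):
        if col not in tab.columns:
            raise ValueError(f"missing mandatory column {col!r} in weight table")
    tab["variant_id"] = tab["variant_id"].astype(str)

    out: dict[str, WeightSet] = {}
    for gene, sub in tab.groupby("gene_id", sort=True):
        nz = sub[sub["weight"] != 0.0]
        if len(nz) == 0:
            warnings.warn(f"gene {gene} has all-zero weights; excluded")
            continue
        nz = nz.sort_values(["mediator_id", "variant_id"], kind="stable").reset_index(drop=True)
        out[str(gene)] = WeightSet(str(gene), nz[["variant_id", "mediator_id", "weight",
                                                 "effect_allele", "other_allele"]],
                                   r2=r2_map.get(gene))
    return out


def _read_predictdb(path: str, mediator_id: str) -> pd.DataFrame:
    con = sqlite3.connect(path)
    try:
        w = pd.read_sql_query("SELECT gene, rsid, weight, eff_allele, ref_allele FROM weights", con)
        try:
            extra = pd.read_sql_query("SELECT * FROM extra", con)
        except Exception:
            extra = pd.DataFrame()
    finally:
        con.close()
    tab = w.rename(columns={"gene": "gene_id", "rsid": "variant_id",
                            "eff_allele": "effect_allele", "ref_allele": "other_allele"})
    tab["mediator_id"] = mediator_id
    r2_col = next((c for c in extra.columns if "R2" in c or "r2" in c), None)
    if r2_col is not None and "gene" in extra.columns:
        tab.attrs["r2"] = dict(zip(extra["gene"], extra[r2_col]))
    return tab


def load_ld_matrix(matrix_path, variants_path, n_ref: int) -> LDPanel:
    """Load a precomputed dense covariance/correlation matrix with a sidecar
    variant list (one id per line, optionally followed by the two alleles)."""
    vt = pd.read_csv(variants_path, sep=r"\s+", header=None, dtype=str)
    ids = vt[0].tolist()
    ea = vt[1].str.upper().to_numpy() if vt.shape[1] > 2 else None
    oa = vt[2].str.upper().to_numpy() if vt.shape[1] > 2 else None
    mat = np.loadtxt(matrix_path)
    return LDPanel(ids, np.atleast_2d(mat), n_ref=n_ref, effect_allele=ea, other_allele=oa)


def ld_from_genotypes(dosages, variant_ids, n_ref: int | None = None,
                      effect_allele=None, other_allele=None) -> LDPanel:
    """Estimate an LD panel from an n_ref×P dosage matrix (entries in [0,2],
    NaN allowed).  Missing entries are mean-imputed per variant; the
    covariance uses denominator n_ref − 1.  Monomorphic variants (zero
    variance) are flagged for downstream exclusion.
    """
    g = np.array(dosages, float)
    if g.ndim != 2 or g.shape[1] != len(variant_ids):
        raise ValueError("dosage matrix must be n_ref × P")
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    if nan_mask.any():
        g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    cov = np.cov(g, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    mono = [variant_ids[p] for p in np.nonzero(np.diag(cov) <= 0)[0]]
    return LDPanel(list(variant_ids), cov, n_ref=n_ref or g.shape[0],
                   effect_allele=None if effect_allele is None else np.asarray(effect_allele),
                   other_allele=None if other_allele is None else np.asarray(other_allele),
                   monomorphic=mono)


def _is_ambiguous(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _orient(ea, oa, ref_ea, ref_oa):
    """Return +1/-1 flip factor aligning (ea, oa) onto (ref_ea, ref_oa), or
    None when irreconcilable.  Strand flips are resolved via complements."""
    if (ea, oa) == (ref_ea, ref_oa):
        return 1.0
    if (ea, oa) == (ref_oa, ref_ea):
        return -1.0
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1.0
    if (cea, coa) == (ref_oa, ref_ea):
        return -1.0
    return None


def harmonize(stats: SummaryStatSet, weights: WeightSet, panel: LDPanel,
              policy: HarmonizePolicy | None = None) -> HarmonizedGene:
    """Intersect variant sets and resolve allele conventions for one gene.

    The surviving variant set is stats ∩ panel, restricted to the weight
    table's variants when the policy says so; stats-only variants otherwise
    enter with weight 0 (they still contribute to the variance-component
    test).  Effect signs in both stats and weights are flipped onto the
    panel's counted allele; when the panel carries no allele metadata the
    weight table's orientation is the reference.  Mediators left without a
    nonzero weight are dropped.
    """
    policy = policy or HarmonizePolicy()
    dropped: list[tuple[str, str]] = []

    stab = stats.table.set_index("variant_id", drop=False)
    panel_pos = {v: i for i, v in enumerate(panel.variant_ids)}
    wtab = weights.table
    wvars = set(wtab["variant_id"])

    # weight-model variants absent from stats or panel: excluded (≡ weight 0)
    for v in wtab["variant_id"].unique():
        if v not in stab.index or v not in panel_pos:
            dropped.append((v, "in weights but absent from stats/panel"))

    candidates = [v for v in panel.variant_ids if v in stab.index]
    if policy.restrict_to_weights:
        candidates = [v for v in candidates if v in wvars]

    mediators = weights.mediator_ids
    wmap = {(r.variant_id, r.mediator_id): r.weight for r in wtab.itertuples()}
    wallele = {r.variant_id: (r.effect_allele, r.other_allele) for r in wtab.itertuples()}

    keep_idx: list[int] = []
    stat_flip: list[float] = []
    weight_flip: dict[str, float] = {}
    for v in candidates:
        i = panel_pos[v]
        if policy.drop_monomorphic and v in panel.monomorphic:
            dropped.append((v, "monomorphic in reference panel"))
            continue
        s_ea, s_oa = stab.loc[v, "effect_allele"], stab.loc[v, "other_allele"]
        if panel.effect_allele is not None:
            ref_ea, ref_oa = panel.effect_allele[i], panel.other_allele[i]
        elif v in wallele:
            ref_ea, ref_oa = wallele[v]
        else:
            ref_ea, ref_oa = s_ea, s_oa
        if policy.drop_ambiguous and _is_ambiguous(ref_ea, ref_oa):
            dropped.append((v, "strand-ambiguous alleles"))
            continue
        sf = _orient(s_ea, s_oa, ref_ea, ref_oa)
        if sf is None:
            dropped.append((v, f"allele mismatch {s_ea}/{s_oa} vs {ref_ea}/{ref_oa}"))
            continue
        if v in wallele:
            wf = _orient(*wallele[v], ref_ea, ref_oa)
            if wf is None:
                dropped.append((v, "weight alleles irreconcilable with panel"))
                continue
            weight_flip[v] = wf
        keep_idx.append(i)
        stat_flip.append(sf)

    if not keep_idx:
        raise ValueError(f"gene {weights.gene_id}: empty variant intersection after harmonization")

    order = np.asarray(keep_idx)
    sub_panel = panel.subset(order)
    variant_ids = sub_panel.variant_ids

    aligned = stab.loc[variant_ids].reset_index(drop=True).copy()
    flip = np.asarray(stat_flip)
    for col in ("beta", "score_u", "z"):
        if col in aligned.columns:
            aligned[col] = aligned[col].to_numpy(float) * flip
    # record alignment: the aligned table's alleles now follow the panel
    swap = flip < 0
    ea, oa = aligned["effect_allele"].to_numpy().copy(), aligned["other_allele"].to_numpy().copy()
    aligned.loc[swap, "effect_allele"] = oa[swap]
    aligned.loc[swap, "other_allele"] = ea[swap]
    astats = SummaryStatSet(aligned, stats.dialect)

    W = np.zeros((len(variant_ids), len(mediators)))
    for pi, v in enumerate(variant_ids):
        for ki, m in enumerate(mediators):
            w = wmap.get((v, m), 0.0)
            if w:
                W[pi, ki] = w * weight_flip.get(v, 1.0)
    live = np.abs(W).sum(axis=0) > 0
    for ki, m in enumerate(mediators):
        if not live[ki]:
            dropped.append((m, "mediator lost all nonzero weights"))
    W = W[:, live]
    mediators = [m for m, ok in zip(mediators, live) if ok]
    if not mediators:
        raise ValueError(f"gene {weights.gene_id}: no mediator retains a nonzero weight")

    return HarmonizedGene(weights.gene_id, variant_ids, W, mediators, astats,
                          sub_panel, dropped)


def harmonized_from_arrays(gene_id, variant_ids, W, beta=None, se=None,
                           score_u=None, score_v=None, z=None, panel=None,
                           dialect=None, mediator_ids=None) -> HarmonizedGene:
    """Assemble a HarmonizedGene directly from aligned arrays (no allele
    bookkeeping) — the entry point used by simulations and tests."""
    P = len(variant_ids)
    cols = {"variant_id": [str(v) for v in variant_ids],
            "effect_allele": ["A"] * P, "other_allele": ["G"] * P}
    if beta is not None:
        cols["beta"], cols["se"] = np.asarray(beta, float), np.asarray(se, float)
        dialect = dialect or "wald"
    if score_u is not None:
        cols["score_u"], cols["score_v"] = np.asarray(score_u, float), np.asarray(score_v, float)
        dialect = dialect or "score"
    if z is not None:
        cols["z"] = np.asarray(z, float)
        dialect = dialect or "standardized"
    stats = SummaryStatSet(pd.DataFrame(cols), dialect)
    W = np.atleast_2d(np.asarray(W, float))
    if W.ndim == 2 and W.shape[0] != P and W.shape[1] == P:
        W = W.T
    if W.ndim == 1:
        W = W[:, None]
    K = W.shape[1]
    return HarmonizedGene(gene_id, [str(v) for v in variant_ids], W,
                          mediator_ids or [f"m{k}" for k in range(K)], stats, panel)
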