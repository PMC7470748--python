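import sqlite3

import numpy as np
import pandas as pd
import pytest

from smist.mediation import mediation_test
from smist.summary_io import (HarmonizePolicy, LDPanel, SummaryStatSet, WeightSet,
                              harmonize, harmonized_from_arrays, ld_from_genotypes,
                              load_summary_stats, load_weights)

STATS_WALD = """variant_id effect_allele other_allele beta se
rs1 A G 0.10 0.05
rs2 C T -0.20 0.04
rs3 G A 0.05 0.06
"""


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadSummaryStats:
    def test_wald_parse(self, tmp_path):
        s = load_summary_stats(write(tmp_path, "s.txt", STATS_WALD), "wald")
        assert len(s) == 3 and s.dialect == "wald"
        assert s.table.loc[1, "beta"] == -0.20

    def test_nonpositive_se_rejected_with_line(self, tmp_path):
        bad = STATS_WALD.replace("-0.20 0.04", "-0.20 0.0")
        s = load_summary_stats(write(tmp_path, "s.txt", bad), "wald")
        assert len(s) == 2
        assert s.rejected == [(3, "non-positive se")]

    def test_missing_column_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="mandatory column"):
            load_summary_stats(write(tmp_path, "s.txt", STATS_WALD), "score")

    def test_column_map(self, tmp_path):
        txt = STATS_WALD.replace("variant_id", "SNP").replace("beta", "B")
        s = load_summary_stats(write(tmp_path, "s.txt", txt), "wald",
                               column_map={"variant_id": "SNP", "beta": "B"})
        assert list(s.table["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_duplicate_variant_fatal(self, tmp_path):
        txt = STATS_WALD + "rs1 A G 0.2 0.1\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_summary_stats(write(tmp_path, "s.txt", txt), "wald")

    def test_score_dialect_converts_downstream(self, tmp_path):
        txt = """variant_id effect_allele other_allele score_u score_v
rs1 A G 2.0 4.0
"""
        s = load_summary_stats(write(tmp_path, "s.txt", txt), "score")
        beta, se = s.effective_wald()
        assert beta[0] == pytest.approx(0.5) and se[0] == pytest.approx(0.5)


class TestLoadWeights:
    WTXT = """gene_id variant_id mediator_id weight effect_allele other_allele
g1 rs1 expr 0.2 A G
g1 rs2 expr -0.1 C T
g1 rs3 expr 0.0 G A
g1 rs4 expr 0.3 A C
g1 rs5 expr 0.05 T C
"""

    def test_zero_weight_dropped(self, tmp_path):
        ws = load_weights(write(tmp_path, "w.txt", self.WTXT))
        assert len(ws["g1"].table) == 4
        assert "rs3" not in ws["g1"].variant_ids

    def test_two_genes_interleaved(self, tmp_path):
        txt = self.WTXT + "g2 rs9 expr 0.7 A G\ng2 rs8 expr 0.1 C T\n"
        ws = load_weights(write(tmp_path, "w.txt", txt))
        assert set(ws) == {"g1", "g2"}
        assert ws["g2"].variant_ids == ["rs8", "rs9"]  # internally ordered

    def test_all_zero_gene_excluded_with_warning(self, tmp_path):
        txt = self.WTXT + "g3 rs7 expr 0.0 A G\n"
        with pytest.warns(UserWarning, match="all-zero"):
            ws = load_weights(write(tmp_path, "w.txt", txt))
        assert "g3" not in ws

    def test_duplicate_pair_fatal(self, tmp_path):
        txt = self.WTXT + "g1 rs1 expr 0.4 A G\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_weights(write(tmp_path, "w.txt", txt))

    def test_predictdb_sqlite(self, tmp_path):
        db = tmp_path / "model.db"
        con = sqlite3.connect(db)
        con.execute("CREATE TABLE weights (gene TEXT, rsid TEXT, weight REAL,"
                    " eff_allele TEXT, ref_allele TEXT)")
        con.executemany("INSERT INTO weights VALUES (?,?,?,?,?)",
                        [("g1", "rs1", 0.2, "A", "G"), ("g1", "rs2", -0.3, "C", "T")])
        con.execute("CREATE TABLE extra (gene TEXT, [pred.perf.R2] REAL)")
        con.execute("INSERT INTO extra VALUES ('g1', 0.12)")
        con.commit()
        con.close()
        ws = load_weights(db)
        assert ws["g1"].variant_ids == ["rs1", "rs2"]
        assert ws["g1"].r2 == pytest.approx(0.12)


class TestLDPanel:
    def test_duplicated_columns_give_unit_correlation(self, rng):
        col = rng.binomial(2, 0.3, size=200).astype(float)
        panel = ld_from_genotypes(np.column_stack([col, col]), ["a", "b"])
        assert panel.cor[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        g = rng.binomial(2, 0.5, size=(10_000, 4)).astype(float)
        panel = ld_from_genotypes(g, list("abcd"))
        off = panel.cor[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) <= 0.05)

    def test_monomorphic_flagged(self):
        g = np.column_stack([np.zeros(50), np.arange(50) % 3])
        panel = ld_from_genotypes(g, ["mono", "ok"])
        assert panel.monomorphic == ["mono"]

    def test_missing_mean_imputed(self):
        g = np.array([[0, 1], [2, np.nan], [1, 1], [np.nan, 0]], float)
        panel = ld_from_genotypes(g, ["a", "b"])
        assert np.all(np.isfinite(panel.cov))
        # imputation uses the per-variant mean of observed dosages
        assert panel.cov[0, 0] == pytest.approx(np.var([0, 2, 1, 1], ddof=1))

    def test_denominator_is_nref_minus_one(self, rng):
        g = rng.binomial(2, 0.4, size=(30, 2)).astype(float)
        panel = ld_from_genotypes(g, ["a", "b"])
        assert np.allclose(panel.cov, np.cov(g, rowvar=False, ddof=1))


def _paired_inputs():
    """The same gene encoded two ways: all alleles aligned, and with one
    variant's stats reported on the opposite allele."""
    stats = pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3"],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "beta": [0.1, -0.2, 0.05],
        "se": [0.05, 0.04, 0.06],
    })
    flipped = stats.copy()
    flipped.loc[2, ["effect_allele", "other_allele"]] = ["A", "G"]
    flipped.loc[2, "beta"] = -0.05
    w = pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3"],
        "mediator_id": "expr",
        "weight": [0.5, -0.2, 0.3],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
    })
    cov = np.array([[0.4, 0.1, 0.05], [0.1, 0.5, 0.02], [0.05, 0.02, 0.45]])
    panel = LDPanel(["rs1", "rs2", "rs3"], cov, n_ref=1000,
                    effect_allele=np.array(["A", "C", "G"]),
                    other_allele=np.array(["G", "T", "A"]))
    return stats, flipped, w, panel


class TestHarmonize:
    def test_aligned_is_identity(self):
        stats, _, w, panel = _paired_inputs()
        hg = harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w), panel)
        assert hg.variant_ids == ["rs1", "rs2", "rs3"]
        assert np.allclose(hg.stats.table["beta"], stats["beta"])
        assert np.allclose(hg.W[:, 0], w["weight"])

    def test_flip_restores_statistics(self):
        stats, flipped, w, panel = _paired_inputs()
        hg_a = harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w), panel)
        hg_b = harmonize(SummaryStatSet(flipped, "wald"), WeightSet("g1", w), panel)
        assert hg_b.stats.table.loc[2, "beta"] == pytest.approx(0.05)
        ra, rb = mediation_test(hg_a), mediation_test(hg_b)
        assert ra.u_gamma == pytest.approx(rb.u_gamma, abs=1e-12)

    def test_ambiguous_dropped_by_policy(self):
        stats, _, w, panel = _paired_inputs()
        stats = stats.copy()
        stats.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        w = w.copy()
        w.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        panel.effect_allele[0], panel.other_allele[0] = "A", "T"
        hg = harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w), panel)
        assert hg.P == 2
        assert ("rs1", "strand-ambiguous alleles") in hg.dropped

    def test_irreconcilable_alleles_dropped(self):
        stats, _, w, panel = _paired_inputs()
        stats = stats.copy()
        stats.loc[1, ["effect_allele", "other_allele"]] = ["A", "C"]
        hg = harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w), panel)
        assert hg.P == 2 and any(v == "rs2" for v, _ in hg.dropped)

    def test_empty_intersection_raises(self):
        stats, _, w, panel = _paired_inputs()
        stats = stats.copy()
        stats["variant_id"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="empty"):
            harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w), panel)

    def test_stats_only_variant_gets_zero_weight(self):
        stats, _, w, panel = _paired_inputs()
        hg = harmonize(SummaryStatSet(stats, "wald"),
                       WeightSet("g1", w.iloc[:2]), panel)
        assert hg.P == 3 and hg.W[2, 0] == 0.0

    def test_restrict_to_weights_policy(self):
        stats, _, w, panel = _paired_inputs()
        hg = harmonize(SummaryStatSet(stats, "wald"), WeightSet("g1", w.iloc[:2]),
                       panel, HarmonizePolicy(restrict_to_weights=True))
        assert hg.P == 2

    def test_idempotence(self):
        stats, flipped, w, panel = _paired_inputs()
        hg = harmonize(SummaryStatSet(flipped, "wald"), WeightSet("g1", w), panel)
        wtab = pd.DataFrame({
            "variant_id": hg.variant_ids, "mediator_id": "expr",
            "weight": hg.W[:, 0],
            "effect_allele": hg.stats.table["effect_allele"],
            "other_allele": hg.stats.table["other_allele"],
        })
        hg2 = harmonize(hg.stats, WeightSet("g1", wtab), hg.panel)
        assert hg2.variant_ids == hg.variant_ids
        assert np.allclose(hg2.W, hg.W)
        assert np.allclose(hg2.stats.table["beta"], hg.stats.table["beta"])
        assert np.allclose(hg2.panel.cov, hg.panel.cov)
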