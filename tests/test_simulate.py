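import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from smist.simulate import (SimulationConfig, make_confounder, run_replicates,
                            simulate_dataset, simulate_genotypes,
                            simulate_phenotype, wald_summary_stats,
                            score_summary_stats, summarize_replicates)


class TestGenotypes:
    def test_independent_block_uncorrelated(self, rng):
        cfg = SimulationConfig(P=6, ld_spec=[(6, 0.0)],
                               mafs=np.full(6, 0.3)).realize(rng)
        g = simulate_genotypes(cfg, 10_000, rng)
        c = np.corrcoef(g.astype(float), rowvar=False)
        assert np.all(np.abs(c[np.triu_indices(6, 1)]) <= 0.05)

    def test_near_singular_regime(self, rng):
        cfg = SimulationConfig(ld_spec="near_singular").realize(rng)
        assert cfg.P == 12
        g = simulate_genotypes(cfg, 20_000, rng)
        c = np.corrcoef(g.astype(float), rowvar=False)
        assert c[np.triu_indices(12, 1)].min() > 0.99

    def test_rare_maf_recovery(self, rng):
        cfg = SimulationConfig(P=4, ld_spec=[(4, 0.0)],
                               mafs=np.full(4, 0.005)).realize(rng)
        g = simulate_genotypes(cfg, 100_000, rng)
        maf = g.mean(axis=0) / 2.0
        assert np.all((maf >= 0.004) & (maf <= 0.006))

    def test_common_maf_within_20pct_relative(self, rng):
        cfg = SimulationConfig(P=10).realize(rng)
        g = simulate_genotypes(cfg, 20_000, rng)
        maf = g.mean(axis=0) / 2.0
        assert np.all(np.abs(maf - cfg.mafs) / cfg.mafs <= 0.2)

    def test_hardy_weinberg_genotype_frequencies(self, rng):
        q = 0.25
        cfg = SimulationConfig(P=1, ld_spec=[(1, 0.0)],
                               mafs=np.array([q])).realize(rng)
        g = simulate_genotypes(cfg, 200_000, rng).ravel()
        freq = np.bincount(g, minlength=3) / len(g)
        assert freq[2] == pytest.approx(q ** 2, abs=0.003)
        assert freq[1] == pytest.approx(2 * q * (1 - q), abs=0.005)


class TestPhenotype:
    def test_baseline_probability_about_5pct(self, rng):
        cfg = SimulationConfig(P=10, gamma=0.0, tau_var=0.0, prop_direct=0.0)
        cfg = cfg.realize(rng)
        g = simulate_genotypes(cfg, 30_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        assert expit(cfg.intercept) == pytest.approx(0.047, abs=0.001)
        assert y.mean() == pytest.approx(expit(-3.0), abs=0.01)

    def test_mediator_variance_decomposition(self, rng):
        cfg = SimulationConfig(P=10, r2_med=0.05, var_m=1.5).realize(rng)
        g = simulate_genotypes(cfg, 100_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        b = g @ cfg.weights
        explained = truth["c"] ** 2 * np.var(b)
        assert explained == pytest.approx(0.075, rel=0.05)
        assert truth["sigma"] ** 2 == pytest.approx(1.425, rel=0.01)
        assert np.var(m) == pytest.approx(1.5, rel=0.05)

    def test_parameter_recovery_regression(self, rng):
        cfg = SimulationConfig(P=10, r2_med=0.2).realize(rng)
        g = simulate_genotypes(cfg, 100_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        b = g @ cfg.weights
        bc = b - b.mean()
        chat = bc @ (m - m.mean()) / (bc @ bc)
        se = truth["sigma"] / np.sqrt(bc @ bc)
        assert abs(chat - truth["c"]) <= 3 * se

    def test_direct_effects_orthogonal_to_predicted_mediator(self, rng):
        cfg = SimulationConfig(P=10, gamma=0.0, tau_var=0.05,
                               prop_direct=1.0).realize(rng)
        g = simulate_genotypes(cfg, 100_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        b = g @ cfg.weights
        raw = g @ truth["delta"]
        a0, a1 = truth["resid_coef"]
        resid = raw - a0 - a1 * b
        assert abs(np.corrcoef(resid, b)[0, 1]) <= 0.01

    def test_complete_null_has_no_effects(self, rng):
        cfg = SimulationConfig(P=10, gamma=0.0, tau_var=0.0,
                               prop_direct=0.0).realize(rng)
        g = simulate_genotypes(cfg, 5_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        assert np.all(truth["delta"] == 0.0)

    def test_inconsistent_mediator_sign_rule(self, rng):
        cfg = SimulationConfig(P=10, inconsistent=True, prop_direct=1.0,
                               gamma=np.log(2)).realize(rng)
        g = simulate_genotypes(cfg, 5_000, rng)
        y, m, truth = simulate_phenotype(g, cfg.weights, cfg, rng)
        nz = (cfg.weights != 0) & (truth["delta"] != 0)
        assert np.all(np.sign(truth["delta"][nz]) == -np.sign(cfg.weights[nz]))


class TestConfounder:
    def test_zero_target_independent(self, rng):
        cfg = SimulationConfig(P=10).realize(rng)
        g = simulate_genotypes(cfg, 10_000, rng).astype(float)
        conf = make_confounder(g, g @ cfg.weights, 0.0, rng)
        assert abs(np.corrcoef(conf, g @ cfg.weights)[0, 1]) <= 0.05

    def test_target_correlation_reached(self, rng):
        cfg = SimulationConfig(P=20).realize(rng)
        g = simulate_genotypes(cfg, 20_000, rng).astype(float)
        b = g @ cfg.weights
        conf = make_confounder(g, b, 0.25, rng)
        assert abs(abs(np.corrcoef(conf, b)[0, 1]) - 0.25) <= 0.03


class TestCaseControlSampling:
    def test_quotas_met(self, rng):
        cfg = SimulationConfig(n_cases=300, n_controls=200, P=10)
        study = simulate_dataset(cfg, rng)
        assert study.y.sum() == 300 and (1 - study.y).sum() == 200
        assert study.g.shape == (500, 10)

    def test_dialect_stats_consistent(self, rng):
        # score and Wald dialects agree on per-variant z for common variants
        cfg = SimulationConfig(n_cases=400, n_controls=400, P=8)
        study = simulate_dataset(cfg, rng)
        u, v = score_summary_stats(study.y, study.g)
        beta, se = wald_summary_stats(study.y, study.g)
        assert np.corrcoef(u / np.sqrt(v), beta / se)[0, 1] > 0.999


class TestRunReplicates:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_cases=100, n_controls=100, P=10)
        a = run_replicates(cfg, 5, seed=42)
        b = run_replicates(cfg, 5, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_summary_structure(self):
        cfg = SimulationConfig(n_cases=100, n_controls=100, P=10)
        df = run_replicates(cfg, 5, seed=1)
        s = summarize_replicates(df, alpha=0.5)
        assert set(s) == {"p_med", "p_vc", "p_fisher", "p_minp", "p_weighted"}
        for v in s.values():
            assert 0 <= v["ci"][0] <= v["rate"] <= v["ci"][1] <= 1
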