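"""Stop rules, the adaptive permutation loop and the genome scan."""

import itertools
import math

import numpy as np
import pytest

from apskat.adaptive import (StoppingConfig, adaptive_pvalue, ci_halfwidth,
                             ci_stop, first_nb_all_B, first_nb_zero_B,
                             genome_scan, minimum_permutations, nb_all_stop,
                             nb_zero_stop, permutation_statistics,
                             recommended_permutations, set_rng,
                             standard_pvalue)
from apskat.exceptions import ConfigurationError
from apskat.io import PhenotypeData, SnpSetCollection
from apskat.null_model import fit_null
from apskat.skat import skat_statistic
from apskat.synthetic import SimulationConfig, simulate_dataset


class TestCiHalfwidth:
    def test_hand_computed_value(self):
        # 1.959964 * sqrt(0.25/100)
        assert ci_halfwidth(0.5, 100, 0.05) == pytest.approx(0.09800, abs=5e-5)

    def test_halves_when_B_quadruples(self):
        assert ci_halfwidth(0.2, 400, 0.01) == pytest.approx(
            ci_halfwidth(0.2, 100, 0.01) / 2.0)

    def test_diverges_as_ci_level_vanishes(self):
        assert ci_halfwidth(0.5, 10, 1e-300) > 1.0  # quantile blows up

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_undefined_at_boundary(self, p):
        with pytest.raises(ValueError):
            ci_halfwidth(p, 100, 0.05)


class TestCiStop:
    def test_far_from_threshold_stops(self):
        cfg = StoppingConfig(alpha_e=0.05, m_sets=20_000, b=400_000)
        assert cfg.alpha_p == pytest.approx(2.5e-6)
        assert ci_stop(0.5, 100, cfg) is True  # interval ~[0.402, 0.598]

    def test_centered_on_threshold_continues(self):
        cfg = StoppingConfig(alpha_e=0.4, m_sets=1, b=100, ci_level=0.05)
        assert ci_stop(0.4, 1000, cfg) is False

    def test_wide_interval_continues(self):
        cfg = StoppingConfig(alpha_e=0.4, m_sets=1, b=100, ci_level=0.001)
        # half-width 3.29 * 0.25 ~ 0.82 covers alpha_p = 0.4
        assert ci_stop(0.5, 4, cfg) is False


class TestNegativeBinomialRules:
    def test_nb_zero_first_fires_at_59_for_5_percent(self):
        assert first_nb_zero_B(0.05) == 59
        # oracle: direct evaluation of (1-alpha_p)^B
        assert 0.95 ** 58 >= 0.05 > 0.95 ** 59
        assert not nb_zero_stop(58, 0.05) and nb_zero_stop(59, 0.05)

    def test_nb_zero_half(self):
        assert first_nb_zero_B(0.5) == 2  # 0.5^1 = 0.5 not < 0.5; 0.25 < 0.5

    def test_nb_zero_never_fires_before_budget_at_genome_scale(self):
        alpha_p = 2.5e-6
        b = recommended_permutations(0.05, 20_000)
        assert b == 2_000_000
        assert not nb_zero_stop(b, alpha_p)
        assert first_nb_zero_B(alpha_p) > 5_000_000

    def test_nb_all_first_fires_at_5_for_genome_setting(self):
        assert first_nb_all_B(0.05, 2.5e-6) == 5
        assert 0.05 ** 4 >= 2.5e-6 > 0.05 ** 5
        assert not nb_all_stop(4, 0.05, 2.5e-6) and nb_all_stop(5, 0.05, 2.5e-6)

    def test_nb_all_single_set_fires_at_two(self):
        assert first_nb_all_B(0.05, 0.05) == 2

    def test_nb_all_never_fires_at_alpha_one(self):
        assert not any(nb_all_stop(B, 1.0, 0.05) for B in range(1, 1000))


class TestStoppingConfig:
    def test_derived_quantities_and_defaults(self):
        cfg = StoppingConfig(alpha_e=0.05, m_sets=20_000)
        assert cfg.alpha_p == pytest.approx(2.5e-6)
        assert cfg.b == 2_000_000           # 5 / alpha_p
        assert cfg.ci_level == cfg.alpha_p  # recommended alpha = alpha_p
        assert cfg.batch == 1000

    def test_minimum_budget_enforced(self):
        with pytest.raises(ConfigurationError, match="resolve"):
            StoppingConfig(alpha_e=0.05, m_sets=1, b=19)

    def test_minimum_permutations_resolver(self):
        assert minimum_permutations(0.05, 20_000) == 400_000
        assert minimum_permutations(0.01, 20_000) == 2_000_000


class TestPermutationStatistics:
    def test_enumeration_contains_observed(self):
        z = np.array([1.0, -0.5, 2.0])
        V = np.array([[1.0], [0.0], [2.0]])
        s_obs = float((V[:, 0] @ z) ** 2)
        all_stats = sorted((V[:, 0] @ np.array(p)) ** 2
                           for p in itertools.permutations(z))
        assert any(math.isclose(s, s_obs) for s in all_stats)
        batch = permutation_statistics(z, V, 50, np.random.default_rng(0))
        assert np.all(batch >= 0)
        assert all(any(math.isclose(b, s, abs_tol=1e-9) for s in all_stats)
                   for b in batch)

    def test_exhaustive_mean_formula(self):
        """Mean permuted statistic over all n! orderings equals
        (sum z^2/(n-1)) * (||V||_F^2 - n ||colmeans(V)||^2) for centered z."""
        rng = np.random.default_rng(3)
        n, m = 6, 2
        V = rng.integers(0, 3, size=(n, m)).astype(float)
        z = rng.standard_normal(n)
        z -= z.mean()
        stats = [float(((np.array(p) @ V) ** 2).sum())
                 for p in itertools.permutations(z)]
        expected = (z @ z / (n - 1)) * (
            (V ** 2).sum() - n * (V.mean(axis=0) ** 2).sum())
        assert np.mean(stats) == pytest.approx(expected, rel=1e-10)


def _null_instance(seed, n=60, m=8):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, 0.1, size=(n, m)).astype(float)
    y = rng.standard_normal(n)
    fit = fit_null(PhenotypeData(values=y, sample_ids=[str(i) for i in range(n)]))
    stat = skat_statistic(fit.residuals, G, np.ones(m))
    return fit, stat


class TestAdaptivePvalue:
    def test_null_sets_stop_early(self):
        """Under the null the engine nearly always settles within the first
        few batches, far above alpha_p."""
        early, large_p = 0, 0
        for seed in range(20):
            fit, stat = _null_instance(seed)
            cfg = StoppingConfig(alpha_e=0.05, m_sets=1, b=500, batch=100)
            res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                                  set_rng(seed, 0))
            assert res.B <= 500 and 0 <= res.r <= res.B
            early += res.stop_reason in ("nb_all", "ci_exclusion")
            large_p += res.p_hat > 2 * cfg.alpha_p
        assert early >= 15
        assert large_p >= 16

    def test_never_exceeded_reports_resolution_floor_with_refine(self):
        """An observed statistic above every permutation statistic keeps r=0;
        refine pushes past the nb rule to p_hat = 1/b at the budget."""
        z = np.array([30.0, 0.1, -0.2, 0.35, -0.5, 0.6, -0.7, 0.8])
        V = z[:, None].copy()  # Cauchy-Schwarz: only the identity ties
        s = float((z @ z) ** 2)
        cfg = StoppingConfig(alpha_e=0.05, m_sets=1, b=2000, batch=500,
                             refine=True)
        res = adaptive_pvalue(z, V, s, cfg, np.random.default_rng(1))
        assert res.r == 0
        assert res.stop_reason == "max_reached"
        assert res.p_hat == pytest.approx(1.0 / 2000)

    def test_without_refine_same_instance_stops_by_nb_zero(self):
        z = np.array([30.0, 0.1, -0.2, 0.35, -0.5, 0.6, -0.7, 0.8])
        V = z[:, None].copy()
        s = float((z @ z) ** 2)
        cfg = StoppingConfig(alpha_e=0.05, m_sets=1, b=2000, batch=59)
        res = adaptive_pvalue(z, V, s, cfg, np.random.default_rng(1))
        assert res.stop_reason == "nb_zero"
        assert res.B == 59 and res.p_hat == pytest.approx(1 / 59)

    def test_replay_is_bit_identical(self):
        fit, stat = _null_instance(99)
        cfg = StoppingConfig(alpha_e=0.05, m_sets=1, b=1000, batch=100)
        r1 = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                             set_rng(7, 3))
        r2 = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                             set_rng(7, 3))
        assert r1 == r2

    def test_agrees_with_exhaustive_enumeration_at_n6(self):
        """p_hat at b=1e4 (refine) lands within 3 binomial SEs of the exact
        permutation p-value from all 720 orderings."""
        rng = np.random.default_rng(21)
        G = rng.integers(0, 3, size=(6, 3)).astype(float)
        y = rng.standard_normal(6)
        fit = fit_null(PhenotypeData(values=y, sample_ids=list("abcdef")))
        stat = skat_statistic(fit.residuals, G, np.ones(3))
        exact_r = sum(
            float(((np.array(p) @ stat.transformed) ** 2).sum()) > stat.s
            for p in itertools.permutations(fit.residuals))
        p_exact = exact_r / math.factorial(6)
        cfg = StoppingConfig(alpha_e=0.05, m_sets=1, b=10_000, refine=True)
        res = adaptive_pvalue(fit.residuals, stat.transformed, stat.s, cfg,
                              set_rng(5, 0))
        se = math.sqrt(p_exact * (1 - p_exact) / res.B)
        assert abs(res.p_hat - p_exact) <= 3 * se


class TestStandardPvalue:
    def test_fixed_budget_runs_all_permutations(self):
        fit, stat = _null_instance(17)
        res = standard_pvalue(fit.residuals, stat.transformed, stat.s, 5000,
                              np.random.default_rng(0), batch=1024)
        assert res.B == 5000 and res.stop_reason == "max_reached"
        assert res.p_hat == pytest.approx(res.r / 5000)


class TestGenomeScan:
    @pytest.fixture()
    def scan_inputs(self, small_panel):
        rng = np.random.default_rng(31)
        cfg = SimulationConfig(n=80, region_length=5000, seed=31)
        return simulate_dataset(small_panel, cfg, n_sets=6,
                                causal_set_fraction=0.5, rng=rng)

    def test_deterministic_under_seed_and_threads(self, scan_inputs):
        g, sets, pheno = scan_inputs
        cfg = StoppingConfig(alpha_e=0.05, m_sets=sets.m_sets, b=2000,
                             batch=500, seed=42)
        t1 = genome_scan(g, sets, pheno, cfg, compute_asymptotic=False)
        t2 = genome_scan(g, sets, pheno, cfg, compute_asymptotic=False)
        t4 = genome_scan(g, sets, pheno, cfg, compute_asymptotic=False, threads=3)
        assert t1.equals(t2)
        assert t1.equals(t4)

    def test_row_contract_and_skipped_sets(self, scan_inputs):
        g, sets, pheno = scan_inputs
        # add a set whose variants are all common or absent
        sets = SnpSetCollection(sets={**sets.sets, "empty_set": ["not_a_variant"]})
        cfg = StoppingConfig(alpha_e=0.05, m_sets=sets.m_sets, b=2000,
                             batch=500, seed=1)
        table = genome_scan(g, sets, pheno, cfg)
        assert len(table) == sets.m_sets
        row = table[table.set_id == "empty_set"].iloc[0]
        assert row.status == "skipped" and row.n_variants_rare == 0
        ok = table[table.status == "ok"]
        assert (ok.B <= 2000).all()
        assert ((ok.r >= 0) & (ok.r <= ok.B)).all()
        assert set(ok.stop_reason) <= {"ci_exclusion", "nb_zero", "nb_all",
                                       "max_reached"}

    def test_null_scan_significance_count_is_small(self, small_panel):
        """With uniform null p-values, ~alpha_e of a 100-set scan (i.e. 0-1
        sets) should clear the Bonferroni per-set threshold."""
        rng = np.random.default_rng(77)
        sim = SimulationConfig(n=60, region_length=5000, causal_fraction=0.0)
        g, sets, pheno = simulate_dataset(small_panel, sim, n_sets=100,
                                          causal_set_fraction=0.0, rng=rng)
        cfg = StoppingConfig(alpha_e=0.05, m_sets=sets.m_sets, seed=3)
        table = genome_scan(g, sets, pheno, cfg, compute_asymptotic=False)
        ok = table[table.status == "ok"]
        assert (ok.p_hat <= cfg.alpha_p).sum() <= 2
        # early stopping keeps the total far below m_sets * b
        assert ok.B.sum() < 0.2 * cfg.b * len(ok)
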