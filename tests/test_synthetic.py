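"""Haplotype panel generation, region sampling, effect assignment, phenotypes."""

import numpy as np
import pytest
from scipy import stats as ss

from apskat.exceptions import ConfigurationError
from apskat.synthetic import (HaplotypePanel, SimulationConfig, assign_effects,
                              draw_genotypes, generate_panel, sample_region,
                              simulate_dataset, simulate_phenotype)


class TestGeneratePanel:
    def test_determinism(self):
        p1 = generate_panel(H=100, S=80, region_length=10_000, seed=3)
        p2 = generate_panel(H=100, S=80, region_length=10_000, seed=3)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        np.testing.assert_array_equal(p1.positions, p2.positions)

    def test_structure_invariants(self, small_panel):
        assert set(np.unique(small_panel.haplotypes)) <= {0, 1}
        assert np.all(np.diff(small_panel.positions) > 0)
        assert small_panel.positions[0] >= 0
        assert small_panel.positions[-1] < small_panel.region_length
        f = small_panel.frequencies
        assert np.all((f > 0) & (f < 1))

    def test_default_spectrum_is_rare_variant_rich(self):
        """The truncated 1/x spectrum puts most variants below MAF 0.05 at the
        default panel size (10,000 haplotypes over 200 kb)."""
        panel = generate_panel(seed=0)
        maf = np.minimum(panel.frequencies, 1 - panel.frequencies)
        assert (maf < 0.05).mean() > 0.5

    def test_minimal_panel(self):
        panel = generate_panel(H=2, S=1, region_length=100, seed=1)
        # either the single site is polymorphic at frequency 0.5 or dropped
        assert panel.n_sites in (0, 1)
        if panel.n_sites:
            assert panel.frequencies[0] == pytest.approx(0.5)

    def test_local_ld_from_copying_process(self):
        """Adjacent sites share copying segments, so nearby-variant dosage
        correlation exceeds the far-pair correlation on average."""
        panel = generate_panel(H=400, S=300, region_length=50_000, seed=9)
        h = panel.haplotypes.astype(float)
        common = np.flatnonzero((h.mean(0) > 0.1) & (h.mean(0) < 0.9))
        h = h[:, common]
        corr = np.corrcoef(h.T)
        near = np.mean([abs(corr[i, i + 1]) for i in range(len(common) - 1)])
        far = np.mean([abs(corr[i, j])
                       for i in range(0, len(common), 7)
                       for j in range(0, len(common), 7)
                       if abs(i - j) > 40])
        assert near > far


class TestSampleRegion:
    def test_full_length_returns_panel(self, small_panel):
        out = sample_region(small_panel, small_panel.region_length,
                            np.random.default_rng(0))
        assert out is small_panel

    def test_window_positions_are_rebased(self, small_panel):
        rng = np.random.default_rng(4)
        region = sample_region(small_panel, 5000, rng)
        assert region.region_length == 5000
        assert np.all((region.positions >= 0) & (region.positions < 5000))

    def test_retry_cap_exhausted(self):
        sparse = HaplotypePanel(
            haplotypes=np.array([[1], [0]], dtype=np.int8),
            positions=np.array([199_999]), region_length=200_000)
        with pytest.raises(ConfigurationError, match="denser"):
            sample_region(sparse, 2, np.random.default_rng(0), max_retries=5)


class TestDrawGenotypes:
    def test_dosage_values(self, small_panel):
        g = draw_genotypes(small_panel, 50, np.random.default_rng(1))
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert g.n == 50 and g.m == small_panel.n_sites

    def test_sample_frequency_converges_to_panel_frequency(self, small_panel):
        f_panel = small_panel.frequencies
        mads = []
        for n in (40, 2000):
            g = draw_genotypes(small_panel, n, np.random.default_rng(2))
            f_sample = g.dosages.mean(axis=0) / 2.0
            mads.append(np.mean(np.abs(f_sample - f_panel)))
        assert mads[1] < mads[0]


class TestAssignEffects:
    def _maf(self):
        return np.array([1e-4, 1e-2, 0.04, 0.2, 0.4])

    def test_zero_causal_fraction_gives_null_model(self):
        cfg = SimulationConfig(causal_fraction=0.0)
        beta = assign_effects(self._maf(), cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(beta, np.zeros(5))

    def test_magnitude_anchors(self):
        cfg = SimulationConfig(causal_fraction=1.0, positive_fraction=1.0,
                               max_effect=2.0)
        beta = assign_effects(self._maf(), cfg, np.random.default_rng(0))
        # rare variants only (maf < 0.05): |beta| = 2.0 * |log10 maf| / 4
        assert beta[0] == pytest.approx(2.0)     # maf 1e-4 hits max effect
        assert beta[1] == pytest.approx(1.0)     # maf 1e-2 -> 2.0 * 2/4
        assert beta[3] == 0.0 and beta[4] == 0.0  # common variants never causal

    def test_causal_count_is_ceiling(self):
        maf = np.full(10, 0.01)
        cfg = SimulationConfig(causal_fraction=0.25)
        beta = assign_effects(maf, cfg, np.random.default_rng(3))
        assert (beta != 0).sum() == 3  # ceil(0.25 * 10)

    def test_sign_fraction(self):
        maf = np.full(4000, 0.01)
        cfg = SimulationConfig(causal_fraction=1.0, positive_fraction=0.8)
        beta = assign_effects(maf, cfg, np.random.default_rng(4))
        assert (beta > 0).mean() == pytest.approx(0.8, abs=0.03)

    def test_no_rare_variants_is_an_error(self):
        cfg = SimulationConfig()
        with pytest.raises(ConfigurationError, match="resample"):
            assign_effects(np.array([0.2, 0.3]), cfg, np.random.default_rng(0))


class TestSimulatePhenotype:
    def test_null_gaussian_moments(self, small_panel):
        g = draw_genotypes(small_panel, 4000, np.random.default_rng(5))
        cfg = SimulationConfig(n=4000)
        ph = simulate_phenotype(g, np.zeros(g.m), cfg, np.random.default_rng(6))
        assert ph.trait_type == "quantitative"
        assert abs(ph.values.mean()) < 0.1
        assert ss.kurtosis(ph.values) == pytest.approx(0.0, abs=0.3)

    def test_t5_noise_is_heavy_tailed(self, small_panel):
        g = draw_genotypes(small_panel, 4000, np.random.default_rng(7))
        cfg = SimulationConfig(n=4000, noise="student_t_df5")
        ph = simulate_phenotype(g, np.zeros(g.m), cfg, np.random.default_rng(8))
        assert ss.kurtosis(ph.values) > 1.0  # t(5) excess kurtosis is 6

    def test_signal_enters_linearly(self, small_panel):
        g = draw_genotypes(small_panel, 300, np.random.default_rng(9))
        beta = np.zeros(g.m)
        beta[0] = 5.0
        cfg = SimulationConfig(n=300, intercept=1.5)
        ph = simulate_phenotype(g, beta, cfg, np.random.default_rng(10))
        lin = 1.5 + g.imputed() @ beta
        resid = ph.values - lin
        assert abs(resid.mean()) < 0.2 and resid.std() == pytest.approx(1.0, abs=0.15)


def test_full_pipeline_determinism(small_panel):
    sim = SimulationConfig(n=50, seed=12)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(12)
        g, sets, ph = simulate_dataset(small_panel, sim, n_sets=4,
                                       causal_set_fraction=0.5, rng=rng)
        out.append((g.dosages.copy(), dict(sets.sets), ph.values.copy()))
    np.testing.assert_array_equal(out[0][0], out[1][0])
    assert out[0][1] == out[1][1]
    np.testing.assert_array_equal(out[0][2], out[1][2])
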