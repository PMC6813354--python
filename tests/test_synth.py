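import numpy as np
import pytest
from scipy.stats import ks_1samp

from poresel import synth
from poresel.constants import kBT
from poresel.potentials import (GaussianComponent, ModelPMF, boltzmann_cdf,
                                demo_two_well_pmf, flat_pmf)


def _cfg(**kw):
    defaults = dict(n_steps=50_000, equilibration_steps=10_000, seed=11)
    defaults.update(kw)
    return synth.LangevinConfig(**defaults)


class TestLangevinSampling:
    def test_harmonic_window_variance_matches_boltzmann(self):
        """Stationary variance of a biased flat landscape is k_BT/k."""
        pmf = flat_pmf((-3.0, 3.0))
        ws = synth.sample_window(pmf, 0.0, 10.0,
                                 _cfg(n_steps=120_000, equilibration_steps=20_000))
        expected = kBT(pmf.temperature) / 10.0
        assert ws.samples.var() == pytest.approx(expected, rel=0.10)

    def test_stiff_spring_pins_walker_to_center(self):
        pmf = flat_pmf((-2.0, 2.0))
        ws = synth.sample_window(
            pmf, 0.5, 1e4,
            _cfg(n_steps=20_000, equilibration_steps=2_000, timestep=1e-7))
        assert np.abs(ws.samples - 0.5).max() < 0.1

    def test_unbiased_sampling_reproduces_boltzmann_density(self):
        """An ensemble of independently equilibrated walkers on a two-well
        landscape is distributed per exp(−w/k_BT) (KS against the exact CDF).
        """
        pmf = ModelPMF(components=(GaussianComponent(-1.5, -1.0, 0.8),
                                   GaussianComponent(1.5, -1.0, 0.8)),
                       domain=(-4.5, 4.5))
        # one walker per "window" with k = 0: independent unbiased runs
        n_walkers = 400
        series = synth.sample_ladder(
            pmf, np.zeros(n_walkers), 0.0,
            _cfg(n_steps=40_001, equilibration_steps=40_000, seed=23))
        finals = np.array([s.samples[-1] for s in series])
        res = ks_1samp(finals, boltzmann_cdf(pmf))
        assert res.pvalue > 0.01

    def test_bit_reproducible_for_fixed_seed(self):
        pmf = demo_two_well_pmf()
        a = synth.sample_window(pmf, 3.0, 10.0, _cfg())
        b = synth.sample_window(pmf, 3.0, 10.0, _cfg())
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_distinct_seeds_give_distinct_trajectories(self):
        pmf = flat_pmf((-3.0, 3.0))
        a = synth.sample_window(pmf, 0.0, 10.0, _cfg(seed=1))
        b = synth.sample_window(pmf, 0.0, 10.0, _cfg(seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_unstable_timestep_rejected_with_width_in_message(self):
        pmf = demo_two_well_pmf()
        # drift-per-step criterion (unbiased walker, steep landscape)
        with pytest.raises(ValueError, match="width"):
            synth.sample_window(pmf, 3.0, 0.0, _cfg(timestep=1e-3))
        # harmonic-stability guard for a stiff spring
        with pytest.raises(ValueError, match="unstable"):
            synth.sample_window(pmf, 3.0, 1e4, _cfg(timestep=1e-4))

    def test_center_outside_domain_rejected(self):
        pmf = flat_pmf((-3.0, 3.0))
        with pytest.raises(ValueError, match="domain"):
            synth.sample_window(pmf, 5.0, 10.0, _cfg())

    def test_samples_respect_reflecting_boundaries(self):
        pmf = flat_pmf((-1.0, 1.0))
        ws = synth.sample_window(pmf, 0.0, 0.0, _cfg(n_steps=30_000,
                                                     equilibration_steps=100))
        assert ws.samples.min() >= -1.0 and ws.samples.max() <= 1.0


class TestHREMD:
    def test_identical_windows_always_exchange(self):
        pmf = flat_pmf((-3.0, 3.0))
        _, log = synth.run_hremd(pmf, [0.0, 0.0], 10.0,
                                 _cfg(n_steps=30_000, equilibration_steps=1_000),
                                 exchange_interval=100)
        assert log.mean_acceptance == 1.0

    def test_far_apart_windows_never_exchange(self):
        pmf = flat_pmf((-3.0, 3.0))
        _, log = synth.run_hremd(
            pmf, [-2.5, 2.5], 50.0,
            _cfg(n_steps=30_000, equilibration_steps=1_000, timestep=5e-6),
            exchange_interval=100)
        assert log.mean_acceptance < 0.01

    def test_demo_ladder_acceptance_in_recorded_band(self):
        """Mean neighbor acceptance on the demo ladder, k=10 at 0.5 Å
        spacing, sits in the band recorded from the seeded reference run
        (≈0.14; analytic flat-landscape estimate erfc(Δ/2σ) ≈ 0.16)."""
        from poresel import wham
        pmf = demo_two_well_pmf()
        ladder = wham.place_windows(12.5, -10.0, 0.5, 10.0)
        _, log = synth.run_hremd(pmf, ladder.centers, ladder.force_constant,
                                 _cfg(n_steps=40_000, equilibration_steps=10_000,
                                      seed=3),
                                 exchange_interval=1000)
        assert 0.05 < log.mean_acceptance < 0.30

    def test_no_exchange_equals_independent_runs(self):
        """With exchanges effectively disabled, each replica reproduces the
        independent single-window trajectory run with the same seed."""
        pmf = demo_two_well_pmf()
        centers = [2.0, 2.5, 3.0]
        cfg = _cfg(n_steps=5_000, equilibration_steps=1_000, seed=31)
        series, log = synth.run_hremd(pmf, centers, 10.0, cfg,
                                      exchange_interval=10**9)
        seeds = synth.ladder_seeds(cfg.seed, len(centers))
        for s, center, seed in zip(series, centers, seeds):
            solo = synth.sample_window(
                pmf, center, 10.0,
                synth.LangevinConfig(n_steps=cfg.n_steps,
                                     equilibration_steps=cfg.equilibration_steps,
                                     timestep=cfg.timestep,
                                     diffusion_coefficient=cfg.diffusion_coefficient,
                                     seed=seed))
            np.testing.assert_array_equal(s.samples, solo.samples)

    def test_unsorted_centers_rejected(self):
        pmf = flat_pmf((-3.0, 3.0))
        with pytest.raises(ValueError, match="sorted"):
            synth.run_hremd(pmf, [0.0, 2.0, 1.0], 10.0, _cfg())


class TestGenerateIV:
    TRUTH = dict(V_rev=10.0, G_max=1.0, V_half=-25.0, V_slope=8.0,
                 voltages=tuple(float(v) for v in range(-80, 61, 10)))

    def test_zero_current_at_reversal(self):
        truth = synth.SyntheticIVTruth(**{**self.TRUTH, "voltages": (10.0,)})
        rec = synth.generate_iv(truth)
        assert rec.peak_currents[0] == 0.0
        assert rec.tail_currents[0] == 0.0

    def test_saturated_limit_is_linear(self):
        truth = synth.SyntheticIVTruth(**self.TRUTH)
        v = 400.0
        assert truth.current(v) == pytest.approx((v - 10.0) * 1.0, rel=1e-6)

    def test_worked_value_at_zero_mV(self):
        truth = synth.SyntheticIVTruth(**self.TRUTH)
        assert truth.current(0.0) == pytest.approx(-9.579, abs=5e-4)

    def test_noise_is_seeded_and_reproducible(self):
        t = synth.SyntheticIVTruth(**self.TRUTH, noise_sd=0.5, seed=3)
        a, b = synth.generate_iv(t), synth.generate_iv(t)
        np.testing.assert_array_equal(a.peak_currents, b.peak_currents)
        np.testing.assert_array_equal(a.tail_currents, b.tail_currents)

    def test_tails_follow_prepulse_conductance(self):
        truth = synth.SyntheticIVTruth(**self.TRUTH)
        rec = synth.generate_iv(truth)
        g_tail = truth.tail_conductance
        v = np.array(sorted(truth.voltages))
        np.testing.assert_allclose(rec.tail_currents, g_tail * (v - 10.0),
                                   rtol=1e-12)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            synth.SyntheticIVTruth(**{**self.TRUTH, "V_slope": 0.0})
        with pytest.raises(ValueError):
            synth.SyntheticIVTruth(**{**self.TRUTH, "G_max": -1.0})
        with pytest.raises(ValueError):
            synth.SyntheticIVTruth(**{**self.TRUTH, "voltages": ()})


class TestGenerateParticles:
    def test_bulk_only_cloud_is_uniform_within_poisson(self):
        spec = synth.DensityFieldSpec(box_lo=(0, 0, 0), box_hi=(8, 8, 8),
                                      bulk_weight=1.0,
                                      mean_particles_per_frame=20.0)
        cloud = synth.generate_particles(spec, 4000, seed=5)
        counts, _ = np.histogramdd(cloud.positions,
                                   bins=(4, 4, 4), range=((0, 8),) * 3)
        expected = cloud.n_particles / 64
        # 4σ Poisson band per octant bin
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(expected))

    def test_zero_frames_gives_empty_cloud(self):
        spec = synth.DensityFieldSpec(box_lo=(0, 0, 0), box_hi=(4, 4, 4))
        cloud = synth.generate_particles(spec, 0, seed=1)
        assert cloud.n_particles == 0 and cloud.n_frames == 0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.DensityFieldSpec(box_lo=(0, 0, 0), box_hi=(4, 4, 4),
                                   hotspots=(synth.Hotspot((2, 2, 2), 0.5, 0.5),),
                                   bulk_weight=0.8)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="empty domain"):
            synth.DensityFieldSpec(box_lo=(0, 0, 0), box_hi=(4, -4, 4))

    def test_expected_density_integrates_to_mean_count(self):
        spec = synth.DensityFieldSpec(
            box_lo=(-6, -6, -6), box_hi=(6, 6, 6),
            hotspots=(synth.Hotspot((0, 0, 0), 1.0, 0.4),),
            bulk_weight=0.6, mean_particles_per_frame=3.0)
        edges = tuple(np.linspace(-6, 6, 25) for _ in range(3))
        dens = synth.expected_density(spec, edges)
        total = dens.sum() * 0.5**3
        assert total == pytest.approx(3.0, rel=1e-6)

    def test_poisson_frame_counts_and_determinism(self):
        spec = synth.DensityFieldSpec(box_lo=(0, 0, 0), box_hi=(4, 4, 4),
                                      mean_particles_per_frame=2.0)
        a = synth.generate_particles(spec, 2000, seed=8)
        b = synth.generate_particles(spec, 2000, seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)
        per_frame = np.bincount(a.frame_index, minlength=2000)
        assert per_frame.mean() == pytest.approx(2.0, abs=0.1)
        assert per_frame.var() == pytest.approx(2.0, rel=0.15)


class TestGenerateDihedrals:
    def test_absorbing_dunked_chain_stays_dunked(self):
        spec = synth.DihedralChainSpec(p_up_to_dunked=0.0, p_dunked_to_up=0.0,
                                       start_state="dunked", emission_sd=5.0)
        trace = synth.generate_dihedrals(spec, 2000, seed=2)
        assert np.all(trace.true_states == "dunked")

    def test_zero_emission_noise_hits_state_means(self):
        spec = synth.DihedralChainSpec(emission_sd=0.0)
        trace = synth.generate_dihedrals(spec, 500, seed=6)
        up = trace.true_states == "up"
        assert np.all(trace.chi1[up] == spec.up_mean[0])
        assert np.all(trace.chi2[~up] == spec.dunked_mean[1])

    def test_stationary_dunked_probability(self):
        spec = synth.DihedralChainSpec(p_up_to_dunked=0.022, p_dunked_to_up=0.178)
        assert spec.stationary_dunked == pytest.approx(0.11)
        trace = synth.generate_dihedrals(spec, 100_000, seed=4)
        frac = np.mean(trace.true_states == "dunked")
        assert frac == pytest.approx(0.11, abs=0.01)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            synth.DihedralChainSpec(p_up_to_dunked=1.5)
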