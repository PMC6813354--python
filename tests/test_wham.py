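import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poresel import synth, wham
from poresel.constants import kBT
from poresel.potentials import flat_pmf
from tests.conftest import wham_oracle


class TestPlaceWindows:
    @pytest.mark.parametrize("z_start,z_end,spacing,expected_n", [
        (12.5, -10.0, 0.5, 46),   # the standard axial protocol
        (0.0, 0.5, 0.5, 2),
        (0.0, 2.0, 0.5, 5),
    ])
    def test_window_counts(self, z_start, z_end, spacing, expected_n):
        ladder = wham.place_windows(z_start, z_end, spacing, 10.0)
        assert len(ladder) == expected_n

    def test_inclusive_endpoints_and_direction(self):
        ladder = wham.place_windows(12.5, -10.0, 0.5, 10.0)
        assert ladder.centers[0] == 12.5
        assert ladder.centers[-1] == -10.0
        assert np.allclose(np.diff(ladder.centers), -0.5)

    def test_non_multiple_span_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            wham.place_windows(0.0, 1.2, 0.5, 10.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            wham.place_windows(0.0, 1.0, -0.5, 10.0)
        with pytest.raises(ValueError):
            wham.place_windows(1.0, 1.0, 0.5, 10.0)

    @given(n=st.integers(min_value=1, max_value=200),
           spacing=st.floats(min_value=0.05, max_value=2.0),
           z0=st.floats(min_value=-50, max_value=50))
    @settings(deadline=None, max_examples=50)
    def test_count_matches_enumeration(self, n, spacing, z0):
        z_end = z0 + n * spacing
        ladder = wham.place_windows(z0, z_end, spacing, 10.0)
        assert len(ladder) == n + 1


class TestBuildHistograms:
    def _series(self, samples, center=0.0):
        return synth.WindowSeries(window_id=0, center=center, force_constant=10.0,
                                  samples=np.asarray(samples, dtype=float),
                                  timestep=1e-5, seed=0)

    def test_single_sample_lands_in_its_bin(self):
        hists = wham.build_histograms([self._series([0.0])], 0.2, (-0.1, 0.1))
        assert hists.counts.sum() == 1
        assert hists.counts[0, 0] == 1

    def test_sample_on_interior_edge_goes_right(self):
        # half-open [left, right) bins: a sample at 0.5 belongs to [0.5, 1.0)
        hists = wham.build_histograms([self._series([0.5])], 0.5, (0.0, 1.0))
        np.testing.assert_array_equal(hists.counts[0], [0, 1])

    def test_uniform_samples_multinomial(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 1000)
        hists = wham.build_histograms([self._series(x)], 0.1, (0.0, 1.0))
        assert hists.counts.sum() == 1000
        # 5σ multinomial band: sd = sqrt(n p (1-p)) ≈ 9.5
        assert np.all(np.abs(hists.counts[0] - 100) < 48)

    def test_out_of_range_counted_not_dropped(self):
        hists = wham.build_histograms([self._series([0.0, 5.0, -3.0])],
                                      0.5, (-1.0, 1.0))
        assert hists.n_out_of_range[0] == 2
        assert hists.n_samples[0] == 3
        assert hists.counts[0].sum() == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            wham.build_histograms([self._series([0.0])], 0.0, (-1.0, 1.0))


class TestSolveWham:
    def test_single_unbiased_window_is_boltzmann_inversion(self):
        """With one window and zero bias WHAM degenerates to
        w = −k_BT ln(counts/total), bin for bin."""
        counts = np.array([50.0, 30.0, 20.0])
        samples = np.concatenate([np.full(int(c), z)
                                  for c, z in zip(counts, [0.1, 0.3, 0.5])])
        series = [synth.WindowSeries(window_id=0, center=0.3, force_constant=0.0,
                                     samples=samples, timestep=1e-5, seed=0)]
        ladder = wham.WindowLadder(centers=(0.3,), force_constant=0.0, spacing=0.2)
        hists = wham.build_histograms(series, 0.2, (0.0, 0.6))
        profile, report = wham.solve_wham(hists, ladder, offset="min")
        kT = kBT(profile.temperature)
        direct = -kT * np.log(counts / counts.sum())
        direct -= direct.min()
        np.testing.assert_allclose(profile.w, direct, atol=1e-12)
        np.testing.assert_allclose(report.eta, 0.0, atol=1e-12)

    def test_two_overlapping_windows_on_flat_truth(self):
        pmf = flat_pmf((-2.0, 2.0))
        cfg = synth.LangevinConfig(n_steps=220_000, equilibration_steps=20_000,
                                   seed=17)
        series = synth.sample_ladder(pmf, [-0.2, 0.2], 5.0, cfg)
        ladder = wham.WindowLadder(centers=(-0.2, 0.2), force_constant=5.0,
                                   spacing=0.4)
        hists = wham.build_histograms(series, 0.1, (-2.0, 2.0))
        profile, _ = wham.solve_wham(hists, ladder, offset="min")
        occ = profile.occupied() & (np.abs(profile.z) < 1.0)  # well-sampled core
        w = profile.w[occ] - profile.w[occ].mean()
        assert np.abs(w).max() < 0.05

    def test_demo_ladder_recovers_truth(self, demo_wham_solution):
        """46-window recovery of the two-well landscape: RMSE < 0.3 kcal/mol
        over occupied bins after common-offset alignment."""
        pmf, ladder, series, hists, profile, report = demo_wham_solution
        occ = profile.occupied()
        truth = np.asarray(pmf(profile.z[occ]))
        diff = profile.w[occ] - truth
        diff -= diff.mean()
        assert float(np.sqrt(np.mean(diff**2))) < 0.3
        assert report.final_residual <= wham.DEFAULT_TOLERANCE

    def test_demo_ladder_matches_independent_oracle(self, demo_wham_solution):
        """The self-consistent iteration agrees pointwise with a direct
        likelihood-minimization WHAM on the same histograms."""
        pmf, ladder, series, hists, profile, report = demo_wham_solution
        z_o, w_o = wham_oracle(hists, ladder)
        occ = profile.occupied() & np.isfinite(w_o)
        diff = profile.w[occ] - w_o[occ]
        diff -= diff.mean()
        assert np.abs(diff).max() < 0.05

    def test_reversed_ladder_gives_same_profile(self, demo_wham_solution):
        pmf, ladder, series, hists, profile, report = demo_wham_solution
        rev_ladder = wham.WindowLadder(centers=ladder.centers[::-1],
                                       force_constant=ladder.force_constant,
                                       spacing=ladder.spacing)
        rev_hists = wham.BiasedHistogramSet(
            bin_edges=hists.bin_edges, counts=hists.counts[::-1],
            n_samples=hists.n_samples[::-1],
            n_out_of_range=hists.n_out_of_range[::-1])
        rev_profile, _ = wham.solve_wham(rev_hists, rev_ladder)
        occ = profile.occupied()
        np.testing.assert_allclose(rev_profile.w[occ], profile.w[occ], atol=1e-4)

    def test_well_sampled_eta_small_and_truncation_is_local(self, demo_wham_solution):
        """Converged relative entropies stay below 0.05 on clean data;
        truncating one window's sampling flags only that window."""
        pmf, ladder, series, hists, profile, report = demo_wham_solution
        assert report.eta.max() < 0.05
        assert report.flagged_windows == []

        bad = 20
        corrupted = list(series)
        s = series[bad]
        kept = s.samples[s.samples > s.center]  # one-sided, truncated sampling
        corrupted[bad] = synth.WindowSeries(
            window_id=s.window_id, center=s.center,
            force_constant=s.force_constant, samples=kept,
            timestep=s.timestep, seed=s.seed)
        hists2 = wham.build_histograms(corrupted, 0.1, (-12.0, 14.5))
        _, report2 = wham.solve_wham(hists2, ladder)
        assert bad in report2.flagged_windows
        others = [w for w in report2.flagged_windows if w != bad]
        assert others == []

    def test_disconnected_ladder_rejected(self):
        samples_a = np.random.default_rng(0).normal(-3.0, 0.1, 500)
        samples_b = np.random.default_rng(1).normal(3.0, 0.1, 500)
        series = [
            synth.WindowSeries(window_id=0, center=-3.0, force_constant=10.0,
                               samples=samples_a, timestep=1e-5, seed=0),
            synth.WindowSeries(window_id=1, center=3.0, force_constant=10.0,
                               samples=samples_b, timestep=1e-5, seed=1),
        ]
        ladder = wham.WindowLadder(centers=(-3.0, 3.0), force_constant=10.0,
                                   spacing=6.0)
        hists = wham.build_histograms(series, 0.1, (-4.0, 4.0))
        with pytest.warns(UserWarning, match="no occupied bin"):
            with pytest.raises(ValueError, match="disconnected"):
                wham.solve_wham(hists, ladder)


class TestRelativeEntropy:
    def test_identical_distributions_give_zero(self):
        p = np.array([[0.2, 0.3, 0.5]])
        eta, flags = wham.relative_entropy(p, p)
        assert eta[0] == 0.0 and not flags[0]

    def test_worked_two_bin_example(self):
        eta, _ = wham.relative_entropy(np.array([[0.5, 0.5]]),
                                       np.array([[0.9, 0.1]]))
        assert eta[0] == pytest.approx(0.511, abs=5e-4)

    def test_single_surviving_term_is_ln2(self):
        eta, flags = wham.relative_entropy(np.array([[1.0, 0.0]]),
                                           np.array([[0.5, 0.5]]))
        assert eta[0] == pytest.approx(np.log(2), rel=1e-12)
        assert not flags[0]

    def test_unsupported_observation_flags_infinite(self):
        eta, flags = wham.relative_entropy(np.array([[0.5, 0.5]]),
                                           np.array([[1.0, 0.0]]))
        assert flags[0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            wham.relative_entropy(np.array([[0.5, 0.5]]),
                                  np.array([[0.5, 0.3, 0.2]]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_nonnegative_on_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6), size=2)
        q = rng.dirichlet(np.ones(6), size=2)
        eta, _ = wham.relative_entropy(p, q)
        assert np.all(eta >= -1e-12)


class TestBlockVariance:
    def test_constant_series_is_zero(self):
        assert wham.block_variance(np.full(100, 3.7), 10) == 0.0

    def test_worked_four_sample_example(self):
        assert wham.block_variance(np.array([1.0, 2.0, 3.0, 4.0]), 2) == 1.0

    def test_iid_gaussian_matches_standard_error(self):
        """Across seeded repeats the block estimate averages to σ²/M."""
        sigma2, M = 4.0, 10_000
        estimates = [wham.block_variance(
            np.random.default_rng(s).normal(0, 2.0, M), 10)
            for s in range(100)]
        assert np.mean(estimates) == pytest.approx(sigma2 / M, rel=0.15)

    def test_remainder_dropped(self):
        x = np.arange(103, dtype=float)
        assert wham.block_variance(x, 10) == wham.block_variance(x[:100], 10)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            wham.block_variance(np.arange(10.0), 1)


class TestPropagatePmfVariance:
    def test_zero_variances_give_zero_profile(self):
        out = wham.propagate_pmf_variance(np.zeros(5), 10.0, 0.5)
        np.testing.assert_array_equal(out, 0.0)

    def test_worked_two_window_example(self):
        out = wham.propagate_pmf_variance(np.array([0.0, 0.01, 0.01]), 10.0, 0.5)
        assert out[-1] == pytest.approx(0.5)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        out = wham.propagate_pmf_variance(rng.uniform(0, 0.1, 20), 10.0, 0.5)
        assert np.all(np.diff(out) >= 0)
        assert out[0] == 0.0

    def test_series_ladder_length_mismatch_rejected(self, demo_wham_solution):
        pmf, ladder, series, hists, profile, report = demo_wham_solution
        with pytest.raises(ValueError, match="window"):
            wham.pmf_variance_profile(profile, series[:-1], ladder)
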