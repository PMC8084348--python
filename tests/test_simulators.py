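import numpy as np
import pytest
from scipy import stats

from cttespike import (CoupledPairParams, EventSeries, LIFParams,
                       NoisyCopyParams, StimulusParams, coupled_rate,
                       simulate_coupled_pair, simulate_homogeneous_poisson,
                       simulate_lif, simulate_noisy_copy, simulate_stimulus)


class TestHomogeneousPoisson:
    def test_isi_distribution_matches_exponential(self):
        s = simulate_homogeneous_poisson(2.0, 100_000, 42)
        isis = np.diff(s.times)
        assert abs(isis.mean() - 0.5) < 5 / np.sqrt(isis.size)
        _, p = stats.kstest(isis, "expon", args=(0, 0.5))
        assert p > 0.01

    def test_single_event_and_validation(self):
        s = simulate_homogeneous_poisson(1.0, 1, 0)
        assert len(s) == 1 and s.times[0] >= 0
        with pytest.raises(ValueError):
            simulate_homogeneous_poisson(0.0, 10, 0)
        with pytest.raises(ValueError):
            simulate_homogeneous_poisson(1.0, 0, 0)

    def test_reproducible(self):
        a = simulate_homogeneous_poisson(1.0, 500, 9)
        b = simulate_homogeneous_poisson(1.0, 500, 9)
        assert np.array_equal(a.times, b.times)


class TestCoupledRate:
    @pytest.mark.parametrize("t_y1,expected", [
        (2.0, 0.5),            # beyond the bump support: baseline
        (0.0, 0.5),            # bump and offset cancel at zero
    ])
    def test_boundary_values(self, t_y1, expected):
        assert coupled_rate(t_y1, CoupledPairParams()) == pytest.approx(expected)

    def test_peak_value(self):
        p = CoupledPairParams()
        val = coupled_rate(0.5, p)
        assert val == pytest.approx(0.5 + 5 - 5 * np.exp(-0.25 / 0.02), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            coupled_rate(-0.1, CoupledPairParams())


class TestCoupledPair:
    def test_thinning_reproduces_conditional_rate(self, coupled_pair_small):
        """Empirical rate binned over t_y1 matches the analytic profile."""
        params, y, x = coupled_pair_small
        ys, xs = y.times, x.times
        bins = np.linspace(0, 1.5, 16)
        idx = np.searchsorted(ys, xs, "left") - 1
        ok = idx >= 0
        ty1_ev = xs[ok] - ys[idx[ok]]
        counts, _ = np.histogram(ty1_ev, bins)
        grid = np.arange(ys[0], xs[-1], 0.01)
        gi = np.searchsorted(ys, grid, "left") - 1
        gok = gi >= 0
        occ, _ = np.histogram(grid[gok] - ys[gi[gok]], bins)
        occ_t = occ * 0.01
        centres = (bins[:-1] + bins[1:]) / 2
        emp = counts / occ_t
        theo = coupled_rate(centres, params)
        # Poisson error per bin
        sd = np.sqrt(np.maximum(counts, 1)) / occ_t
        assert np.all(np.abs(emp - theo) < 5 * sd + 0.05 * theo)

    def test_baseline_rate_beyond_cutoff(self, coupled_pair_small):
        params, y, x = coupled_pair_small
        idx = np.searchsorted(y.times, x.times, "left") - 1
        ok = idx >= 0
        ty1 = x.times[ok] - y.times[idx[ok]]
        far = ty1 >= params.t_cut
        # occupation time with t_y1 >= t_cut
        grid = np.arange(y.times[0], x.times[-1], 0.01)
        gi = np.searchsorted(y.times, grid, "left") - 1
        gok = gi >= 0
        occ_far = np.sum((grid[gok] - y.times[gi[gok]]) >= params.t_cut) * 0.01
        rate = far.sum() / occ_far
        assert rate == pytest.approx(params.lambda_x_base, rel=0.1)

    def test_zero_bump_gives_independent_poisson(self):
        p = CoupledPairParams(m=1e-9, lambda_h=2.0)
        y, x = simulate_coupled_pair(p, 5000, 1)
        isis = np.diff(x.times)
        _, pval = stats.kstest(isis, "expon", args=(0, 1 / p.lambda_x_base))
        assert pval > 0.01

    def test_bound_validation(self):
        with pytest.raises(ValueError):
            CoupledPairParams(lambda_h=1.0)  # below base + m

    def test_exact_event_count_and_reproducibility(self):
        p = CoupledPairParams()
        y1, x1 = simulate_coupled_pair(p, 1234, 3)
        y2, x2 = simulate_coupled_pair(p, 1234, 3)
        assert len(x1) == 1234
        assert np.array_equal(x1.times, x2.times)
        assert np.array_equal(y1.times, y2.times)


class TestNoisyCopy:
    def test_noiseless_daughters_are_exact_shifts(self):
        p = NoisyCopyParams(sigma_M=1e-12, sigma_D=1e-12)
        m, d1, d2 = simulate_noisy_copy(p, 100, 0)
        np.testing.assert_allclose(d2.times - d1.times, 0.25, atol=1e-6)
        np.testing.assert_allclose(np.diff(m.times), 1.0, atol=1e-6)

    def test_mean_daughter_offsets(self):
        p = NoisyCopyParams()
        m, d1, d2 = simulate_noisy_copy(p, 4000, 8)
        assert np.mean(d2.times - m.times) == pytest.approx(0.5, abs=0.01)
        assert np.mean(d1.times - m.times) == pytest.approx(0.25, abs=0.01)

    def test_translation_shifts_daughter_alignment(self):
        """After translating D1 by 10T, D1 events sit 0.25 - 10 before D2."""
        p = NoisyCopyParams(omega=10.0)
        m, d1, d2 = simulate_noisy_copy(p, 3000, 8)
        # D1 = M + a_D1 + omega, D2 = M + a_D2, so D1 - D2 = omega - 0.25
        target_lag = 10.0 - 0.25
        j = np.clip(np.searchsorted(d1.times, d2.times + target_lag),
                    1, len(d1.times) - 1)
        best = np.minimum(np.abs(d1.times[j] - (d2.times + target_lag)),
                          np.abs(d1.times[j - 1] - (d2.times + target_lag)))
        assert np.median(best) < 0.2

    def test_outputs_strictly_increasing(self):
        p = NoisyCopyParams(sigma_D=0.6)  # large jitter forces reordering
        m, d1, d2 = simulate_noisy_copy(p, 2000, 4)
        for s in (m, d1, d2):
            assert np.all(np.diff(s.times) > 0)


class TestStimulus:
    def test_refractory_renewal_rate(self):
        p = StimulusParams(rate_low=20.0, rate_high=20.0, refractory=0.005,
                           bound_rate=40.0)
        s = simulate_stimulus(p, 800.0, 3)
        expected = 20.0 / (1 + 20.0 * 0.005)
        assert len(s) / 800.0 == pytest.approx(expected, rel=0.05)

    def test_zero_rate_gives_empty_series(self):
        p = StimulusParams(rate_low=0.0, rate_high=0.0, bound_rate=1.0)
        assert len(simulate_stimulus(p, 10.0, 0)) == 0

    def test_window_rates_vary_beyond_poisson(self):
        """Per-window counts are over-dispersed relative to a constant rate,
        reflecting the per-window uniform rate draws."""
        p = StimulusParams(window_length=0.5, rate_low=0.0, rate_high=40.0,
                           refractory=0.0)
        s = simulate_stimulus(p, 2000.0, 5)
        edges = np.arange(0, 2000.0 + 0.5, 0.5)
        counts, _ = np.histogram(s.times, edges)
        # homogeneous Poisson would give variance == mean; uniform window
        # rates add var(r)*w^2 = (40^2/12)*0.25
        dispersion = counts.var() / counts.mean()
        assert dispersion > 2.0

    def test_refractory_enforced(self):
        p = StimulusParams(rate_low=35.0, rate_high=40.0, refractory=0.01)
        s = simulate_stimulus(p, 200.0, 1)
        assert np.all(np.diff(s.times) >= 0.01 - 1e-12)


class TestLIF:
    def test_silent_without_input(self):
        lif = LIFParams()
        out = simulate_lif(lif, [], 10.0)
        assert len(out) == 0

    def test_single_strong_input_spikes_at_delay(self):
        lif = LIFParams(connections=[(0, "excitatory", 25.0, 0.002)])
        stim = EventSeries(np.array([1.0]))
        out = simulate_lif(lif, [stim], 5.0)
        np.testing.assert_allclose(out.times, [1.002], atol=1e-12)

    def test_subthreshold_input_stays_silent(self):
        lif = LIFParams(connections=[(0, "excitatory", 10.0, 0.0)])
        stim = EventSeries(np.array([1.0, 5.0]))  # decays fully in between
        out = simulate_lif(lif, [stim], 10.0)
        assert len(out) == 0

    def test_inhibition_cancels_excitation(self):
        lif = LIFParams(connections=[(0, "excitatory", 25.0, 0.01),
                                     (1, "inhibitory", 25.0, 0.0)])
        stim = EventSeries(np.array([1.0]))
        inhib = EventSeries(np.array([1.005]))
        out = simulate_lif(lif, [stim, inhib], 5.0)
        assert len(out) == 0

    def test_benchmark_drive_fires_near_20hz(self):
        # six stimuli at 18 mV / 2 ms delay, one third inhibitory, drive
        # the target at roughly 20 Hz (checked loosely)
        ss = np.random.SeedSequence(77).spawn(6)
        sp = StimulusParams()
        stimuli = [simulate_stimulus(sp, 120.0, s) for s in ss]
        conns = [(i, "inhibitory" if i < 2 else "excitatory", 18.0, 0.002)
                 for i in range(6)]
        lif = LIFParams(connections=conns)
        out = simulate_lif(lif, stimuli, 120.0)
        rate = len(out) / 120.0
        assert 10.0 < rate < 30.0
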