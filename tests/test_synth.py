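"""Synthetic-session generator: schedule, count model, rendering, LFP."""

import numpy as np
import pytest

from lamdec.synth import (NeuronSpec, SessionConfig, Trial,
                          build_stimulus_schedule, correlation_permutation,
                          generate_session, impose_noise_correlations,
                          render_spike_times, sample_trial_counts,
                          synthesize_lfp, temporal_intensity)
from lamdec.tuning import fano_factor, modulation_ratio


def _spec(**kw):
    base = dict(depth=500.0, preferred_direction=90.0, tuning_amplitude=0.0,
                baseline=20.0, tuning_concentration=2.0, direction_bias=0.0,
                modulation_ratio_target=0.0, fano_target=1.0, optimal_sf=2.0)
    base.update(kw)
    return NeuronSpec(**base)


TRIAL = Trial(90.0, 2.0, "mono", 0.0)


class TestSchedule:
    def test_balance_and_direction_grid(self):
        cfg = SessionConfig(reps_per_direction=5, sf_set=(2.0,), seed=0)
        sched = build_stimulus_schedule(cfg)
        assert len(sched) == 180
        counts = sched.groupby(["direction", "sf", "eye"]).size()
        assert (counts == 5).all()
        assert sorted(sched["direction"].unique()) == list(range(0, 360, 10))

    def test_orientation_pooling_gives_18_classes(self):
        cfg = SessionConfig(reps_per_direction=5, sf_set=(2.0,), seed=0)
        sched = build_stimulus_schedule(cfg)
        assert len(np.unique(sched["direction"] % 180)) == 18

    def test_same_seed_same_schedule(self):
        cfg = SessionConfig(reps_per_direction=5, seed=11)
        a = build_stimulus_schedule(cfg)
        b = build_stimulus_schedule(cfg)
        assert a.equals(b)

    @pytest.mark.parametrize("kw", [dict(reps_per_direction=1),
                                    dict(compartment_thicknesses=(0.0, 311, 281, 489)),
                                    dict(depth_range=(0.0, 100.0)),
                                    dict(noise_corr=0.9)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SessionConfig(**kw)


class TestCountModel:
    @pytest.mark.parametrize("target,tol", [(1.0, 0.05), (1.9, 0.1), (0.5, 0.06)])
    def test_fano_recovery(self, rng, target, tol):
        spec = _spec(fano_target=target)
        counts = np.array([sample_trial_counts(spec, TRIAL, rng)
                           for _ in range(4000)])
        total = counts.sum(axis=1)
        assert total.mean() == pytest.approx(20.0, rel=0.05)
        # Fano holds at the whole-trial scale and in 100 ms windows
        assert total.var(ddof=1) / total.mean() == pytest.approx(target, abs=tol)
        assert fano_factor([counts]) == pytest.approx(target, abs=tol)

    def test_zero_rate_gives_zero_counts(self, rng):
        spec = _spec(tuning_amplitude=0.0, baseline=0.0)
        assert sample_trial_counts(spec, TRIAL, rng).sum() == 0

    def test_tuned_mean_follows_von_mises(self, rng):
        spec = _spec(tuning_amplitude=30.0, baseline=2.0,
                     tuning_concentration=2.0)
        pref = np.mean([sample_trial_counts(spec, TRIAL, rng).sum()
                        for _ in range(300)])
        orth = np.mean([sample_trial_counts(
            spec, Trial(0.0, 2.0, "mono", 0.0), rng).sum()
            for _ in range(300)])
        expected_orth = 2.0 + 30.0 * np.exp(-4.0)
        assert pref == pytest.approx(32.0, rel=0.1)
        assert orth == pytest.approx(expected_orth, rel=0.2)


class TestSpikeRendering:
    def test_unmodulated_f1f0_near_zero(self, rng):
        spec = _spec(baseline=30.0, modulation_ratio_target=0.0)
        trains = [render_spike_times(sample_trial_counts(spec, TRIAL, rng),
                                     spec, TRIAL, rng, latency=0.0)
                  for _ in range(500)]
        assert modulation_ratio(trains, 4.0) < 0.15

    def test_rectified_sine_gives_pi_over_2(self, rng):
        # Fourier components of a half-wave rectified sine: F1/F0 = pi/2
        spec = _spec(baseline=30.0, modulation_ratio_target=np.pi / 2)
        trains = [render_spike_times(sample_trial_counts(spec, TRIAL, rng),
                                     spec, TRIAL, rng, latency=0.0)
                  for _ in range(500)]
        assert modulation_ratio(trains, 4.0) == pytest.approx(np.pi / 2, abs=0.1)

    def test_unit_cosine_modulation(self, rng):
        spec = _spec(baseline=30.0, modulation_ratio_target=1.0)
        trains = [render_spike_times(sample_trial_counts(spec, TRIAL, rng),
                                     spec, TRIAL, rng, latency=0.0)
                  for _ in range(500)]
        assert modulation_ratio(trains, 4.0) == pytest.approx(1.0, abs=0.1)

    def test_zero_count_empty_train(self, rng):
        out = render_spike_times(0, _spec(), TRIAL, rng)
        assert out.size == 0

    def test_times_within_response_window(self, rng):
        spec = _spec(baseline=50.0)
        t = render_spike_times(sample_trial_counts(spec, TRIAL, rng),
                               spec, TRIAL, rng, latency=0.05)
        assert t.min() >= TRIAL.onset + 0.05
        assert t.max() <= TRIAL.onset + 1.05


class TestNoiseCorrelations:
    def test_independent_when_target_zero(self, rng):
        counts = rng.poisson(15, size=(1000, 10))
        out = impose_noise_correlations(counts, 0.0, rng)
        assert np.array_equal(out, counts)

    def test_planted_correlation_calibrated(self, rng):
        counts = rng.poisson(15, size=(1000, 20))
        out = impose_noise_correlations(counts, 0.2, rng)
        c = np.corrcoef(out.T)
        mean_r = c[np.triu_indices(20, 1)].mean()
        assert mean_r == pytest.approx(0.2, abs=0.03)
        # marginals (hence means) preserved exactly
        assert np.array_equal(np.sort(out, axis=0), np.sort(counts, axis=0))

    def test_single_neuron_unchanged(self, rng):
        counts = rng.poisson(10, size=(50, 1))
        assert np.array_equal(impose_noise_correlations(counts, 0.3, rng), counts)

    def test_out_of_range_target_rejected(self, rng):
        with pytest.raises(ValueError):
            impose_noise_correlations(np.zeros((10, 2)), 0.7, rng)

    def test_shuffling_removes_planted_correlation(self, rng):
        counts = rng.poisson(15, size=(1000, 10))
        out = impose_noise_correlations(counts, 0.3, rng)
        for j in range(out.shape[1]):       # independent trial shuffling
            out[:, j] = out[rng.permutation(len(out)), j]
        c = np.corrcoef(out.T)
        assert abs(c[np.triu_indices(10, 1)].mean()) < 0.02


class TestLfp:
    def test_boundary_at_sink_bottom(self):
        cfg = SessionConfig(seed=0)
        from lamdec.csd import estimate_laminar_model
        lfp = synthesize_lfp(cfg, (961.0, 1242.0), np.arange(5) * 1.25)
        model = estimate_laminar_model(lfp, np.arange(5) * 1.25)
        assert abs(model.boundary_46 - 1242.0) <= 80.0

    def test_zero_amplitude_no_sink(self):
        from lamdec.csd import NoSinkError, estimate_laminar_model
        cfg = SessionConfig(seed=0)
        lfp = synthesize_lfp(cfg, (961.0, 1242.0), np.arange(5) * 1.25,
                             amplitude=0.0)
        with pytest.raises(NoSinkError):
            estimate_laminar_model(lfp, np.arange(5) * 1.25)

    def test_same_seed_identical_lfp(self):
        cfg = SessionConfig(seed=9, lfp_noise_sd=1.0)
        a = synthesize_lfp(cfg, (961.0, 1242.0), [0.0, 1.25])
        b = synthesize_lfp(cfg, (961.0, 1242.0), [0.0, 1.25])
        assert np.array_equal(a.data, b.data)


class TestFullSession:
    def test_columnar_preference_tight(self, small_session):
        prefs = np.array([n.preferred_direction % 180.0
                          for n in small_session.neurons])
        z = np.exp(2j * np.deg2rad(prefs))
        circ_sd = np.rad2deg(np.sqrt(-2 * np.log(abs(z.mean())))) / 2
        assert circ_sd < 10.0

    def test_noncolumnar_preference_drifts(self):
        cfg = SessionConfig(n_neurons=30, columnar=False, sf_set=(2.0,),
                            reps_per_direction=5, seed=5)
        s = generate_session(cfg)
        prefs = np.array([n.preferred_direction % 180.0 for n in s.neurons])
        depths = s.depths
        shallow = prefs[depths < 400].mean()
        deep = prefs[depths > 1400].mean()
        assert abs(deep - shallow) >= 60.0   # 120 deg planted over full span

    def test_spikes_within_trial_bounds(self, small_session):
        s = small_session
        onsets = s.trials["onset"].values
        period = s.config.stim_duration + s.config.isi
        for j in range(s.n_neurons):
            for t, st in enumerate(s.spikes[j]):
                if len(st):
                    assert st.min() >= onsets[t]
                    assert st.max() <= onsets[t] + period

    def test_trial_lists_complete(self, small_session):
        s = small_session
        assert all(len(per) == len(s.trials) for per in s.spikes)

    def test_same_seed_reproducible(self):
        cfg = SessionConfig(n_neurons=6, sf_set=(2.0,), reps_per_direction=5,
                            seed=21)
        a, b = generate_session(cfg), generate_session(cfg)
        assert a.trials.equals(b.trials)
        assert all(np.array_equal(x, y)
                   for ja, jb in zip(a.spikes, b.spikes)
                   for x, y in zip(ja, jb))


def test_clipped_cosine_intensity_monotone_in_target():
    """Clip depth solves the requested F1/F0 on (1, pi/2)."""
    t = np.linspace(0, 1, 4001)
    for target in (1.1, 1.3, 1.5):
        prof = temporal_intensity(target, 4.0, t)
        f0 = prof.mean()
        f1 = 2 * abs(np.mean(prof * np.exp(-2j * np.pi * 4.0 * t)))
        assert f1 / f0 == pytest.approx(target, abs=0.02)
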