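"""Sliding FFT, period-amplitude views and bout detection/statistics."""

import numpy as np
import pytest

from embryomotion import (MovementTrace, average_spectrogram, bout_stats,
                          detect_bouts, generate_trace, get_preset, modal_period,
                          period_amplitude, process_trace, sliding_fft)
from embryomotion.spectral import n_windows


def movement(values, fr=4.0, start=14.0):
    return MovementTrace(values=np.asarray(values, dtype=float), frame_rate=fr,
                         record_start=start)


class TestSlidingFFT:
    def test_zero_trace_zero_amplitudes(self):
        sp = sliding_fft(movement(np.zeros(4 * 3600 * 2)), 3600.0, 1800.0)
        assert np.all(sp.amplitudes == 0.0)

    def test_on_bin_sinusoid_amplitude_recovered_exactly(self):
        # amplitude A at period 120 s, on-bin for a 1-hr window
        fs, A, period = 4.0, 2.5, 120.0
        t = np.arange(int(2 * 3600 * fs)) / fs
        x = A * np.sin(2 * np.pi * t / period) + A  # offset keeps values >= 0
        sp = sliding_fft(movement(x, fr=fs), 3600.0, 1800.0)
        k = np.argmin(np.abs(sp.frequencies - 1.0 / period))
        assert sp.frequencies[k] == pytest.approx(1.0 / period, abs=1e-12)
        assert np.all(np.abs(sp.amplitudes[:, k] - A) < 1e-9)
        others = np.delete(sp.amplitudes, k, axis=1)
        assert np.all(others < 1e-9)

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_fft(movement(np.zeros(100)), 3600.0, 1800.0)

    def test_wild_type_argmax_period_within_one_bin_of_bout_period(self):
        preset = get_preset("wild_type")  # bout period 180 s, jitter 0
        trace, _ = generate_trace(preset, seed=21, record_duration=7.5)
        m = process_trace(trace, hatch_time=preset.hatch_time)
        sp = sliding_fft(m)
        bin_width = sp.frequencies[1] - sp.frequencies[0]
        periods = 1.0 / sp.frequencies
        in_band = (periods >= 4.0) & (periods <= 1800.0)
        for i, center in enumerate(sp.window_centers):
            if center < preset.rhythmic_onset:
                continue
            f_peak = sp.frequencies[in_band][np.argmax(sp.amplitudes[i][in_band])]
            assert abs(f_peak - 1.0 / 180.0) <= bin_width + 1e-12

    def test_parseval_per_window_rectangular(self):
        rng = np.random.default_rng(7)
        x = np.abs(rng.normal(size=4 * 3600 * 2))
        sp = sliding_fft(movement(x), 3600.0, 1800.0)
        w = int(3600 * 4)
        for i in range(sp.amplitudes.shape[0]):
            seg = x[i * w // 2: i * w // 2 + w]
            var = np.mean((seg - seg.mean()) ** 2)
            amps = sp.amplitudes[i]
            # one-sided 2|X|/N bins: var = sum(a^2)/2, except Nyquist = a^2/4
            recon = np.sum(amps[:-1] ** 2) / 2 + amps[-1] ** 2 / 4
            assert recon == pytest.approx(var, rel=1e-6)

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(size=4 * 3600 * 2))
        a = sliding_fft(movement(x))
        b = sliding_fft(movement(5.0 * x))
        assert np.allclose(b.amplitudes, 5.0 * a.amplitudes, rtol=1e-12)

    def test_window_count_formula(self):
        for n, w, s in [(14400, 14400, 7200), (100_000, 14400, 7200),
                        (107_999, 14400, 7200), (108_000, 14400, 7200)]:
            # brute-force enumeration of full windows
            brute = len([i for i in range(0, n, s) if i + w <= n])
            assert n_windows(n, w, s) == brute == (n - w) // s + 1
        x = np.zeros(100_000)
        sp = sliding_fft(movement(x), 3600.0, 1800.0)
        assert sp.amplitudes.shape[0] == n_windows(100_000, 14400, 7200)


class TestAverageSpectrogram:
    def test_average_of_identical_is_itself(self):
        x = np.abs(np.random.default_rng(9).normal(size=4 * 3600 * 2))
        sp = sliding_fft(movement(x))
        avg = average_spectrogram([sp, sp, sp])
        assert np.allclose(avg.amplitudes, sp.amplitudes, rtol=1e-15, atol=0)
        assert np.all(avg.n_contributing == 3)

    def test_matches_brute_force_mean_over_cohort(self):
        rng = np.random.default_rng(10)
        sps = [sliding_fft(movement(np.abs(rng.normal(size=4 * 3600 * 2))))
               for _ in range(12)]
        avg = average_spectrogram(sps)
        brute = sum(sp.amplitudes for sp in sps) / 12.0
        assert np.allclose(avg.amplitudes, brute, rtol=0, atol=1e-15)

    def test_incompatible_grids_rejected(self):
        x = np.abs(np.random.default_rng(11).normal(size=4 * 3600 * 2))
        a = sliding_fft(movement(x), 3600.0, 1800.0)
        b = sliding_fft(movement(x), 1800.0, 900.0)
        with pytest.raises(ValueError, match="incompatible"):
            average_spectrogram([a, b])


class TestPeriodAmplitude:
    def test_band_excluding_bout_period_removes_peak(self):
        preset = get_preset("wild_type")
        trace, _ = generate_trace(preset, seed=22, record_duration=7.5)
        m = process_trace(trace, hatch_time=preset.hatch_time)
        sp = sliding_fft(m)
        full = period_amplitude(sp, (18.0, 21.0), band=(4.0, 1800.0))
        assert modal_period(full) == pytest.approx(180.0, abs=1e-9)
        clipped = period_amplitude(sp, (18.0, 21.0), band=(4.0, 150.0))
        assert clipped.periods.max() <= 150.0
        assert clipped.amplitudes.max() < full.amplitudes.max() / 2

    def test_mutant_modal_period_smaller_than_wild_type(self):
        modes = {}
        for name in ("wild_type", "mutant"):
            preset = get_preset(name)
            per_embryo = []
            for seed in range(6):
                trace, _ = generate_trace(preset, seed=100 + seed,
                                          record_duration=7.5)
                m = process_trace(trace, hatch_time=preset.hatch_time)
                pa = period_amplitude(sliding_fft(m), (18.0, 21.0))
                per_embryo.append(modal_period(pa))
            modes[name] = np.mean(per_embryo)
        assert modes["mutant"] < modes["wild_type"]

    def test_empty_band_rejected(self, wt_movement):
        m, _ = wt_movement
        sp = sliding_fft(m)
        with pytest.raises(ValueError):
            period_amplitude(sp, (18.0, 21.0), band=(5.0, 4.0))


class TestBoutDetection:
    def test_zero_trace_no_bouts(self):
        assert detect_bouts(movement(np.zeros(10_000)), bout_threshold=0.1) == []

    def test_square_wave_bouts_exact(self):
        # 60 s on / 120 s off at amplitude 1.0; threshold at half amplitude:
        # the smoothed edge ramp crosses A/2 exactly at the true bout edge
        fs = 4.0
        cycle = np.concatenate([np.ones(int(60 * fs)), np.zeros(int(120 * fs))])
        x = np.tile(cycle, 20)
        bouts = detect_bouts(movement(x, fr=fs, start=18.0), bout_threshold=0.5,
                             smooth_window=10.0, min_duration=5.0, merge_gap=10.0)
        assert len(bouts) == 20
        for k, b in enumerate(bouts):
            assert b.duration == pytest.approx(60.0, abs=1.0 / fs)
            assert (b.start - 18.0) * 3600.0 == pytest.approx(k * 180.0, abs=1.0 / fs)

    def test_merge_rule_two_bouts_with_short_gap(self):
        # two 60-s bouts separated by a 5-s gap, merge_gap 10 -> one 125-s bout
        fs = 4.0
        x = np.concatenate([np.zeros(400), np.ones(240), np.zeros(20),
                            np.ones(240), np.zeros(400)])
        bouts = detect_bouts(movement(x, fr=fs), bout_threshold=0.5,
                             smooth_window=0.25, min_duration=5.0, merge_gap=10.0)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(125.0, abs=0.5)

    def test_min_duration_filter(self):
        fs = 4.0
        x = np.concatenate([np.zeros(200), np.ones(8), np.zeros(200)])
        bouts = detect_bouts(movement(x, fr=fs), bout_threshold=0.5,
                             smooth_window=0.25, min_duration=5.0, merge_gap=1.0)
        assert bouts == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_bouts(movement(np.ones(100)), bout_threshold=0.0)

    def test_subthreshold_noise_between_bouts_is_ignored(self):
        fs = 4.0
        cycle = np.concatenate([np.ones(int(60 * fs)), np.zeros(int(120 * fs))])
        x = np.tile(cycle, 10)
        rng = np.random.default_rng(12)
        noisy = x + (x == 0) * rng.uniform(0, 0.2, size=x.size)
        clean = detect_bouts(movement(x, fr=fs), bout_threshold=0.5)
        noised = detect_bouts(movement(noisy, fr=fs), bout_threshold=0.5)
        assert len(clean) == len(noised) == 10


class TestBoutStats:
    def test_single_bout(self):
        from embryomotion import Bout

        stats = bout_stats([Bout(start=18.0, end=18.0 + 30 / 3600, duration=30.0,
                                 mean_amplitude=1.0)])
        assert stats["count"] == 1 and stats["mean_duration"] == 30.0

    def test_empty(self):
        stats = bout_stats([])
        assert stats["count"] == 0 and stats["undefined"]

    def test_wild_type_bouts_longer_than_mutant(self):
        means = {}
        for name in ("wild_type", "mutant"):
            preset = get_preset(name)
            durations = []
            for seed in range(4):
                trace, _ = generate_trace(preset, seed=200 + seed,
                                          record_duration=7.5)
                m = process_trace(trace, hatch_time=preset.hatch_time)
                keep = m.times() >= preset.rhythmic_onset
                rhythmic = MovementTrace(values=m.values[keep], frame_rate=4.0,
                                         record_start=preset.rhythmic_onset)
                stats = bout_stats(detect_bouts(rhythmic, bout_threshold=0.1))
                durations.append(stats["mean_duration"])
            means[name] = np.mean(durations)
        assert means["wild_type"] > means["mutant"]
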