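"""Sliding-window FFT spectrograms, period-amplitude views, and bout analysis.

The rhythmic (neurogenic) phase of embryonic movement is characterised by
bursts of activity recurring every few minutes.  A sliding FFT (1-hr windows,
30-min steps by default) over the thresholded movement trace exposes the
burst periodicity; re-indexing amplitude by period p = 1/f gives the
period-amplitude distribution; and a simple smooth-threshold-merge detector
recovers individual activity bouts and their durations.

Amplitude convention: per window, the mean is subtracted, the (default
rectangular) taper applied, and the one-sided spectrum normalised as
``2 |X_k| / N`` with the DC bin excluded — an on-bin sinusoid of amplitude A
then reads A at its frequency.  Absolute amplitudes are only comparable
within this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motility import MovementTrace, rolling_baseline

__all__ = [
    "Spectrogram",
    "PeriodAmplitude",
    "Bout",
    "sliding_fft",
    "average_spectrogram",
    "period_amplitude",
    "modal_period",
    "detect_bouts",
    "bout_stats",
    "n_windows",
]

#: default period band (s): Nyquist-safe at 4 Hz up to half the 1-hr FFT window
DEFAULT_BAND = (4.0, 1800.0)


@dataclass
class Spectrogram:
    """Window-time x frequency amplitude matrix (one-sided, DC removed)."""

    window_centers: np.ndarray     # hAEL
    frequencies: np.ndarray        # Hz, strictly increasing, > 0
    amplitudes: np.ndarray         # (n_windows, n_freqs), intensity units
    window_length: float           # s
    step: float                    # s
    taper: str = "rectangular"
    embryo_label: str = "embryo"
    n_contributing: np.ndarray | None = None   # embryos per cell, set by averaging

    def periods(self) -> np.ndarray:
        """Period view p = 1/f, in seconds (descending order of period)."""
        return 1.0 / self.frequencies


@dataclass
class PeriodAmplitude:
    """Per-embryo amplitude as a function of movement period within a band."""

    periods: np.ndarray            # s, restricted to band
    amplitudes: np.ndarray         # same length
    band: tuple[float, float]
    embryo_label: str = "embryo"


@dataclass(frozen=True)
class Bout:
    """One contiguous supra-threshold activity episode."""

    start: float           # hAEL
    end: float             # hAEL
    duration: float        # s
    mean_amplitude: float  # intensity units


def n_windows(n_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of full sliding windows: floor((N - W) / S) + 1 (trailing partial
    window discarded)."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // step_samples + 1


def sliding_fft(trace: MovementTrace, window_length: float = 3600.0,
                step: float = 1800.0, taper: str = "rectangular") -> Spectrogram:
    """Sliding-window one-sided amplitude spectrogram of a movement trace."""
    fs = trace.frame_rate
    w = window_length * fs
    s = step * fs
    if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError("window_length and step must be multiples of the sample period")
    w, s = int(round(w)), int(round(s))
    x = trace.values
    if x.size < w:
        raise ValueError(
            f"trace ({x.size} samples) is shorter than one window ({w} samples); "
            "use a shorter window_length")
    if taper == "rectangular":
        win = None
    elif taper == "hann":
        win = np.hanning(w)
    else:
        raise ValueError(f"unknown taper {taper!r} (rectangular or hann)")
    k = n_windows(x.size, w, s)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)[1:]
    amps = np.empty((k, freqs.size))
    centers = np.empty(k)
    t0 = trace.record_start
    for i in range(k):
        seg = x[i * s: i * s + w]
        seg = seg - seg.mean()
        if win is not None:
            seg = seg * win
        spec = np.abs(np.fft.rfft(seg))[1:] * (2.0 / w)
        amps[i] = spec
        centers[i] = t0 + (i * s + w / 2.0) / fs / 3600.0
    return Spectrogram(window_centers=centers, frequencies=freqs, amplitudes=amps,
                       window_length=window_length, step=step, taper=taper,
                       embryo_label=trace.embryo_label)


def average_spectrogram(spectrograms: list[Spectrogram],
                        center_tol: float = 1e-9) -> Spectrogram:
    """Element-wise mean across embryos on identical frequency/window grids."""
    if not spectrograms:
        raise ValueError("nothing to average")
    ref = spectrograms[0]
    for sp in spectrograms[1:]:
        if sp.frequencies.shape != ref.frequencies.shape or \
                not np.allclose(sp.frequencies, ref.frequencies, rtol=0, atol=1e-12):
            raise ValueError("incompatible frequency grids")
        if sp.window_centers.shape != ref.window_centers.shape or \
                not np.allclose(sp.window_centers, ref.window_centers, rtol=0, atol=center_tol):
            raise ValueError("incompatible window grids")
    stack = np.stack([sp.amplitudes for sp in spectrograms])
    return Spectrogram(
        window_centers=ref.window_centers.copy(),
        frequencies=ref.frequencies.copy(),
        amplitudes=stack.mean(axis=0),
        window_length=ref.window_length,
        step=ref.step,
        taper=ref.taper,
        embryo_label=f"mean_of_{len(spectrograms)}",
        n_contributing=np.full(ref.amplitudes.shape, len(spectrograms), dtype=int),
    )


def period_amplitude(spectrogram: Spectrogram, time_window: tuple[float, float],
                     band: tuple[float, float] = DEFAULT_BAND) -> PeriodAmplitude:
    """Amplitudes averaged over the FFT windows whose centers fall in
    ``time_window`` (hAEL), re-indexed by period and restricted to ``band``."""
    pmin, pmax = band
    if not 0 < pmin < pmax:
        raise ValueError(f"empty or invalid period band {band}")
    sel = (spectrogram.window_centers >= time_window[0]) & \
          (spectrogram.window_centers < time_window[1])
    if not sel.any():
        raise ValueError(f"no FFT windows inside {time_window}")
    periods = 1.0 / spectrogram.frequencies
    in_band = (periods >= pmin) & (periods <= pmax)
    if not in_band.any():
        raise ValueError(f"band {band} contains no frequency bins")
    mean_amp = spectrogram.amplitudes[sel].mean(axis=0)
    order = np.argsort(periods[in_band])
    return PeriodAmplitude(
        periods=periods[in_band][order],
        amplitudes=mean_amp[in_band][order],
        band=(pmin, pmax),
        embryo_label=spectrogram.embryo_label,
    )


def modal_period(pa: PeriodAmplitude) -> float:
    """The period carrying the largest amplitude (the distribution's mode)."""
    return float(pa.periods[int(np.argmax(pa.amplitudes))])


def detect_bouts(trace: MovementTrace, bout_threshold: float,
                 smooth_window: float = 10.0, min_duration: float = 5.0,
                 merge_gap: float = 10.0) -> list[Bout]:
    """Detect activity bouts in a thresholded movement trace.

    Smooth with a centred moving average over ``smooth_window`` seconds, take
    maximal runs above ``bout_threshold``, merge runs separated by gaps
    shorter than ``merge_gap`` seconds, then discard bouts shorter than
    ``min_duration`` seconds.  Deterministic.
    """
    if bout_threshold <= 0:
        raise ValueError("bout_threshold must be positive")
    fs = trace.frame_rate
    w = max(int(round(smooth_window * fs)), 1)
    smooth = rolling_baseline(trace.values, w)
    above = smooth > bout_threshold
    if not above.any():
        return []
    # maximal runs of True
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)   # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s0, e0 in runs[1:]:
        gap = (s0 - merged[-1][1]) / fs
        if gap < merge_gap:
            merged[-1] = (merged[-1][0], e0)
        else:
            merged.append((s0, e0))
    bouts = []
    for s0, e0 in merged:
        duration = (e0 - s0) / fs
        if duration < min_duration:
            continue
        bouts.append(Bout(
            start=trace.record_start + s0 / fs / 3600.0,
            end=trace.record_start + e0 / fs / 3600.0,
            duration=duration,
            mean_amplitude=float(trace.values[s0:e0].mean()),
        ))
    return bouts


def bout_stats(bouts: list[Bout]) -> dict:
    """Count, mean/median duration (s) and mean inter-bout interval (s).

    An empty list gives count 0 with NaN summaries (flagged ``undefined``).
    """
    if not bouts:
        return {"count": 0, "mean_duration": float("nan"),
                "median_duration": float("nan"), "mean_interval": float("nan"),
                "undefined": True}
    durations = np.array([b.duration for b in bouts])
    starts = np.array([b.start for b in bouts])
    intervals = np.diff(np.sort(starts)) * 3600.0
    return {
        "count": len(bouts),
        "mean_duration": float(durations.mean()),
        "median_duration": float(np.median(durations)),
        "mean_interval": float(intervals.mean()) if intervals.size else float("nan"),
        "undefined": False,
    }
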