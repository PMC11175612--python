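"""Synthetic embryo recordings with ground truth.

Generates per-embryo raw MGV traces carrying the statistical structure the
analysis pipeline assumes, so every downstream stage is testable without
recorded data:

* a slow developmental baseline — linear drift, a smooth sigmoidal step at
  tracheal gas-filling, and a discontinuity at hatching;
* a disorganised low-rate "myogenic" phase — Poisson-timed transient events
  with gamma-distributed amplitudes, each one full zero-mean oscillation
  cycle so the 15-s rolling baseline of the analysis is not perturbed;
* a rhythmic "neurogenic" phase — periodic rectangular-envelope bouts
  carrying a zero-mean sinusoidal oscillation (~1-s individual movements; the
  default carrier frequency sits on a spectral null of the analysis pipeline's
  15-s rolling-baseline filter, so the baseline tracks development, not
  movement — the situation the 15-s window is designed for);
* additive Gaussian sensor noise.

Everything is deterministic given (preset, seed).  The generator also renders
tiny frame stacks (for end-to-end I/O tests) and matched two-channel calcium
traces sharing a multiplicative motion artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .acquisition import ImageStack, RawTrace, Rectangle
from .calcium import DualChannelTrace
from .presets import CohortSpec, GenotypePreset

__all__ = [
    "GroundTruth",
    "generate_trace",
    "generate_cohort",
    "render_frame_stack",
    "generate_calcium_pair",
]


@dataclass
class GroundTruth:
    """What the generator injected — the oracle for downstream recovery tests."""

    bout_intervals: list[tuple[float, float]] = field(default_factory=list)  # hAEL
    event_times: list[float] = field(default_factory=list)                   # hAEL
    phase_boundaries: tuple[float, float, float] = (16.0, 18.0, 21.0)
    injected_total_activity: float = 0.0      # sum of |movement| over samples
    injected_myogenic_activity: float = 0.0
    injected_neurogenic_activity: float = 0.0
    calcium_event_times: list[float] | None = None


def _derive_seed(root: int, index: int) -> int:
    """Stable per-embryo seed below 2**31."""
    return int(np.random.SeedSequence([int(root), int(index)]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_trace(
    preset: GenotypePreset,
    frame_rate: float = 4.0,
    record_start: float = 14.0,
    record_duration: float = 7.5,
    seed: int = 0,
) -> tuple[RawTrace, GroundTruth]:
    """Generate one raw MGV trace plus its ground truth.

    The movement signal is identically zero outside
    ``[movement_onset, hatch_time)``; the bout oscillation is zero before
    ``rhythmic_onset``.  ``injected_total_activity`` accumulates the rectified
    movement signal component by component (events never overlap bouts, and
    overlapping Poisson events are thinned), so it equals
    ``sum(abs(movement))`` over the rendered samples.
    """
    rng = np.random.default_rng(seed)
    n = int(round(record_duration * 3600.0 * frame_rate))
    if n < 1:
        raise ValueError("record window contains no samples")
    t_sec = np.arange(n) / frame_rate              # seconds since record start
    t_h = record_start + t_sec / 3600.0            # hAEL
    record_end = record_start + record_duration

    if record_end <= preset.movement_onset or record_start >= preset.hatch_time:
        warnings.warn(
            f"record window [{record_start}, {record_end}] hAEL does not overlap the "
            f"movement period [{preset.movement_onset}, {preset.hatch_time}]; "
            "trace is drift + noise only", stacklevel=2)

    # --- baseline drift with developmental events
    baseline = preset.drift_slope * (t_h - record_start)
    if preset.gasfill_step != 0.0:
        gf_sec = (preset.gasfill_time - record_start) * 3600.0
        baseline = baseline + preset.gasfill_step * expit((t_sec - gf_sec) / preset.gasfill_rise)
    if preset.hatch_step != 0.0:
        baseline = baseline + preset.hatch_step * (t_h >= preset.hatch_time)

    movement = np.zeros(n)
    truth = GroundTruth(phase_boundaries=(
        preset.movement_onset, preset.rhythmic_onset, preset.hatch_time))

    # --- myogenic phase: Poisson-timed zero-mean transient events
    myo_start = max(preset.movement_onset, record_start)
    myo_end = min(preset.rhythmic_onset, record_end)
    ev_dur = preset.myogenic_event_duration
    if preset.myogenic_event_rate > 0 and myo_end > myo_start:
        span_min = (myo_end - myo_start) * 60.0
        n_events = rng.poisson(preset.myogenic_event_rate * span_min)
        starts_sec = np.sort(rng.uniform(
            (myo_start - record_start) * 3600.0,
            (myo_end - record_start) * 3600.0 - ev_dur,
            size=n_events,
        ))
        mean_amp, cv = preset.myogenic_event_amplitude
        if cv > 0:
            shape = 1.0 / cv**2
            amps = rng.gamma(shape, mean_amp / shape, size=n_events)
        else:
            amps = np.full(n_events, mean_amp)
        last_end = -np.inf
        for s0, amp in zip(starts_sec, amps):
            if s0 < last_end:       # thin overlapping events to keep components disjoint
                continue
            last_end = s0 + ev_dur
            i0 = int(np.ceil(s0 * frame_rate))
            i1 = min(int(np.ceil((s0 + ev_dur) * frame_rate)), n)
            if i1 <= i0:
                continue
            phase = 2.0 * np.pi * (t_sec[i0:i1] - s0) / ev_dur
            component = amp * np.sin(phase)
            movement[i0:i1] += component
            truth.injected_myogenic_activity += float(np.abs(component).sum())
            truth.event_times.append(record_start + s0 / 3600.0)

    # --- neurogenic phase: periodic bouts with within-bout oscillation
    rhythm_start_sec = (preset.rhythmic_onset - record_start) * 3600.0
    hatch_sec = (preset.hatch_time - record_start) * 3600.0
    if preset.bout_amplitude > 0 and preset.bout_duration > 0:
        j = 0
        while True:
            s0 = rhythm_start_sec + j * preset.bout_period
            if preset.bout_jitter > 0:
                s0 += rng.normal(0.0, preset.bout_jitter)
                s0 = max(s0, rhythm_start_sec)
            j += 1
            if s0 + preset.bout_duration > hatch_sec:
                break
            s1 = s0 + preset.bout_duration
            i0 = max(int(np.ceil(s0 * frame_rate)), 0)
            i1 = min(int(np.ceil(s1 * frame_rate)), n)
            if i1 <= i0:
                if s0 > t_sec[-1]:
                    break
                continue
            osc = np.sin(2.0 * np.pi * preset.within_bout_freq * (t_sec[i0:i1] - s0))
            component = preset.bout_amplitude * osc
            movement[i0:i1] += component
            truth.injected_neurogenic_activity += float(np.abs(component).sum())
            truth.bout_intervals.append(
                (record_start + s0 / 3600.0, record_start + s1 / 3600.0))

    truth.injected_total_activity = (
        truth.injected_myogenic_activity + truth.injected_neurogenic_activity)

    noise = rng.normal(0.0, preset.noise_sd, size=n) if preset.noise_sd > 0 else 0.0
    trace = RawTrace(
        values=baseline + movement + noise,
        frame_rate=frame_rate,
        record_start=record_start,
        embryo_label=preset.name,
    )
    return trace, truth


def generate_cohort(spec: CohortSpec) -> list[tuple[RawTrace, GroundTruth]]:
    """One trace per embryo; per-embryo seeds derived from ``spec.seed``.

    Bit-for-bit reproducible: the i-th embryo's seed depends only on
    (spec.seed, i), so identical specs give identical cohorts.
    """
    out = []
    index = 0
    for preset, n_embryos in spec.presets:
        for k in range(n_embryos):
            trace, truth = generate_trace(
                preset,
                frame_rate=spec.frame_rate,
                record_start=spec.record_start,
                record_duration=spec.record_duration,
                seed=_derive_seed(spec.seed, index),
            )
            trace.embryo_label = f"{preset.name}_{k + 1:02d}"
            out.append((trace, truth))
            index += 1
    return out


def render_frame_stack(
    trace: RawTrace,
    roi: Rectangle,
    frame_size: tuple[int, int] = (36, 48),
    background: float = 20.0,
    seed: int = 0,
) -> ImageStack:
    """Render a trace as a small uint8 grayscale stack.

    Every pixel inside ``roi`` carries the trace value (so the ROI mean equals
    the trace within uint8 quantisation, <= 0.5 intensity units); pixels
    outside are constant background.  Values outside [0, 255] trigger a linear
    rescale into [5, 250], reported as a warning.
    """
    if not roi.inside(frame_size):
        raise ValueError(f"ROI {roi} extends outside frame {frame_size}")
    values = np.asarray(trace.values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if lo < 0.0 or hi > 255.0:
        span = hi - lo if hi > lo else 1.0
        scale = 245.0 / span
        offset = 5.0 - lo * scale
        warnings.warn(
            f"trace range [{lo:.3g}, {hi:.3g}] outside uint8; rescaled with "
            f"value*{scale:.6g} + {offset:.6g}", stacklevel=2)
        values = values * scale + offset
    frames = np.full((values.size, *frame_size), np.uint8(round(background)), dtype=np.uint8)
    quantised = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    frames[:, roi.row_start:roi.row_stop, roi.col_start:roi.col_stop] = (
        quantised[:, None, None])
    return ImageStack(frames=frames, frame_rate=trace.frame_rate,
                      record_start=trace.record_start)


def generate_calcium_pair(
    event_times: list[float],
    event_amplitude: float,
    motion_artifact: np.ndarray,
    cadence: float = 1.5,
    seed: int = 0,
    baseline_signal: float = 100.0,
    baseline_reporter: float = 100.0,
    decay_tau: float = 6.0,
    noise_sd: float = 0.0,
    record_start: float = 18.0,
) -> tuple[DualChannelTrace, GroundTruth]:
    """Matched GCaMP-like signal and tdTomato-like reporter traces.

    Both channels share the strictly positive multiplicative ``motion_artifact``
    (so the ratio cancels it); the signal channel additionally carries one
    fast-rise / exponential-decay transient (time constant ``decay_tau``
    seconds) per entry of ``event_times`` (seconds since record start).
    """
    artifact = np.asarray(motion_artifact, dtype=float)
    if artifact.ndim != 1 or artifact.size < 1:
        raise ValueError("motion_artifact must be a non-empty 1-D series")
    if np.any(artifact <= 0):
        raise ValueError("motion_artifact must be strictly positive (it divides downstream)")
    if not cadence > 0:
        raise ValueError("cadence must be positive")
    n = artifact.size
    t = np.arange(n) * cadence
    rng = np.random.default_rng(seed)
    kernels = np.zeros(n)
    for t0 in event_times:
        mask = t >= t0
        kernels[mask] += event_amplitude * np.exp(-(t[mask] - t0) / decay_tau)
    signal = baseline_signal * artifact * (1.0 + kernels)
    reporter = baseline_reporter * artifact
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
        reporter = reporter + rng.normal(0.0, noise_sd, size=n)
    pair = DualChannelTrace(signal=signal, reporter=reporter, cadence=cadence,
                            record_start=record_start)
    truth = GroundTruth(calcium_event_times=list(event_times))
    return pair, truth
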