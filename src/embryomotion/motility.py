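"""Raw MGV trace -> movement trace -> phase-wise quantification.

The pipeline mirrors the standard embryo-motility workflow: subtract a 60-frame
(15-s at 4 Hz) centred rolling average from the raw mean-grey-value trace, take
absolute deviations, zero everything below the 0.01 noise threshold, crop at
larval hatching, and sum the surviving deviations per developmental phase
(myogenic ~16-18 hAEL, neurogenic ~18 hAEL to hatching).

All times are hAEL.  Windows on the time axis are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .acquisition import RawTrace

__all__ = [
    "MovementTrace",
    "PhaseWindows",
    "PipelineConfig",
    "rolling_baseline",
    "apply_threshold",
    "detrend_rectify",
    "crop_at_hatch",
    "suggest_hatch",
    "segment_phases",
    "quantify_phase",
    "process_trace",
]


@dataclass
class MovementTrace:
    """Detrended, rectified, noise-thresholded activity series.

    ``values`` are non-negative MGV deviations; anything that fell strictly
    below ``threshold_applied`` is exactly 0.
    """

    values: np.ndarray
    frame_rate: float
    record_start: float  # hAEL
    embryo_label: str = "embryo"
    hatch_time: float | None = None
    threshold_applied: float = 0.0
    baseline_window: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("movement values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("movement values must be non-negative")

    def times(self) -> np.ndarray:
        return self.record_start + np.arange(self.values.size) / self.frame_rate / 3600.0

    @property
    def record_end(self) -> float:
        return self.record_start + self.values.size / self.frame_rate / 3600.0


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open phase intervals in hAEL; myogenic.end coincides with neurogenic.start."""

    myogenic: tuple[float, float]
    neurogenic: tuple[float, float]
    source: str = "fixed-times"   # or "annotated"
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.myogenic[1] != self.neurogenic[0]:
            raise ValueError("myogenic end must equal neurogenic start")
        if self.myogenic[0] >= self.myogenic[1] or self.neurogenic[0] >= self.neurogenic[1]:
            raise ValueError("phase windows must have positive length")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the movement pipeline (defaults follow the standard protocol)."""

    baseline_window: int = 60          # samples (15 s at 4 Hz)
    noise_threshold: float = 0.01      # intensity units
    myogenic_start: float = 16.0       # hAEL
    neurogenic_start: float = 18.0     # hAEL
    shrink_edges: bool = True          # False: trim half-window margins instead

    def __post_init__(self) -> None:
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")
        if self.noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")


def rolling_baseline(trace: RawTrace | np.ndarray, window: int) -> np.ndarray:
    """Centred moving average: ``window // 2`` samples on each side, shrinking
    symmetrically toward the trace edges.  Same length as the input."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = trace.values if isinstance(trace, RawTrace) else np.asarray(trace, dtype=float)
    n = x.size
    half = window // 2
    out = np.empty(n)
    if n >= 2 * half + 1:
        # interior: vectorised mean over the full symmetric window; identical
        # reduction order to np.mean of each slice
        if half > 0:
            windows = np.lib.stride_tricks.sliding_window_view(x, 2 * half + 1)
            out[half:n - half] = windows.mean(axis=1)
        else:
            out[:] = x
    for i in range(min(half, n)):
        out[i] = x[max(0, i - half): i + half + 1].mean()
    for i in range(max(n - half, 0), n):
        out[i] = x[max(0, i - half): i + half + 1].mean()
    if n < 2 * half + 1:
        for i in range(n):
            out[i] = x[max(0, i - half): i + half + 1].mean()
    return out


def apply_threshold(deviations: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out rectified deviations strictly below the noise threshold."""
    dev = np.asarray(deviations, dtype=float).copy()
    dev[dev < threshold] = 0.0
    return dev


def detrend_rectify(trace: RawTrace, config: PipelineConfig = PipelineConfig()) -> MovementTrace:
    """|raw - rolling baseline|, then per-sample noise thresholding.

    Deviations strictly below ``config.noise_threshold`` are set to exactly 0.
    """
    baseline = rolling_baseline(trace, config.baseline_window)
    dev = apply_threshold(np.abs(trace.values - baseline), config.noise_threshold)
    if not config.shrink_edges:
        half = config.baseline_window // 2
        dev[:half] = 0.0
        if half:
            dev[-half:] = 0.0
    return MovementTrace(
        values=dev,
        frame_rate=trace.frame_rate,
        record_start=trace.record_start,
        embryo_label=trace.embryo_label,
        threshold_applied=config.noise_threshold,
        baseline_window=config.baseline_window,
    )


def crop_at_hatch(trace: MovementTrace, hatch_time: float) -> MovementTrace:
    """Drop all samples at or after ``hatch_time`` (hAEL)."""
    if hatch_time < trace.record_start:
        raise ValueError(
            f"hatch_time {hatch_time} precedes record start {trace.record_start}")
    if hatch_time > trace.record_end:
        warnings.warn(
            f"hatch_time {hatch_time} hAEL is after the record end "
            f"{trace.record_end:.4f}; trace unchanged", stacklevel=2)
        return replace(trace, hatch_time=hatch_time)
    keep = trace.times() < hatch_time
    if not keep.any():
        raise ValueError("cropping at hatch would remove every sample")
    return replace(trace, values=trace.values[keep], hatch_time=hatch_time)


def suggest_hatch(trace: RawTrace, step_window: float = 30.0,
                  min_snr: float = 5.0) -> tuple[float | None, float]:
    """Advisory hatch-time candidate: the largest sustained raw-MGV step in the
    final third of the recording.

    Returns ``(candidate_hAEL or None, confidence)`` where confidence is the
    step size in units of the trace's robust sample-to-sample noise.  Ties go
    to the earlier candidate.  Never applied automatically.
    """
    x = trace.values
    n = x.size
    w = max(int(round(step_window * trace.frame_rate)), 1)
    if n < 3 * w:
        return None, 0.0
    # mean(after) - mean(before) at every split point in the final third
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(w, n - w)
    step = (csum[idx + w] - csum[idx]) / w - (csum[idx] - csum[idx - w]) / w
    start = max(2 * n // 3, w)
    sel = idx >= start
    if not sel.any():
        return None, 0.0
    diffs = np.diff(x)
    noise = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) + 1e-30
    mags = np.abs(step[sel])
    best = int(np.argmax(mags))      # argmax returns the first (earliest) maximum
    confidence = float(mags[best] / noise)
    if confidence < min_snr:
        return None, confidence
    i = int(idx[sel][best])
    return float(trace.record_start + i / trace.frame_rate / 3600.0), confidence


def segment_phases(trace: MovementTrace, config: PipelineConfig = PipelineConfig(),
                   boundary_override: float | None = None) -> PhaseWindows:
    """Fixed-time phase windows (myogenic [16, 18), neurogenic [18, hatch))
    clipped to the record window; an annotated boundary overrides the default."""
    myo_start = config.myogenic_start
    boundary = boundary_override if boundary_override is not None else config.neurogenic_start
    end = trace.hatch_time if trace.hatch_time is not None else trace.record_end
    end = min(end, trace.record_end)
    clipped = False
    if trace.record_start > myo_start:
        myo_start = trace.record_start
        clipped = True
    if end > trace.record_end:
        end = trace.record_end
        clipped = True
    if myo_start >= boundary or boundary >= end:
        if myo_start < end <= boundary or boundary <= myo_start < end:
            raise ValueError(
                "record window overlaps only one phase; quantify it directly "
                "with quantify_phase")
        raise ValueError(
            f"record window [{trace.record_start}, {trace.record_end:.3f}] is "
            "disjoint from both phases")
    return PhaseWindows(
        myogenic=(myo_start, boundary),
        neurogenic=(boundary, end),
        source="annotated" if boundary_override is not None else "fixed-times",
        clipped=clipped,
    )


def quantify_phase(trace: MovementTrace, window: tuple[float, float]) -> float:
    """Sum of thresholded rectified deviations over the half-open hAEL window."""
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    t = trace.times()
    mask = (t >= start) & (t < end)
    if not mask.any():
        raise ValueError(f"window [{start}, {end}) contains no samples")
    return float(np.sum(trace.values[mask]))


def process_trace(trace: RawTrace, hatch_time: float | None = None,
                  config: PipelineConfig = PipelineConfig()) -> MovementTrace:
    """Convenience: detrend + rectify + threshold, then crop at hatching."""
    movement = detrend_rectify(trace, config)
    if hatch_time is not None:
        movement = crop_at_hatch(movement, hatch_time)
    return movement
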