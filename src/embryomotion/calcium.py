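"""Ratiometric calcium activity with passive-reporter motion correction.

An embryo expressing a calcium sensor (GCaMP6s) and a calcium-insensitive
reporter (tdTomato) is imaged in alternating channels (one cycle per 1.5 s).
Movement changes both channels by the same multiplicative factor, so the
per-cycle ratio signal/reporter cancels the motion artifact.  Activity is then
the ratio minus its baseline, taken as the minimum of the ratio in a 10-min
window centred on each cycle (shrinking at the trace ends), and summed over
the recording.

Negative excursions (possible from channel-specific noise) are retained, not
clipped.  A conventional division-normalised variant
(ratio - baseline) / baseline is available via ``normalise=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DualChannelTrace", "DFFTrace", "ratio_trace", "dff", "sum_dff",
           "count_transients"]


@dataclass
class DualChannelTrace:
    """Frame-aligned signal (GCaMP) and reporter (tdTomato) intensities."""

    signal: np.ndarray
    reporter: np.ndarray
    cadence: float = 1.5        # seconds per image cycle
    record_start: float = 18.0  # hAEL

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)
        if self.signal.shape != self.reporter.shape or self.signal.ndim != 1:
            raise ValueError("signal and reporter must be 1-D and the same length")
        if not self.cadence > 0:
            raise ValueError("cadence must be positive")

    def times(self) -> np.ndarray:
        return self.record_start + np.arange(self.signal.size) * self.cadence / 3600.0


@dataclass
class DFFTrace:
    """Baseline-subtracted ratiometric activity (dimensionless)."""

    values: np.ndarray
    cadence: float
    record_start: float
    baseline_window: float = 600.0   # s

    def times(self) -> np.ndarray:
        return self.record_start + np.arange(self.values.size) * self.cadence / 3600.0


def ratio_trace(d: DualChannelTrace) -> np.ndarray:
    """Element-wise signal / reporter; rejects non-positive reporter samples."""
    bad = np.nonzero(d.reporter <= 0)[0]
    if bad.size:
        raise ValueError(
            f"reporter must be strictly positive; offending indices: {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else ""))
    return d.signal / d.reporter


def dff(d: DualChannelTrace, baseline_window: float = 600.0,
        normalise: bool = False) -> DFFTrace:
    """Ratio minus its sliding-minimum baseline.

    The baseline at cycle i is the minimum of the ratio over a window of
    ``baseline_window`` seconds centred on i (window shrinks at the edges).
    With ``normalise=True`` the difference is additionally divided by the
    baseline (conventional dF/F); the subtractive form is the default.
    """
    if baseline_window <= 0:
        raise ValueError("baseline_window must be positive")
    ratio = ratio_trace(d)
    half = int(round(baseline_window / d.cadence)) // 2
    window = 2 * half + 1
    if window > ratio.size:
        import warnings

        warnings.warn("trace shorter than the baseline window; window shrinks "
                      "to the full trace", stacklevel=2)
    baseline = (pd.Series(ratio)
                .rolling(window, center=True, min_periods=1)
                .min()
                .to_numpy())
    values = ratio - baseline
    if normalise:
        values = values / baseline
    return DFFTrace(values=values, cadence=d.cadence, record_start=d.record_start,
                    baseline_window=baseline_window)


def sum_dff(trace: DFFTrace, window: tuple[float, float] | None = None) -> float:
    """Sum of dF/F over a half-open hAEL window (whole trace when omitted).

    Negative excursions count as-is.
    """
    if window is None:
        return float(np.sum(trace.values))
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    t = trace.times()
    mask = (t >= start) & (t < end)
    if not mask.any():
        raise ValueError(f"window [{start}, {end}) contains no samples")
    return float(np.sum(trace.values[mask]))


def count_transients(trace: DFFTrace, threshold: float) -> int:
    """Number of maximal runs of dF/F above ``threshold`` (threshold-crossing
    transient count; used as the recovery oracle on synthetic recordings)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = trace.values > threshold
    if not above.any():
        return 0
    return int(np.count_nonzero(np.diff(above.astype(np.int8)) == 1) + above[0])
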