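"""Frame-stack and trace I/O: the digital equivalent of the ImageJ multi-measure step.

Recordings are grayscale frame stacks (multi-page TIFF, or AVI/MJPEG when an
imageio video plugin is available).  A rectangular region of interest (ROI) is
placed over each embryo and the mean grey value (MGV) inside the rectangle is
measured for every frame, yielding one raw intensity trace per embryo.

Conventions
-----------
* Pixel coordinates are 0-based, half-open ``[start, stop)`` in (row, column)
  order.  ImageJ's conventions are converted at the parser boundary.
* Time is carried in hours after egg laying (hAEL); frame index <-> hAEL
  conversion happens only at I/O (``record_start + frame / frame_rate / 3600``).
* Colour video is converted to grayscale with BT.601 luma weights
  (0.299 R + 0.587 G + 0.114 B).
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "Rectangle",
    "ROISet",
    "RawTrace",
    "load_stack",
    "load_roiset",
    "extract_mgv",
    "read_traces",
    "write_traces",
]

_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Rectangle:
    """Half-open pixel rectangle: rows ``[row_start, row_stop)``, cols ``[col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(f"empty rectangle: {self}")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError(f"negative pixel bounds: {self}")

    @property
    def area(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row_stop <= shape[0] and self.col_stop <= shape[1]


@dataclass
class ImageStack:
    """A grayscale recording: ``frames`` is (n_frames, n_rows, n_cols)."""

    frames: np.ndarray
    frame_rate: float
    record_start: float  # hAEL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (frame, row, col) array")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass
class ROISet:
    """Labelled rectangles, one per embryo.  Labels must be unique."""

    rois: list[tuple[str, Rectangle]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.rois]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dup}")
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        for i, (la, a) in enumerate(self.rois):
            for lb, b in self.rois[i + 1 :]:
                if (a.row_start < b.row_stop and b.row_start < a.row_stop
                        and a.col_start < b.col_stop and b.col_start < a.col_stop):
                    warnings.warn(f"ROIs {la!r} and {lb!r} overlap", stacklevel=3)
                    return

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class RawTrace:
    """Per-embryo mean grey value (MGV) time series anchored in hAEL."""

    values: np.ndarray
    frame_rate: float
    record_start: float  # hAEL
    embryo_label: str = "embryo"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def times(self) -> np.ndarray:
        """Sample times in hAEL."""
        return self.record_start + np.arange(self.values.size) / self.frame_rate / 3600.0

    def exclude(self, reason: str) -> "RawTrace":
        return replace(self, excluded=True, exclusion_reason=reason)


# ---------------------------------------------------------------------------
# stacks


def load_stack(path: str | Path, frame_rate: float, record_start: float) -> ImageStack:
    """Load a TIFF stack (lossless) or an AVI (requires an imageio video plugin).

    Colour frames are collapsed to grayscale with BT.601 luma weights.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
    elif suffix == ".avi":
        frames = _read_avi(path)
    else:
        raise ValueError(f"unsupported stack format: {path.name} (expected .tif/.tiff/.avi)")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # colour -> luma
        frames = frames[..., :3].astype(float) @ _BT601
    return ImageStack(frames=frames, frame_rate=frame_rate, record_start=record_start)


def _read_avi(path: Path) -> np.ndarray:
    try:
        import imageio.v3 as iio

        return iio.imread(path, index=None)
    except Exception as exc:  # pragma: no cover - depends on installed codecs
        raise RuntimeError(
            f"could not decode {path.name}: AVI support needs an imageio video "
            "plugin (ffmpeg or pyav); install one or convert the recording to a "
            "multi-page TIFF"
        ) from exc


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (lossless round-trip)."""
    tifffile.imwrite(Path(path), stack.frames)


# ---------------------------------------------------------------------------
# ROIs

_IJ_MAGIC = b"Iout"
_IJ_RECT = 1


def _parse_imagej_roi(blob: bytes, label: str) -> Rectangle:
    # ImageJ .roi layout: magic "Iout" (0), version (4, int16), type (6, int8),
    # top/left/bottom/right (8/10/12/14, int16, 1-px grid so bottom/right are
    # already exclusive).  Big-endian throughout.
    if blob[:4] != _IJ_MAGIC:
        raise ValueError(f"{label}: not an ImageJ ROI (bad magic)")
    roi_type = blob[6]
    if roi_type != _IJ_RECT:
        raise ValueError(f"{label}: only rectangular ROIs are supported (type={roi_type})")
    top, left, bottom, right = struct.unpack(">4h", blob[8:16])
    return Rectangle(row_start=top, row_stop=bottom, col_start=left, col_stop=right)


def load_roiset(path: str | Path, frame_shape: tuple[int, int] | None = None) -> ROISet:
    """Read an ImageJ ROI archive (.roi or RoiSet .zip) or the JSON rectangle dialect.

    JSON dialect::

        {"rois": [{"label": "e01", "row_start": 0, "row_stop": 10,
                   "col_start": 0, "col_stop": 10}, ...]}

    If ``frame_shape`` is given, rectangles extending outside it are an error.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        spec = json.loads(path.read_text())
        rois = [
            (str(r["label"]),
             Rectangle(int(r["row_start"]), int(r["row_stop"]),
                       int(r["col_start"]), int(r["col_stop"])))
            for r in spec["rois"]
        ]
    elif suffix == ".roi":
        rois = [(path.stem, _parse_imagej_roi(path.read_bytes(), path.stem))]
    elif suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if not name.lower().endswith(".roi"):
                    continue
                label = Path(name).stem
                rois.append((label, _parse_imagej_roi(zf.read(name), label)))
    else:
        raise ValueError(f"unsupported ROI format: {path.name}")
    roiset = ROISet(rois=rois)
    if frame_shape is not None:
        for label, rect in roiset.rois:
            if not rect.inside(frame_shape):
                raise ValueError(f"ROI {label!r} extends outside frame {frame_shape}: {rect}")
    return roiset


def extract_mgv(stack: ImageStack, rois: ROISet) -> list[RawTrace]:
    """Mean grey value per ROI per frame — one :class:`RawTrace` per ROI."""
    shape = stack.frame_shape
    for label, rect in rois.rois:
        if not rect.inside(shape):
            raise ValueError(f"ROI {label!r} extends outside frame {shape}: {rect}")
    traces = []
    for label, rect in rois.rois:
        sub = stack.frames[:, rect.row_start:rect.row_stop, rect.col_start:rect.col_stop]
        n = stack.n_frames
        vals = np.empty(n, dtype=float)
        for f in range(n):
            # flatten to a contiguous 1-D copy so the reduction order is the
            # canonical row-major pixel order regardless of view strides
            vals[f] = np.ascontiguousarray(sub[f], dtype=float).ravel().mean()
        traces.append(RawTrace(values=vals, frame_rate=stack.frame_rate,
                               record_start=stack.record_start, embryo_label=label))
    return traces


# ---------------------------------------------------------------------------
# trace tables

_HEADER_MAGIC = "# embryomotion traces v1"


def write_traces(traces: list[RawTrace], path: str | Path) -> None:
    """Write a cohort of frame-aligned traces as a TSV with a ``#`` header block.

    Columns: ``time_hAEL`` then one column per embryo label.  Values round-trip
    at full float64 precision.  Exclusion flags are persisted in the header.
    """
    if not traces:
        raise ValueError("no traces to write")
    fr = traces[0].frame_rate
    start = traces[0].record_start
    n = traces[0].values.size
    for t in traces:
        if t.frame_rate != fr or t.record_start != start or t.values.size != n:
            raise ValueError("traces must share frame_rate, record_start and length")
    excluded = ";".join(f"{t.embryo_label}={t.exclusion_reason or 'excluded'}"
                        for t in traces if t.excluded)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_HEADER_MAGIC + "\n")
        fh.write(f"# frame_rate_hz: {fr!r}\n")
        fh.write(f"# record_start_hael: {start!r}\n")
        fh.write(f"# time_unit: hAEL\n")
        if excluded:
            fh.write(f"# excluded: {excluded}\n")
        fh.write("time_hAEL\t" + "\t".join(t.embryo_label for t in traces) + "\n")
        times = traces[0].times()
        cols = [t.values for t in traces]
        for i in range(n):
            fh.write("\t".join([repr(float(times[i]))]
                               + [repr(float(c[i])) for c in cols]) + "\n")


def read_traces(path: str | Path) -> list[RawTrace]:
    """Read a trace table written by :func:`write_traces` (or any TSV with a
    time column in hAEL or frames plus metadata in the header block)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    table = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if table.shape[1] < 2:
        raise ValueError("trace table needs a time column and at least one embryo column")
    time_col = table.columns[0]
    if table.isna().any().any():
        rows, cols = np.nonzero(table.isna().to_numpy())
        raise ValueError(
            f"missing cell at data row {rows[0]}, column {table.columns[cols[0]]!r}")
    frame_rate = float(meta.get("frame_rate_hz", "nan"))
    record_start_meta = meta.get("record_start_hael")
    time = table[time_col].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time column is not strictly increasing")
    unit = meta.get("time_unit", "hAEL").lower()
    if unit in {"hael", "hours"}:
        record_start = float(record_start_meta) if record_start_meta is not None else float(time[0])
    elif unit in {"frames", "frame"}:
        if not np.isfinite(frame_rate) or record_start_meta is None:
            raise ValueError("frame-indexed tables need frame_rate_hz and record_start_hael metadata")
        record_start = float(record_start_meta)
        time = record_start + time / frame_rate / 3600.0
    else:
        raise ValueError(f"unknown time_unit {unit!r}")
    if not np.isfinite(frame_rate):
        # infer from the median time step
        frame_rate = 1.0 / (float(np.median(np.diff(time))) * 3600.0)
    excluded = {}
    for item in meta.get("excluded", "").split(";"):
        if "=" in item:
            lab, _, reason = item.partition("=")
            excluded[lab.strip()] = reason.strip()
    traces = []
    for col in table.columns[1:]:
        traces.append(RawTrace(
            values=table[col].to_numpy(dtype=float),
            frame_rate=frame_rate,
            record_start=record_start,
            embryo_label=str(col),
            excluded=str(col) in excluded,
            exclusion_reason=excluded.get(str(col), ""),
        ))
    return traces
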