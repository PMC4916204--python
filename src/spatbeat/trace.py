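"""Contraction-trace extraction from video frames.

A trans-illuminated spat heart changes pixel colour with each contraction.
The analog edge detector the method emulates compared pixel colour at an
*active* point over the heart with a *reference* point outside the animal;
the difference channel is the contraction waveform.  Here both "points" are
small discs (the robust digital analog of a point riding on an analog video
line), colour is projected to a scalar with configurable channel weights
(rec.601 luma by default), and the trace is ``mean(active) - mean(reference)``
sampled once per frame.

Coordinates are 0-based, row-major pixels; time is in seconds from the first
frame.  Traces round-trip through a two-column CSV (``time_s,value``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, ParameterError

REC601_WEIGHTS = (0.299, 0.587, 0.114)

__all__ = [
    "FrameSequence",
    "ROISpec",
    "ContractionTrace",
    "extract_trace",
    "load_trace",
    "save_trace",
    "read_frames",
    "write_frames",
]


@dataclass
class FrameSequence:
    """An ordered stack of equally shaped frames with a fixed frame rate.

    ``frames`` is an array of shape ``(n, H, W)`` (grayscale) or
    ``(n, H, W, 3)`` (colour), any numeric dtype.
    """

    frames: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ParameterError(
                f"frames must be (n,H,W) or (n,H,W,3); got shape {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ParameterError("colour frames must have 3 channels")
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class ROISpec:
    """Active and reference disc regions plus the colour projection.

    Each region is ``(center_row, center_col, radius)`` in pixels.  The two
    discs must be disjoint and lie fully inside the frame.
    """

    active: tuple[float, float, float]
    reference: tuple[float, float, float]
    channel_weights: tuple[float, float, float] = REC601_WEIGHTS

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        for name, (r, c, rad) in (("active", self.active), ("reference", self.reference)):
            if rad < 0:
                raise GeometryError(f"{name} radius must be non-negative")
            if not (rad <= r <= h - 1 - rad and rad <= c <= w - 1 - rad):
                raise GeometryError(
                    f"{name} region ({r},{c},r={rad}) exceeds frame bounds {h}x{w}"
                )
        ar, ac, arad = self.active
        rr, rc, rrad = self.reference
        if np.hypot(ar - rr, ac - rc) <= arad + rrad:
            raise GeometryError("active and reference regions must be disjoint")

    def disc_mask(self, frame_shape: tuple[int, int], which: str) -> np.ndarray:
        r, c, rad = getattr(self, which)
        h, w = frame_shape
        rows, cols = np.ogrid[:h, :w]
        return (rows - r) ** 2 + (cols - c) ** 2 <= rad**2


def _normalize_mask(
    intervals, t0: float, t_end: float
) -> list[tuple[float, float]]:
    """Sort, merge and clip half-open exclusion intervals to the trace span."""
    clipped = []
    for start, end in intervals:
        start, end = float(start), float(end)
        if end <= start:
            raise ParameterError(f"exclusion interval [{start},{end}) is empty")
        start, end = max(start, t0), min(end, t_end)
        if end > start:
            clipped.append((start, end))
    clipped.sort()
    merged: list[tuple[float, float]] = []
    for start, end in clipped:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class ContractionTrace:
    """Uniformly sampled active-minus-reference intensity signal.

    ``exclusion_mask`` is a list of half-open ``[start, end)`` intervals in
    seconds marking artifact periods (valve motion, waste excretion) to be
    ignored by downstream beat detection.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    exclusion_mask: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")
        self.exclusion_mask = _normalize_mask(
            self.exclusion_mask, self.t0, self.t_end
        )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.n_samples / self.sample_rate

    def sample_mask(self) -> np.ndarray:
        """Boolean mask, True where the sample is *not* excluded."""
        keep = np.ones(self.n_samples, dtype=bool)
        t = self.times
        for start, end in self.exclusion_mask:
            keep &= ~((t >= start) & (t < end))
        return keep


def extract_trace(frames: FrameSequence, roi: ROISpec) -> ContractionTrace:
    """Project each frame to ``mean(active disc) - mean(reference disc)``.

    Colour frames are first collapsed with ``roi.channel_weights``; grayscale
    frames are used as-is.  One sample per frame; the trace inherits the
    sequence's frame rate and start time.  Because both regions see any
    spatially uniform illumination drift equally, the difference cancels it.
    """
    if frames.n_frames == 0:
        raise ParameterError("empty frame sequence")
    roi.validate(frames.frame_shape)
    arr = frames.frames.astype(float)
    if arr.ndim == 4:
        w = np.asarray(roi.channel_weights, dtype=float)
        arr = np.tensordot(arr, w, axes=([3], [0]))
    active = roi.disc_mask(frames.frame_shape, "active")
    reference = roi.disc_mask(frames.frame_shape, "reference")
    vals = arr[:, active].mean(axis=1) - arr[:, reference].mean(axis=1)
    return ContractionTrace(vals, sample_rate=frames.frame_rate, t0=frames.t0)


def save_trace(trace: ContractionTrace, path: str | os.PathLike) -> None:
    """Write a trace as a two-column UTF-8 CSV with header ``time_s,value``.

    The exclusion mask is not serialized here; exclusions travel in their own
    ``start_s,end_s`` CSV (see :func:`spatbeat.beats.load_exclusions`).
    """
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def load_trace(path: str | os.PathLike) -> ContractionTrace:
    """Read a ``time_s,value`` CSV back into a :class:`ContractionTrace`.

    Times must be strictly increasing and uniformly spaced to within 1e-6
    relative tolerance; the first offending row is named otherwise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise FormatError(f"expected header 'time_s,value', got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("trace CSV needs at least 2 rows")
    dt = np.diff(t)
    # diff k spans data rows k and k+1; the offending row is the latter,
    # i.e. CSV line k+3 counting the header as line 1
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 3
        raise FormatError(f"time_s not strictly increasing at CSV row {row}")
    dt0 = (t[-1] - t[0]) / (t.size - 1)
    bad = np.abs(dt - dt0) > 1e-6 * dt0
    if np.any(bad):
        row = int(np.argmax(bad)) + 3
        raise FormatError(f"non-uniform sample spacing at CSV row {row}")
    fs = 1.0 / dt0
    fs_round = round(fs, 6)
    if fs_round > 0 and abs(fs - fs_round) <= 1e-6 * fs:
        fs = fs_round
    return ContractionTrace(v, sample_rate=fs, t0=float(t[0]))


def read_frames(path: str | os.PathLike, frame_rate: float) -> FrameSequence:
    """Read frames from a directory of PNGs, a multi-page TIFF, or an AVI.

    PNG directories are read in lexicographic filename order.  AVI requires an
    imageio ffmpeg/pyav backend; a clear error is raised when none is present.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        names = sorted(q for q in p.iterdir() if q.suffix.lower() == ".png")
        if not names:
            raise FormatError(f"no PNG frames found in {p}")
        frames = np.stack([iio.imread(q) for q in names])
    elif p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(p)
    elif p.suffix.lower() == ".avi":
        try:
            frames = np.stack(list(iio.imiter(p)))
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise FormatError(
                f"could not decode AVI {p}; an ffmpeg/pyav imageio backend is required"
            ) from exc
    else:
        raise FormatError(f"unsupported frame source: {p}")
    if frames.ndim == 2:
        frames = frames[None]
    return FrameSequence(frames, frame_rate=frame_rate)


def write_frames(frames: FrameSequence, path: str | os.PathLike) -> None:
    """Write frames as a multi-page TIFF (``.tif``) or a directory of PNGs."""
    p = Path(path)
    arr = frames.frames
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, arr)
    else:
        import imageio.v3 as iio

        p.mkdir(parents=True, exist_ok=True)
        ndigits = max(5, len(str(arr.shape[0])))
        for i, frame in enumerate(arr):
            iio.imwrite(p / f"frame_{i:0{ndigits}d}.png", frame)
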