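"""Thermal-ramp segmentation, asystole classification, and Q10.

The acute challenge protocol steps the chamber from 22°C down to 10°C and
back in 2°C increments, dwelling 10 min at each experimental temperature
(13 steps in all).  The servo holds water within ±1°C of the set-point, so a
segment's analysis window opens when the thermocouple reading first settles
into that band and closes at the step's scheduled end.

Asystole is operational, not visual: fewer than 45 contractions within a
10-minute segment (scaled pro-rata for shorter windows).  Segment heart rate
is reported under two conventions — ``active_only`` (undefined during
asystole) and ``zeroed`` (0 during asystole) — because group statistics in
the source methodology use both.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .beats import BeatSeries, IBISeries, compute_ibi, mean_hr
from .errors import ConfigurationError, ParameterError

ASYSTOLE_BEATS_PER_600S = 45.0
SETTLE_TOLERANCE_C = 1.0

__all__ = [
    "ProtocolStep",
    "RampProtocol",
    "TempTrace",
    "Segment",
    "Q10Record",
    "segment_ramp",
    "classify_asystole",
    "segment_hr",
    "annotate_segments",
    "segments_to_frame",
    "compute_q10",
    "q10_records",
]


@dataclass(frozen=True)
class ProtocolStep:
    set_point: float  # °C
    dwell_s: float
    phase: str  # cooling | warming | baseline


@dataclass(frozen=True)
class RampProtocol:
    """Ordered set-point steps. Consecutive set-points within a phase differ
    by exactly ``step_size`` in magnitude."""

    steps: tuple[ProtocolStep, ...]
    step_size: float = 2.0
    settle_time_s: float = 80.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigurationError("protocol needs at least one step")
        if any(s.dwell_s <= 0 for s in self.steps):
            raise ConfigurationError("dwell times must be positive")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.phase == b.phase and not math.isclose(
                abs(b.set_point - a.set_point), self.step_size
            ):
                raise ConfigurationError(
                    f"set-points {a.set_point}->{b.set_point} violate "
                    f"step_size={self.step_size} within phase {a.phase!r}"
                )

    @property
    def total_duration(self) -> float:
        return sum(s.dwell_s for s in self.steps)

    def step_windows(self) -> list[tuple[float, float]]:
        """Scheduled [start, end) of each step, seconds from protocol start."""
        out, t = [], 0.0
        for s in self.steps:
            out.append((t, t + s.dwell_s))
            t += s.dwell_s
        return out

    @classmethod
    def default_ramp(
        cls,
        start_c: float = 22.0,
        low_c: float = 10.0,
        step_c: float = 2.0,
        dwell_s: float = 600.0,
    ) -> "RampProtocol":
        """22→10→22°C in 2°C steps, 10 min per step (13 steps).

        The initial 22°C step and the 10°C trough belong to the cooling arm;
        the return steps are the warming arm.
        """
        down = np.arange(start_c, low_c - step_c / 2, -step_c)
        up = np.arange(low_c + step_c, start_c + step_c / 2, step_c)
        steps = [ProtocolStep(float(t), dwell_s, "cooling") for t in down]
        steps += [ProtocolStep(float(t), dwell_s, "warming") for t in up]
        return cls(tuple(steps), step_size=step_c)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            "step_size": self.step_size,
            "settle_time_s": self.settle_time_s,
            "steps": [
                {"set_point": s.set_point, "dwell_s": s.dwell_s, "phase": s.phase}
                for s in self.steps
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RampProtocol":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        steps = tuple(
            ProtocolStep(float(d["set_point"]), float(d["dwell_s"]), str(d["phase"]))
            for d in data["steps"]
        )
        return cls(
            steps,
            step_size=float(data.get("step_size", 2.0)),
            settle_time_s=float(data.get("settle_time_s", 80.0)),
        )


@dataclass
class TempTrace:
    """Thermocouple record: strictly increasing times (s) and °C readings."""

    times: np.ndarray
    celsius: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.celsius = np.asarray(self.celsius, dtype=float)
        if self.times.shape != self.celsius.shape or self.times.ndim != 1:
            raise ParameterError("times and celsius must be matching 1-D arrays")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("temperature times must be strictly increasing")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TempTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["celsius"].to_numpy(float))

    def save(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"time_s": self.times, "celsius": self.celsius}).to_csv(
            path, index=False, float_format="%.10g", lineterminator="\n"
        )


@dataclass
class Segment:
    """One per-set-point analysis window with its cardiac summary."""

    set_point: float
    phase: str
    start_s: float
    end_s: float
    usable: bool = True
    low_confidence: bool = False
    beat_count: int | None = None
    asystole: bool | None = None
    hr_active: float | None = None  # beats/min; NaN when asystolic/undefined
    hr_zeroed: float | None = None  # beats/min; 0 when asystolic
    ibis: IBISeries | None = field(default=None, repr=False)

    @property
    def window_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Q10Record:
    spat_id: str
    phase: str
    hr_warm: float
    t_warm: float
    hr_cold: float
    t_cold: float
    q10: float  # NaN when undefined (either endpoint rate is 0/missing)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.q10)


def segment_ramp(
    temp: TempTrace,
    protocol: RampProtocol,
    tolerance_c: float = SETTLE_TOLERANCE_C,
) -> list[Segment]:
    """Carve the recording into one window per protocol step.

    A window opens at the first reading from which the temperature stays
    within ``tolerance_c`` of the set-point through the step's scheduled end,
    and closes at that scheduled end.  A step whose reading never settles is
    returned flagged ``usable=False``.  Windows with under 300 usable seconds
    are flagged low-confidence but kept.
    """
    if temp.times.size == 0:
        raise ParameterError("empty temperature trace")
    segments: list[Segment] = []
    for step, (t_start, t_end) in zip(protocol.steps, protocol.step_windows()):
        sel = (temp.times >= t_start) & (temp.times < t_end)
        times = temp.times[sel]
        readings = temp.celsius[sel]
        if times.size == 0:
            segments.append(
                Segment(step.set_point, step.phase, t_start, t_end, usable=False)
            )
            continue
        outside = np.abs(readings - step.set_point) > tolerance_c
        if outside.any():
            last_bad = np.flatnonzero(outside)[-1]
            if last_bad == times.size - 1:  # never settles before step end
                segments.append(
                    Segment(step.set_point, step.phase, t_start, t_end, usable=False)
                )
                continue
            start = float(times[last_bad + 1])
        else:
            start = t_start
        seg = Segment(step.set_point, step.phase, start, t_end)
        seg.low_confidence = seg.window_s < 300.0
        segments.append(seg)
    return segments


def classify_asystole(
    beat_count: int, window_s: float, threshold_per_600s: float = ASYSTOLE_BEATS_PER_600S
) -> bool:
    """True when the segment shows fewer than 45 contractions per 10 min,
    scaled pro-rata to the window length (45 beats in 600 s is *active*)."""
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    return beat_count < threshold_per_600s * (window_s / 600.0)


def segment_hr(ibis: IBISeries | None, asystole: bool, convention: str) -> float:
    """Segment mean HR under a reporting convention.

    ``active_only`` → 60000/mean(valid IBIs), NaN when asystolic;
    ``zeroed``      → same, but exactly 0 when asystolic.  Sporadic residual
    beats inside an asystolic segment never contribute a rate.
    """
    if convention not in ("active_only", "zeroed"):
        raise ParameterError(f"unknown convention {convention!r}")
    if asystole:
        return 0.0 if convention == "zeroed" else float("nan")
    if ibis is None:
        return float("nan")
    return mean_hr(ibis)


def annotate_segments(
    segments: list[Segment],
    beats: BeatSeries,
    exclusions: list[tuple[float, float]] | None = None,
) -> list[Segment]:
    """Fill beat counts, asystole flags and HR for each usable segment.

    Windows are half-open and disjoint, so each beat lands in at most one
    segment.  IBIs are formed within a window only (never across windows) and
    honour artifact exclusions.
    """
    out = []
    for seg in segments:
        seg = replace(seg)
        if not seg.usable:
            out.append(seg)
            continue
        sel = (beats.event_times >= seg.start_s) & (beats.event_times < seg.end_s)
        ev = BeatSeries(beats.event_times[sel])
        seg.beat_count = int(len(ev))
        seg.asystole = classify_asystole(seg.beat_count, seg.window_s)
        seg.ibis = compute_ibi(ev, exclusions)
        seg.hr_active = segment_hr(seg.ibis, seg.asystole, "active_only")
        seg.hr_zeroed = segment_hr(seg.ibis, seg.asystole, "zeroed")
        out.append(seg)
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Tabulate segments as the CSV-facing segment table."""
    return pd.DataFrame(
        {
            "set_point_c": [s.set_point for s in segments],
            "phase": [s.phase for s in segments],
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "usable": [s.usable for s in segments],
            "beat_count": [s.beat_count for s in segments],
            "asystole": [s.asystole for s in segments],
            "hr_active": [s.hr_active for s in segments],
            "hr_zeroed": [s.hr_zeroed for s in segments],
        }
    )


def compute_q10(hr_warm: float, t_warm: float, hr_cold: float, t_cold: float) -> float:
    """Temperature coefficient Q10 = (HR_warm/HR_cold)^(10/(T_warm-T_cold)).

    Returns NaN (undefined-result flag) when either rate is 0 or missing —
    asystole is excluded from rate ratios.  Requires ``t_warm > t_cold``.
    """
    if not t_warm > t_cold:
        raise ParameterError("t_warm must exceed t_cold")
    if not (hr_warm > 0 and hr_cold > 0) or not (
        np.isfinite(hr_warm) and np.isfinite(hr_cold)
    ):
        return float("nan")
    return float((hr_warm / hr_cold) ** (10.0 / (t_warm - t_cold)))


def q10_records(
    segment_table: pd.DataFrame, endpoints: str = "coldest_active"
) -> pd.DataFrame:
    """Per-spat, per-phase Q10 from a cohort segment table.

    ``endpoints='coldest_active'`` (default): the phase's warmest active
    set-point (normally 22°C) versus the coldest set-point at which the spat
    was still active.  ``endpoints='fixed'``: 22°C versus 10°C, undefined when
    either endpoint is asystolic.  Expects columns
    ``spat_id, group, set_point, phase, asystole, hr_active``.
    """
    if endpoints not in ("coldest_active", "fixed"):
        raise ParameterError(f"unknown endpoints rule {endpoints!r}")
    rows = []
    for (spat, phase), sub in segment_table.groupby(["spat_id", "phase"], sort=False):
        active = sub[(~sub["asystole"].astype(bool)) & sub["hr_active"].notna()]
        group = sub["group"].iloc[0] if "group" in sub else None
        if endpoints == "fixed":
            warm = sub[sub["set_point"] == 22.0]
            cold = sub[sub["set_point"] == 10.0]
            warm = warm[~warm["asystole"].astype(bool)]
            cold = cold[~cold["asystole"].astype(bool)]
        else:
            warm = active[active["set_point"] == active["set_point"].max()]
            cold = active[active["set_point"] == active["set_point"].min()]
        if len(warm) == 0 or len(cold) == 0:
            hw = tw = hc = tc = q10 = float("nan")
        else:
            hw, tw = float(warm["hr_active"].iloc[0]), float(warm["set_point"].iloc[0])
            hc, tc = float(cold["hr_active"].iloc[0]), float(cold["set_point"].iloc[0])
            q10 = compute_q10(hw, tw, hc, tc) if tw > tc else float("nan")
        rows.append(
            {
                "spat_id": spat,
                "group": group,
                "phase": phase,
                "hr_warm": hw,
                "t_warm": tw,
                "hr_cold": hc,
                "t_cold": tc,
                "q10": q10,
            }
        )
    return pd.DataFrame(rows)
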