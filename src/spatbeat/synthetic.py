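"""Ground-truthed synthetic inputs at three levels of realism.

Every downstream stage of the pipeline is testable without any recorded data
because this module generates, with known ground truth:

1. **Beat trains** — contraction onset times from a (piecewise) heart-rate
   profile.  Construction is interval-based: a deterministic grid at
   ``60/HR(t)`` seconds plus additive Gaussian jitter per interval, truncated
   at a 150 ms refractory floor.  This is deliberately not a Poisson process:
   the downstream statistics (SDNN, RMSSD, pNN50) are interval-based, and the
   Gaussian-on-intervals form is a documented modelling choice — no
   distributional form for molluscan IBI jitter is established.
2. **Contraction waveforms and rendered video** — each beat triggers a
   gamma-shaped pulse (fast rise, slower decay: an asymmetric leading edge
   like a real contraction) on the heart region, over Gaussian background
   noise; the reference point statistics are stationary.
3. **Whole cohorts** — two acclimation groups (cool ``Ta10``, warm ``Ta22``)
   of spat run through the 22→10→22°C ramp.  Per spat, HR follows
   ``clip(intercept_i + slope_g*(T-22), 0)`` with a Normal between-spat
   intercept; each spat carries a Normal arrest threshold below which the
   cooling arm is asystolic (resumption during warming happens at
   ``threshold + resume_offset``, negative by default: spat arrest at warmer
   temperatures than those at which they resume).  Crossing into arrest emits
   a short geometric-decay tail of 1–5 increasingly slow sporadic beats, then
   silence.  IBI jitter grows linearly as temperature falls and is uniformly
   scaled up in the cool-acclimated group, reproducing the inverse
   HRV-temperature relationship.

Default cohort parameters are the study conditions: 8 spat per group, warm
group intercept 83.2 beats/min at 22°C falling 7.3 beats/min per °C, cool
group 78.6 and 5.1 (rates with asystole counted as HR = 0), warm-group arrest
thresholds centred at 13°C so that 8/8 are asystolic by 10°C versus ~3/8 in
the cool group.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .beats import BeatSeries, compute_ibi
from .errors import ConfigurationError, ParameterError
from .hrv import time_domain_hrv
from .thermal import RampProtocol, TempTrace, classify_asystole, segment_hr
from .trace import ContractionTrace, FrameSequence

__all__ = [
    "CohortConfig",
    "VideoScene",
    "CohortDataset",
    "pulse_kernel",
    "make_beat_train",
    "make_trace",
    "make_video",
    "make_temp_trace",
    "make_cohort",
    "write_cohort",
]

GROUPS = ("Ta10", "Ta22")


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a simulated two-group acclimation cohort.

    ``hr_slope_cooling`` is dHR/dT in beats/min per °C (positive: rate falls
    as temperature falls); ``resume_offset`` is resume temperature minus
    arrest temperature (negative ⇒ spat resume at colder temperatures during
    warming than those at which they arrested during cooling).
    """

    n_per_group: int = 8
    groups: tuple[str, str] = GROUPS
    hr_intercept_22c: dict = field(
        default_factory=lambda: {"Ta10": 78.6, "Ta22": 83.2}
    )
    hr_slope_cooling: dict = field(
        default_factory=lambda: {"Ta10": 5.1, "Ta22": 7.3}
    )
    intercept_sd: float = 12.0
    arrest_threshold_mean: dict = field(
        default_factory=lambda: {"Ta10": 9.5, "Ta22": 13.0}
    )
    arrest_threshold_sd: dict = field(
        default_factory=lambda: {"Ta10": 1.2, "Ta22": 1.0}
    )
    resume_offset: float = -2.0
    ibi_jitter_sd_at_22c: float = 10.0  # ms
    ibi_jitter_growth: float = 4.0  # ms per °C of cooling
    jitter_group_multiplier: float = 1.8  # applied to Ta10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        non_negative = {
            "intercept_sd": self.intercept_sd,
            "ibi_jitter_sd_at_22c": self.ibi_jitter_sd_at_22c,
            "ibi_jitter_growth": self.ibi_jitter_growth,
            "jitter_group_multiplier": self.jitter_group_multiplier,
        }
        for name, value in non_negative.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for g in self.groups:
            for d, name in (
                (self.hr_intercept_22c, "hr_intercept_22c"),
                (self.hr_slope_cooling, "hr_slope_cooling"),
                (self.arrest_threshold_mean, "arrest_threshold_mean"),
                (self.arrest_threshold_sd, "arrest_threshold_sd"),
            ):
                if g not in d:
                    raise ConfigurationError(f"{name} missing entry for group {g!r}")
            if self.hr_intercept_22c[g] < 0 or self.hr_slope_cooling[g] < 0:
                raise ConfigurationError("rates must be non-negative")
            if self.arrest_threshold_sd[g] < 0:
                raise ConfigurationError("arrest_threshold_sd must be non-negative")

    def hr_at(self, group: str, temp_c: float, intercept: float | None = None) -> float:
        """Group HR at a temperature, clipped at zero."""
        b0 = self.hr_intercept_22c[group] if intercept is None else intercept
        return max(0.0, b0 + self.hr_slope_cooling[group] * (temp_c - 22.0))

    def jitter_sd_ms(self, group: str, temp_c: float) -> float:
        sd = self.ibi_jitter_sd_at_22c + self.ibi_jitter_growth * max(0.0, 22.0 - temp_c)
        if group == "Ta10":
            sd *= self.jitter_group_multiplier
        return sd


@dataclass(frozen=True)
class VideoScene:
    """Geometry and photometry of a rendered trans-illumination scene.

    The heart disc must sit strictly inside the shell ellipse and the
    reference point strictly outside it, mirroring the physical arrangement
    of active and reference points.
    """

    frame_size: tuple[int, int] = (128, 128)  # (H, W)
    frame_rate: float = 60.0
    heart_center: tuple[float, float] = (60.0, 56.0)  # (row, col)
    heart_radius: float = 10.0
    shell_center: tuple[float, float] = (64.0, 64.0)
    shell_axes: tuple[float, float] = (42.0, 34.0)  # (row semi-axis, col semi-axis)
    contraction_color_delta: float = 40.0
    background_noise_sd: float = 3.0
    active_point: tuple[float, float] = (60.0, 56.0)
    reference_point: tuple[float, float] = (12.0, 116.0)

    def _ellipse_value(self, r: float, c: float) -> float:
        a, b = self.shell_axes
        return ((r - self.shell_center[0]) / a) ** 2 + (
            (c - self.shell_center[1]) / b
        ) ** 2

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.background_noise_sd < 0:
            raise ConfigurationError("background_noise_sd must be non-negative")
        hr, hc = self.heart_center
        rad = self.heart_radius
        for pr, pc in ((hr - rad, hc), (hr + rad, hc), (hr, hc - rad), (hr, hc + rad)):
            if self._ellipse_value(pr, pc) >= 1.0:
                raise ConfigurationError("heart region must lie strictly inside shell")
        if self._ellipse_value(*self.reference_point) <= 1.0:
            raise ConfigurationError("reference point must lie strictly outside shell")


def pulse_kernel(tau_s: np.ndarray, rise_s: float = 0.05) -> np.ndarray:
    """Gamma-shaped contraction pulse, unit peak at ``tau = rise_s``.

    ``k(τ) = (τ/rise)·exp(1 − τ/rise)`` for τ ≥ 0, else 0.  With the default
    50 ms rise the pulse reaches half-maximum ~12 ms after onset (rise well
    under 100 ms) and decays below 5% of peak by 300 ms.
    """
    tau = np.asarray(tau_s, dtype=float)
    with np.errstate(over="ignore"):
        k = (tau / rise_s) * np.exp(1.0 - tau / rise_s)
    return np.where(tau >= 0, k, 0.0)


def make_beat_train(
    hr_profile: float | Callable[[float], float],
    duration_s: float,
    jitter_sd_ms: float = 0.0,
    refractory_ms: float = 150.0,
    seed=None,
    t0: float = 0.0,
) -> BeatSeries:
    """Generate contraction onset times from a heart-rate profile.

    ``hr_profile`` is beats/min, either a constant or a callable of time (s);
    it must be non-negative.  While the rate is zero no events are emitted;
    when activity (re)starts an event is placed at the first active instant,
    then successive intervals are ``60/HR(t)`` s plus ``N(0, jitter_sd_ms)``
    truncated at the refractory floor.  Event times are strictly increasing
    and the expected count over an interval matches ``∫ HR(t)/60 dt``.
    """
    if jitter_sd_ms < 0:
        raise ParameterError("jitter_sd_ms must be non-negative")
    if refractory_ms < 0:
        raise ParameterError("refractory_ms must be non-negative")
    if duration_s < 0:
        raise ParameterError("duration_s must be non-negative")
    hr = hr_profile if callable(hr_profile) else (lambda _t, r=float(hr_profile): r)
    rng = np.random.default_rng(seed)
    refr_s = refractory_ms / 1000.0
    scan_dt = 0.05  # silence-scan resolution, s
    end = t0 + duration_s
    events: list[float] = []
    t = t0
    while t < end:
        rate = float(hr(t))
        if rate < 0:
            raise ParameterError(f"hr_profile negative ({rate}) at t={t}")
        if rate == 0.0:
            t += scan_dt
            continue
        events.append(t)
        interval = 60.0 / rate
        if jitter_sd_ms > 0:
            interval += rng.normal(0.0, jitter_sd_ms / 1000.0)
        t += max(interval, refr_s, 1e-6)
    return BeatSeries(np.asarray(events))


def make_trace(
    beats: BeatSeries,
    duration_s: float,
    sample_rate: float = 60.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    rise_s: float = 0.05,
    seed=None,
    t0: float = 0.0,
) -> ContractionTrace:
    """Render a beat train directly to a contraction waveform (no video).

    Superposes one pulse kernel per beat over Gaussian noise — the waveform
    analog of what :func:`make_video` + trace extraction produces, at a
    fraction of the cost; used for large detector-validation batches.
    """
    n = int(round(duration_s * sample_rate))
    times = t0 + np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    support = int(np.ceil(1.0 * sample_rate))  # kernel negligible after 1 s
    for tb in beats.event_times:
        i0 = int(np.ceil((tb - t0) * sample_rate))
        if i0 >= n:
            continue
        i1 = min(n, max(i0, 0) + support)
        i0 = max(i0, 0)
        values[i0:i1] += amplitude * pulse_kernel(times[i0:i1] - tb, rise_s)
    return ContractionTrace(values, sample_rate=sample_rate, t0=t0)


def make_video(
    beats: BeatSeries,
    scene: VideoScene | None = None,
    duration_s: float | None = None,
    seed=None,
    rise_s: float = 0.05,
) -> tuple[FrameSequence, np.ndarray]:
    """Render 8-bit RGB frames of a pulsating heart inside a shell.

    Returns the frame sequence and the ground-truth beat times that fall
    within the rendered duration.  The heart disc brightens by
    ``contraction_color_delta`` (with a smooth radial falloff) following the
    pulse kernel at each beat; everything rides on stationary Gaussian noise.
    """
    scene = scene or VideoScene()
    if duration_s is None:
        duration_s = (
            float(beats.event_times[-1]) + 1.0 if len(beats) else 1.0
        )
    if len(beats) and beats.event_times[-1] >= duration_s:
        raise ConfigurationError("duration must cover all beat times")
    h, w = scene.frame_size
    n = int(round(duration_s * scene.frame_rate))
    times = np.arange(n) / scene.frame_rate

    rows, cols = np.ogrid[:h, :w]
    shell = (
        ((rows - scene.shell_center[0]) / scene.shell_axes[0]) ** 2
        + ((cols - scene.shell_center[1]) / scene.shell_axes[1]) ** 2
    ) <= 1.0
    d2 = (rows - scene.heart_center[0]) ** 2 + (cols - scene.heart_center[1]) ** 2
    heart = d2 <= scene.heart_radius**2
    falloff = np.clip(1.0 - np.sqrt(d2) / max(scene.heart_radius, 1e-9), 0.0, 1.0)

    base = np.full((h, w), 150.0)
    base[shell] = 110.0
    base[heart] = 95.0

    # per-frame pulse modulation at the heart
    modulation = np.zeros(n)
    for tb in beats.event_times:
        i0 = int(np.ceil(tb * scene.frame_rate))
        i1 = min(n, i0 + int(np.ceil(scene.frame_rate)))
        if i0 < n:
            modulation[max(i0, 0):i1] += pulse_kernel(
                times[max(i0, 0):i1] - tb, rise_s
            )

    rng = np.random.default_rng(seed)
    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    for i in range(n):
        img = base + scene.contraction_color_delta * modulation[i] * falloff
        img = img[:, :, None] + np.zeros((1, 1, 3))
        if scene.background_noise_sd > 0:
            img = img + rng.normal(0.0, scene.background_noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = beats.event_times[beats.event_times < duration_s].copy()
    return FrameSequence(frames, frame_rate=scene.frame_rate), gt


def make_temp_trace(
    protocol: RampProtocol,
    sample_hz: float = 1.0,
    tau_s: float = 20.0,
    noise_sd: float = 0.05,
    seed=None,
) -> TempTrace:
    """Simulate the thermocouple channel for a ramp protocol.

    Each step change approaches the new set-point exponentially with time
    constant ``tau_s`` (default 20 s: a 2°C step settles within ±1°C in under
    80 s, as the physical chamber does), plus small reading noise.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, protocol.total_duration, 1.0 / sample_hz)
    temps = np.empty_like(times)
    prev_sp = protocol.steps[0].set_point
    for step, (t0, t1) in zip(protocol.steps, protocol.step_windows()):
        sel = (times >= t0) & (times < t1)
        tt = times[sel] - t0
        temps[sel] = step.set_point + (prev_sp - step.set_point) * np.exp(-tt / tau_s)
        prev_sp = step.set_point
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=temps.size)
    return TempTrace(times, temps)


@dataclass
class CohortDataset:
    """A simulated cohort: per-segment table, drawn ground truth, raw beats."""

    segments: pd.DataFrame
    truth: pd.DataFrame
    beats: dict[str, BeatSeries]
    config: CohortConfig
    protocol: RampProtocol
    seed: int | None = None


def _residual_tail(rng, start_s: float, end_s: float, last_hr: float) -> list[float]:
    """1-5 increasingly slow sporadic beats at the onset of arrest."""
    n_res = int(rng.integers(1, 6))
    interval = 1.5 * 60.0 / max(last_hr, 1.0)
    t, out = start_s, []
    for _ in range(n_res):
        t += interval
        if t >= end_s:
            break
        out.append(t)
        interval *= 2.0
    return out


def make_cohort(
    config: CohortConfig | None = None,
    protocol: RampProtocol | None = None,
    seed: int | None = None,
) -> CohortDataset:
    """Simulate a full two-group cohort through the ramp protocol.

    Per spat: a Normal intercept and Normal arrest threshold are drawn; each
    protocol step gets a constant-rate jittered beat train (or an arrest
    tail/silence), and the segment summary (beat count, asystole under the
    <45/10 min rule, HR under both conventions, time-domain HRV) is computed
    with the *production* pipeline primitives so the table is exactly what
    the analysis modules consume.  Identical (config, protocol, seed) give
    identical output.
    """
    config = config or CohortConfig()
    protocol = protocol or RampProtocol.default_ramp()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.groups) * config.n_per_group)

    rows, truth_rows, beats_by_spat = [], [], {}
    windows = protocol.step_windows()
    spat_counter = 0
    for group in config.groups:
        for i in range(config.n_per_group):
            rng = np.random.default_rng(children[spat_counter])
            spat_id = f"{group}_{i + 1:02d}"
            spat_counter += 1
            intercept = rng.normal(
                config.hr_intercept_22c[group], config.intercept_sd
            )
            arrest_thr = rng.normal(
                config.arrest_threshold_mean[group],
                config.arrest_threshold_sd[group],
            )
            resume_thr = arrest_thr + config.resume_offset
            truth_rows.append(
                {
                    "spat_id": spat_id,
                    "group": group,
                    "intercept": intercept,
                    "slope": config.hr_slope_cooling[group],
                    "arrest_threshold": arrest_thr,
                    "resume_threshold": resume_thr,
                }
            )
            all_events: list[np.ndarray] = []
            prev_active, prev_hr = False, 0.0
            for step_index, (step, (t0, t1)) in enumerate(zip(protocol.steps, windows)):
                temp = step.set_point
                hr = config.hr_at(group, temp, intercept)
                thr = resume_thr if step.phase == "warming" else arrest_thr
                arrested = temp < thr or hr <= 0.0
                if not arrested:
                    train = make_beat_train(
                        hr,
                        duration_s=t1 - t0,
                        jitter_sd_ms=config.jitter_sd_ms(group, temp),
                        seed=rng,
                        t0=t0,
                    )
                    ev = train.event_times
                    prev_active, prev_hr = True, hr
                else:
                    tail = (
                        _residual_tail(rng, t0, t1, prev_hr) if prev_active else []
                    )
                    ev = np.asarray(tail)
                    prev_active = False
                all_events.append(ev)
                ibis = compute_ibi(BeatSeries(ev))
                count = int(ev.size)
                asys = classify_asystole(count, t1 - t0)
                summary = time_domain_hrv(ibis)
                rows.append(
                    {
                        "spat_id": spat_id,
                        "group": group,
                        "step_index": step_index,
                        "set_point": temp,
                        "phase": step.phase,
                        "start_s": t0,
                        "end_s": t1,
                        "beat_count": count,
                        "asystole": asys,
                        "hr_active": segment_hr(ibis, asys, "active_only"),
                        "hr_zeroed": segment_hr(ibis, asys, "zeroed"),
                        "true_hr": hr if not arrested else 0.0,
                        "mean_ibi_ms": summary.mean_ibi,
                        "sdnn_ms": summary.sdnn,
                        "rmssd_ms": summary.rmssd,
                        "pnn50_pct": summary.pnn50,
                        "n_intervals": summary.n_intervals,
                        "n_pairs": summary.n_pairs,
                    }
                )
            beats_by_spat[spat_id] = BeatSeries(np.concatenate(all_events))
    return CohortDataset(
        segments=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        beats=beats_by_spat,
        config=config,
        protocol=protocol,
        seed=seed,
    )


def write_cohort(dataset: CohortDataset, out_dir: str | os.PathLike) -> None:
    """Write a cohort to a directory: segment/truth CSVs, config YAML, and a
    sidecar JSON embedding the seed for provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.segments.to_csv(out / "segments.csv", index=False, lineterminator="\n")
    dataset.truth.to_csv(out / "truth.csv", index=False, lineterminator="\n")
    cfg = asdict(dataset.config)
    cfg["groups"] = list(cfg["groups"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    dataset.protocol.to_yaml(out / "protocol.yaml")
    with open(out / "meta.json", "w") as fh:
        json.dump({"seed": dataset.seed, "generator": "spatbeat.make_cohort"}, fh)
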