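"""Time-domain heart-rate variability and the spectral "clear peak" screen.

Time-domain metrics follow the standard human HRV definitions applied to
valid (artifact-excluded) intervals:

* ``mean_ibi`` — arithmetic mean of valid IBIs (ms)
* ``sdnn``     — sample standard deviation (n−1 denominator) of valid IBIs
* ``rmssd``    — root mean square of successive differences, pairs taken only
  between *consecutive* valid intervals (no pair across an exclusion gap)
* ``pnn50``    — percentage of those pairs with |Δ| strictly greater than 50 ms

The frequency-domain screen resamples the tachogram (IBI vs onset time) at
4 Hz by cubic interpolation and takes a Welch periodogram (256-sample Hann
segments, 50% overlap).  A band shows a "clear peak" when its maximum exceeds
3× the band's median power and is a local maximum of the spectrum.  Bands are
the human-analog LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) ranges, appropriate
because spat heart rates are human-like in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .beats import IBISeries
from .errors import ParameterError

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

__all__ = ["HRVSummary", "SpectrumReport", "time_domain_hrv", "psd_screen"]


@dataclass(frozen=True)
class HRVSummary:
    """Per-segment time-domain metrics; NaN marks an undefined statistic."""

    mean_ibi: float
    sdnn: float
    rmssd: float
    pnn50: float
    n_intervals: int
    n_pairs: int


def _successive_pairs(ibis: IBISeries) -> np.ndarray:
    """Differences between consecutive valid intervals (adjacent in sequence)."""
    v = ibis.valid_flags
    adjacent = v[:-1] & v[1:]
    return np.diff(ibis.intervals_ms)[adjacent]


def time_domain_hrv(ibis: IBISeries) -> HRVSummary:
    """Compute mean IBI, SDNN, RMSSD and pNN50 from a validated IBI series.

    Empty input yields an all-NaN summary; SDNN needs at least 2 intervals,
    RMSSD/pNN50 at least one consecutive valid pair.
    """
    vi = ibis.valid_intervals
    n = int(vi.size)
    diffs = _successive_pairs(ibis) if len(ibis) else np.empty(0)
    n_pairs = int(diffs.size)
    mean_ibi = float(np.mean(vi)) if n >= 1 else float("nan")
    sdnn = float(np.std(vi, ddof=1)) if n >= 2 else float("nan")
    if n_pairs >= 1:
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / n_pairs)
    else:
        rmssd = pnn50 = float("nan")
    return HRVSummary(mean_ibi, sdnn, rmssd, pnn50, n, n_pairs)


@dataclass
class SpectrumReport:
    """Welch spectrum of the tachogram plus per-band peak verdicts."""

    frequencies: np.ndarray
    power: np.ndarray  # ms^2/Hz
    bands: dict[str, tuple[float, float]]
    peak_found: dict[str, bool] = field(default_factory=dict)
    peak_freq: dict[str, float] = field(default_factory=dict)
    evaluable: bool = True
    reason: str = ""

    @property
    def any_peak(self) -> bool:
        return any(self.peak_found.values())


def psd_screen(
    ibis: IBISeries,
    bands: dict[str, tuple[float, float]] | None = None,
    resample_hz: float = 4.0,
    nperseg: int = 256,
    peak_ratio: float = 3.0,
) -> SpectrumReport:
    """Screen the IBI spectrum for defined LF/HF-band peaks.

    Requires at least 64 valid intervals spanning at least 120 s; otherwise
    the report is flagged not-evaluable.  ``peak_ratio`` operationalizes a
    "clear peak": band maximum > ratio × band median power, and the maximum
    must be a local maximum of the full spectrum (a band edge riding a 1/f
    slope does not count).
    """
    if bands is None:
        bands = {"LF": LF_BAND, "HF": HF_BAND}
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi:
            raise ParameterError(f"band {name!r} range invalid")

    t = ibis.valid_onsets
    x = ibis.valid_intervals
    empty = SpectrumReport(np.empty(0), np.empty(0), bands, evaluable=False)
    if x.size < 64:
        empty.reason = f"only {x.size} valid intervals (need >= 64)"
        return empty
    span = float(t[-1] - t[0])
    if span < 120.0:
        empty.reason = f"span {span:.1f} s (need >= 120 s)"
        return empty

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = interpolate.interp1d(t, x, kind="cubic", assume_sorted=True)(grid)
    nps = min(nperseg, tach.size)
    freqs, power = signal.welch(
        tach,
        fs=resample_hz,
        window="hann",
        nperseg=nps,
        noverlap=nps // 2,
        detrend="constant",
    )

    report = SpectrumReport(freqs, power, bands)
    # interpolation round-off on a flat tachogram must not masquerade as power
    noise_floor = 1e-15 * max(1.0, float(np.mean(tach)) ** 2)
    for name, (lo, hi) in bands.items():
        idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if idx.size == 0:
            report.peak_found[name] = False
            continue
        band_power = power[idx]
        imax = idx[int(np.argmax(band_power))]
        med = float(np.median(band_power))
        is_local_max = (
            0 < imax < freqs.size - 1
            and power[imax] > power[imax - 1]
            and power[imax] > power[imax + 1]
        )
        found = bool(
            power[imax] > peak_ratio * med
            and is_local_max
            and power[imax] > noise_floor
        )
        report.peak_found[name] = found
        if found:
            report.peak_freq[name] = float(freqs[imax])
    return report
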