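# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `spatbeat`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model and trace extraction

A trans-illuminated spat heart modulates pixel colour once per contraction.
The analog edge-detection instrument this package emulates compared a single
*active* point over the heart against a *reference* point outside the
animal; we use small disc regions instead of single pixels (the robust
digital analog of a point riding on an analog video line) and define the
contraction trace as

    s[k] = w·mean(active disc in frame k) − w·mean(reference disc in frame k)

with `w` a colour-projection 3-vector (rec.601 luma by default, configurable
because a heart's colour change may be channel-specific). One sample per
frame; time in seconds from the first frame; pixel coordinates are 0-based,
row-major. Two structural properties follow directly and are enforced by
tests: the trace is linear in frame intensity, and any spatially uniform,
time-varying illumination offset cancels exactly.

Automatic heart localization and motion stabilization are out of scope: the
regions are supplied by the experimenter, as they were on the physical rig.

## Beat detection

The detector is a software Schmitt trigger operating on the trace:

* **Threshold** — midpoint of the 10th and 90th percentiles of the
  non-excluded samples (the instrument's internal comparator level is
  undocumented, so an amplitude-invariant adaptive default is used; a fixed
  operator threshold can be supplied).
* **Hysteresis** — the trigger must re-arm below `threshold − 0.10 ×
  (p90 − p10)` before it may fire again, suppressing chatter near threshold.
* **Refractory** — 150 ms, capping detectable rate at 400 beats/min, far
  above spat maxima (~90 beats/min); prevents double-firing on pulse
  overshoot.
* **Event time** — the exact sample time of the crossing sample, with no
  sub-sample interpolation: at 60 frames/s the 16.7 ms resolution is ample
  for the 50 ms granularity that pNN50 requires.

A trace whose 10–90 percentile range is at the numerical noise floor
produces an empty series with a warning rather than an error. Exclusion
intervals (valve movement, waste excretion and similar artifacts) are
user-supplied `start_s,end_s` half-open intervals; events inside them are
discarded, and an IBI whose span intersects one is flagged invalid — a gap
is never bridged into a fake long interval.

## Thermal segmentation, asystole and Q10

The ramp protocol is 22→10→22 °C in 2 °C steps with 600 s per set-point
(13 steps; the initial 22 °C step and the 10 °C trough belong to the cooling
arm, which terminates at the trough). The chamber servo holds water within
±1 °C, so a segment's analysis window opens at the first thermocouple
reading from which the trace stays inside that band through the step's
scheduled end; a step that never settles is flagged unusable, and windows
with under 300 usable seconds are flagged low-confidence but kept.

Asystole is operational: fewer than 45 contractions per 10-minute segment,
scaled pro-rata for shorter windows (so exactly 45 beats in 600 s is
active). Segment HR is `60000 / mean(valid IBIs)` and is reported under two
conventions: `active_only` (undefined during asystole) and `zeroed`
(exactly 0 during asystole). Sporadic residual beats inside an asystolic
segment never contribute a rate under either convention.

Q10 = (HR_warm/HR_cold)^(10/(T_warm−T_cold)). The endpoint rule is
configurable because the canonical choice is genuinely open: the default
uses, per spat and phase, the phase's warmest active set-point against the
coldest set-point at which that spat was still active (asystolic segments
cannot enter a ratio of rates); a fixed 22 °C vs 10 °C rule is also
provided. Q10 is flagged undefined when either endpoint rate is 0.

## Time-domain HRV and the spectral screen

Within a segment, "normal" intervals are the valid (artifact-excluded)
intervals; no additional ectopy filter is applied since molluscan
arrhythmia taxonomy is undefined. Definitions: mean IBI (arithmetic mean),
SDNN (sample SD, n−1 denominator — the denominator convention is a
documented choice), RMSSD (root mean square of successive differences,
pairs formed only between consecutive valid intervals), pNN50 (percentage
of pairs with |Δ| strictly greater than 50 ms).

The spectral screen asks a single question: does the IBI spectrum show
defined LF/HF-band peaks that would justify frequency-domain analysis? The
tachogram is resampled at 4 Hz by cubic interpolation and Welch-averaged
(256-sample Hann segments, 50% overlap). A band (LF 0.04–0.15 Hz, HF
0.15–0.40 Hz — human-analog ranges, appropriate because spat rates are
human-like) reports a "clear peak" when its maximum exceeds 3× the band's
median power, is a local maximum of the spectrum, and sits above a
round-off floor. The 3× criterion is this package's operationalization of
"clear peak" (configurable); at 400 intervals it recovers an injected
0.10 Hz, ±50 ms modulation and reports no peak on white interval jitter in
≥ 90% of seeds. The screen requires ≥ 64 valid intervals spanning ≥ 120 s.

## The mixed model

Heart rate across the ramp is modelled as

    HR_its = β0 + βg·group_i + βT·(T_ts − 22) + βgT·group_i·(T_ts − 22)
             + βph·phase_ts + u_i + ε_its

with `group` an indicator for cool acclimation (Ta10), `phase` an indicator
for the warming arm (the 22 °C baseline is coded cooling), `u_i ~ N(0, σ²u)`
a random spat intercept, and residuals first-order autocorrelated within
spat: `corr(ε_its, ε_its') = ρ^|step(s) − step(s')|` (missing segments keep
their step spacing in the lag). Estimation is REML: the profile objective
over `(log σ²u, log σ²ε, artanh ρ)` is minimized with Nelder–Mead, with a
small relative ridge on each block covariance for stability in the
noise-free limit. Confidence intervals are Wald-type on the REML fit;
exact replication of any particular denominator-degrees-of-freedom
convention is a non-goal. Each group's per-°C gradient (and the
difference, with CI and p) is reported as a linear combination of fixed
effects. Columns without variation (single group or single phase) are
dropped and reported as NaN so partial designs remain estimable. On
optimizer failure the fit falls back to ρ = 0 and then to OLS, warning and
flagging `converged=False`. In the ρ = 0 special case the implementation
matches statsmodels `MixedLM` REML estimates to ~1e-4, which the test suite
checks as an independent cross-validation.

Exact tests: McNemar's two-sided exact p is `min(1, 2·P[Bin(b+c, ½) ≤
min(b, c)])` over the discordant pair counts; Fisher's exact test uses the
two-sided point-probability rule (the convention consistent with common
statistical packages), checked in tests against a full hypergeometric
enumeration in exact rational arithmetic. Q10 contrasts use a global
mid-rank transform followed by ordinary two-way ANOVA (Type II sums of
squares; the designs are balanced). All tests are two-sided with no
multiplicity correction, and an all-tied rank vector short-circuits to
F = 0, p = 1.

## Synthetic generator: what it emulates

Beat trains are interval-based: events on a deterministic `60/HR(t)` s grid
plus additive Gaussian per-interval jitter truncated at the 150 ms
refractory floor. Gaussian-on-intervals is a modelling choice — no
distributional form for molluscan IBI jitter is established — made because
the downstream statistics are interval-based and a point process would
confound rate and variability. Waveforms and video superpose a gamma-shaped
pulse `k(τ) = (τ/a)·e^{1−τ/a}` (rise constant a = 50 ms: half-maximum ~12 ms
after onset, decay below 5% of peak by 300 ms — an asymmetric leading edge
like a real contraction) on Gaussian background noise; the default scene is
128×128 px 8-bit RGB at 60 frames/s with the heart disc strictly inside a
shell ellipse and the reference point strictly outside it.

Cohort defaults are the study conditions:

| parameter | Ta22 (warm) | Ta10 (cool) | rationale |
|---|---|---|---|
| n per group | 8 | 8 | study design |
| HR intercept at 22 °C | 83.2 | 78.6 beats/min | fitted group means (zeroed convention) |
| cooling slope dHR/dT | 7.3 | 5.1 beats/min/°C | fitted group gradients (zeroed convention) |
| between-spat intercept SD | 12 | 12 beats/min | implied by the ±12.5 CI half-width at n = 8 |
| arrest threshold | N(13, 1) °C | N(9.5, 1.2) °C | reproduces 8/8 vs ~3/8 asystolic at 10 °C |
| resume offset | −2 °C | −2 °C | arrest during cooling occurs at warmer T than resumption during warming |
| IBI jitter SD | 10 ms at 22 °C + 4 ms/°C of cooling | × 1.8 | inverse HRV–temperature relation; higher RMSSD/pNN50 under cool acclimation |

Per spat, the intercept and arrest threshold are drawn once; each step gets
a constant-rate jittered train, and the segment in which a spat crosses its
arrest threshold emits a geometric-decay tail of 1–5 increasingly slow
sporadic beats before silence. HR is clipped at zero, so deep-cold warm-
group segments are silent even without threshold arrest. Segment summaries
(count, asystole, both HR conventions, HRV) are computed with the
production pipeline primitives, and identical (config, protocol, seed)
yield byte-identical datasets; per-spat streams come from spawned
`SeedSequence` children.

**What passing synthetic tests does not show:** the generator has no
valve-motion or feeding artifacts beyond user-injected exclusion intervals,
no heart drift or focus change, stationary background noise, and linear
HR(T) with a sharp arrest threshold. Real recordings can violate any of
these; detector recall/precision ≥ 98% and mixed-model slope recovery
within 10% are claims about this data-generating process, not about any
particular rig. Empirical group-level magnitudes that depend on real
animals (e.g. Q10 near 2.4–2.7, absolute HRV levels) are not reproduced by
construction — the linear-with-clipping HR model implies larger Q10 than a
true exponential rate law would.

## Problem sizes and numerical choices

Validation batches were sized for a desk-scale run: 1000 waveform traces of
60 s for detector–oracle equivalence, 20 rendered 10 s videos at 64×64 px
for the full video path, 20 replicate cohorts for parameter recovery, and
2000 null simulations for exact-test conservatism. Tolerances in the test
suite: exact identities to 1e-12, hand-computed statistics to the printed
precision, stochastic recoveries to 10%. Degenerate inputs resolve to
flags, not errors: empty IBI series give all-NaN HRV, flat traces give
empty beat series with a warning, zero discordant pairs give p = 1, and an
asystolic Q10 endpoint gives NaN.
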