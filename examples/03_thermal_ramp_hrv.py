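"""Run one simulated spat through the 22-10-22 degC ramp: segment the
recording on the thermocouple channel, classify asystole, and compute
per-segment heart rate, time-domain HRV and Q10.

The table shows HR falling with temperature, asystole at the cold trough,
and RMSSD growing as the chamber cools — the inverse HRV-temperature
relationship.  Q10 summarizes the fold-change in rate per 10 degC.
"""

import pandas as pd

from spatbeat import (
    RampProtocol,
    annotate_segments,
    compute_q10,
    make_cohort,
    make_temp_trace,
    segment_ramp,
    time_domain_hrv,
)

protocol = RampProtocol.default_ramp()
cohort = make_cohort(seed=21)
spat_id = "Ta22_01"
beats = cohort.beats[spat_id]

temp = make_temp_trace(protocol, seed=22)
segments = annotate_segments(segment_ramp(temp, protocol), beats)

rows = []
for seg in segments:
    hrv = time_domain_hrv(seg.ibis)
    rows.append(
        {
            "T_exp": seg.set_point,
            "phase": seg.phase,
            "beats": seg.beat_count,
            "asystole": seg.asystole,
            "HR (zeroed)": round(seg.hr_zeroed, 1),
            "RMSSD ms": round(hrv.rmssd, 1) if hrv.n_pairs else None,
        }
    )
print(pd.DataFrame(rows).to_string(index=False))

active = [s for s in segments if s.phase == "cooling" and not s.asystole]
warm, cold = active[0], active[-1]
q10 = compute_q10(warm.hr_active, warm.set_point, cold.hr_active, cold.set_point)
print(
    f"\ncooling-phase Q10 ({warm.set_point:.0f} -> {cold.set_point:.0f} degC): "
    f"{q10:.2f}  (fold-change in HR per 10 degC)"
)
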