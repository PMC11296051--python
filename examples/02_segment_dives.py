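"""Detect dives and split them into descent / bottom / ascent phases.

Dives are maximal runs of depth > 0.4 m; shallow (<= 2 m) or short
(<= 10 s) excursions are 'surface dives' and are not phase-split.
"""

from pcedetect import SimConfig, detect_dives, flag_foraging, simulate_trip
from pcedetect.dives import dive_table

cfg = SimConfig(trip_duration_s=1200, seed=42)
series, events, _ = simulate_trip(cfg, "ind000")

dives = detect_dives(series)
for d in dives:
    d.foraging = flag_foraging(d, series.label)

table = dive_table(dives)
print(table[["dive_id", "start_s", "max_depth_m", "duration_s", "kind",
             "descent_end_s", "ascent_start_s", "foraging"]].to_string(
                 index=False))
print(f"\n{sum(d.kind == 'regular' for d in dives)} regular dives, "
      f"{sum(d.foraging for d in dives)} foraging dives")
# Each regular dive's descent ends where the normalized depth rate drops
# below 0.5 while the depth exceeds half the dive maximum; ascent is the
# mirrored criterion.
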