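"""Solar and tidal cycles over a high-Arctic sampling window.

Computes the solar-elevation and M2-tide series for the northern station
(82.5N, 30E, mid-June) and lists the detected extrema — the events
(solar min/max, high/low tide) transcript phases are later compared against.
"""

import datetime as dt

from polarhythm import env_series, midnight_sun

LAT, LON = 82.5, 30.0
start = dt.datetime(2018, 6, 18, 10, 0)  # local clock, UTC+2 convention

env = env_series(LAT, LON, start, hours=26, step_min=10)

print(f"midnight sun on 18 June at {LAT}N: {midnight_sun(LAT, LON, start.date())}")
print(f"solar elevation range over the window: "
      f"{env.solar_elev_deg.min():.1f} to {env.solar_elev_deg.max():.1f} deg")
for e in env.events:
    clock = (start + dt.timedelta(hours=e.time_h)).strftime("%d %b %H:%M")
    print(f"  {e.kind:9s} at t={e.time_h:5.1f} h ({clock})")
# The sun never sets (all elevations > 0) yet still oscillates daily;
# the ~12.4 h spacing of the tide events is the semidiurnal M2 cycle.
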