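"""Per-pregnancy exposure metrics for one woman.

Builds trimester windows from conception/delivery dates, time-weights a
concentration surface over them, and converts tap-water concentrations
plus questionnaire water use into ingestion and blood-uptake doses.
"""

import datetime as dt

import numpy as np
import pandas as pd

from dbpexposure import (
    WaterUseProfile, compute_time_weights, default_factors, ingestion,
    integrated_uptake, pregnancy_windows, twa_concentration,
)
from dbpexposure.concentration import ConcentrationSurface

# a toy monthly surface for two zones with a seasonal swing
cells = pd.period_range("2008-01", "2009-12", freq="M")
frame = pd.DataFrame(
    [(z, c, 45.6 + off + 5 * np.sin(2 * np.pi * (c.month - 4) / 12),
      np.nan, "fitted")
     for z, off in (("WSZ1", 0.0), ("WSZ2", 4.0)) for c in cells],
    columns=["wsz_id", "time_cell", "pred_ugL", "sd", "provenance"])
surface = ConcentrationSurface("TTHM", "M", frame)

conception, delivery = dt.date(2008, 3, 10), dt.date(2008, 12, 14)
windows = pregnancy_windows(conception, delivery)
profile = WaterUseProfile(tap_Lday=1.0, squash_Lday=0.2, tea_Lday=0.5,
                          coffee_Lday=0.2, shower_minwk=90, bath_minwk=60,
                          swim_minwk=0, filter_home=False)
factors = default_factors()

for label, window in windows.items():
    weights = compute_time_weights(window, conception, delivery, "month")
    # she works in WSZ2: 40/112 workplace, 72/112 residence weighting
    twa = twa_concentration(surface, weights, "WSZ1", "WSZ2")
    ing = ingestion(profile, {"TTHM": twa}, factors)["TTHM"]
    upt = integrated_uptake(profile, {"TTHM": twa}, factors, ["TTHM"])["TTHM"]
    print(f"{label:>5}: TWA {twa:5.1f} ug/L | ingestion {ing:5.1f} ug/day | "
          f"uptake {upt['total']:.3f} ug/day "
          f"(shower+bath+swim {upt['sbs']:.3f})")
# TWA is the ug/L concentration she experienced over the window; ingestion
# is the swallowed dose; uptake is the estimated blood dose across pathways.
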