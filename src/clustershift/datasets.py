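"""Built-in phenotype tables.

``PEAK_WSC``, ``WSC_AT_22DAA`` and friends hold the published line means
for the Chara 1-FEH mutant study (stem WSC in % dry weight); everything
else produced here is synthetic fill so that a complete time course can
be assembled without the unavailable raw data. Synthetic points are
marked ``anchor=False`` in :func:`load_wsc_table` and are shaped only to
preserve the anchored peak positions (12 DAA under water deficit, 27 DAA
well watered) and the anchored decline over the 12->22 DAA window.
"""

from __future__ import annotations

import pandas as pd

LINES = ("Chara", "w1", "w2", "w3")
PARENT_LINE = "Chara"

#: Peak stem WSC (%dw) under water deficit; the peak falls at 12 DAA.
PEAK_WSC_DEFICIT = {"Chara": 31.0, "w1": 28.5, "w2": 29.9, "w3": 26.3}
#: Stem WSC (%dw) at 22 DAA (permanent wilting point) under water deficit.
WSC_AT_22DAA_DEFICIT = {"Chara": 5.7, "w1": 9.5, "w2": 6.7, "w3": 11.1}
#: Peak stem WSC (%dw) under well-watered conditions; the peak falls at 27 DAA.
PEAK_WSC_WATERED = {"Chara": 35.0, "w1": 34.5, "w2": 29.9, "w3": 33.9}
#: Published 12->22 DAA declines (%dw) as printed; Chara's printed value
#: differs from its printed endpoints (31.0 - 5.7 = 25.3) by one rounding
#: step. Computations in :mod:`clustershift.wsc` always use endpoints.
PUBLISHED_DECLINE_DEFICIT = {"Chara": 25.2, "w1": 20.5, "w2": 21.8, "w3": 15.2}
#: Main-stem grain weight (g/ear) at 32 DAA under water deficit.
GRAIN_WEIGHT_32DAA_DEFICIT = {"Chara": 0.87, "w3": 0.56}

PEAK_DAA_DEFICIT = 12
PEAK_DAA_WATERED = 27
WILTING_DAA = 22
STAGES_DAA = (7, 12, 17, 22, 27, 32)


def load_wsc_table() -> pd.DataFrame:
    """Line-mean stem WSC time courses for both watering treatments.

    Returns a tidy frame with columns ``line, treatment, daa,
    stem_wsc_pct_dw, anchor``. Rows with ``anchor=True`` are the published
    means; the rest are synthetic interpolations/extrapolations chosen so
    that each series has a unique maximum at the published peak stage.
    """
    rows = []
    for line in LINES:
        peak = PEAK_WSC_DEFICIT[line]
        low = WSC_AT_22DAA_DEFICIT[line]
        deficit = {
            7: round(peak - 3.0, 1),
            12: peak,
            17: round((peak + low) / 2.0, 1),
            22: low,
            27: round(max(low - 1.5, 1.0), 1),
            32: round(max(low - 2.5, 0.5), 1),
        }
        for daa, wsc in deficit.items():
            rows.append((line, "water_deficit", daa, wsc, daa in (12, 22)))

        wpeak = PEAK_WSC_WATERED[line]
        watered = {
            7: round(wpeak - 8.0, 1),
            12: round(wpeak - 6.0, 1),
            17: round(wpeak - 4.0, 1),
            22: round(wpeak - 2.0, 1),
            27: wpeak,
            32: round(wpeak - 3.0, 1),
        }
        for daa, wsc in watered.items():
            rows.append((line, "well_watered", daa, wsc, daa == 27))
    return pd.DataFrame(
        rows, columns=["line", "treatment", "daa", "stem_wsc_pct_dw", "anchor"]
    )


def deficit_decline(line: str) -> float:
    """12->22 DAA decline (%dw) recomputed from the anchored endpoints."""
    return PEAK_WSC_DEFICIT[line] - WSC_AT_22DAA_DEFICIT[line]
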