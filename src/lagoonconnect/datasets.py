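"""Published reference data for the Ahe atoll system (Tuamotu, French
Polynesia), used as model inputs and worked-example fixtures.

These small tables transcribe field-survey and reanalysis-derived values
for Ahe: the per-sector pearl-oyster stock estimates (reared concessions
at 12,000 oysters/ha plus the wild stock mapped with the Takapoto
density-by-depth survey), the 12-regime trade-wind climatology derived
from daily ERA-Interim winds (1979-2011) at the closest grid point, and
basic rim geometry. They serve as inputs to worked examples and as
generator targets for the synthetic wind module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lagoonconnect.wind import RegimeSpec
from lagoonconnect.regimes import WINTER_MONTHS, SUMMER_MONTHS

__all__ = [
    "ahe_stock_table",
    "ahe_wind_regime_table",
    "ahe_regime_specs",
    "AHE_SEASON_OF_REGIME",
    "AHE_RIM_PERIMETER_KM",
    "AHE_HOA_TOTAL_WIDTH_KM",
    "AHE_LAGOON_AREA_KM2",
    "AHE_MEAN_DEPTH_M",
    "AHE_MAX_DEPTH_M",
    "AHE_LAGOON_VOLUME_M3",
    "AHE_PASS_DEPTH_M",
    "ERA_WIND_START",
    "ERA_WIND_END",
]

AHE_LAGOON_AREA_KM2 = 142.0
AHE_MEAN_DEPTH_M = 41.0
AHE_MAX_DEPTH_M = 70.0
AHE_LAGOON_VOLUME_M3 = 5.9e9
AHE_PASS_DEPTH_M = 11.0
AHE_RIM_PERIMETER_KM = 77.0
AHE_HOA_TOTAL_WIDTH_KM = 4.0

#: Daily wind record span used for the Ahe regime climatology.
ERA_WIND_START = "1979-01-01"
ERA_WIND_END = "2011-12-31"

_STOCK = {
    # sector: (reared, natural) oyster counts
    1: (1_092_000, 379_280),
    2: (972_000, 633_580),
    3: (2_364_000, 450_540),
    4: (1_848_000, 518_370),
    5: (1_212_000, 452_690),
    6: (0, 347_360),
    7: (2_616_000, 449_960),
    8: (0, 297_540),
    9: (2_184_000, 413_620),
    10: (864_000, 381_790),
    11: (948_000, 431_570),
    12: (264_000, 399_560),
}


def ahe_stock_table() -> pd.DataFrame:
    """Reared and natural oyster stock cumulated by spawning sector."""
    df = pd.DataFrame.from_dict(_STOCK, orient="index", columns=["reared", "natural"])
    df.index.name = "sector"
    return df


_REGIMES = [
    # id, reference start date, n sequences, probability %, speed mean/SD, direction mean/SD
    (1, "28/08/81", 135, 11.2, 7.1, 0.9, 96.1, 11.3),
    (2, "16/03/82", 98, 8.1, 4.6, 1.9, 87.6, 66.2),
    (3, "20/12/84", 87, 7.2, 3.7, 0.9, 42.5, 91.4),
    (4, "14/05/86", 83, 6.9, 4.9, 1.8, 94.3, 51.1),
    (5, "24/05/86", 94, 7.8, 5.9, 1.5, 93.2, 18.8),
    (6, "12/01/94", 83, 6.9, 4.2, 1.4, 75.8, 63.7),
    (7, "22/01/94", 88, 7.3, 4.8, 1.4, 81.3, 61.6),
    (8, "02/05/94", 160, 13.3, 4.4, 1.3, 80.9, 37.7),
    (9, "06/01/99", 108, 9.0, 5.7, 1.2, 89.0, 17.6),
    (10, "07/03/99", 86, 7.1, 6.2, 1.2, 94.6, 20.0),
    (11, "06/04/99", 122, 10.1, 5.4, 1.3, 87.8, 14.1),
    (12, "25/09/08", 59, 4.9, 7.6, 1.1, 100.0, 12.8),
]

#: Seasonal grouping of the Ahe wind regimes: 3, 8, 9, 11 occur mostly in
#: austral winter (Jun-Oct); 2, 4, 5, 6 in austral summer (Nov-May);
#: 1, 7, 10, 12 recur all year (transition).
AHE_SEASON_OF_REGIME = {
    1: "transition", 2: "summer", 3: "winter", 4: "summer",
    5: "summer", 6: "summer", 7: "transition", 8: "winter",
    9: "winter", 10: "transition", 11: "winter", 12: "transition",
}


def ahe_wind_regime_table() -> pd.DataFrame:
    """The 12-regime trade-wind climatology for Ahe (1979-2011).

    Columns: reference sequence start date, member count over the 1203
    classified sequences, occurrence probability (%), wind speed mean/SD
    (m/s), wind direction mean/SD (degrees coming-from), season label.
    """
    df = pd.DataFrame(
        _REGIMES,
        columns=["regime", "start_date", "n_sequences", "probability_pct",
                 "speed_mean", "speed_sd", "direction_mean", "direction_sd"],
    ).set_index("regime")
    df["season"] = pd.Series(AHE_SEASON_OF_REGIME)
    return df


def ahe_regime_specs() -> list[RegimeSpec]:
    """Regime specifications for the synthetic wind generator.

    Speed/direction statistics follow the Ahe climatology table; the
    monthly occurrence weights concentrate each regime's probability
    mass in its season (winter regimes in Jun-Oct, summer regimes in
    Nov-May, transition regimes spread uniformly), scaled so overall
    regime shares match the climatological occurrence probabilities.
    """
    specs = []
    for rid, _sd, _n, prob, sp_m, sp_sd, dir_m, dir_sd in _REGIMES:
        season = AHE_SEASON_OF_REGIME[rid]
        if season == "winter":
            months = set(WINTER_MONTHS)
        elif season == "summer":
            months = set(SUMMER_MONTHS)
        else:
            months = set(range(1, 13))
        w = np.array([prob if (m in months) else 0.05 * prob for m in range(1, 13)])
        specs.append(RegimeSpec(mean_speed=sp_m, mean_direction=dir_m,
                                speed_sd=sp_sd, direction_sd=min(dir_sd, 45.0),
                                monthly_weights=tuple(w)))
    return specs
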