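"""Published national lifetime-risk estimates, for the reporting layer.

These are the printed life-table lifetime-risk columns (percent, one
decimal) from the national English analysis of 2016-2019 hospital-episode
data, by sex and event definition, plus the headline pre-pandemic vs
pandemic (2020) values.  They serve as inputs to the descriptive helpers
(largest between-epoch increase, sex difference, relative pandemic change)
— the package recomputes those contrasts from these columns rather than
hard-coding them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["england_lifetime_risk_2016_2019", "england_pandemic_headline"]

_BANDS = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85-89", "90+",
]

_MEN_FIRST = [3.1, 5.1, 7.1, 9.4, 11.8, 14.3, 16.8, 19.4, 22.0, 24.9, 28.1,
              31.7, 35.8, 40.2, 44.8, 49.4, 53.5, 56.9, 59.1]
_MEN_ALL = [4.5, 7.3, 10.0, 13.0, 16.2, 19.6, 23.1, 26.7, 30.5, 34.8, 39.6,
            45.2, 51.5, 58.1, 64.5, 70.5, 75.1, 78.3, 80.0]
_WOMEN_FIRST = [2.1, 3.6, 5.1, 7.4, 10.8, 15.4, 20.2, 24.3, 27.5, 30.6, 33.7,
                36.9, 40.3, 43.9, 47.8, 51.8, 55.4, 58.3, 60.2]
_WOMEN_ALL = [3.1, 5.2, 7.3, 10.3, 15.1, 21.3, 27.9, 33.6, 38.2, 42.8, 47.5,
              52.1, 56.9, 61.9, 66.9, 71.6, 75.4, 78.1, 79.5]


def england_lifetime_risk_2016_2019() -> pd.DataFrame:
    """Cumulative lifetime risk (%) by age band, sex and event definition.

    Life-table method, England 2016-2019, values as printed to one decimal.
    Columns: band, plus one column per (sex, definition).
    """
    return pd.DataFrame(
        {
            "band": _BANDS,
            "M_first": _MEN_FIRST,
            "M_all": _MEN_ALL,
            "F_first": _WOMEN_FIRST,
            "F_all": _WOMEN_ALL,
        }
    )


def england_pandemic_headline() -> pd.DataFrame:
    """Headline lifetime risks (%) pre-pandemic (2016-2019) vs pandemic (2020)."""
    rows = [
        ("F", "first", 60.2, 40.8),
        ("M", "first", 59.1, 40.4),
        ("F", "all", 79.5, 72.2),
        ("M", "all", 80.0, 75.4),
    ]
    return pd.DataFrame(rows, columns=["sex", "event_definition", "pre", "post"])
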