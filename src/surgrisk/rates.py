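"""Age- and sex-specific incidence and mortality rates per person-year.

Counts become rates by dividing pooled events (or deaths) by pooled
person-years over the requested calendar years.  Person-years use the
standard demographic approximation mid-year population x 1 year.  Rates
for a multi-year period are pooled (sum of events / sum of person-years),
not averages of yearly rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .registry_io import (
    AgeBandSchema,
    EventTable,
    MortalityTable,
    PopulationTable,
    SEXES,
)

__all__ = ["RateTable", "person_years", "incidence_rates", "mortality_rates", "build_rate_table"]

RATE_COLUMNS = [
    "period",
    "sex",
    "band",
    "event_definition",
    "person_years",
    "incidence_rate",
    "mortality_rate",
]


@dataclass(frozen=True)
class RateTable:
    """Per (sex, band): person-years, surgery incidence rate and all-cause
    mortality rate, for one period and one event definition (first/all)."""

    data: pd.DataFrame
    schema: AgeBandSchema

    def __post_init__(self) -> None:
        missing = [c for c in RATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"rate table missing column(s) {missing}")
        for col in ("person_years", "incidence_rate", "mortality_rate"):
            if (self.data[col] < 0).any():
                raise ValueError(f"negative {col} in rate table")
        dup = self.data.duplicated(subset=["period", "sex", "band", "event_definition"])
        if dup.any():
            raise ValueError("duplicate (period, sex, band, event_definition) row")

    def for_stratum(self, sex: str, period: str | None = None) -> pd.DataFrame:
        """Rows for one sex (and period), ordered by the schema's bands."""
        df = self.data[self.data["sex"] == sex]
        if period is not None:
            df = df[df["period"] == period]
        order = {b: i for i, b in enumerate(self.schema.labels)}
        return df.sort_values("band", key=lambda s: s.map(order)).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data[RATE_COLUMNS].to_csv(path, index=False)


def person_years(population: PopulationTable, years: list[int]) -> pd.DataFrame:
    """Person-years per (sex, band): sum of mid-year populations x 1 year.

    Additive over disjoint year sets.  A requested year absent from the
    table is an error.
    """
    df = population.data
    present = set(df["year"])
    missing = [y for y in years if y not in present]
    if missing:
        raise ValueError(f"population table has no rows for year(s) {missing}")
    sub = df[df["year"].isin(list(years))]
    out = sub.groupby(["sex", "band"], as_index=False)["midyear_population"].sum()
    return out.rename(columns={"midyear_population": "person_years"})


def _rate_from_counts(
    counts: pd.DataFrame, count_col: str, py: pd.DataFrame, what: str
) -> pd.DataFrame:
    merged = py.merge(counts, on=["sex", "band"], how="left")
    merged[count_col] = merged[count_col].fillna(0)
    zero_py = merged["person_years"] == 0
    if (zero_py & (merged[count_col] > 0)).any():
        row = merged[zero_py & (merged[count_col] > 0)].iloc[0]
        raise ValueError(
            f"{what}: {int(row[count_col])} events with zero person-years "
            f"in stratum ({row['sex']}, {row['band']})"
        )
    if zero_py.any():
        warnings.warn(f"{what}: zero person-years in some strata; rate set to 0")
    merged["rate"] = 0.0
    nz = ~zero_py
    merged.loc[nz, "rate"] = merged.loc[nz, count_col] / merged.loc[nz, "person_years"]
    return merged[["sex", "band", "person_years", "rate"]]


def incidence_rates(
    events: EventTable,
    py: pd.DataFrame,
    event_definition: str,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Surgery incidence per person-year per (sex, band).

    ``event_definition="first"`` uses first-surgery counts, ``"all"`` every
    procedure; counts are pooled over years and categories.
    """
    if event_definition not in ("first", "all"):
        raise ValueError("event_definition must be 'first' or 'all'")
    col = "first_events" if event_definition == "first" else "all_events"
    counts = events.totals(years)[["sex", "band", col]]
    out = _rate_from_counts(counts, col, py, "incidence")
    return out.rename(columns={"rate": "incidence_rate"})


def mortality_rates(
    deaths: MortalityTable, py: pd.DataFrame, years: list[int] | None = None
) -> pd.DataFrame:
    """All-cause mortality per person-year per (sex, band)."""
    counts = deaths.totals(years)[["sex", "band", "deaths"]]
    out = _rate_from_counts(counts, "deaths", py, "mortality")
    return out.rename(columns={"rate": "mortality_rate"})


def build_rate_table(
    events: EventTable,
    population: PopulationTable,
    deaths: MortalityTable,
    years: list[int],
    event_definition: str,
    period: str | None = None,
    schema: AgeBandSchema | None = None,
) -> RateTable:
    """Assemble the full RateTable for one period and event definition."""
    schema = schema or population.schema
    period = period or (f"{min(years)}-{max(years)}" if len(years) > 1 else str(years[0]))
    py = person_years(population, years)
    inc = incidence_rates(events, py, event_definition, years)
    mor = mortality_rates(deaths, py, years)
    df = inc.merge(mor[["sex", "band", "mortality_rate"]], on=["sex", "band"])
    df["period"] = period
    df["event_definition"] = event_definition
    return RateTable(df[RATE_COLUMNS], schema)
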