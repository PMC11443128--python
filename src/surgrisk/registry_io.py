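"""Domain tables, CSV readers/writers, grid validation and the event filter.

The analysis runs on three stratified count tables — surgical events,
mid-year population, and all-cause deaths — indexed by calendar year, sex
and 5-year age band.  Everything downstream (rates, life tables, period
comparisons) consumes these containers, so their invariants are enforced
eagerly at construction time.

File dialect: comma-separated UTF-8 with one header row and fixed column
names (see ``EVENT_COLUMNS`` etc.).  Sex is a two-level factor ``F``/``M``;
any other coding is rejected at parse time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "OPEN",
    "AgeBand",
    "AgeBandSchema",
    "EventTable",
    "PopulationTable",
    "MortalityTable",
    "ValidationIssue",
    "ValidationReport",
    "ParseError",
    "read_tables",
    "validate_grid",
    "filter_events",
]

SEXES = ("F", "M")

#: sentinel width for the final, open-ended age band
OPEN = None

EVENT_COLUMNS = ["year", "sex", "band", "category", "all_events", "first_events"]
POPULATION_COLUMNS = ["year", "sex", "band", "midyear_population"]
MORTALITY_COLUMNS = ["year", "sex", "band", "deaths"]


class ParseError(ValueError):
    """Raised when an input file violates the documented format or an invariant."""


# ---------------------------------------------------------------------------
# Age-band schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeBand:
    """One age band [lower, lower+width) in whole years; width ``OPEN`` means [lower, inf)."""

    label: str
    lower: int
    width: int | None  # None (OPEN) only for the final band


@dataclass(frozen=True)
class AgeBandSchema:
    """Ordered, contiguous 5-year age epochs — the coordinate system of every table.

    The default is the 19 epochs 0-4, 5-9, ..., 85-89, 90+ conventionally
    used for abridged life tables of national data.
    """

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("schema needs at least one band")
        if self.bands[0].lower != 0:
            raise ValueError("bands must start at age 0")
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.width is OPEN:
                raise ValueError("only the final band may be open-ended")
            if prev.lower + prev.width != nxt.lower:
                raise ValueError(
                    f"bands {prev.label!r} and {nxt.label!r} are not contiguous"
                )
            if prev.width <= 0:
                raise ValueError(f"band {prev.label!r} has non-positive width")
        if self.bands[-1].width is not OPEN:
            raise ValueError("the final band must be open-ended")

    @classmethod
    def default(cls) -> "AgeBandSchema":
        bands = [AgeBand(f"{lo}-{lo + 4}", lo, 5) for lo in range(0, 90, 5)]
        bands.append(AgeBand("90+", 90, OPEN))
        return cls(tuple(bands))

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def widths(self) -> list[int | None]:
        return [b.width for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown band label {label!r}") from None


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def _check_bands(df: pd.DataFrame, schema: AgeBandSchema, source: str) -> None:
    unknown = set(df["band"]) - set(schema.labels)
    if unknown:
        raise ParseError(f"{source}: unknown band label(s) {sorted(unknown)}")


def _check_sex(df: pd.DataFrame, source: str) -> None:
    bad = set(df["sex"]) - set(SEXES)
    if bad:
        raise ParseError(f"{source}: sex must be one of {SEXES}, got {sorted(bad)}")


def _check_nonneg(df: pd.DataFrame, cols: Iterable[str], source: str) -> None:
    for c in cols:
        if (df[c] < 0).any():
            row = df.index[df[c] < 0][0]
            raise ParseError(f"{source}: negative {c} at row {row}")


def _check_unique(df: pd.DataFrame, keys: list[str], source: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise ParseError(f"{source}: duplicate stratum {first}")


@dataclass(frozen=True)
class EventTable:
    """Surgical event counts per (year, sex, band, category).

    ``all_events`` counts every procedure (a patient may recur within a
    stratum); ``first_events`` counts only each patient's first-ever
    documented surgery, so ``first_events <= all_events`` row-wise.  The
    ``category`` tag (default ``"other"``) exists so that obstetric
    procedures can be excluded in the sensitivity analysis.
    """

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"events: missing column(s) {missing}")
        _check_sex(df, "events")
        _check_bands(df, self.schema, "events")
        _check_nonneg(df, ["all_events", "first_events"], "events")
        bad = df["first_events"] > df["all_events"]
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(f"events: first_events exceeds all_events at row {row}")
        _check_unique(df, ["year", "sex", "band", "category"], "events")

    @property
    def categories(self) -> set[str]:
        return set(self.data["category"])

    def totals(
        self, years: Sequence[int] | None = None
    ) -> pd.DataFrame:
        """Sum counts over years and categories -> one row per (sex, band)."""
        df = self.data
        if years is not None:
            df = df[df["year"].isin(list(years))]
        return (
            df.groupby(["sex", "band"], as_index=False)[["all_events", "first_events"]]
            .sum()
        )

    def to_csv(self, path: str | Path) -> None:
        self.data[EVENT_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class PopulationTable:
    """Mid-year population per (year, sex, band); the exposure denominator."""

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"population: missing column(s) {missing}")
        _check_sex(df, "population")
        _check_bands(df, self.schema, "population")
        _check_nonneg(df, ["midyear_population"], "population")
        _check_unique(df, ["year", "sex", "band"], "population")

    def to_csv(self, path: str | Path) -> None:
        self.data[POPULATION_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class MortalityTable:
    """All-cause death counts per (year, sex, band)."""

    data: pd.DataFrame
    schema: AgeBandSchema = field(default_factory=AgeBandSchema.default)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"deaths: missing column(s) {missing}")
        _check_sex(df, "deaths")
        _check_bands(df, self.schema, "deaths")
        _check_nonneg(df, ["deaths"], "deaths")
        _check_unique(df, ["year", "sex", "band"], "deaths")

    def totals(self, years: Sequence[int] | None = None) -> pd.DataFrame:
        df = self.data
        if years is not None:
            df = df[df["year"].isin(list(years))]
        return df.groupby(["sex", "band"], as_index=False)[["deaths"]].sum()

    def to_csv(self, path: str | Path) -> None:
        self.data[MORTALITY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    stratum: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "ok: no issues"
        lines = [f"{'ok' if self.ok else 'FAILED'}: {len(self.issues)} issue(s)"]
        lines += [f"  [{i.severity}] {i.stratum}: {i.message}" for i in self.issues]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "issues": [
                    {"severity": i.severity, "stratum": i.stratum, "message": i.message}
                    for i in self.issues
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, columns: list[str], source: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{source}: file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"sex": str, "band": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{source}: cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: {path} missing column(s) {missing}")
    return df


def read_tables(
    events_path: str | Path,
    population_path: str | Path,
    deaths_path: str | Path,
    schema: AgeBandSchema | None = None,
) -> tuple[EventTable, PopulationTable, MortalityTable, ValidationReport]:
    """Parse the three input CSVs and resolve band labels against *schema*.

    Returns the parsed tables plus a light report (currently only a
    ``"no strata"`` warning for header-only files); structural violations
    raise :class:`ParseError` naming file and field.
    """
    schema = schema or AgeBandSchema.default()
    ev = _read_csv(events_path, EVENT_COLUMNS, "events")
    if "category" in ev.columns:
        ev["category"] = ev["category"].fillna("other")
    po = _read_csv(population_path, POPULATION_COLUMNS, "population")
    de = _read_csv(deaths_path, MORTALITY_COLUMNS, "deaths")
    events = EventTable(ev, schema)
    population = PopulationTable(po, schema)
    deaths = MortalityTable(de, schema)
    issues = []
    for name, df in (("events", ev), ("population", po), ("deaths", de)):
        if df.empty:
            issues.append(ValidationIssue("warning", name, "no strata"))
    return events, population, deaths, ValidationReport(tuple(issues))


def validate_grid(
    events: EventTable,
    population: PopulationTable,
    deaths: MortalityTable,
    years: Sequence[int],
) -> ValidationReport:
    """Check that every (year, sex, band) stratum is present in every table.

    Missing strata and strata with events but zero population are reported
    as errors; nothing raises — findings accumulate in the report.
    """
    schema = population.schema
    issues: list[ValidationIssue] = []
    expected = {
        (y, s, b) for y in years for s in SEXES for b in schema.labels
    }

    ev_present = set(
        map(tuple, events.data.groupby(["year", "sex", "band"]).size().index)
    )
    po_present = set(map(tuple, population.data[["year", "sex", "band"]].itertuples(index=False)))
    de_present = set(map(tuple, deaths.data[["year", "sex", "band"]].itertuples(index=False)))

    for name, present in (
        ("events", ev_present),
        ("population", po_present),
        ("deaths", de_present),
    ):
        for stratum in sorted(expected - present, key=str):
            issues.append(
                ValidationIssue("error", f"{name} {stratum}", "missing stratum")
            )

    # events recorded where nobody lives
    pop_idx = population.data.set_index(["year", "sex", "band"])["midyear_population"]
    ev_sum = events.data.groupby(["year", "sex", "band"])["all_events"].sum()
    for stratum, n_events in ev_sum.items():
        if n_events > 0 and stratum in pop_idx.index and pop_idx[stratum] == 0:
            issues.append(
                ValidationIssue(
                    "error", f"events {stratum}", "events without population"
                )
            )
    return ValidationReport(tuple(issues))


def filter_events(events: EventTable, exclude_categories: set[str]) -> EventTable:
    """Drop event rows whose category is excluded (the sensitivity analysis).

    Retained rows are unchanged; applying the same exclusion twice is a
    no-op.  Unknown categories in *exclude_categories* are rejected.
    """
    if not exclude_categories:
        return events
    keep = ~events.data["category"].isin(list(exclude_categories))
    return EventTable(events.data[keep].reset_index(drop=True), events.schema)
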