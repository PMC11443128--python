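"""End-to-end analysis: configuration, orchestration, and report outputs.

``run_analysis`` stitches the stages together: read and validate the three
input tables, compute rates, build per-year life tables (or cumulative
incidences), average the pre-period years, bootstrap the post-period CI,
and compare the periods — writing ``rates.csv``, per-stratum
``lifetable_*.csv``, a Table-1-shaped ``estimates.csv`` and, when a post
period is configured, ``comparison.json``.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inference import average_years, compare_periods, round_half_up, single_year_ci
from .rates import build_rate_table
from .registry_io import AgeBandSchema, SEXES, filter_events, read_tables, validate_grid
from .risk_methods import (
    DEFAULT_FINAL_BAND_WIDTH,
    DEFAULT_RADIX,
    build_life_table,
    cumulative_incidence,
    lifetime_risk_lifetable,
)

__all__ = ["AnalysisConfig", "AnalysisError", "run_analysis"]

log = logging.getLogger("surgrisk")


class AnalysisError(RuntimeError):
    """Raised when inputs fail validation; no partial outputs are written."""


@dataclass
class AnalysisConfig:
    """Everything `run_analysis` needs; mirrors the CLI flags and YAML keys.

    Defaults follow the study design: pre-period 2016-2019 averaged yearly
    estimates, optional single-year 2020 post period.
    """

    events_path: str
    population_path: str
    deaths_path: str
    out_dir: str
    pre_years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    post_years: tuple[int, ...] = ()
    methods: tuple[str, ...] = ("lifetable", "cumulative")
    event_definitions: tuple[str, ...] = ("first", "all")
    exclude_categories: tuple[str, ...] = ()
    final_band_width: float = DEFAULT_FINAL_BAND_WIDTH
    radix: float = DEFAULT_RADIX
    level: float = 0.95
    seed: int = 0
    reps: int = 5000

    def __post_init__(self) -> None:
        if not self.pre_years:
            raise ValueError("pre-period years must be non-empty")
        if set(self.pre_years) & set(self.post_years):
            raise ValueError("pre and post year sets must be disjoint")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        for m in self.methods:
            if m not in ("lifetable", "cumulative"):
                raise ValueError(f"unknown method {m!r}")
        for d in self.event_definitions:
            if d not in ("first", "all"):
                raise ValueError(f"unknown event definition {d!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("pre_years", "post_years", "methods", "event_definitions", "exclude_categories"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _yearly_estimates(events, population, deaths, years, schema, method,
                      event_definition, final_band_width, radix):
    out = {s: [] for s in SEXES}
    for year in years:
        rates = build_rate_table(events, population, deaths, [year],
                                 event_definition, schema=schema)
        for sex in SEXES:
            if method == "lifetable":
                lt = build_life_table(rates, schema, radix=radix, sex=sex)
                est = lifetime_risk_lifetable(lt, sex=sex, period=str(year),
                                              event_definition=event_definition)
            else:
                est = cumulative_incidence(rates, schema, final_band_width,
                                           sex=sex, period=str(year),
                                           event_definition=event_definition)
            out[sex].append(est)
    return out


def run_analysis(config: AnalysisConfig, schema: AgeBandSchema | None = None) -> dict:
    """Run the configured analysis and write the report bundle.

    Returns a dict with the estimates and comparisons keyed by
    (sex, method, event_definition).  Validation failure raises
    :class:`AnalysisError` before anything is written.
    """
    schema = schema or AgeBandSchema.default()
    events, population, deaths, report = read_tables(
        config.events_path, config.population_path, config.deaths_path, schema
    )
    all_years = list(config.pre_years) + list(config.post_years)
    grid = validate_grid(events, population, deaths, all_years)
    if not grid.ok:
        raise AnalysisError(f"input validation failed:\n{grid}")
    if config.exclude_categories:
        events = filter_events(events, set(config.exclude_categories))
        log.info("excluded categories: %s", sorted(config.exclude_categories))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("analysis config: %s", config)

    results: dict = {"estimates": {}, "comparisons": {}}
    est_rows = []
    rate_frames = []
    for method in config.methods:
        for event_def in config.event_definitions:
            rates_pre = build_rate_table(events, population, deaths,
                                         list(config.pre_years), event_def,
                                         schema=schema)
            rate_frames.append(rates_pre.data)
            yearly = _yearly_estimates(events, population, deaths,
                                       config.pre_years, schema, method,
                                       event_def, config.final_band_width,
                                       config.radix)
            for sex in SEXES:
                if len(config.pre_years) > 1:
                    pre_est = average_years(yearly[sex], config.level)
                else:
                    pre_est = single_year_ci(
                        events, population, deaths, config.pre_years[0], sex,
                        schema, method, event_def, config.final_band_width,
                        config.level, config.reps, config.seed,
                    )
                results["estimates"][(sex, method, event_def, "pre")] = pre_est
                if method == "lifetable":
                    lt = build_life_table(rates_pre, schema, radix=config.radix, sex=sex)
                    lt.to_csv(out_dir / f"lifetable_{sex}_{event_def}_pre.csv")
                for band, risk in pre_est.risk_by_age.items():
                    est_rows.append({
                        "period": pre_est.period, "sex": sex, "method": method,
                        "event_definition": event_def, "band": band,
                        "risk_pct": round_half_up(float(risk), 1),
                    })
                if config.post_years:
                    if len(config.post_years) == 1:
                        post_est = single_year_ci(
                            events, population, deaths, config.post_years[0],
                            sex, schema, method, event_def,
                            config.final_band_width, config.level,
                            config.reps, config.seed,
                        )
                    else:
                        post_yearly = _yearly_estimates(
                            events, population, deaths, config.post_years,
                            schema, method, event_def,
                            config.final_band_width, config.radix,
                        )
                        post_est = average_years(post_yearly[sex], config.level)
                    comp = compare_periods(pre_est, post_est)
                    results["estimates"][(sex, method, event_def, "post")] = post_est
                    results["comparisons"][(sex, method, event_def)] = comp

    pd.concat(rate_frames, ignore_index=True).drop_duplicates().to_csv(
        out_dir / "rates.csv", index=False
    )
    pd.DataFrame(est_rows).to_csv(out_dir / "estimates.csv", index=False)
    if results["comparisons"]:
        payload = {
            "seed": config.seed,
            "reps": config.reps,
            "level": config.level,
            "pre_years": list(config.pre_years),
            "post_years": list(config.post_years),
            "comparisons": [
                {"sex": k[0], "method": k[1], "event_definition": k[2], **c.to_dict()}
                for k, c in results["comparisons"].items()
            ],
        }
        (out_dir / "comparison.json").write_text(json.dumps(payload, indent=2))
    log.info("wrote outputs to %s", out_dir)
    return results


def configure_logging(level: str = "INFO") -> None:
    """Log to stderr only, keeping stdout clean for machine output."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
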