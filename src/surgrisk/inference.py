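"""Confidence intervals, multi-year averaging, and the period comparison.

Three uncertainty mechanisms are implemented:

* ``average_years`` — the multi-year (e.g. 2016-2019) estimate is the mean
  of the yearly lifetime risks, with a t-interval on k yearly replicates
  (k-1 degrees of freedom; k is small, so the t quantile matters).
* ``single_year_ci`` — a single year has no between-year dispersion, so
  its CI comes from a parametric bootstrap: event and death counts are
  independently redrawn as Poisson with the observed means, the lifetime
  risk recomputed each time, and the percentile interval taken.
* ``compare_periods`` — pre- vs pandemic-period comparison: absolute and
  relative change, CI overlap, and a two-sided paired t-test pairing the
  per-age-band cumulative risks (19 pairs under the default schema).

Descriptive helpers (``max_successive_increase``, ``sex_difference``)
reproduce the between-epoch and between-sex contrasts reported alongside
the headline risks.  Presentation rounding is round-half-up, applied only
at the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import AgeBandSchema, EventTable, MortalityTable, PopulationTable
from .rates import build_rate_table
from .risk_methods import (
    DEFAULT_FINAL_BAND_WIDTH,
    LifetimeRiskEstimate,
    build_life_table,
    cumulative_incidence,
    cumulative_risk_from_hazards,
    lifetime_risk_from_hazards,
    lifetime_risk_lifetable,
)

__all__ = [
    "PeriodComparison",
    "average_years",
    "single_year_ci",
    "compare_periods",
    "max_successive_increase",
    "sex_difference",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PeriodComparison:
    """Pre- vs post-period contrast of two lifetime-risk estimates."""

    pre: LifetimeRiskEstimate
    post: LifetimeRiskEstimate
    absolute_change: float  # percentage points, pre - post
    relative_change: float | None  # percent of the pre value
    ci_overlap: bool | None
    t_statistic: float
    p_value: float
    pairing_unit: str = "age band"

    def to_dict(self) -> dict:
        return {
            "pre_value": self.pre.value,
            "post_value": self.post.value,
            "absolute_change": self.absolute_change,
            "relative_change": self.relative_change,
            "ci_overlap": self.ci_overlap,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "pairing_unit": self.pairing_unit,
            "method": self.pre.method,
            "event_definition": self.pre.event_definition,
            "sex": self.pre.sex,
            "periods": [self.pre.period, self.post.period],
        }


def average_years(
    yearly: list[LifetimeRiskEstimate], level: float = 0.95
) -> LifetimeRiskEstimate:
    """Average k yearly estimates; CI = mean +/- t_{(1+level)/2, k-1} * SD/sqrt(k).

    The per-band risk curve is averaged bandwise the same way.  Requires at
    least two years (a single year has no dispersion; use
    :func:`single_year_ci` instead).
    """
    if len(yearly) < 2:
        raise ValueError("need at least two yearly estimates to average")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    first = yearly[0]
    for est in yearly[1:]:
        if (est.sex, est.method, est.event_definition) != (
            first.sex,
            first.method,
            first.event_definition,
        ):
            raise ValueError("yearly estimates must share sex, method and event definition")
    k = len(yearly)
    values = np.array([e.value for e in yearly])
    tq = stats.t.ppf(0.5 * (1 + level), k - 1)
    mean = float(values.mean())
    half = float(tq * values.std(ddof=1) / np.sqrt(k))
    curves = pd.concat([e.risk_by_age for e in yearly], axis=1)
    period = f"{min(e.period for e in yearly)}-{max(e.period for e in yearly)}"
    return LifetimeRiskEstimate(
        value=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        method=first.method,
        event_definition=first.event_definition,
        sex=first.sex,
        period=period,
        risk_by_age=curves.mean(axis=1),
    )


def _estimate_from_rates(rates, schema, sex, method, event_definition, final_band_width):
    if method == "lifetable":
        lt = build_life_table(rates, schema, sex=sex)
        return lifetime_risk_lifetable(
            lt, sex=sex, period=rates.data["period"].iloc[0],
            event_definition=event_definition,
        )
    if method == "cumulative":
        return cumulative_incidence(
            rates, schema, final_band_width=final_band_width, sex=sex,
            event_definition=event_definition,
        )
    raise ValueError("method must be 'lifetable' or 'cumulative'")


def single_year_ci(
    events: EventTable,
    population: PopulationTable,
    deaths: MortalityTable,
    year: int,
    sex: str,
    schema: AgeBandSchema | None = None,
    method: str = "lifetable",
    event_definition: str = "first",
    final_band_width: float = DEFAULT_FINAL_BAND_WIDTH,
    level: float = 0.95,
    reps: int = 5000,
    seed: int = 0,
) -> LifetimeRiskEstimate:
    """Point estimate plus parametric-bootstrap CI for one calendar year.

    Event and death counts in every stratum are independently redrawn as
    Poisson with the observed counts as means (person-years held fixed),
    the lifetime risk recomputed *reps* times, and the percentile interval
    at *level* returned.  Deterministic for a given *seed*.
    """
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    schema = schema or population.schema
    rates = build_rate_table(events, population, deaths, [year], event_definition, schema=schema)
    point = _estimate_from_rates(rates, schema, sex, method, event_definition, final_band_width)

    sub = rates.for_stratum(sex)
    py = sub["person_years"].to_numpy(dtype=float)
    ev_mean = sub["incidence_rate"].to_numpy(dtype=float) * py
    de_mean = sub["mortality_rate"].to_numpy(dtype=float) * py
    if ev_mean.sum() == 0 and de_mean.sum() == 0:
        warnings.warn("all counts are zero: degenerate CI (0, 0)")
        return point.with_ci(0.0, 0.0)

    rng = np.random.default_rng(seed)
    safe_py = np.where(py > 0, py, 1.0)
    widths = np.array(
        [b.width if b.width is not None else np.inf for b in schema.bands], dtype=float
    )
    lam = rng.poisson(ev_mean, size=(reps, len(ev_mean))) / safe_py
    mu = rng.poisson(de_mean, size=(reps, len(de_mean))) / safe_py
    if method == "lifetable":
        draws = 100.0 * lifetime_risk_from_hazards(lam, mu, widths)
    else:
        finite = np.where(np.isinf(widths), final_band_width, widths)
        draws = 100.0 * cumulative_risk_from_hazards(lam, finite)
    alpha = 1 - level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return point.with_ci(min(float(lo), point.value), max(float(hi), point.value))


def compare_periods(
    pre: LifetimeRiskEstimate, post: LifetimeRiskEstimate
) -> PeriodComparison:
    """Contrast two period estimates sharing sex, method and event definition.

    The paired t-test pairs the per-band cumulative risks (one pair per
    age band); CI overlap is reported when both estimates carry intervals.
    """
    for attr in ("sex", "method", "event_definition"):
        if getattr(pre, attr) != getattr(post, attr):
            raise ValueError(f"estimates differ in {attr}")
    if not pre.risk_by_age.index.equals(post.risk_by_age.index):
        raise ValueError("estimates use different band schemas")

    absolute = pre.value - post.value
    relative = 100.0 * absolute / pre.value if pre.value > 0 else None

    diffs = pre.risk_by_age.to_numpy() - post.risk_by_age.to_numpy()
    if diffs.size < 2 or np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            t_stat, p_val = 0.0, 1.0
        else:
            warnings.warn("zero-variance nonzero differences: t undefined, p set by sign")
            t_stat = np.inf if diffs.mean() > 0 else -np.inf
            p_val = 0.0
    else:
        res = stats.ttest_rel(pre.risk_by_age.to_numpy(), post.risk_by_age.to_numpy())
        t_stat, p_val = float(res.statistic), float(res.pvalue)

    overlap = None
    if pre.ci_low is not None and post.ci_low is not None:
        overlap = pre.ci_low <= post.ci_high and post.ci_low <= pre.ci_high
    return PeriodComparison(
        pre=pre,
        post=post,
        absolute_change=absolute,
        relative_change=relative,
        ci_overlap=overlap,
        t_statistic=t_stat,
        p_value=p_val,
    )


def max_successive_increase(
    risk_by_age: pd.Series, schema: AgeBandSchema | None = None
) -> tuple[str, str, float]:
    """Largest increase in cumulative risk between consecutive age bands.

    Returns ``(from_band, to_band, increase_in_points)``.  Ties (within a
    hair of floating-point noise) are broken toward the older epoch pair.
    """
    if len(risk_by_age) < 2:
        raise ValueError("need at least two bands")
    diffs = np.diff(risk_by_age.to_numpy(dtype=float))
    best = diffs.max()
    tied = np.isclose(diffs, best, rtol=0.0, atol=1e-9)
    idx = int(np.nonzero(tied)[0][-1])  # oldest pair among ties
    labels = list(risk_by_age.index)
    return labels[idx], labels[idx + 1], float(diffs[idx])


def sex_difference(
    f: LifetimeRiskEstimate, m: LifetimeRiskEstimate, band: str
) -> float:
    """Female minus male cumulative risk (percentage points) at one band."""
    for attr in ("method", "event_definition", "period"):
        if getattr(f, attr) != getattr(m, attr):
            raise ValueError(f"estimates differ in {attr}")
    if band not in f.risk_by_age.index or band not in m.risk_by_age.index:
        raise KeyError(f"band {band!r} absent from risk_by_age")
    return float(f.risk_by_age[band] - m.risk_by_age[band])
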