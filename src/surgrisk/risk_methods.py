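"""The two lifetime-risk estimators.

Lifetime risk is the probability that a newborn experiences a first event
(here: surgery) before death, under current age-specific rates.

*Life-table method* (primary).  Within each age band the surgery hazard
``lambda`` and all-cause mortality hazard ``mu`` are taken constant, so
waiting times are exponential and death acts as a competing risk.  With
total hazard ``h = lambda + mu`` over a band of width ``n`` years, the
probability of a first event within the band for someone entering it
event-free is

    a = (lambda / h) * (1 - exp(-h * n)),

the probability of reaching the next band event-free is ``s = exp(-h n)``,
and for the open-ended final band the cohort is followed to extinction:
``a = lambda / h``, ``s = 0``.  The life table accumulates expected first
events ``d_x = l_x * a_x`` down the age bands; lifetime risk is
``sum(d_x) / l_0``.

*Cumulative-incidence method*.  Ignores mortality: lifetime risk is
``1 - exp(-sum(lambda_x * n_x))`` with the open band truncated to a finite
width (default 10 years, i.e. follow-up to about age 100).  Because it
removes the competing risk of death it never falls below the life-table
estimate.

The rate-to-probability conversion is pluggable (``conversion=``): besides
the default exponential form, a Chiang-type actuarial form
``q = n*r / (1 + n*r/2)`` is provided for sensitivity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry_io import OPEN, AgeBandSchema
from .rates import RateTable

__all__ = [
    "LifeTable",
    "LifetimeRiskEstimate",
    "band_transition",
    "build_life_table",
    "lifetime_risk_lifetable",
    "cumulative_incidence",
    "DEFAULT_RADIX",
    "DEFAULT_FINAL_BAND_WIDTH",
]

DEFAULT_RADIX = 100_000.0
DEFAULT_FINAL_BAND_WIDTH = 10.0


@dataclass(frozen=True)
class LifeTable:
    """Columns of the competing-risk (double-decrement) life table.

    Per band: ``l`` event-free survivors entering the band (radix ``l_0``),
    ``a`` conditional probability of a first event within the band, ``s``
    probability of reaching the next band alive and event-free, ``d``
    expected first events, ``cum_risk`` cumulative first-event probability.
    """

    data: pd.DataFrame  # band, l, a, s, d, cum_risk
    radix: float

    @property
    def lifetime_risk(self) -> float:
        """Cumulative first-event probability over the whole table (fraction)."""
        return float(self.data["cum_risk"].iloc[-1])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class LifetimeRiskEstimate:
    """A lifetime-risk value in percent, with optional CI and per-band curve."""

    value: float  # percent
    method: str  # "lifetable" | "cumulative"
    event_definition: str  # "first" | "all"
    sex: str
    period: str
    risk_by_age: pd.Series  # percent, indexed by band label
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("lifetime risk cannot be negative")
        if self.method == "lifetable" and self.value > 100 + 1e-9:
            raise ValueError("life-table lifetime risk cannot exceed 100%")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("provide both CI bounds or neither")
        if self.ci_low is not None and not (
            self.ci_low <= self.value + 1e-9 and self.value <= self.ci_high + 1e-9
        ):
            raise ValueError("CI must bracket the point estimate")

    def with_ci(self, low: float, high: float) -> "LifetimeRiskEstimate":
        return LifetimeRiskEstimate(
            value=self.value,
            method=self.method,
            event_definition=self.event_definition,
            sex=self.sex,
            period=self.period,
            risk_by_age=self.risk_by_age,
            ci_low=low,
            ci_high=high,
        )


# ---------------------------------------------------------------------------
# Rate -> probability conversions
# ---------------------------------------------------------------------------


def _exponential(lam: float, mu: float, n: float | None) -> tuple[float, float]:
    h = lam + mu
    if h == 0.0:
        if n is OPEN:
            warnings.warn("open band with zero total hazard: immortal event-free tail")
        return 0.0, 1.0
    if n is OPEN:
        return lam / h, 0.0
    surv = math.exp(-h * n)
    return (lam / h) * (1.0 - surv), surv


def _chiang(lam: float, mu: float, n: float | None) -> tuple[float, float]:
    # actuarial mid-interval form; open band handled as in the exponential form
    if n is OPEN:
        return _exponential(lam, mu, n)
    h = lam + mu
    if h == 0.0:
        return 0.0, 1.0
    q = n * h / (1.0 + 0.5 * n * h)
    q = min(q, 1.0)
    return (lam / h) * q, 1.0 - q


CONVERSIONS = {"exponential": _exponential, "chiang": _chiang}


def lifetime_risk_from_hazards(
    lam: np.ndarray, mu: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    """Vectorised life-table lifetime risk (fraction) from hazard arrays.

    *lam*, *mu* have bands on the last axis and may carry leading axes
    (e.g. bootstrap replicates); *widths* holds band widths in years with
    ``inf`` marking the open final band.  Uses the exponential conversion.
    """
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    h = lam + mu
    open_band = np.isinf(widths)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(h > 0, lam / np.where(h > 0, h, 1.0), 0.0)
        decay = np.exp(-h * np.where(open_band, 0.0, widths))
    a = np.where(open_band, frac, frac * (1.0 - decay))
    s = np.where(open_band, 0.0, decay)
    # survival to the start of each band: shifted cumulative product of s
    S = np.cumprod(s, axis=-1)
    S = np.concatenate(
        [np.ones_like(S[..., :1]), S[..., :-1]], axis=-1
    )
    return (S * a).sum(axis=-1)


def cumulative_risk_from_hazards(lam: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Vectorised cumulative-incidence lifetime risk (fraction); *widths*
    must already be finite (open band truncated)."""
    lam = np.asarray(lam, dtype=float)
    return 1.0 - np.exp(-(lam * widths).sum(axis=-1))


def band_transition(
    lam: float, mu: float, n: float | None, conversion: str = "exponential"
) -> tuple[float, float]:
    """Convert band hazards to (event probability a, survival probability s).

    ``n`` is the band width in years, or ``OPEN`` for the unbounded final
    band, where the cohort is followed to extinction (``s = 0`` and
    ``a = lambda / (lambda + mu)``, the competing-exponential first-passage
    probability).
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    if n is not OPEN and n <= 0:
        raise ValueError("band width must be positive")
    return CONVERSIONS[conversion](lam, mu, n)


def build_life_table(
    rates: RateTable,
    schema: AgeBandSchema | None = None,
    radix: float = DEFAULT_RADIX,
    sex: str | None = None,
    period: str | None = None,
    conversion: str = "exponential",
) -> LifeTable:
    """Build the competing-risk life table from one sex/period's rate rows.

    *rates* must cover every band of the schema exactly once (pass ``sex=``
    / ``period=`` to select a stratum from a larger table).
    """
    schema = schema or rates.schema
    df = rates.data
    if sex is not None:
        df = df[df["sex"] == sex]
    if period is not None:
        df = df[df["period"] == period]
    by_band = df.set_index("band")
    missing = [b for b in schema.labels if b not in by_band.index]
    if missing:
        raise ValueError(f"rate table missing band(s) {missing}")
    if by_band.index.duplicated().any():
        raise ValueError("rate table has multiple rows per band; select one stratum")

    rows = []
    l = float(radix)
    cum = 0.0
    for band in schema.bands:
        lam = float(by_band.loc[band.label, "incidence_rate"])
        mu = float(by_band.loc[band.label, "mortality_rate"])
        a, s = band_transition(lam, mu, band.width, conversion)
        d = l * a
        cum += d / radix
        rows.append(
            {"band": band.label, "l": l, "a": a, "s": s, "d": d, "cum_risk": cum}
        )
        l *= s
    return LifeTable(pd.DataFrame(rows), radix)


def lifetime_risk_lifetable(
    lt: LifeTable,
    sex: str = "",
    period: str = "",
    event_definition: str = "first",
) -> LifetimeRiskEstimate:
    """Headline statistic from a life table: percent, with the per-band curve.

    Confidence intervals are not attached here; they come from the
    inference layer (multi-year averaging or count resampling).
    """
    risk_by_age = pd.Series(
        (100.0 * lt.data["cum_risk"]).to_numpy(),
        index=pd.Index(lt.data["band"], name="band"),
    )
    return LifetimeRiskEstimate(
        value=float(risk_by_age.iloc[-1]),
        method="lifetable",
        event_definition=event_definition,
        sex=sex,
        period=period,
        risk_by_age=risk_by_age,
    )


def cumulative_incidence(
    rates: RateTable,
    schema: AgeBandSchema | None = None,
    final_band_width: float = DEFAULT_FINAL_BAND_WIDTH,
    sex: str | None = None,
    period: str | None = None,
    event_definition: str = "first",
) -> LifetimeRiskEstimate:
    """Lifetime risk from incidence rates only: ``1 - exp(-sum lambda*n)``.

    The open final band is truncated to *final_band_width* years.  Because
    mortality is ignored this estimator is an upper bound on the life-table
    estimate whenever any mortality rate is positive.
    """
    if final_band_width <= 0:
        raise ValueError("final_band_width must be positive")
    schema = schema or rates.schema
    df = rates.data
    if sex is not None:
        df = df[df["sex"] == sex]
    if period is not None:
        df = df[df["period"] == period]
    by_band = df.set_index("band")
    missing = [b for b in schema.labels if b not in by_band.index]
    if missing:
        raise ValueError(f"rate table missing band(s) {missing}")

    widths = np.array(
        [b.width if b.width is not OPEN else final_band_width for b in schema.bands],
        dtype=float,
    )
    lam = by_band.loc[schema.labels, "incidence_rate"].to_numpy(dtype=float)
    cum_rate = np.cumsum(lam * widths)
    risk_by_age = pd.Series(
        100.0 * (1.0 - np.exp(-cum_rate)),
        index=pd.Index(schema.labels, name="band"),
    )
    return LifetimeRiskEstimate(
        value=float(risk_by_age.iloc[-1]),
        method="cumulative",
        event_definition=event_definition,
        sex=sex or "",
        period=period or "",
        risk_by_age=risk_by_age,
    )
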