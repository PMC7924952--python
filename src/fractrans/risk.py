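"""Individualized risk outputs.

Everything here is driven by the generator matrix of a covariate
profile: instantaneous risks (%/year), k-year transition-probability
matrices, sojourn times, cumulative mortality curves, crude incidence
rates, and the "skeletal age" translation of a mortality hazard ratio
into years of effective age lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FittedModel, StratifiedFit
from .model_core import (
    DEFAULT_STATE_SPACE,
    STATE_LABELS,
    CovariateProfile,
    ModelParameters,
    build_generator,
    sojourn_times,
    transition_probability,
)

__all__ = [
    "SkeletalAgeResult",
    "IncidenceRate",
    "resolve_params",
    "instantaneous_risk_table",
    "five_year_matrix",
    "cumulative_mortality_curve",
    "sojourn_table",
    "skeletal_age",
    "incidence_rate",
    "crude_proportion",
]

_STATE_NAMES = [STATE_LABELS[i] for i in range(1, 6)]


def resolve_params(source, profile: CovariateProfile
                   ) -> tuple[ModelParameters, FittedModel | None]:
    """Accept a ModelParameters, FittedModel or StratifiedFit."""
    if isinstance(source, StratifiedFit):
        fit = source.for_profile(profile)
        return fit.params, fit
    if isinstance(source, FittedModel):
        return source.params, source
    if isinstance(source, ModelParameters):
        return source, None
    raise TypeError(f"cannot interpret {type(source).__name__} as model parameters")


def instantaneous_risk_table(source, profile: CovariateProfile) -> pd.DataFrame:
    """Per-transition instantaneous risks (%/year) for one profile.

    When ``source`` is a fitted model, Wald 95% CIs on the log-rate
    scale (delta method over alpha and beta) are attached.
    """
    params, fit = resolve_params(source, profile)
    rows = []
    for (r, s) in params.state_space.allowed:
        q = params.intensity(r, s, profile)
        lo = hi = float("nan")
        if fit is not None and (r, s) in fit.covariance and q > 0:
            se = fit.linear_predictor_se(r, s, profile)
            lo, hi = q * math.exp(-1.96 * se), q * math.exp(1.96 * se)
        rows.append({
            "from_state": r, "to_state": s,
            "transition": f"{_STATE_NAMES[r-1]} -> {_STATE_NAMES[s-1]}",
            "risk_pct_per_year": 100.0 * q,
            "ci_low": 100.0 * lo, "ci_high": 100.0 * hi,
        })
    return pd.DataFrame(rows)


def five_year_matrix(source, profile: CovariateProfile,
                     horizon: float = 5.0) -> pd.DataFrame:
    """k-year transition-probability matrix in percent (default 5 years)."""
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if isinstance(source, np.ndarray):
        Q = source
    else:
        params, _ = resolve_params(source, profile)
        Q = build_generator(params, profile)
    P = transition_probability(Q, horizon) * 100.0
    return pd.DataFrame(P, index=_STATE_NAMES, columns=_STATE_NAMES)


def cumulative_mortality_curve(source, profile: CovariateProfile,
                               start_state: int,
                               times: np.ndarray) -> np.ndarray:
    """P(death by t | in ``start_state`` at 0) over a sorted time grid."""
    if not 1 <= start_state <= 4:
        raise ValueError("start_state must be a live state 1-4")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be sorted")
    params, _ = resolve_params(source, profile)
    Q = build_generator(params, profile)
    return np.array([transition_probability(Q, t)[start_state - 1, 4]
                     for t in times])


def sojourn_table(source, profile: CovariateProfile,
                  tscores: tuple[float, ...] = (0.0, -1.5, -2.5)) -> pd.DataFrame:
    """Expected sojourn time (years) per live state across a T-score grid."""
    cols = {}
    for t in tscores:
        p = replace(profile, fnbmd_tscore=t)
        params, _ = resolve_params(source, p)
        soj = sojourn_times(build_generator(params, p), params.state_space)
        cols[f"tscore_{t:g}"] = soj[:4]
    return pd.DataFrame(cols, index=_STATE_NAMES[:4])


@dataclass(frozen=True)
class SkeletalAgeResult:
    """Chronological age translated through a mortality hazard ratio.

    A hazard ratio ``H`` against a background in which mortality risk
    grows by a factor ``h`` (about 1.1) per year of age is equivalent to
    ``log(H)/log(h)`` years of effective age; skeletal age adds those
    years to chronological age.  ``years_lost`` is negative (years
    gained) when H < 1.
    """

    chronological_age: float
    hazard_ratio: float
    annual_growth: float
    years_lost: float
    skeletal_age: float


def skeletal_age(age: float, hazard_ratio: float,
                 annual_growth: float = 1.1) -> SkeletalAgeResult:
    """Effective ("skeletal") age implied by a mortality hazard ratio."""
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if annual_growth <= 1:
        raise ValueError("annual mortality growth h must exceed 1")
    lost = math.log(hazard_ratio) / math.log(annual_growth)
    return SkeletalAgeResult(age, hazard_ratio, annual_growth, lost, age + lost)


@dataclass(frozen=True)
class IncidenceRate:
    """Crude incidence per 1000 person-years with exact Poisson 95% CI."""

    events: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float


def incidence_rate(events: int, person_years: float) -> IncidenceRate:
    """Events per 1000 person-years with the exact (Garwood) Poisson CI."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be nonnegative")
    lo = 0.0 if events == 0 else stats.chi2.ppf(0.025, 2 * events) / 2
    hi = stats.chi2.ppf(0.975, 2 * events + 2) / 2
    scale = 1000.0 / person_years
    return IncidenceRate(events, person_years, events * scale,
                         lo * scale, hi * scale)


def crude_proportion(count: int, denominator: int,
                     ndigits: int | None = None) -> float:
    """Crude percentage ``100 * count / denominator``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    pct = 100.0 * count / denominator
    return round(pct, ndigits) if ndigits is not None else pct
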