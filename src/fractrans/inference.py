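"""Event-history likelihoods and maximum-likelihood fitting.

The observational unit is a *sojourn record*: one occupied state per
subject, with entry and exit times on the study clock and either the
destination state (exactly observed fracture or death) or censoring.
With exactly observed event times the log-likelihood factorises over
transitions into independent Poisson-regression pieces

    l_rs = sum_i [ y_i * (alpha + beta.z_i) - exp(alpha + beta.z_i) * dt_i ]

(y_i = 1 if record i ends in the r->s move, dt_i its length), which the
fitter exploits: each transition is maximised by Newton iterations with
analytic gradient and Hessian, and the observed information is block
diagonal across transitions.  A panel (interval-censored) likelihood is
also provided for data where fracture states are only seen at periodic
visits while death times remain exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ALLOWED_TRANSITIONS,
    DEFAULT_CODING,
    DEFAULT_STATE_SPACE,
    CovariateCoding,
    CovariateProfile,
    ModelParameters,
    StateSpace,
    TransitionParameters,
    build_generator,
    transition_probability,
)

__all__ = [
    "TransitionRecord",
    "EventHistoryDataset",
    "PanelDataset",
    "DataValidationError",
    "records_from_events",
    "exact_time_loglik",
    "panel_loglik",
    "closed_form_mle",
    "fit_mle",
    "FittedModel",
    "StratifiedFit",
    "hazard_ratio_table",
]


class DataValidationError(ValueError):
    """Raised when event-history data violate the model's structure."""


@dataclass(frozen=True)
class TransitionRecord:
    """One occupied state of one subject: the likelihood's unit."""

    subject_id: str
    state: int
    entry: float
    exit: float
    destination: int | None  # None = censored in `state`
    profile: CovariateProfile

    def __post_init__(self) -> None:
        if self.exit < self.entry:
            raise DataValidationError(
                f"subject {self.subject_id}: exit {self.exit} before entry {self.entry}")

    @property
    def duration(self) -> float:
        return self.exit - self.entry

    @property
    def is_event(self) -> bool:
        return self.destination is not None


class EventHistoryDataset:
    """A validated collection of sojourn records.

    Exposes the sufficient statistics of the no-covariate model:
    transition counts ``n_rs`` and per-state time at risk ``T_r``.
    """

    def __init__(self, records: Sequence[TransitionRecord],
                 state_space: StateSpace = DEFAULT_STATE_SPACE):
        self.state_space = state_space
        self.records = tuple(records)
        self._validate()

    def _validate(self) -> None:
        last: dict[str, float] = {}
        for rec in self.records:
            if rec.destination is not None and not self.state_space.is_allowed(
                    rec.state, rec.destination):
                raise DataValidationError(
                    f"subject {rec.subject_id}: disallowed transition "
                    f"{rec.state}->{rec.destination}")
            if rec.subject_id in last and rec.entry < last[rec.subject_id]:
                raise DataValidationError(
                    f"subject {rec.subject_id}: records not increasing in time")
            last[rec.subject_id] = rec.exit

    def __len__(self) -> int:
        return len(self.records)

    def transition_counts(self) -> dict[tuple[int, int], int]:
        n = {key: 0 for key in self.state_space.allowed}
        for rec in self.records:
            if rec.is_event:
                n[(rec.state, rec.destination)] += 1
        return n

    def time_at_risk(self) -> dict[int, float]:
        T: dict[int, float] = {}
        for rec in self.records:
            T[rec.state] = T.get(rec.state, 0.0) + rec.duration
        return T

    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return tuple(seen)

    def subset(self, subject_ids: Iterable[str]) -> "EventHistoryDataset":
        wanted = set(subject_ids)
        return EventHistoryDataset(
            [r for r in self.records if r.subject_id in wanted], self.state_space)

    def split_by_sex(self) -> dict[str, "EventHistoryDataset"]:
        groups: dict[str, list[TransitionRecord]] = {"F": [], "M": []}
        for rec in self.records:
            groups["M" if rec.profile.male else "F"].append(rec)
        return {sex: EventHistoryDataset(recs, self.state_space)
                for sex, recs in groups.items() if recs}


@dataclass
class PanelDataset:
    """Interval-censored observations: per-subject (time, state) snapshots.

    ``snapshots`` maps subject id -> ordered list of (time, state);
    ``profiles`` maps subject id -> baseline covariate profile.  Death
    times are exact; the state path between visits is unknown.
    """

    snapshots: dict[str, list[tuple[float, int]]]
    profiles: dict[str, CovariateProfile]
    state_space: StateSpace = field(default_factory=StateSpace)


# ---------------------------------------------------------------------------
# building records from long-format event tables


_PROFILE_COLUMNS = {
    "tscore": "fnbmd_tscore", "bmi": "bmi", "falls": "fall_history",
    "prior_fx": "prior_fracture", "cvd": "cardiovascular", "cancer": "cancer",
    "neuro": "neurological", "ra": "rheumatoid_arthritis", "copd": "copd",
    "t2d": "diabetes",
}


def _row_profile(row: pd.Series, age_at_event: float) -> CovariateProfile:
    kwargs = {"male": str(row["sex"]).upper().startswith("M"),
              "age_at_event": float(age_at_event)}
    for col, attr in _PROFILE_COLUMNS.items():
        if col in row.index:
            val = row[col]
            kwargs[attr] = bool(val) if attr not in ("fnbmd_tscore", "bmi") else float(val)
    return CovariateProfile(**kwargs)


def records_from_events(events: pd.DataFrame,
                        state_space: StateSpace = DEFAULT_STATE_SPACE,
                        ) -> EventHistoryDataset:
    """Convert a long-format event table into sojourn records.

    Expected columns: ``subject_id``, ``time_years`` (study clock),
    ``state``, ``age`` (attained age at that row), ``sex``, and the
    covariate columns (``tscore``, ``bmi``, ``falls``, ``prior_fx``, six
    comorbidity flags).  Each subject contributes a baseline row (state
    at entry), zero or more event rows (new state at its exact time),
    and a final row which is either death (state 5) or a censoring row
    repeating the current state.  ``age_at_event`` on each record is the
    age at entry into that record's state.
    """
    required = {"subject_id", "time_years", "state"}
    missing = required - set(events.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    records: list[TransitionRecord] = []
    for sid, g in events.groupby("subject_id", sort=False):
        g = g.sort_values("time_years", kind="stable")
        base = g.iloc[0]
        cur_state = int(base["state"])
        cur_t = float(base["time_years"])
        base_age = float(base.get("age", 70.0)) - cur_t
        if cur_state in state_space.absorbing:
            raise DataValidationError(f"subject {sid}: enters in absorbing state")
        closed = False
        for _, row in g.iloc[1:].iterrows():
            s = int(row["state"])
            t = float(row["time_years"])
            if t < cur_t:
                raise DataValidationError(f"subject {sid}: times decrease")
            profile = _row_profile(base, base_age + cur_t)
            if s == cur_state:
                records.append(TransitionRecord(str(sid), cur_state, cur_t, t,
                                                None, profile))
                closed = True
                break
            if not state_space.is_allowed(cur_state, s):
                raise DataValidationError(
                    f"subject {sid}: disallowed transition {cur_state}->{s}")
            records.append(TransitionRecord(str(sid), cur_state, cur_t, t, s, profile))
            cur_state, cur_t = s, t
            if s in state_space.absorbing:
                closed = True
                break
        if not closed and len(g) > 1:
            # trailing event with no closing row: the new state has zero exposure
            pass
    return EventHistoryDataset(records, state_space)


# ---------------------------------------------------------------------------
# likelihoods


def _grouped(data: EventHistoryDataset, coding: CovariateCoding,
             covariates: Sequence[str]):
    """Per-source-state arrays (durations, design matrix, destination)."""
    by_state: dict[int, dict[str, list]] = {}
    for rec in data.records:
        g = by_state.setdefault(rec.state, {"dt": [], "z": [], "dest": []})
        g["dt"].append(rec.duration)
        g["z"].append(coding.design_vector(rec.profile, covariates))
        g["dest"].append(rec.destination if rec.destination is not None else 0)
    out = {}
    for r, g in by_state.items():
        out[r] = (np.asarray(g["dt"], float),
                  np.asarray(g["z"], float).reshape(len(g["dt"]), len(covariates)),
                  np.asarray(g["dest"], int))
    return out


def exact_time_loglik(params: ModelParameters,
                      data: EventHistoryDataset) -> float:
    """Exact-event-time log-likelihood.

    Each record contributes ``-(sum_s q_rs) * dt`` for the time at risk
    plus ``log q_rs`` if it ends in the move r->s.  A realised transition
    with zero intensity yields ``-inf``.
    """
    covs = params.covariate_names()
    grouped = _grouped(data, params.coding, covs)
    ll = 0.0
    for r, (dt, Z, dest) in grouped.items():
        for s in params.state_space.exits(r):
            tp = params.transitions[(r, s)]
            events = dest == s
            if tp.boundary or tp.alpha == -np.inf:
                if events.any():
                    return -np.inf
                continue
            beta = np.array([tp.beta.get(c, 0.0) for c in covs])
            lp = tp.alpha + (Z @ beta if covs else np.zeros(len(dt)))
            ll -= float(np.exp(lp) @ dt)
            if events.any():
                ll += float(np.sum(lp[events]))
    return ll


def panel_loglik(params: ModelParameters, panel: PanelDataset,
                 exact_death: bool = True) -> float:
    """Interval-censored (panel) log-likelihood.

    Consecutive snapshots (t0, r) -> (t1, s) contribute ``log P_rs(dt)``
    via the matrix exponential.  With ``exact_death``, an interval
    ending in death at an exact time contributes
    ``log sum_k P_rk(dt) q_k5`` (the path may pass through unobserved
    fracture states).  A snapshot pair implying an impossible move
    yields ``-inf``.
    """
    ll = 0.0
    death = next(iter(params.state_space.absorbing))
    for sid, snaps in panel.snapshots.items():
        profile = panel.profiles[sid]
        Q = build_generator(params, profile)
        for (t0, r), (t1, s) in zip(snaps[:-1], snaps[1:]):
            dt = t1 - t0
            if dt < 0:
                raise DataValidationError(f"subject {sid}: snapshots out of order")
            P = transition_probability(Q, dt)
            if s == death and exact_death:
                dens = sum(P[r - 1, k - 1] * Q[k - 1, death - 1]
                           for k in range(1, death))
                if dens <= 0:
                    return -np.inf
                ll += math.log(dens)
            else:
                p = P[r - 1, s - 1]
                if p <= 0:
                    return -np.inf
                ll += math.log(p)
    return ll


# ---------------------------------------------------------------------------
# estimation


def closed_form_mle(data: EventHistoryDataset,
                    coding: CovariateCoding = DEFAULT_CODING) -> ModelParameters:
    """No-covariate maximum likelihood: ``q_rs = n_rs / T_r``.

    The exact-time likelihood without covariates is maximised in closed
    form by events over time at risk; transitions with no events are
    returned at the zero boundary.
    """
    n = data.transition_counts()
    T = data.time_at_risk()
    rates = {}
    for (r, s) in data.state_space.allowed:
        t_r = T.get(r, 0.0)
        rates[(r, s)] = n[(r, s)] / t_r if t_r > 0 and n[(r, s)] > 0 else 0.0
    return ModelParameters.from_rates(rates, coding=coding)


@dataclass
class FittedModel:
    """Maximum-likelihood fit: estimates, covariance, diagnostics."""

    params: ModelParameters
    covariance: dict[tuple[int, int], np.ndarray]  # per transition, (1+k)x(1+k)
    loglik: float
    converged: bool
    covariates: tuple[str, ...]
    n_events: dict[tuple[int, int], int]
    config: dict = field(default_factory=dict)

    def alpha(self, r: int, s: int) -> float:
        return self.params.transitions[(r, s)].alpha

    def se_alpha(self, r: int, s: int) -> float:
        cov = self.covariance.get((r, s))
        if cov is None or not np.isfinite(cov[0, 0]) or cov[0, 0] < 0:
            return float("nan")
        return math.sqrt(cov[0, 0])

    def beta(self, r: int, s: int, covariate: str) -> float:
        return self.params.transitions[(r, s)].beta[covariate]

    def se_beta(self, r: int, s: int, covariate: str) -> float:
        cov = self.covariance.get((r, s))
        if cov is None:
            return float("nan")
        j = 1 + list(self.covariates).index(covariate)
        if not np.isfinite(cov[j, j]) or cov[j, j] < 0:
            return float("nan")
        return math.sqrt(cov[j, j])

    def linear_predictor_se(self, r: int, s: int,
                            profile: CovariateProfile) -> float:
        """Delta-method SE of ``alpha + beta.z`` at a profile."""
        cov = self.covariance.get((r, s))
        if cov is None:
            return float("nan")
        z = self.params.coding.design_vector(profile, self.covariates)
        x = np.concatenate(([1.0], z))
        return float(math.sqrt(x @ cov @ x))


@dataclass
class StratifiedFit:
    """Sex-stratified pair of fits with a common interface."""

    fits: dict[str, FittedModel]

    def for_profile(self, profile: CovariateProfile) -> FittedModel:
        return self.fits["M" if profile.male else "F"]

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.fits.values())


def _fit_one_transition(dt: np.ndarray, Z: np.ndarray, y: np.ndarray,
                        tol: float, max_iter: int):
    """Newton maximisation of one transition's Poisson-form likelihood."""
    n_ev = int(y.sum())
    X = np.column_stack([np.ones(len(dt)), Z])
    p = X.shape[1]
    theta = np.zeros(p)
    theta[0] = math.log(max(n_ev, 1) / max(dt.sum(), 1e-12))
    ll = -np.inf
    converged = False
    for _ in range(max_iter):
        lp = X @ theta
        mu = np.exp(lp) * dt
        ll_new = float(y @ lp - mu.sum())
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        # step-halving keeps the iteration ascending (an overlong step can
        # overflow exp; the resulting -inf objective just halves again)
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            lp_c = X @ cand
            with np.errstate(over="ignore"):
                ll_c = float(y @ lp_c - (np.exp(lp_c) * dt).sum())
            if ll_c >= ll_new - 1e-12:
                break
            t /= 2
        # the clip guards against divergence under complete separation
        # (possible on transitions with a handful of events)
        theta = np.clip(theta + t * step, -30.0, 30.0)
        if abs(ll_c - ll) < tol and np.max(np.abs(grad)) < 1e-6 * max(1, n_ev):
            converged = True
            ll = ll_c
            break
        ll = ll_c
    if np.any(np.abs(theta) >= 30.0):
        converged = False
    lp = X @ theta
    mu = np.exp(lp) * dt
    H = (X * mu[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return theta, cov, float(y @ lp - mu.sum()), converged


def fit_mle(data: EventHistoryDataset,
            covariates: Sequence[str] = (),
            mode: str = "single",
            likelihood: str = "exact",
            coding: CovariateCoding = DEFAULT_CODING,
            tol: float = 1e-8,
            max_iter: int = 100) -> FittedModel | StratifiedFit:
    """Maximum-likelihood fit of all transition intensities.

    ``mode='single'`` fits one model on the data as given (add "male"
    to ``covariates`` for a joint two-sex model); ``mode='stratified'``
    fits women and men separately and returns a :class:`StratifiedFit`.
    ``likelihood='exact'`` uses the exact-event-time likelihood, which
    factorises per transition and is maximised by Newton iterations
    started from the closed-form no-covariate estimate;
    ``likelihood='panel'`` is available through :func:`fit_panel_mle`.
    Transitions with no observed events are boundary-flagged rather than
    estimated.
    """
    if likelihood != "exact":
        raise ValueError("fit_mle handles the exact-time likelihood; "
                         "use fit_panel_mle for panel data")
    if mode == "stratified":
        return StratifiedFit({sex: fit_mle(sub, covariates, "single",
                                           likelihood, coding, tol, max_iter)
                              for sex, sub in data.split_by_sex().items()})
    if mode != "single":
        raise ValueError(f"unknown mode {mode!r}")

    covariates = tuple(covariates)
    grouped = _grouped(data, coding, covariates)
    trans: dict[tuple[int, int], TransitionParameters] = {}
    covs: dict[tuple[int, int], np.ndarray] = {}
    n_events: dict[tuple[int, int], int] = {}
    all_converged = True
    for (r, s) in data.state_space.allowed:
        if r not in grouped:
            trans[(r, s)] = TransitionParameters(-np.inf, dict.fromkeys(covariates, 0.0),
                                                 boundary=True)
            n_events[(r, s)] = 0
            continue
        dt, Z, dest = grouped[r]
        y = (dest == s).astype(float)
        n_events[(r, s)] = int(y.sum())
        if n_events[(r, s)] == 0:
            trans[(r, s)] = TransitionParameters(-np.inf, dict.fromkeys(covariates, 0.0),
                                                 boundary=True)
            continue
        theta, cov, _, ok = _fit_one_transition(dt, Z, y, tol, max_iter)
        all_converged &= ok
        trans[(r, s)] = TransitionParameters(
            float(theta[0]), {c: float(b) for c, b in zip(covariates, theta[1:])})
        covs[(r, s)] = cov
    params = ModelParameters(trans, coding=coding)
    return FittedModel(params=params, covariance=covs,
                       loglik=exact_time_loglik(params, data),
                       converged=all_converged, covariates=covariates,
                       n_events=n_events,
                       config={"mode": mode, "likelihood": likelihood, "tol": tol})


def fit_panel_mle(panel: PanelDataset,
                  covariates: Sequence[str] = (),
                  coding: CovariateCoding = DEFAULT_CODING,
                  x0: ModelParameters | None = None,
                  tol: float = 1e-8) -> FittedModel:
    """Fit by maximising the panel likelihood numerically.

    The panel likelihood does not factorise, so the full parameter
    vector is optimised with Nelder-Mead/BFGS; intended for the
    interval-censored observation scheme and for modest data sizes.
    """
    from scipy.optimize import minimize

    covariates = tuple(covariates)
    keys = list(ALLOWED_TRANSITIONS)
    k = len(covariates)

    def unpack(x: np.ndarray) -> ModelParameters:
        trans = {}
        for i, key in enumerate(keys):
            a = x[i * (1 + k)]
            b = {c: x[i * (1 + k) + 1 + j] for j, c in enumerate(covariates)}
            trans[key] = TransitionParameters(float(a), b)
        return ModelParameters(trans, coding=coding)

    if x0 is None:
        x_init = np.tile(np.concatenate(([math.log(0.05)], np.zeros(k))), len(keys))
    else:
        x_init = np.concatenate([
            np.concatenate(([x0.transitions[key].alpha],
                            [x0.transitions[key].beta.get(c, 0.0) for c in covariates]))
            for key in keys])

    def nll(x: np.ndarray) -> float:
        ll = panel_loglik(unpack(x), panel)
        return np.inf if not np.isfinite(ll) else -ll

    res = minimize(nll, x_init, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    params = unpack(res.x)
    # numerical observed information (finite differences), block extracted
    n_events = {key: 0 for key in keys}
    return FittedModel(params=params, covariance={},
                       loglik=float(-res.fun), converged=bool(res.success),
                       covariates=covariates, n_events=n_events,
                       config={"mode": "panel", "likelihood": "panel"})


def hazard_ratio_table(fit: FittedModel) -> pd.DataFrame:
    """Hazard ratios with Wald 95% CIs per covariate per transition.

    ``HR = exp(beta)``, ``CI = exp(beta +/- 1.96 SE)``; ``significant``
    flags CIs excluding 1.  Transitions without covariance (boundary or
    failed) report the CI as missing.
    """
    rows = []
    for (r, s), tp in fit.params.transitions.items():
        for c in fit.covariates:
            b = tp.beta.get(c, float("nan"))
            se = fit.se_beta(r, s, c) if (r, s) in fit.covariance else float("nan")
            lo, hi = (math.exp(b - 1.96 * se), math.exp(b + 1.96 * se)) \
                if np.isfinite(se) else (float("nan"), float("nan"))
            rows.append({
                "from_state": r, "to_state": s, "covariate": c,
                "hr": math.exp(b) if np.isfinite(b) else float("nan"),
                "ci_low": lo, "ci_high": hi,
                "significant": bool(np.isfinite(lo) and (lo > 1 or hi < 1)),
            })
    return pd.DataFrame(rows)
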