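"""Cohort file I/O, descriptive tables, and calibration reporting.

The on-disk cohort format is a long CSV, one row per subject-
observation: ``subject_id, time_years, state, age, sex, tscore, bmi,
falls, prior_fx, cvd, cancer, neuro, ra, copd, t2d``.  Output files
carry a comment header (tool version, seed, config hash) so every run
is traceable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .inference import (
    DataValidationError,
    EventHistoryDataset,
    FittedModel,
    StratifiedFit,
    records_from_events,
)
from .model_core import (
    ALLOWED_TRANSITIONS,
    CovariateCoding,
    ModelParameters,
    TransitionParameters,
    build_generator,
)

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "write_fit",
    "read_fit",
    "baseline_table",
    "calibration_table",
]

COHORT_COLUMNS = ("subject_id", "time_years", "state", "age", "sex", "tscore",
                  "bmi", "falls", "prior_fx", "cvd", "cancer", "neuro", "ra",
                  "copd", "t2d")

_BINARY_COLS = ("falls", "prior_fx", "cvd", "cancer", "neuro", "ra", "copd", "t2d")


def _metadata_header(seed=None, config_hash=None) -> str:
    parts = [f"# fractrans {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_hash is not None:
        parts.append(f"# config_hash: {config_hash}")
    return "\n".join(parts) + "\n"


def config_hash(obj) -> str:
    """Short stable hash of a configuration object."""
    try:
        payload = json.dumps(asdict(obj), sort_keys=True, default=str)
    except TypeError:
        payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_cohort_frame(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate the long-format cohort CSV."""
    df = pd.read_csv(path, comment="#")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"cohort file missing columns {sorted(missing)}")
    bad_state = ~df["state"].isin([1, 2, 3, 4, 5])
    if bad_state.any():
        row = df.index[bad_state][0]
        raise DataValidationError(
            f"column 'state', row {row}: value {df.loc[row, 'state']} not in 1-5")
    if (df["time_years"] < 0).any():
        row = df.index[df["time_years"] < 0][0]
        raise DataValidationError(f"column 'time_years', row {row}: negative time")
    dec = df.groupby("subject_id")["time_years"].apply(
        lambda s: bool((s.diff().dropna() < 0).any()))
    if dec.any():
        raise DataValidationError(
            f"subject {dec.index[dec][0]}: times decrease within subject")
    return df


def read_cohort(path: str | Path) -> EventHistoryDataset:
    """Parse a cohort CSV into a validated event-history dataset."""
    return records_from_events(read_cohort_frame(path))


def write_cohort(frame: pd.DataFrame, path: str | Path,
                 seed=None, cfg_hash=None) -> None:
    """Write a long-format cohort table with a metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(seed, cfg_hash))
        frame.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# fitted-model (de)serialization


def _fit_to_dict(fit: FittedModel) -> dict:
    return {
        "covariates": list(fit.covariates),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "coding": asdict(fit.params.coding),
        "transitions": {
            f"{r}-{s}": {
                "alpha": tp.alpha if math.isfinite(tp.alpha) else None,
                "beta": tp.beta,
                "boundary": tp.boundary,
                "n_events": fit.n_events.get((r, s), 0),
                "covariance": fit.covariance[(r, s)].tolist()
                if (r, s) in fit.covariance else None,
            }
            for (r, s), tp in fit.params.transitions.items()
        },
    }


def write_fit(fit: FittedModel | StratifiedFit, path: str | Path,
              seed=None) -> None:
    """Serialise a fitted model (or sex-stratified pair) to JSON."""
    if isinstance(fit, StratifiedFit):
        payload = {"kind": "stratified",
                   "fits": {sex: _fit_to_dict(f) for sex, f in fit.fits.items()}}
    else:
        payload = {"kind": "single", "fit": _fit_to_dict(fit)}
    payload["tool_version"] = __version__
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _fit_from_dict(d: dict) -> FittedModel:
    coding = CovariateCoding(**d["coding"])
    trans, covs, n_events = {}, {}, {}
    for key, block in d["transitions"].items():
        r, s = (int(x) for x in key.split("-"))
        alpha = block["alpha"] if block["alpha"] is not None else -np.inf
        trans[(r, s)] = TransitionParameters(alpha, dict(block["beta"]),
                                             boundary=block["boundary"])
        n_events[(r, s)] = block["n_events"]
        if block["covariance"] is not None:
            covs[(r, s)] = np.asarray(block["covariance"])
    params = ModelParameters(trans, coding=coding)
    return FittedModel(params=params, covariance=covs, loglik=d["loglik"],
                       converged=d["converged"],
                       covariates=tuple(d["covariates"]), n_events=n_events)


def read_fit(path: str | Path) -> FittedModel | StratifiedFit:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload["kind"] == "stratified":
        return StratifiedFit({sex: _fit_from_dict(d)
                              for sex, d in payload["fits"].items()})
    return _fit_from_dict(payload["fit"])


# ---------------------------------------------------------------------------
# descriptive baseline table


_CONTINUOUS = {"entry_age": "Age (years)", "bmi": "BMI (kg/m^2)",
               "fnbmd": "FNBMD (g/cm^2)", "tscore": "FNBMD T-score"}
_BINARY = {"falls": "History of falls", "prior_fx": "Prior fracture",
           "cvd": "Cardiovascular disease", "cancer": "Cancer",
           "neuro": "Neurological disease", "ra": "Rheumatoid arthritis",
           "copd": "Respiratory disease", "t2d": "Type 2 diabetes"}


def baseline_table(baseline: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary by sex with two-sample tests.

    Continuous variables: mean (SD) and Welch-free two-sample t-test;
    binaries: n (%) and the chi-squared test without continuity
    correction.  Zero-variance variables report an undefined p-value.
    """
    women = baseline[baseline["sex"] == "F"]
    men = baseline[baseline["sex"] == "M"]
    rows = [{"variable": "Number of participants",
             "women": f"{len(women)}", "men": f"{len(men)}", "p_value": np.nan}]
    for col, label in _CONTINUOUS.items():
        if col not in baseline.columns:
            continue
        w, m = women[col].astype(float), men[col].astype(float)
        if w.std(ddof=1) == 0 and m.std(ddof=1) == 0:
            p = np.nan
        else:
            p = stats.ttest_ind(w, m, equal_var=True).pvalue
        rows.append({"variable": label,
                     "women": f"{w.mean():.2f} ({w.std(ddof=1):.2f})",
                     "men": f"{m.mean():.2f} ({m.std(ddof=1):.2f})",
                     "p_value": p})
    for col, label in _BINARY.items():
        if col not in baseline.columns:
            continue
        w, m = women[col].astype(int), men[col].astype(int)
        table = np.array([[w.sum(), len(w) - w.sum()],
                          [m.sum(), len(m) - m.sum()]])
        if (table.sum(axis=0) == 0).any():
            p = np.nan  # zero-variance binary: test undefined
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
        rows.append({"variable": label,
                     "women": f"{w.sum()} ({100 * w.mean():.1f})",
                     "men": f"{m.sum()} ({100 * m.mean():.1f})",
                     "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observed-vs-predicted calibration


def calibration_table(fit, dataset: EventHistoryDataset,
                      horizon: float = 5.0,
                      age_bands: tuple[float, ...] = (60, 65, 70, 75, 80, 85, 90),
                      ) -> pd.DataFrame:
    """Observed vs model-predicted probability of leaving each state.

    Strata are sex x age band (age at state entry) x current state.
    The observed fraction exiting within ``horizon`` years is the
    Kaplan-Meier estimate 1 - S(horizon) on the records of the stratum
    (exit to any destination is the event; censored records censor);
    the predicted probability is the stratum mean of
    ``1 - exp(-horizon * sum_s q_rs(z))`` under the fitted intensities.
    Empty strata are kept and flagged.
    """
    from lifelines import KaplanMeierFitter

    from .risk import resolve_params

    edges = list(age_bands) + [np.inf]
    rows = []
    recs = list(dataset.records)
    for sex in ("F", "M"):
        for lo, hi in zip(edges[:-1], edges[1:]):
            for state in (1, 2, 3, 4):
                members = [r for r in recs
                           if (r.profile.male == (sex == "M"))
                           and r.state == state
                           and lo <= r.profile.age_at_event < hi]
                band = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f"{lo:g}+"
                if not members:
                    rows.append({"sex": sex, "age_band": band, "state": state,
                                 "n": 0, "observed": np.nan, "predicted": np.nan,
                                 "diff": np.nan, "se": np.nan, "within_3se": np.nan,
                                 "empty": True})
                    continue
                durations = np.array([r.duration for r in members])
                events = np.array([r.is_event for r in members])
                km = KaplanMeierFitter()
                km.fit(durations, event_observed=events)
                observed = float(1.0 - km.predict(horizon))
                preds = []
                for r in members:
                    params, _ = resolve_params(fit, r.profile)
                    Q = build_generator(params, r.profile)
                    preds.append(1.0 - math.exp(Q[state - 1, state - 1] * horizon))
                predicted = float(np.mean(preds))
                se = math.sqrt(max(predicted * (1 - predicted), 1e-12) / len(members))
                diff = observed - predicted
                rows.append({"sex": sex, "age_band": band, "state": state,
                             "n": len(members), "observed": observed,
                             "predicted": predicted, "diff": diff, "se": se,
                             "within_3se": bool(abs(diff) <= 3 * se),
                             "empty": False})
    return pd.DataFrame(rows)
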