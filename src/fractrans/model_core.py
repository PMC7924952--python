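"""Five-state continuous-time Markov model of bone health.

The model tracks an older individual through five states: (1) no
fracture, (2) initial fracture, (3) second fracture, (4) third or
further fracture, and (5) death.  Death is absorbing, and the model is
progressive: the only allowed moves are to the next fracture state or
to death, never backwards.  Each allowed move (r, s) is governed by a
per-year transition intensity

    q_rs(z) = exp(alpha_rs + beta_rs . z)

where ``z`` is a coded covariate vector (deviations from a reference
profile) so that ``exp(alpha_rs)`` is the intensity of a "typical"
individual and ``exp(beta)`` are hazard ratios.  The intensities fill a
5x5 generator matrix Q whose matrix exponential ``expm(t*Q)`` yields the
transition-probability matrix P(t); the expected sojourn time in a
transient state is ``-1/q_rr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_STATES",
    "STATE_LABELS",
    "ALLOWED_TRANSITIONS",
    "ABSORBING_STATE",
    "TYPICAL_WOMAN_RATES",
    "TYPICAL_MAN_RATES",
    "StateSpace",
    "CovariateProfile",
    "CovariateCoding",
    "CodingError",
    "TransitionParameters",
    "ModelParameters",
    "linear_predictor",
    "build_generator",
    "validate_generator",
    "transition_probability",
    "piecewise_transition_probability",
    "sojourn_times",
]

N_STATES = 5
ABSORBING_STATE = 5
STATE_LABELS = {
    1: "no fracture",
    2: "initial fracture",
    3: "second fracture",
    4: "third+ fracture",
    5: "death",
}
#: The seven allowed moves: next fracture state, or death from any live state.
ALLOWED_TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 5), (2, 3), (2, 5), (3, 4), (3, 5), (4, 5),
)

#: Per-year transition intensities of a "typical" 70-year-old woman/man
#: (femoral-neck T-score -1.5, BMI 26.6 kg/m^2, no falls, no prior
#: fracture, no comorbidities) as estimated in the Dubbo Osteoporosis
#: Epidemiology Study.  Used as defaults for simulation and as worked
#: reference profiles throughout.
TYPICAL_WOMAN_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.027, (2, 3): 0.048, (3, 4): 0.063,
    (1, 5): 0.018, (2, 5): 0.021, (3, 5): 0.022, (4, 5): 0.129,
}
TYPICAL_MAN_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.017, (2, 3): 0.041, (3, 4): 0.133,
    (1, 5): 0.032, (2, 5): 0.050, (3, 5): 0.165, (4, 5): 0.339,
}


class CodingError(KeyError):
    """A coefficient refers to a covariate the coding does not define."""


@dataclass(frozen=True)
class StateSpace:
    """State labels, the absorbing state, and the allowed-transition set."""

    labels: Mapping[int, str] = field(default_factory=lambda: dict(STATE_LABELS))
    absorbing: frozenset[int] = frozenset({ABSORBING_STATE})
    allowed: tuple[tuple[int, int], ...] = ALLOWED_TRANSITIONS

    def __post_init__(self) -> None:
        if len(self.allowed) != 7:
            raise ValueError("expected exactly 7 allowed transitions")
        for r, s in self.allowed:
            if r in self.absorbing:
                raise ValueError(f"transition out of absorbing state {r}")
            if s <= r:
                raise ValueError(f"non-progressive transition ({r}, {s})")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def exits(self, r: int) -> tuple[int, ...]:
        """Destination states reachable in one step from state ``r``."""
        return tuple(s for (a, s) in self.allowed if a == r)

    def is_allowed(self, r: int, s: int) -> bool:
        return (r, s) in self.allowed


DEFAULT_STATE_SPACE = StateSpace()


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline risk factors of one individual.

    ``age_at_event`` is the age at entry into the *current* state: the
    age covariate is refreshed at each state entry, which avoids
    immortal-time bias in the later states.
    """

    male: bool = False
    age_at_event: float = 70.0
    fnbmd_tscore: float = -1.5
    bmi: float = 26.6
    fall_history: bool = False
    prior_fracture: bool = False
    cardiovascular: bool = False
    cancer: bool = False
    neurological: bool = False
    rheumatoid_arthritis: bool = False
    copd: bool = False
    diabetes: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.fnbmd_tscore):
            raise ValueError("fnbmd_tscore must be finite")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")

    def with_age(self, age: float) -> "CovariateProfile":
        return replace(self, age_at_event=age)


#: Binary covariates, coded 0/1 with 0 = reference.
BINARY_COVARIATES = (
    "male", "falls", "prior_fracture", "cardiovascular", "cancer",
    "neurological", "rheumatoid_arthritis", "copd", "diabetes",
)


@dataclass(frozen=True)
class CovariateCoding:
    """How raw covariate values map to model-scale deviations.

    The reference ("typical") profile codes to the zero vector.  Age is
    coded per ``age_unit`` years above ``age_reference``; the T-score is
    coded per SD *below* ``tscore_reference`` (so a positive coefficient
    means lower bone density raises risk); BMI per ``bmi_unit`` kg/m^2
    above ``bmi_reference``.  The units are configurable because
    published hazard ratios do not always state theirs.
    """

    age_reference: float = 70.0
    age_unit: float = 5.0
    tscore_reference: float = -1.5
    tscore_unit: float = -1.0
    bmi_reference: float = 26.6
    bmi_unit: float = 5.0

    def encode(self, profile: CovariateProfile) -> dict[str, float]:
        """Full coded covariate vector for ``profile``."""
        return {
            "male": 1.0 if profile.male else 0.0,
            "age": (profile.age_at_event - self.age_reference) / self.age_unit,
            "tscore": (profile.fnbmd_tscore - self.tscore_reference) / self.tscore_unit,
            "bmi": (profile.bmi - self.bmi_reference) / self.bmi_unit,
            "falls": 1.0 if profile.fall_history else 0.0,
            "prior_fracture": 1.0 if profile.prior_fracture else 0.0,
            "cardiovascular": 1.0 if profile.cardiovascular else 0.0,
            "cancer": 1.0 if profile.cancer else 0.0,
            "neurological": 1.0 if profile.neurological else 0.0,
            "rheumatoid_arthritis": 1.0 if profile.rheumatoid_arthritis else 0.0,
            "copd": 1.0 if profile.copd else 0.0,
            "diabetes": 1.0 if profile.diabetes else 0.0,
        }

    def design_vector(self, profile: CovariateProfile,
                      covariates: Sequence[str]) -> np.ndarray:
        z = self.encode(profile)
        try:
            return np.array([z[c] for c in covariates], dtype=float)
        except KeyError as exc:  # pragma: no cover - message only
            raise CodingError(f"unknown covariate {exc.args[0]!r}") from exc


DEFAULT_CODING = CovariateCoding()


def linear_predictor(profile: CovariateProfile,
                     beta: Mapping[str, float],
                     coding: CovariateCoding = DEFAULT_CODING) -> float:
    """``beta . z`` with ``z`` the coded deviation from the reference profile.

    Returns 0 for the reference profile regardless of ``beta``.  Raises
    :class:`CodingError` if ``beta`` names a covariate the coding does
    not define.
    """
    z = coding.encode(profile)
    total = 0.0
    for name, b in beta.items():
        if name not in z:
            raise CodingError(f"unknown covariate {name!r}")
        total += b * z[name]
    return total


@dataclass
class TransitionParameters:
    """Baseline log-intensity and covariate coefficients of one transition.

    ``alpha`` is the log per-year rate at the reference profile;
    ``exp(beta[k])`` is the hazard ratio per coded unit of covariate k.
    ``boundary`` flags a rate estimated at the zero boundary (no events).
    """

    alpha: float
    beta: dict[str, float] = field(default_factory=dict)
    boundary: bool = False

    def rate(self, profile: CovariateProfile,
             coding: CovariateCoding = DEFAULT_CODING) -> float:
        if self.boundary or self.alpha == -np.inf:
            return 0.0
        return math.exp(self.alpha + linear_predictor(profile, self.beta, coding))


@dataclass
class ModelParameters:
    """One :class:`TransitionParameters` block per allowed transition."""

    transitions: dict[tuple[int, int], TransitionParameters]
    coding: CovariateCoding = field(default_factory=CovariateCoding)
    state_space: StateSpace = field(default_factory=StateSpace)

    def __post_init__(self) -> None:
        missing = set(self.state_space.allowed) - set(self.transitions)
        if missing:
            raise ValueError(f"missing parameters for transitions {sorted(missing)}")
        extra = set(self.transitions) - set(self.state_space.allowed)
        if extra:
            raise ValueError(f"parameters for disallowed transitions {sorted(extra)}")

    @classmethod
    def from_rates(cls, rates: Mapping[tuple[int, int], float],
                   beta: Mapping[tuple[int, int], Mapping[str, float]] | None = None,
                   coding: CovariateCoding = DEFAULT_CODING) -> "ModelParameters":
        """Build parameters from per-year reference-profile rates.

        A zero rate is stored as a boundary block (alpha = -inf).
        """
        beta = beta or {}
        trans = {}
        for key, rate in rates.items():
            b = dict(beta.get(key, {}))
            if rate > 0:
                trans[key] = TransitionParameters(math.log(rate), b)
            else:
                trans[key] = TransitionParameters(-np.inf, b, boundary=True)
        return cls(trans, coding=coding)

    def intensity(self, r: int, s: int, profile: CovariateProfile) -> float:
        return self.transitions[(r, s)].rate(profile, self.coding)

    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for tp in self.transitions.values():
            for k in tp.beta:
                if k not in names:
                    names.append(k)
        return tuple(names)


def build_generator(params: ModelParameters,
                    profile: CovariateProfile) -> np.ndarray:
    """5x5 generator matrix Q for one covariate profile.

    Off-diagonal entries are ``q_rs = exp(alpha_rs + beta_rs . z)`` on
    allowed transitions and 0 elsewhere; each diagonal entry is minus
    the row sum, and the absorbing row is all zero.
    """
    n = params.state_space.n_states
    Q = np.zeros((n, n))
    for (r, s), tp in params.transitions.items():
        try:
            q = tp.rate(profile, params.coding)
        except OverflowError:
            q = math.inf
        if not math.isfinite(q):
            raise OverflowError(
                f"non-finite intensity for transition {r}->{s} "
                f"(alpha={tp.alpha}, profile={profile})")
        Q[r - 1, s - 1] = q
    for i in range(n):
        Q[i, i] = -(Q[i].sum() - Q[i, i])
    return Q


def validate_generator(Q: np.ndarray,
                       state_space: StateSpace = DEFAULT_STATE_SPACE,
                       atol: float = 1e-10) -> None:
    """Raise ``ValueError`` unless Q is a valid generator for the model."""
    Q = np.asarray(Q, dtype=float)
    n = state_space.n_states
    if Q.shape != (n, n):
        raise ValueError(f"generator must be {n}x{n}")
    if not np.all(np.isfinite(Q)):
        raise ValueError("generator has non-finite entries")
    if np.abs(Q.sum(axis=1)).max() > atol:
        raise ValueError("generator rows must sum to 0")
    off = Q - np.diag(np.diag(Q))
    if off.min() < 0:
        raise ValueError("off-diagonal intensities must be nonnegative")
    for r in range(1, n + 1):
        for s in range(1, n + 1):
            if r != s and not state_space.is_allowed(r, s) and Q[r - 1, s - 1] != 0:
                raise ValueError(f"nonzero intensity on disallowed transition {r}->{s}")
    for a in state_space.absorbing:
        if np.any(Q[a - 1] != 0):
            raise ValueError(f"absorbing state {a} must have a zero row")


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix ``P(t) = expm(t*Q)``.

    Uses scaling-and-squaring with Pade approximation (the generator is
    upper triangular, but the general algorithm is kept for robustness).
    Tiny negative round-off entries are clipped to 0.
    """
    if t < 0:
        raise ValueError("horizon t must be nonnegative")
    P = expm(float(t) * np.asarray(Q, dtype=float))
    np.clip(P, 0.0, None, out=P)
    return P


def piecewise_transition_probability(
        segments: Iterable[tuple[np.ndarray, float]]) -> np.ndarray:
    """Transition probabilities under piecewise-constant intensities.

    ``segments`` is an ordered sequence of (generator, duration) pairs;
    the result is the ordered product of the per-segment matrix
    exponentials (the age covariate is only refreshed at state entry, so
    a prediction horizon crossing a state entry is handled by chaining
    segments).  An empty sequence yields the identity.
    """
    P = None
    for Q, dur in segments:
        if dur < 0:
            raise ValueError("segment durations must be nonnegative")
        Pi = transition_probability(Q, dur)
        P = Pi if P is None else P @ Pi
    if P is None:
        return np.eye(N_STATES)
    return P


def sojourn_times(Q: np.ndarray,
                  state_space: StateSpace = DEFAULT_STATE_SPACE) -> np.ndarray:
    """Expected sojourn time (years) per state, ``-1/q_rr``.

    Transient states with no exit intensity get ``inf`` (the model never
    leaves them); absorbing states get ``nan`` (sojourn undefined).
    """
    Q = np.asarray(Q, dtype=float)
    out = np.empty(state_space.n_states)
    for r in range(1, state_space.n_states + 1):
        if r in state_space.absorbing:
            out[r - 1] = np.nan
        elif Q[r - 1, r - 1] == 0:
            out[r - 1] = np.inf
        else:
            out[r - 1] = -1.0 / Q[r - 1, r - 1]
    return out
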