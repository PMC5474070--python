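"""Learning-rule primitives for experience-weighted attraction (EWA) models.

An EWA model has two parts: a reinforcement rule that accumulates realized
pay-offs into per-option *attraction* scores, and a choice rule that maps
attractions to choice probabilities.  Here the attraction update is

    A[i, t+1] = (1 - phi_j) * A[i, t] + phi_j * pi_t        (chosen option i)

where ``phi_j`` is individual ``j``'s updating (recency) weight and ``pi_t``
the realized pay-off, and the choice rule is the multinomial-logistic
(soft-max)

    P(i) = exp(lam * A[i]) / sum_k exp(lam * A[k]).

Realized choice mixes this individual component with a social-cue component
``S`` (built in :mod:`ewalearn.cues`) with weight ``gam_j``:

    P(i) = (1 - gam_j) * P_ind(i) + gam_j * S(i).

Pay-off for a successful fruit-processing bout is the inverse log of the
opening time, ``1 / log(T_open)``; failures pay zero.  Learning parameters
are tied to individual state (age) through logistic links on the log-odds
scale, e.g. ``phi_j = logistic(alpha_j + mu_phi * age_j)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_softmax

__all__ = [
    "CUE_NAMES",
    "MIN_DURATION_S",
    "TechniqueSet",
    "AttractionState",
    "LearnerParams",
    "PopulationParams",
    "payoff_from_outcome",
    "update_attractions",
    "individual_choice_probs",
    "combine_probs",
    "link_learning_param",
    "standardize_ages",
]

#: Order of the five social cues used everywhere a 5-vector of cue values or
#: cue weights (beta) appears: observed pay-off, demonstrator alpha rank,
#: matrilineal kinship, age similarity (cohort), demonstrator age.
CUE_NAMES: tuple[str, ...] = ("pay", "rank", "kin", "coho", "age")

#: Durations are clamped below at this value so log(T_open) > 0 and the
#: pay-off 1/log(T) stays finite and positive.  Observed opening times are
#: tens to hundreds of seconds, so the clamp only guards synthetic edge cases.
MIN_DURATION_S: float = 2.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TechniqueSet:
    """Ordered set of technique labels with a label -> index bijection."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) == 0:
            raise ValueError("TechniqueSet needs at least one technique")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate technique labels in {self.names}")

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names


@dataclass
class AttractionState:
    """Per-individual, per-technique attraction scores A[j, i] at step t."""

    A: np.ndarray
    individuals: tuple[str, ...]
    techniques: TechniqueSet
    t: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.individuals = tuple(self.individuals)
        if self.A.shape != (len(self.individuals), len(self.techniques)):
            raise ValueError(
                f"attraction matrix shape {self.A.shape} does not match "
                f"{len(self.individuals)} individuals x "
                f"{len(self.techniques)} techniques"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValueError("attraction scores must be finite")

    @classmethod
    def naive(
        cls,
        individuals: tuple[str, ...] | list[str],
        techniques: TechniqueSet,
        initial: dict[str, np.ndarray] | None = None,
    ) -> "AttractionState":
        """All-zero attractions, optionally seeding experienced individuals.

        ``initial`` maps individual id -> length-K attraction vector and is
        how knowledgeable immigrants (who arrive already skilled at a
        technique) are represented.
        """
        A = np.zeros((len(individuals), len(techniques)))
        ids = tuple(individuals)
        if initial:
            pos = {j: r for r, j in enumerate(ids)}
            for j, row in initial.items():
                A[pos[j]] = np.asarray(row, dtype=float)
        return cls(A=A, individuals=ids, techniques=techniques)

    def row(self, individual: str) -> np.ndarray:
        try:
            r = self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None
        return self.A[r]


@dataclass
class LearnerParams:
    """Fully realized per-individual learning parameters.

    lam is global (shared) soft-max sensitivity; phi, gam, f and the 5-vector
    beta (cue weights, ordered as :data:`CUE_NAMES`) vary by individual.
    """

    lam: float
    phi: np.ndarray
    gam: np.ndarray
    f: np.ndarray
    beta: np.ndarray  # shape (J, 5)
    individuals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.gam = np.atleast_1d(np.asarray(self.gam, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi must lie in [0, 1]")
        if np.any(self.gam < 0) or np.any(self.gam > 1):
            raise ValueError("gam must lie in [0, 1]")
        if np.any(self.f <= 0):
            raise ValueError("f must be > 0")
        J = len(self.phi)
        if not (len(self.gam) == len(self.f) == self.beta.shape[0] == J):
            raise ValueError("per-individual parameter arrays disagree in length")
        if self.beta.shape[1] != len(CUE_NAMES):
            raise ValueError(f"beta must have {len(CUE_NAMES)} columns")

    @property
    def n_individuals(self) -> int:
        return len(self.phi)


@dataclass
class PopulationParams:
    """Population-level (hyper)parameters of the multilevel EWA model.

    Individual-level values are logistic / log transforms of a linear
    combination of a population intercept, a standardized-age slope and a
    mean-zero individual deviation with the SD in ``sigma``:

        phi_j = logistic(a_phi + sigma['phi'] * z_j + mu_phi * age_j)
        gam_j = logistic(a_gam + sigma['gam'] * z_j + mu_gam * age_j)
        f_j   = exp(log_f + sigma['f'] * z_j)
        beta_jk = beta[k] + sigma['b_<cue>'] * z_jk

    ``sigma`` keys are any of {'phi', 'gam', 'f', 'b_pay', ..., 'b_age'};
    missing keys mean no individual variation for that parameter.
    """

    lam: float
    a_phi: float
    a_gam: float
    mu_phi: float = 0.0
    mu_gam: float = 0.0
    log_f: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(len(CUE_NAMES)))
    sigma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(CUE_NAMES),):
            raise ValueError(f"beta must be a length-{len(CUE_NAMES)} vector")
        if any(v < 0 for v in self.sigma.values()):
            raise ValueError("sigma entries must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    def mean_phi(self, age_std: float = 0.0) -> float:
        return link_learning_param(self.a_phi, self.mu_phi, age_std)

    def mean_gam(self, age_std: float = 0.0) -> float:
        return float(expit(self.a_gam + self.mu_gam * age_std))

    def draw_individuals(
        self,
        ages_std: np.ndarray,
        rng: np.random.Generator,
        individuals: tuple[str, ...] = (),
    ) -> LearnerParams:
        """Sample per-individual parameters given standardized ages."""
        ages_std = np.asarray(ages_std, dtype=float)
        J = len(ages_std)
        s = self.sigma

        def z(key: str, size) -> np.ndarray:
            sd = s.get(key, 0.0)
            return sd * rng.standard_normal(size) if sd > 0 else np.zeros(size)

        phi = expit(self.a_phi + z("phi", J) + self.mu_phi * ages_std)
        gam = expit(self.a_gam + z("gam", J) + self.mu_gam * ages_std)
        f = np.exp(self.log_f + z("f", J))
        beta = np.tile(self.beta, (J, 1))
        for k, cue in enumerate(CUE_NAMES):
            beta[:, k] += z(f"b_{cue}", J)
        return LearnerParams(
            lam=self.lam, phi=phi, gam=gam, f=f, beta=beta,
            individuals=tuple(individuals),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def payoff_from_outcome(
    success: bool, duration_s: float, *, min_duration_s: float = MIN_DURATION_S
) -> float:
    """Pay-off of one processing attempt.

    Failures pay zero regardless of time invested.  A success opening the
    fruit in ``duration_s`` seconds pays ``1 / log(duration_s)``: pay-offs
    decline as opening time grows, steepest early on.  Durations are clamped
    below at ``min_duration_s`` so the log stays positive.
    """
    if not success:
        return 0.0
    if not duration_s > 0:
        raise ValueError(f"successful bout needs a positive duration, got {duration_s}")
    return 1.0 / math.log(max(float(duration_s), min_duration_s))


def update_attractions(
    state: AttractionState,
    actor: str,
    chosen: str,
    payoff: float,
    phi_j: float,
) -> AttractionState:
    """Reinforce the performed technique's attraction for the actor.

    Returns a new state with ``A[actor, chosen]`` moved toward the pay-off by
    the convex combination ``(1-phi_j)*A + phi_j*payoff``; all other cells are
    untouched (unperformed options neither decay nor update) and the step
    counter is incremented.
    """
    if not 0.0 <= phi_j <= 1.0:
        raise ValueError(f"phi_j must lie in [0, 1], got {phi_j}")
    try:
        r = state.individuals.index(actor)
    except ValueError:
        raise KeyError(f"unknown actor {actor!r}") from None
    try:
        c = state.techniques.index[chosen]
    except KeyError:
        raise KeyError(f"unknown technique {chosen!r}") from None
    A = state.A.copy()
    A[r, c] = (1.0 - phi_j) * A[r, c] + phi_j * payoff
    return replace(state, A=A, t=state.t + 1)


def individual_choice_probs(
    state: AttractionState, actor: str, lam: float
) -> np.ndarray:
    """Soft-max choice probabilities ``softmax(lam * A[actor])``.

    lam = 0 gives uniform choice; large lam concentrates on the largest
    attraction.  Invariant to adding a constant to all attractions.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    return np.exp(log_softmax(lam * state.row(actor)))


def combine_probs(
    p_ind: np.ndarray, p_soc: np.ndarray | None, gam_j: float
) -> np.ndarray:
    """Mix individual and social choice probabilities with weight gam_j.

    When no social information exists for the decision (``p_soc is None``)
    the individual component is returned unchanged.
    """
    if not 0.0 <= gam_j <= 1.0:
        raise ValueError(f"gam_j must lie in [0, 1], got {gam_j}")
    p_ind = np.asarray(p_ind, dtype=float)
    if p_soc is None:
        return p_ind
    p_soc = np.asarray(p_soc, dtype=float)
    if p_soc.shape != p_ind.shape:
        raise ValueError(
            f"probability vectors disagree in length: {p_ind.shape} vs {p_soc.shape}"
        )
    return (1.0 - gam_j) * p_ind + gam_j * p_soc


def link_learning_param(alpha_j: float, mu: float, age_j: float) -> float:
    """Logistic link from a varying intercept and age slope to (0, 1)."""
    return float(expit(alpha_j + mu * age_j))


def standardize_ages(ages: np.ndarray) -> np.ndarray:
    """Center ages and scale by the group SD (zeros if the SD is zero)."""
    ages = np.asarray(ages, dtype=float)
    sd = ages.std()
    if sd == 0:
        return np.zeros_like(ages)
    return (ages - ages.mean()) / sd
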