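"""Social-cue construction: moving-window tallies and the social choice rule.

Social information available to an observer at a decision is everything that
observer witnessed (was in the audience of) within a moving window of the
previous ``window_days`` days of bouts.  For each technique ``i`` the window
yields an observed frequency ``N_i`` and a 5-vector of aggregated cue values
``kappa_i`` (see :data:`ewalearn.core.CUE_NAMES`).  The social choice
probability is then log-linear in the cues with frequency dependence
exponent ``f``:

    S(i) = N_i^f * exp(B_i) / sum_k N_k^f * exp(B_k),
    B_i  = sum_k beta_k * kappa[i, k]

normalized over techniques actually observed (N_i > 0); with no observed
bouts at all there is no social term and the decision falls back to
individual attraction alone.  ``f = 1`` is unbiased (frequency-proportional)
copying, ``f > 1`` conformity, ``f < 1`` anti-conformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CUE_NAMES, TechniqueSet, payoff_from_outcome, standardize_ages

__all__ = [
    "BoutRecord",
    "CueWindowSummary",
    "RosterInfo",
    "cue_vector",
    "tally_window",
    "social_choice_probs",
    "preference_curve",
]


@dataclass(frozen=True)
class BoutRecord:
    """One observed or simulated fruit-processing attempt."""

    day: int
    seq: int
    actor: str
    technique: str
    success: bool
    duration_s: float
    audience: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "audience", frozenset(self.audience))
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if self.actor in self.audience:
            raise ValueError(f"actor {self.actor!r} cannot be in its own audience")
        if self.success and not self.duration_s > 0:
            raise ValueError("successful bout needs a positive duration")

    @property
    def payoff(self) -> float:
        return payoff_from_outcome(self.success, self.duration_s)


@dataclass
class CueWindowSummary:
    """Window tally for one decision: counts N_i and mean cue values kappa."""

    N: np.ndarray                  # (K,) observed bouts per technique
    kappa: np.ndarray              # (K, 5) mean cue values, zero rows where N=0
    window_days: int

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.N < 0):
            raise ValueError("counts must be non-negative")
        if self.kappa.shape != (len(self.N), len(CUE_NAMES)):
            raise ValueError("kappa must be (n_techniques, 5)")

    @property
    def empty(self) -> bool:
        return not np.any(self.N > 0)


class RosterInfo:
    """Fast lookups over an individual table (id, age_years, matriline, alpha).

    Ages are standardized against the group's own mean/SD once here; the
    standardized demonstrator age is the 'age bias' cue and also feeds the
    logistic links of the learning parameters.
    """

    def __init__(self, roster: pd.DataFrame):
        required = {"age_years", "matriline", "alpha"}
        missing = required - set(roster.columns)
        if missing:
            raise ValueError(f"roster is missing columns: {sorted(missing)}")
        if roster[["age_years", "matriline"]].isna().any().any():
            raise ValueError("roster has missing age or matriline entries")
        if (roster["age_years"] < 0).any():
            raise ValueError("ages must be >= 0")
        self.ids: tuple[str, ...] = tuple(str(i) for i in roster.index)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in roster")
        self.position = {j: r for r, j in enumerate(self.ids)}
        self.age = dict(zip(self.ids, roster["age_years"].astype(float)))
        ages_std = standardize_ages(roster["age_years"].to_numpy(dtype=float))
        self.age_std = dict(zip(self.ids, ages_std))
        self.ages_std = ages_std
        self.matriline = dict(zip(self.ids, roster["matriline"].astype(str)))
        self.alpha = dict(zip(self.ids, roster["alpha"].astype(bool)))

    def __contains__(self, j: object) -> bool:
        return j in self.position

    def __len__(self) -> int:
        return len(self.ids)


def _as_info(roster: pd.DataFrame | RosterInfo) -> RosterInfo:
    return roster if isinstance(roster, RosterInfo) else RosterInfo(roster)


def cue_vector(
    demonstrator: str,
    observer: str,
    outcome: tuple[bool, float],
    roster: pd.DataFrame | RosterInfo,
) -> np.ndarray:
    """Cue 5-vector for one observed demonstration, ordered as CUE_NAMES.

    pay  : 1/log(T_open) for a success, 0 for a failure
    rank : 1 if the demonstrator is the alpha, else 0
    kin  : 1 if demonstrator and observer share a matriline, else 0
    coho : inverse absolute age difference, 1/(1 + |age_d - age_o|)
    age  : demonstrator's standardized age
    """
    info = _as_info(roster)
    for j in (demonstrator, observer):
        if j not in info:
            raise ValueError(f"individual {j!r} not in roster")
    success, duration_s = outcome
    return np.array([
        payoff_from_outcome(success, duration_s),
        1.0 if info.alpha[demonstrator] else 0.0,
        1.0 if info.matriline[demonstrator] == info.matriline[observer] else 0.0,
        1.0 / (1.0 + abs(info.age[demonstrator] - info.age[observer])),
        info.age_std[demonstrator],
    ])


def in_window(
    bout: BoutRecord,
    observer: str,
    now_day: int,
    window_days: int,
    now_seq: int | None = None,
) -> bool:
    """Window membership for one bout.

    Bouts from the previous ``window_days`` full days (``now_day -
    window_days <= day < now_day``) count, plus same-day bouts that occurred
    earlier in sequence when ``now_seq`` is given.  The observer must be in
    the bout's audience; an individual's own bouts never appear (they are
    individual experience, carried by the attraction scores).
    """
    if observer not in bout.audience:
        return False
    if now_day - window_days <= bout.day < now_day:
        return True
    return bout.day == now_day and now_seq is not None and bout.seq < now_seq


def tally_window(
    history: list[BoutRecord],
    observer: str,
    now_day: int,
    window_days: int,
    *,
    techniques: TechniqueSet,
    roster: pd.DataFrame | RosterInfo,
    now_seq: int | None = None,
) -> CueWindowSummary:
    """Tally the observer's social-information window at (now_day, now_seq).

    N counts witnessed bouts per technique; kappa rows are the arithmetic
    mean of the cue vectors over those bouts (frequency information enters
    once, through N, so cues are averaged rather than summed).  Failed bouts
    count in N and contribute a zero pay-off cue.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    info = _as_info(roster)
    if observer not in info:
        raise KeyError(f"unknown observer {observer!r}")
    K = len(techniques)
    N = np.zeros(K, dtype=int)
    ksum = np.zeros((K, len(CUE_NAMES)))
    tix = techniques.index
    for b in history:
        if not in_window(b, observer, now_day, window_days, now_seq):
            continue
        i = tix[b.technique]
        N[i] += 1
        ksum[i] += cue_vector(b.actor, observer, (b.success, b.duration_s), info)
    kappa = np.zeros_like(ksum)
    seen = N > 0
    kappa[seen] = ksum[seen] / N[seen, None]
    return CueWindowSummary(N=N, kappa=kappa, window_days=window_days)


def social_choice_probs(
    summary: CueWindowSummary, f_j: float, beta_j: np.ndarray
) -> np.ndarray | None:
    """Social choice probabilities S_i from a window summary.

    S_i is proportional to N_i^f * exp(beta . kappa_i) over techniques with
    N_i > 0; unobserved techniques get probability 0.  Returns None when the
    window is empty (no social term exists for this decision).
    """
    if not f_j > 0:
        raise ValueError(f"f_j must be > 0, got {f_j}")
    beta_j = np.asarray(beta_j, dtype=float)
    if summary.empty:
        return None
    N = summary.N.astype(float)
    seen = N > 0
    # log-space for stability: f*log N + beta.kappa, softmax over seen options
    logw = np.full(len(N), -np.inf)
    logw[seen] = f_j * np.log(N[seen]) + summary.kappa[seen] @ beta_j
    logw -= logw[seen].max()
    w = np.exp(logw)
    return w / w.sum()


def preference_curve(
    freq_grid: np.ndarray,
    n_total: int,
    f_j: float,
    beta_j: np.ndarray,
    payoff_high: float,
) -> np.ndarray:
    """P(copy the high-pay-off option) vs its observed frequency, two options.

    At each grid frequency g, the high-pay-off option was seen
    ``g * n_total`` times with mean pay-off cue ``payoff_high``, the
    alternative the remaining times with all cues zero (e.g. never opened).
    With f = 1 and beta = 0 the curve is the diagonal — unbiased copying.
    """
    if n_total < 2:
        raise ValueError("need n_total >= 2 demonstrations")
    freq_grid = np.asarray(freq_grid, dtype=float)
    beta_j = np.asarray(beta_j, dtype=float)
    out = np.empty(len(freq_grid))
    for g_ix, g in enumerate(freq_grid):
        n_high = g * n_total
        if abs(n_high - round(n_high)) > 1e-9:
            raise ValueError(
                f"grid frequency {g} does not map to an integer count of {n_total}"
            )
        n_high = int(round(n_high))
        kappa = np.zeros((2, len(CUE_NAMES)))
        kappa[0, 0] = payoff_high
        summary = CueWindowSummary(
            N=np.array([n_high, n_total - n_high]), kappa=kappa, window_days=0
        )
        S = social_choice_probs(summary, f_j, beta_j)
        out[g_ix] = 0.0 if S is None else S[0]
    return out


class WindowIndex:
    """Incremental per-observer window tallies over a growing bout history.

    Shared engine for the forward simulator and the likelihood design
    builder: bouts are appended in (day, seq) order and queried with the same
    half-open window semantics as :func:`tally_window`, in O(window) per
    query with precomputed per-bout cue pieces.
    """

    def __init__(
        self,
        techniques: TechniqueSet,
        roster: pd.DataFrame | RosterInfo,
        window_days: int,
    ):
        if window_days < 1:
            raise ValueError(f"window_days must be >= 1, got {window_days}")
        self.techniques = techniques
        self.info = _as_info(roster)
        self.window_days = int(window_days)
        self._tix = techniques.index
        # parallel per-bout arrays
        self.days: list[int] = []
        self.seqs: list[int] = []
        self.tech_ix: list[int] = []
        self.pay: list[float] = []
        self.rank: list[float] = []
        self.age: list[float] = []
        self.age_std: list[float] = []
        self.mat: list[str] = []
        self.audience: list[frozenset[str]] = []

    def append(self, bout: BoutRecord) -> None:
        if self.days and (bout.day, bout.seq) < (self.days[-1], self.seqs[-1]):
            raise ValueError("bouts must be appended in (day, seq) order")
        d = bout.actor
        self.days.append(bout.day)
        self.seqs.append(bout.seq)
        self.tech_ix.append(self._tix[bout.technique])
        self.pay.append(payoff_from_outcome(bout.success, bout.duration_s))
        self.rank.append(1.0 if self.info.alpha[d] else 0.0)
        self.age.append(self.info.age[d])
        self.age_std.append(self.info.age_std[d])
        self.mat.append(self.info.matriline[d])
        self.audience.append(bout.audience)

    def query(self, observer: str, now_day: int, now_seq: int) -> CueWindowSummary:
        K = len(self.techniques)
        N = np.zeros(K, dtype=int)
        ksum = np.zeros((K, len(CUE_NAMES)))
        obs_age = self.info.age[observer]
        obs_mat = self.info.matriline[observer]
        wd = self.window_days
        # walk backwards; history is day-ordered so we can stop early
        for b in range(len(self.days) - 1, -1, -1):
            day = self.days[b]
            if day < now_day - wd:
                break
            if day > now_day or (day == now_day and self.seqs[b] >= now_seq):
                continue
            if observer not in self.audience[b]:
                continue
            i = self.tech_ix[b]
            N[i] += 1
            ksum[i, 0] += self.pay[b]
            ksum[i, 1] += self.rank[b]
            ksum[i, 2] += 1.0 if self.mat[b] == obs_mat else 0.0
            ksum[i, 3] += 1.0 / (1.0 + abs(self.age[b] - obs_age))
            ksum[i, 4] += self.age_std[b]
        kappa = np.zeros_like(ksum)
        seen = N > 0
        kappa[seen] = ksum[seen] / N[seen, None]
        return CueWindowSummary(N=N, kappa=kappa, window_days=wd)
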