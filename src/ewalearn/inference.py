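"""Multilevel Bayesian fitting of EWA learning models to bout tables.

The likelihood replays the bout table once in time order: at each bout the
probability of the observed technique is the individual/social mixture given
the actor's current attractions and its social-information window, and the
actor's attraction is then updated with the realized pay-off.  Social-window
tallies depend only on the data, so they are precomputed once into a
:class:`Design`; the per-bout replay as a function of parameters is a tight
loop compiled with numba.

Individual-level parameters are tied to population-level means, standardized
age slopes and mean-zero individual deviations (non-centered, independent
per parameter) through logistic links for phi and gam and a log link for f.
Posterior sampling uses the affine-invariant ensemble sampler (emcee) behind
a single ``fit_model`` interface; walkers play the role of chains.
Weakly-informative priors: standard normal on cue weights, link-scale
intercepts and slopes; half-normal(1) on between-individual SDs; normal(1,1)
on log lambda.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import CUE_NAMES, LearnerParams, TechniqueSet
from .cues import BoutRecord, RosterInfo, WindowIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "spec_by_label",
    "canonical_specs",
    "PriorSet",
    "MCMCConfig",
    "Design",
    "build_design",
    "log_likelihood",
    "FitResult",
    "fit_model",
    "recover",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

_VALID_VARYING = frozenset({"phi", "gam", "f"} | {f"b_{c}" for c in CUE_NAMES})


@dataclass(frozen=True)
class ModelSpec:
    """One learning strategy: which components of the full model are free.

    social_learning off means gam is fixed at 0 (pure individual learning);
    frequency_dependence off fixes f = 1 (unbiased frequency use);
    cues_active lists the cue weights estimated (others fixed at 0);
    age_effects frees the standardized-age slopes on phi and gam;
    varying_effects lists parameters given per-individual deviations.
    """

    label: str
    social_learning: bool = False
    frequency_dependence: bool = False
    cues_active: tuple[str, ...] = ()
    age_effects: bool = False
    varying_effects: tuple[str, ...] = ("phi",)
    window_days: int = 14

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues_active",
                           tuple(c for c in CUE_NAMES if c in self.cues_active))
        bad = set(self.varying_effects) - _VALID_VARYING
        if bad:
            raise ValueError(f"unknown varying effects: {sorted(bad)}")
        unknown = set(self.cues_active) - set(CUE_NAMES)
        if unknown:
            raise ValueError(f"unknown cues: {sorted(unknown)}")
        if not self.social_learning and (self.cues_active or self.frequency_dependence):
            raise ValueError(
                "cues/frequency dependence require social_learning=True"
            )
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    # -- canonical strategy set ---------------------------------------------

    @classmethod
    def individual_only(cls, **kw) -> "ModelSpec":
        return cls(label="individual-only", social_learning=False, **kw)

    @classmethod
    def unbiased_frequency(cls, **kw) -> "ModelSpec":
        return cls(label="unbiased-frequency", social_learning=True,
                   varying_effects=("phi", "gam"), **kw)

    @classmethod
    def frequency_dependent(cls, **kw) -> "ModelSpec":
        return cls(label="frequency-dependent", social_learning=True,
                   frequency_dependence=True, varying_effects=("phi", "gam"), **kw)

    @classmethod
    def single_cue(cls, cue: str, **kw) -> "ModelSpec":
        if cue not in CUE_NAMES:
            raise ValueError(f"unknown cue {cue!r}")
        return cls(label=f"cue-{cue}", social_learning=True,
                   cues_active=(cue,), varying_effects=("phi", "gam"), **kw)

    @classmethod
    def global_model(cls, age_effects: bool = True,
                     varying_effects: tuple[str, ...] = ("phi", "gam", "f", "b_pay"),
                     **kw) -> "ModelSpec":
        return cls(label="global", social_learning=True,
                   frequency_dependence=True, cues_active=CUE_NAMES,
                   age_effects=age_effects, varying_effects=varying_effects, **kw)


def canonical_specs(window_days: int = 14) -> list[ModelSpec]:
    """The nine-strategy model set.

    Individual learning only; unbiased frequency copying; frequency-dependent
    copying (f free); one model per single cue (pay-off, rank, kin, age
    similarity, age bias); and the global model with every cue, free f and
    age effects on phi and gam.
    """
    return [
        ModelSpec.individual_only(window_days=window_days),
        ModelSpec.unbiased_frequency(window_days=window_days),
        ModelSpec.frequency_dependent(window_days=window_days),
        *[ModelSpec.single_cue(c, window_days=window_days) for c in CUE_NAMES],
        ModelSpec.global_model(window_days=window_days),
    ]


_LABELS = {
    "individual-only": ModelSpec.individual_only,
    "unbiased-frequency": ModelSpec.unbiased_frequency,
    "frequency-dependent": ModelSpec.frequency_dependent,
    **{f"cue-{c}": (lambda c=c, **kw: ModelSpec.single_cue(c, **kw)) for c in CUE_NAMES},
    "global": ModelSpec.global_model,
}


def spec_by_label(label: str, **kw) -> ModelSpec:
    try:
        return _LABELS[label](**kw)
    except KeyError:
        raise ValueError(
            f"unknown model label {label!r}; valid labels: {sorted(_LABELS)}"
        ) from None


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSet:
    """Weakly informative priors, as (mean, sd) pairs on the sampled scale."""

    log_lam: tuple[float, float] = (1.0, 1.0)
    intercept: tuple[float, float] = (0.0, 1.0)   # a_phi, a_gam (log-odds)
    slope: tuple[float, float] = (0.0, 1.0)       # mu_phi, mu_gam
    log_f: tuple[float, float] = (0.0, 1.0)
    beta: tuple[float, float] = (0.0, 1.0)
    sigma_scale: float = 1.0                      # half-normal scale on SDs


# ---------------------------------------------------------------------------
# Likelihood design (data-dependent, parameter-free precomputation)
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Bout table compiled to arrays for the likelihood replay."""

    actor_ix: np.ndarray      # (n,) int
    tech_ix: np.ndarray       # (n,) int
    payoff: np.ndarray        # (n,) float
    N: np.ndarray             # (n, K) float window counts
    kappa: np.ndarray         # (n, K, 5) mean cue values
    has_soc: np.ndarray       # (n,) bool
    A0: np.ndarray            # (J, K) initial attractions
    info: RosterInfo
    techniques: TechniqueSet
    window_days: int

    @property
    def n_bouts(self) -> int:
        return len(self.actor_ix)

    @property
    def n_individuals(self) -> int:
        return len(self.info)


def build_design(
    bouts: list[BoutRecord],
    roster: pd.DataFrame | RosterInfo,
    techniques: TechniqueSet,
    window_days: int = 14,
    initial_attractions: dict[str, np.ndarray] | None = None,
) -> Design:
    """Precompute every parameter-free piece of the likelihood.

    Bouts must already be in strictly increasing (day, seq) order; silently
    re-sorting would corrupt the attraction dynamics, so disorder is an
    error.
    """
    info = roster if isinstance(roster, RosterInfo) else RosterInfo(roster)
    n, K = len(bouts), len(techniques)
    keys = [(b.day, b.seq) for b in bouts]
    if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
        raise ValueError("bouts must be sorted by (day, seq) with unique keys")
    actor_ix = np.empty(n, dtype=np.int64)
    tech_ix = np.empty(n, dtype=np.int64)
    payoff = np.empty(n)
    N = np.zeros((n, K))
    kappa = np.zeros((n, K, len(CUE_NAMES)))
    widx = WindowIndex(techniques, info, window_days)
    tix = techniques.index
    for m, b in enumerate(bouts):
        if b.actor not in info:
            raise KeyError(f"actor {b.actor!r} not in roster (bout {m})")
        if b.technique not in tix:
            raise KeyError(f"technique {b.technique!r} not in technique set (bout {m})")
        summary = widx.query(b.actor, b.day, b.seq)
        actor_ix[m] = info.position[b.actor]
        tech_ix[m] = tix[b.technique]
        payoff[m] = b.payoff
        N[m] = summary.N
        kappa[m] = summary.kappa
        widx.append(b)
    A0 = np.zeros((len(info), K))
    if initial_attractions:
        for j, row in initial_attractions.items():
            A0[info.position[str(j)]] = np.asarray(row, dtype=float)
    return Design(
        actor_ix=actor_ix, tech_ix=tech_ix, payoff=payoff, N=N, kappa=kappa,
        has_soc=N.sum(axis=1) > 0, A0=A0, info=info, techniques=techniques,
        window_days=window_days,
    )


@njit(cache=True)
def _replay_kernel(actor_ix, tech_ix, payoff, N, kappa, has_soc, A0,
                   lam, phi, gam, f, beta):  # pragma: no cover - compiled
    n, K = N.shape
    A = A0.copy()
    out = np.empty(n)
    p = np.empty(K)
    logw = np.empty(K)
    for m in range(n):
        j = actor_ix[m]
        # individual component: softmax(lam * A[j])
        mx = lam * A[j, 0]
        for i in range(1, K):
            v = lam * A[j, i]
            if v > mx:
                mx = v
        tot = 0.0
        for i in range(K):
            p[i] = math.exp(lam * A[j, i] - mx)
            tot += p[i]
        for i in range(K):
            p[i] /= tot
        # social component over observed techniques
        if has_soc[m]:
            mxw = -1.0e308
            for i in range(K):
                if N[m, i] > 0.0:
                    w = f[j] * math.log(N[m, i])
                    for k in range(kappa.shape[2]):
                        w += beta[j, k] * kappa[m, i, k]
                    logw[i] = w
                    if w > mxw:
                        mxw = w
                else:
                    logw[i] = -np.inf
            stot = 0.0
            for i in range(K):
                logw[i] = math.exp(logw[i] - mxw) if logw[i] > -np.inf else 0.0
                stot += logw[i]
            g = gam[j]
            for i in range(K):
                p[i] = (1.0 - g) * p[i] + g * logw[i] / stot
        out[m] = math.log(p[tech_ix[m]])
        c = tech_ix[m]
        A[j, c] = (1.0 - phi[j]) * A[j, c] + phi[j] * payoff[m]
    return out


def _pointwise(design: Design, learner: LearnerParams) -> np.ndarray:
    return _replay_kernel(
        design.actor_ix, design.tech_ix, design.payoff, design.N, design.kappa,
        design.has_soc, design.A0, float(learner.lam), learner.phi, learner.gam,
        learner.f, learner.beta,
    )


def log_likelihood(
    bouts: list[BoutRecord],
    roster: pd.DataFrame | RosterInfo,
    techniques: TechniqueSet,
    learner: LearnerParams,
    window_days: int = 14,
    initial_attractions: dict[str, np.ndarray] | None = None,
    design: Design | None = None,
) -> tuple[float, np.ndarray]:
    """Total and per-bout log-likelihood of a bout table.

    ``learner`` holds the realized per-individual parameters, ordered as the
    roster; pass a prebuilt ``design`` to skip the window precomputation.
    """
    if design is None:
        design = build_design(bouts, roster, techniques, window_days,
                              initial_attractions)
    if learner.n_individuals != design.n_individuals:
        raise ValueError(
            f"learner has {learner.n_individuals} individuals, "
            f"roster has {design.n_individuals}"
        )
    pointwise = _pointwise(design, learner)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Parameter layout: spec -> flat unconstrained vector
# ---------------------------------------------------------------------------

class ParamLayout:
    """Mapping between a flat unconstrained vector and realized parameters.

    Layout per free component: a population mean (log / log-odds scale), an
    optional age slope, and optionally a log-SD plus J standardized
    deviations (non-centered).
    """

    def __init__(self, spec: ModelSpec, ages_std: np.ndarray, priors: PriorSet):
        self.spec = spec
        self.ages_std = np.asarray(ages_std, dtype=float)
        self.priors = priors
        J = len(self.ages_std)
        self.J = J
        names: list[str] = []
        mean: list[float] = []
        sd: list[float] = []
        is_log_sigma: list[bool] = []

        def add(name, prior, log_sigma=False):
            names.append(name)
            mean.append(prior[0])
            sd.append(prior[1])
            is_log_sigma.append(log_sigma)
            return len(names) - 1

        def add_block(base, prior, varying):
            ix = {"mean": add(base, prior)}
            if varying:
                ix["log_sigma"] = add(f"log_sigma_{base}", (0.0, 1.0), log_sigma=True)
                ix["z"] = [add(f"z_{base}[{j}]", (0.0, 1.0)) for j in range(J)]
            return ix

        v = set(spec.varying_effects)
        self.i_log_lam = add("log_lam", priors.log_lam)
        self.phi = add_block("a_phi", priors.intercept, "phi" in v)
        if spec.age_effects:
            self.phi["mu"] = add("mu_phi", priors.slope)
        self.gam = None
        if spec.social_learning:
            self.gam = add_block("a_gam", priors.intercept, "gam" in v)
            if spec.age_effects:
                self.gam["mu"] = add("mu_gam", priors.slope)
        self.f = None
        if spec.social_learning and spec.frequency_dependence:
            self.f = add_block("log_f", priors.log_f, "f" in v)
        self.b = {}
        if spec.social_learning:
            for cue in spec.cues_active:
                self.b[cue] = add_block(f"b_{cue}", priors.beta, f"b_{cue}" in v)

        self.names = names
        self._mean = np.array(mean)
        self._sd = np.array(sd)
        self._is_ls = np.array(is_log_sigma, dtype=bool)
        self.ndim = len(names)
        self._ix = {n: i for i, n in enumerate(names)}

    def _block_values(self, theta: np.ndarray, block, link) -> np.ndarray:
        x = np.full(self.J, theta[block["mean"]])
        if "z" in block:
            sigma = math.exp(theta[block["log_sigma"]])
            x = x + sigma * theta[block["z"]]
        if "mu" in block:
            x = x + theta[block["mu"]] * self.ages_std
        return link(x)

    def unpack(self, theta: np.ndarray) -> LearnerParams:
        """Realize per-individual learning parameters from a flat vector."""
        theta = np.asarray(theta, dtype=float)
        J = self.J
        lam = math.exp(theta[self.i_log_lam])
        phi = self._block_values(theta, self.phi, expit)
        gam = (self._block_values(theta, self.gam, expit)
               if self.gam is not None else np.zeros(J))
        f = (self._block_values(theta, self.f, np.exp)
             if self.f is not None else np.ones(J))
        beta = np.zeros((J, len(CUE_NAMES)))
        for cue, block in self.b.items():
            beta[:, CUE_NAMES.index(cue)] = self._block_values(
                theta, block, lambda x: x)
        return LearnerParams(lam=lam, phi=phi, gam=gam, f=f, beta=beta)

    def log_prior(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        norm = ~self._is_ls
        z = (theta[norm] - self._mean[norm]) / self._sd[norm]
        lp = -0.5 * float(z @ z) - float(np.log(self._sd[norm]).sum())
        if self._is_ls.any():
            ls = theta[self._is_ls]
            sigma = np.exp(ls)
            scale = self.priors.sigma_scale
            # half-normal(scale) on sigma, with log-scale Jacobian
            lp += float(ls.sum() - 0.5 * np.sum((sigma / scale) ** 2))
        return lp

    def init_positions(self, nwalkers: int, rng: np.random.Generator) -> np.ndarray:
        """Walker starting points: prior means with modest scatter.

        Log-SDs start near log(0.3) so varying effects begin small.
        """
        center = np.where(self._is_ls, math.log(0.3), self._mean)
        scatter = np.where(self._is_ls, 0.3, 0.5 * self._sd)
        return center + scatter * rng.standard_normal((nwalkers, self.ndim))

    def prior_draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Exact draws from the prior (for prior-predictive checks)."""
        out = np.empty((size, self.ndim))
        for i in range(self.ndim):
            if self._is_ls[i]:
                out[:, i] = np.log(np.abs(
                    rng.normal(0.0, self.priors.sigma_scale, size)))
            else:
                out[:, i] = rng.normal(self._mean[i], self._sd[i], size)
        return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings: chains are emcee walkers.

    Walkers start in a tight ball around a MAP estimate (L-BFGS) and move by
    differential-evolution proposals, which keeps burn-in short even for the
    hierarchical specs with per-individual deviations.
    """

    chains: int | None = None     # default: max(2*ndim + 2, 32), rounded even
    iterations: int = 1500
    warmup: int = 500
    seed: int = 0
    max_draws: int = 1000         # posterior draws kept (thinned)
    map_init: bool = True

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")


@dataclass
class FitResult:
    """Posterior sample, pointwise log-likelihood and diagnostics for one spec."""

    draws: pd.DataFrame           # (n_draws, ndim) named columns
    pointwise_loglik: np.ndarray  # (n_draws, n_bouts)
    diagnostics: dict
    spec: ModelSpec
    seed: int
    layout: ParamLayout

    @property
    def n_points(self) -> int:
        return self.pointwise_loglik.shape[1]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def learner_draws(self) -> list[LearnerParams]:
        """Per-draw realized individual-level parameters."""
        return [self.layout.unpack(row) for row in self.draws.to_numpy()]

    def population_draws(self) -> pd.DataFrame:
        """Draws of interpretable population-level quantities.

        lam; phi_mean / gam_mean (population-mean individual at the average
        age, on the probability scale); f; active cue weights; age slopes.
        """
        d = self.draws
        out = {"lam": np.exp(d["log_lam"])}
        out["phi_mean"] = expit(d["a_phi"])
        if "a_gam" in d:
            out["gam_mean"] = expit(d["a_gam"])
        if "log_f" in d:
            out["f"] = np.exp(d["log_f"])
        for col in d.columns:
            if col.startswith("b_") or col.startswith("mu_"):
                out[col] = d[col]
        return pd.DataFrame(out)

    def summary(self, ci: float = 0.89) -> pd.DataFrame:
        """Median and central credible interval per population quantity."""
        pop = self.population_draws()
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        return pd.DataFrame({
            "median": pop.median(),
            f"lo{ci:.0%}": pop.quantile(lo / 100),
            f"hi{ci:.0%}": pop.quantile(hi / 100),
        })


def fit_model(
    bouts: list[BoutRecord],
    roster: pd.DataFrame | RosterInfo,
    techniques: TechniqueSet,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
    priors: PriorSet | None = None,
    initial_attractions: dict[str, np.ndarray] | None = None,
    design: Design | None = None,
) -> FitResult:
    """Sample the posterior of one model spec on a bout table.

    Deterministic for fixed data, spec and MCMC seed.  Non-convergence (by
    split-R-hat across walkers) flags the result and logs a warning; it does
    not raise.
    """
    import emcee

    mcmc = mcmc or MCMCConfig()
    priors = priors or PriorSet()
    info = roster if isinstance(roster, RosterInfo) else RosterInfo(roster)
    if design is None:
        design = build_design(bouts, info, techniques, spec.window_days,
                              initial_attractions)
    layout = ParamLayout(spec, info.ages_std, priors)

    def log_prob(theta):
        lp = layout.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = _pointwise(design, layout.unpack(theta)).sum()
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    ndim = layout.ndim
    nwalkers = mcmc.chains or max(2 * ndim + 2, 32)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(mcmc.seed)
    if mcmc.map_init:
        from scipy.optimize import minimize

        def neg(t):  # finite surrogate so finite differences stay defined
            lp = log_prob(t)
            return -lp if np.isfinite(lp) else 1e12 + float(t @ t)

        x0 = np.where(layout._is_ls, math.log(0.3), layout._mean)
        res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 500})
        p0 = res.x + 0.05 * rng.standard_normal((nwalkers, ndim))
    else:
        p0 = layout.init_positions(nwalkers, rng)
    # nudge any starting point with non-finite posterior toward the center
    for w in range(nwalkers):
        tries = 0
        while not np.isfinite(log_prob(p0[w])) and tries < 50:
            p0[w] = layout.init_positions(1, rng)[0] * 0.5
            tries += 1

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(mcmc.seed).get_state())
    sampler.run_mcmc(state, mcmc.iterations, progress=False)

    chain = sampler.get_chain(discard=mcmc.warmup)      # (steps, walkers, ndim)
    diagnostics = _diagnostics(chain, layout.names,
                               float(np.mean(sampler.acceptance_fraction)))
    if not diagnostics["converged"]:
        logger.warning(
            "fit of %s flagged as non-converged (max R-hat %.3f, "
            "mean acceptance %.2f)", spec.label,
            diagnostics["max_rhat"], diagnostics["mean_acceptance"],
        )

    flat = chain.reshape(-1, ndim)
    stride = max(1, len(flat) // mcmc.max_draws)
    kept = flat[::stride][: mcmc.max_draws]
    draws = pd.DataFrame(kept, columns=layout.names)
    pointwise = np.empty((len(kept), design.n_bouts))
    for s, row in enumerate(kept):
        pointwise[s] = _pointwise(design, layout.unpack(row))
    if np.isnan(pointwise).any():
        raise RuntimeError("NaN in pointwise log-likelihood")
    return FitResult(draws=draws, pointwise_loglik=pointwise,
                     diagnostics=diagnostics, spec=spec, seed=mcmc.seed,
                     layout=layout)


def _diagnostics(chain: np.ndarray, names: list[str], accept: float) -> dict:
    """R-hat / ESS over walkers-as-chains, via arviz."""
    import arviz as az

    # arviz wants (chain, draw, ...)
    posterior = {n: chain[:, :, i].T for i, n in enumerate(names)}
    idata = az.convert_to_dataset(posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    max_rhat = float(max(rhat[n].values for n in names))
    min_ess = float(min(ess[n].values for n in names))
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "mean_acceptance": accept,
        "converged": bool(max_rhat < 1.2 and min_ess > 50),
    }


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def recover(
    true_config,
    spec: ModelSpec,
    n_replicates: int,
    seeds: list[int] | None = None,
    mcmc: MCMCConfig | None = None,
    ci: float = 0.89,
) -> pd.DataFrame:
    """Simulate-and-refit study: bias, RMSE and interval coverage.

    Each replicate simulates a fresh bout table from ``true_config`` (new
    individual-level deviations each time), fits ``spec``, and compares the
    posterior of each population-level quantity with its generating value.
    Returns one row per tracked parameter with columns truth, mean posterior
    median, bias, rmse, coverage (fraction of replicates whose central
    ``ci`` interval contains the truth), sign_rate (posterior median matches
    the truth's sign), excludes_zero_rate (interval excludes zero) and the
    per-replicate medians.
    """
    from .simulate import simulate_group

    if n_replicates == 0:
        return pd.DataFrame(
            columns=["parameter", "truth", "median", "bias", "rmse", "coverage"]
        )
    if seeds is None:
        seeds = [10_000 + 13 * r for r in range(n_replicates)]
    if len(seeds) < n_replicates:
        raise ValueError("need one seed per replicate")
    tp = true_config.true_params
    truth = {"lam": tp.lam, "phi_mean": tp.mean_phi(), }
    if spec.social_learning:
        truth["gam_mean"] = tp.mean_gam()
        if spec.frequency_dependence:
            truth["f"] = math.exp(tp.log_f)
        for cue in spec.cues_active:
            truth[f"b_{cue}"] = tp.beta[CUE_NAMES.index(cue)]
    if spec.age_effects:
        truth["mu_phi"] = tp.mu_phi
        truth["mu_gam"] = tp.mu_gam

    lo_q, hi_q = (1 - ci) / 2, (1 + ci) / 2
    medians: dict[str, list[float]] = {k: [] for k in truth}
    covered: dict[str, list[bool]] = {k: [] for k in truth}
    excludes: dict[str, list[bool]] = {k: [] for k in truth}
    for r in range(n_replicates):
        bouts = simulate_group(true_config, seed=seeds[r])
        m = mcmc or MCMCConfig()
        fit = fit_model(bouts, true_config.roster, true_config.technique_set,
                        spec, mcmc=replace(m, seed=seeds[r] % (2**31)),
                        initial_attractions=true_config.initial_attractions)
        pop = fit.population_draws()
        for k in truth:
            med = float(pop[k].median())
            lo, hi = float(pop[k].quantile(lo_q)), float(pop[k].quantile(hi_q))
            medians[k].append(med)
            covered[k].append(lo <= truth[k] <= hi)
            excludes[k].append(lo > 0 or hi < 0)

    rows = []
    for k, t in truth.items():
        med = np.array(medians[k])
        rows.append({
            "parameter": k, "truth": t, "median": med.mean(),
            "bias": float((med - t).mean()),
            "rmse": float(np.sqrt(((med - t) ** 2).mean())),
            "coverage": float(np.mean(covered[k])),
            "sign_rate": float(np.mean(np.sign(med) == np.sign(t))) if t else np.nan,
            "excludes_zero_rate": float(np.mean(excludes[k])),
            "replicate_medians": medians[k],
        })
    return pd.DataFrame(rows)
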