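"""WAIC model comparison and window-width sensitivity.

WAIC (widely applicable information criterion) scores out-of-sample
predictive accuracy from the pointwise posterior log-likelihood matrix
``ll[s, i]`` (draw s, bout i):

    lppd   = sum_i log mean_s exp(ll[s, i])
    p_waic = sum_i var_s ll[s, i]
    WAIC   = -2 (lppd - p_waic)

The pointwise unit is the single bout-choice event.  Model weights follow
the Akaike rule w_m proportional to exp(-dWAIC_m / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import FitResult, MCMCConfig, ModelSpec, PriorSet, fit_model

__all__ = ["WAICResult", "ModelTable", "waic", "compare_models", "window_sensitivity"]


@dataclass(frozen=True)
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.p_waic < 0:
            raise ValueError("p_waic must be >= 0")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if abs(self.waic - (-2.0 * (self.lppd - self.p_waic))) > 1e-10 * max(
            1.0, abs(self.waic)
        ):
            raise ValueError("waic must equal -2*(lppd - p_waic)")


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from a (draws x points) pointwise log-likelihood matrix.

    Requires at least two draws (the effective-parameter term is a variance
    over draws) and one point; the standard error is sqrt(n * var) of the
    per-point WAIC contributions.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be a 2-D (draws x points) matrix")
    S, n = ll.shape
    if S < 2:
        raise ValueError("need >= 2 posterior draws (variance over draws undefined)")
    if n < 1:
        raise ValueError("need >= 1 pointwise entry")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    w_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * w_i.var(ddof=1))) if n > 1 else 0.0
    lppd, p = float(lppd_i.sum()), float(p_i.sum())
    return WAICResult(lppd=lppd, p_waic=p, waic=-2.0 * (lppd - p), se=se, n_points=n)


@dataclass
class ModelTable:
    """Ranked model-comparison table with Akaike-style WAIC weights."""

    table: pd.DataFrame   # columns: label, waic, se, p_waic, lppd, d_waic, weight

    def __post_init__(self) -> None:
        w = self.table["weight"].to_numpy()
        if np.any(w < 0) or np.any(w > 1) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must lie in [0, 1] and sum to 1")
        if abs(self.table["d_waic"].iloc[0]) > 1e-12:
            raise ValueError("best model must have d_waic = 0")

    @property
    def best(self) -> str:
        return str(self.table["label"].iloc[0])


def compare_models(fits: list[FitResult]) -> ModelTable:
    """WAIC-rank a set of fits of different specs on identical data."""
    if not fits:
        raise ValueError("need at least one fit")
    n_points = {f.n_points for f in fits}
    if len(n_points) != 1:
        raise ValueError(
            f"fits disagree on the number of pointwise units: {sorted(n_points)}"
        )
    rows = []
    for f in fits:
        w = waic(f.pointwise_loglik)
        rows.append({"label": f.spec.label, "waic": w.waic, "se": w.se,
                     "p_waic": w.p_waic, "lppd": w.lppd})
    df = pd.DataFrame(rows).sort_values("waic", kind="stable", ignore_index=True)
    df["d_waic"] = df["waic"] - df["waic"].iloc[0]
    rel = np.exp(-0.5 * df["d_waic"].to_numpy())
    df["weight"] = rel / rel.sum()
    return ModelTable(table=df)


def window_sensitivity(
    bouts,
    roster,
    techniques,
    spec: ModelSpec,
    widths: tuple[int, ...] = (7, 14, 21, 28),
    mcmc: MCMCConfig | None = None,
    priors: PriorSet | None = None,
    initial_attractions=None,
) -> pd.DataFrame:
    """Refit one spec at several social-window widths.

    Returns one row per width with the WAIC fields and the posterior medians
    of the population-level quantities, for checking that the sign and
    magnitude of the social-learning parameters are stable in the window
    choice.
    """
    rows = []
    for w in widths:
        if w < 1:
            raise ValueError(f"window width must be a positive integer, got {w}")
        fit = fit_model(bouts, roster, techniques, replace(spec, window_days=w),
                        mcmc=mcmc, priors=priors,
                        initial_attractions=initial_attractions)
        wa = waic(fit.pointwise_loglik)
        row = {"window_days": w, "waic": wa.waic, "se": wa.se, "p_waic": wa.p_waic}
        for name, med in fit.population_draws().median().items():
            row[f"median_{name}"] = float(med)
        rows.append(row)
    return pd.DataFrame(rows)
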