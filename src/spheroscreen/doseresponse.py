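"""Sigmoid dose-response fitting and Bayesian IC50 inference.

The dose-response model is the variable-slope Hill curve

    Y(X) = scale / (1 + (IC50 / X) ** HillSlope)

with HillSlope < 0 for an inhibitory response (Y falls from the upper
plateau toward 0 as the dose X increases past the IC50).  Continuous
metabolic activities are fitted by nonlinear least squares (scale = 100).
Binary predicted classes (0 = low viability, 1 = high) are fitted with a
Bernoulli likelihood p(X) = 1 / (1 + (IC50/X)**HillSlope) sampled by an
affine-invariant ensemble MCMC (emcee): uniform priors IC50 in (0, 20] uM
and HillSlope in [-50, -0.1], 32 walkers, 500 retained iterations after a
500-iteration burn-in, posterior medians and 2.5/97.5 percentiles reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "sigmoid_response",
    "fit_continuous",
    "fit_binary_bayes",
    "posterior_mode",
    "grid_ml_binary",
    "predicted_dose_response_table",
]

PRIOR_IC50 = (0.0, 20.0)
PRIOR_SLOPE = (-50.0, -0.1)
_P_CEIL = 1.0 - 1e-9  # numerical stand-in for the exact control plateau p = 1


def sigmoid_response(X, ic50: float, hillslope: float, scale: float = 100.0):
    """Variable-slope sigmoid ``scale / (1 + (ic50/X)**hillslope)``.

    ``X`` must be positive (zero-dose controls sit on the upper plateau and
    are handled by the caller).  ``scale`` is 100 for metabolic percentages
    and 1 for class probabilities.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("X must be positive; map controls to the plateau")
    out = scale / (1.0 + (ic50 / X) ** hillslope)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseFit:
    """A fitted dose-response curve with uncertainty intervals."""

    mode: str  # "continuous" or "binary_bayes"
    ic50: float
    hillslope: float
    ic50_interval: tuple[float, float]
    hillslope_interval: tuple[float, float]
    r_squared: float | None = None
    converged: bool = True
    flagged_poor_fit: bool = False
    seed: int | None = None
    posterior: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {
            "mode": self.mode,
            "ic50": self.ic50,
            "hillslope": self.hillslope,
            "ic50_interval_95": list(self.ic50_interval),
            "hillslope_interval_95": list(self.hillslope_interval),
            "converged": self.converged,
            "flagged_poor_fit": self.flagged_poor_fit,
        }
        if self.r_squared is not None:
            out["r_squared"] = self.r_squared
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def fit_continuous(activities, concentrations) -> DoseResponseFit:
    """Least-squares Hill fit of continuous metabolic activity (%).

    Zero-dose rows are dropped (they define the 100% plateau by
    normalization).  Reports IC50 and Hill slope with 95% Wald intervals
    from the fit covariance and the coefficient of determination; fits with
    R^2 < 0.5 are flagged as poor, and non-convergence yields a flagged fit
    rather than an exception.
    """
    y = np.asarray(activities, dtype=float)
    x = np.asarray(concentrations, dtype=float)
    if y.size != x.size:
        raise ValueError("activities and concentrations must align")
    pos = x > 0
    x, y = x[pos], y[pos]
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct positive concentrations")

    def model(X, ic50, slope):
        return 100.0 / (1.0 + (ic50 / X) ** slope)

    p0 = (float(np.exp(np.mean(np.log(x)))), -1.0)
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=p0, bounds=((1e-9, -50.0), (1e4, -1e-3)), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return DoseResponseFit(
            "continuous", float("nan"), float("nan"), (float("nan"),) * 2,
            (float("nan"),) * 2, r_squared=float("nan"),
            converged=False, flagged_poor_fit=True,
        )
    resid = y - model(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    ic50, slope = float(popt[0]), float(popt[1])
    return DoseResponseFit(
        "continuous",
        ic50,
        slope,
        (ic50 - 1.96 * float(se[0]), ic50 + 1.96 * float(se[0])),
        (slope - 1.96 * float(se[1]), slope + 1.96 * float(se[1])),
        r_squared=r2,
        flagged_poor_fit=not np.isfinite(r2) or r2 < 0.5,
    )


def _binary_log_likelihood(theta, x, y):
    ic50, slope = theta
    p = np.empty_like(x)
    zero = x <= 0
    p[zero] = _P_CEIL  # controls sit on the upper plateau
    p[~zero] = 1.0 / (1.0 + (ic50 / x[~zero]) ** slope)
    p = np.clip(p, 1e-12, _P_CEIL)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _log_posterior(theta, x, y):
    ic50, slope = theta
    if not (PRIOR_IC50[0] < ic50 <= PRIOR_IC50[1]):
        return -np.inf
    if not (PRIOR_SLOPE[0] <= slope <= PRIOR_SLOPE[1]):
        return -np.inf
    return _binary_log_likelihood(theta, x, y)


def fit_binary_bayes(
    classes,
    concentrations,
    n_walkers: int = 32,
    n_steps: int = 500,
    n_burn: int = 500,
    seed: int = 0,
) -> DoseResponseFit:
    """Bayesian logistic dose-response fit of binary viability classes.

    ``classes`` are 0 (low viability) / 1 (high viability); string labels
    "low"/"high" are accepted.  Ensemble MCMC with uniform priors on the
    IC50 and Hill slope; walkers start in a small Gaussian ball around a
    coarse grid maximum-likelihood point (uniform-box starts leave walkers
    permanently stranded when the posterior is much narrower than the prior,
    as the stretch move cannot contract across the gap).  Deterministic for
    a fixed seed.
    """
    y = np.asarray(classes)
    if y.dtype.kind in "OUS":
        y = (y == "high").astype(float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(concentrations, dtype=float)
    if y.size != x.size:
        raise ValueError("classes and concentrations must align")
    if np.all(y == 0) or np.all(y == 1):
        raise ValueError("no transition in data: both classes must be present")

    rng = np.random.RandomState(seed)
    start = grid_ml_binary(y, x, n_ic50=80, n_slope=40)
    p0 = np.column_stack(
        [
            np.clip(
                start[0] + 0.05 * (PRIOR_IC50[1] - PRIOR_IC50[0]) * rng.randn(n_walkers),
                PRIOR_IC50[0] + 1e-3,
                PRIOR_IC50[1],
            ),
            np.clip(
                start[1] + 0.05 * (PRIOR_SLOPE[1] - PRIOR_SLOPE[0]) * rng.randn(n_walkers),
                PRIOR_SLOPE[0],
                PRIOR_SLOPE[1],
            ),
        ]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 2, _log_posterior, args=(x, y))
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(p0, n_burn, progress=False)
    sampler.run_mcmc(state, n_steps, progress=False)

    chain = sampler.get_chain(discard=n_burn, flat=True)
    logp = sampler.get_log_prob(discard=n_burn, flat=True)
    posterior = pd.DataFrame(chain, columns=["ic50", "hillslope"])
    posterior["log_prob"] = logp
    med = np.median(chain, axis=0)
    lo, hi = np.percentile(chain, [2.5, 97.5], axis=0)
    return DoseResponseFit(
        "binary_bayes",
        float(med[0]),
        float(med[1]),
        (float(lo[0]), float(hi[0])),
        (float(lo[1]), float(hi[1])),
        seed=seed,
        posterior=posterior,
    )


def posterior_mode(fit: DoseResponseFit) -> tuple[float, float]:
    """The posterior sample with the highest log-probability."""
    if fit.posterior is None:
        raise ValueError("fit carries no posterior samples")
    row = fit.posterior.loc[fit.posterior["log_prob"].idxmax()]
    return float(row["ic50"]), float(row["hillslope"])


def grid_ml_binary(
    classes,
    concentrations,
    n_ic50: int = 400,
    n_slope: int = 200,
) -> tuple[float, float]:
    """Maximum-likelihood (IC50, slope) by exhaustive grid search.

    Independent check of the MCMC fit: evaluates the same Bernoulli
    likelihood on a dense grid over the prior box and returns the argmax.
    """
    y = np.asarray(classes)
    if y.dtype.kind in "OUS":
        y = (y == "high").astype(float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(concentrations, dtype=float)
    ic50s = np.linspace(0.02, PRIOR_IC50[1], n_ic50)
    slopes = np.linspace(PRIOR_SLOPE[0], PRIOR_SLOPE[1], n_slope)
    best, best_ll = (ic50s[0], slopes[0]), -np.inf
    for ic50 in ic50s:
        for slope in slopes:
            ll = _binary_log_likelihood((ic50, slope), x, y)
            if ll > best_ll:
                best_ll, best = ll, (float(ic50), float(slope))
    return best


def predicted_dose_response_table(classes, concentrations) -> pd.DataFrame:
    """Plot-ready table of (concentration, class, multiplicity).

    Collapses identical (concentration, class) points and counts overlaps —
    the point-size scaling of predicted dose-response plots.
    """
    y = np.asarray(classes)
    x = np.asarray(concentrations, dtype=float)
    if y.size != x.size:
        raise ValueError("classes and concentrations must align")
    if y.size == 0:
        return pd.DataFrame(columns=["concentration_um", "class", "multiplicity"])
    df = pd.DataFrame({"concentration_um": x, "class": y})
    out = (
        df.groupby(["concentration_um", "class"], sort=True)
        .size()
        .reset_index(name="multiplicity")
    )
    return out
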