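"""Bayesian no-intercept regression of logit-VAFs across two assays.

When two panels call the same mutation, their VAFs should agree up to a
scale factor near 1.  The model logit(vaf_b) = beta * logit(vaf_a) + eps,
with a Normal(1, 0.5) prior on the slope and an Exponential(mean 1) prior
on the error variance, is fitted by affine-invariant ensemble MCMC.
Mutations seen in only one panel's regions can then be checked against the
posterior-predictive VAF interval implied by the cross-panel relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import emcee
import numpy as np
from scipy.special import expit, logit as _logit
from scipy.stats import expon, norm

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz

from .variant_io import VariantKey


def logit_clamped(v: float | np.ndarray, eps: float = 1e-4) -> float | np.ndarray:
    """log(v/(1-v)) with v clamped to [eps, 1-eps] so boundary VAFs stay finite."""
    return _logit(np.clip(v, eps, 1.0 - eps))


@dataclass(frozen=True)
class VafPair:
    patient_id: str
    key: VariantKey
    vaf_a: float  # reference assay
    vaf_b: float  # test assay


@dataclass
class RegressionPosterior:
    slope: np.ndarray        # posterior draws of beta
    error_scale: np.ndarray  # posterior draws of the error sd
    converged: bool
    rhat: float              # split-R-hat of the slope across chains
    n_chains: int
    n_draws: int
    notes: str = ""


def _log_posterior(
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    slope_prior_scale: float,
) -> float:
    beta, log_var = theta
    var = np.exp(log_var)
    lp = norm.logpdf(beta, loc=1.0, scale=slope_prior_scale)
    # exponential(mean 1) prior on the variance; + log-Jacobian of log transform
    lp += expon.logpdf(var) + log_var
    if x.size:
        lp += float(np.sum(norm.logpdf(y - beta * x, scale=np.sqrt(var))))
    return lp if np.isfinite(lp) else -np.inf


def fit_vaf_regression(
    pairs: Sequence[VafPair],
    draws: int = 2000,
    chains: int = 4,
    seed: int = 0,
    slope_prior_scale: float = 0.5,
    slope_prior_scale_is_variance: bool = False,
    warmup: int = 1000,
    eps: float = 1e-4,
) -> RegressionPosterior:
    """Posterior over the cross-assay slope and error scale.

    Runs ``chains`` independent ensemble samplers (8 walkers each), keeps
    ``draws`` post-warmup draws per chain, and flags non-convergence when
    the split-R-hat of the slope across chains exceeds 1.01.  With no pairs
    the likelihood is flat and the posterior reduces to the prior.
    ``slope_prior_scale_is_variance`` reads the 0.5 of the slope prior as a
    variance rather than a standard deviation.
    """
    x = np.array([logit_clamped(p.vaf_a, eps) for p in pairs])
    y = np.array([logit_clamped(p.vaf_b, eps) for p in pairs])
    scale = np.sqrt(slope_prior_scale) if slope_prior_scale_is_variance else slope_prior_scale

    n_walkers = 8
    steps_post = max(1, -(-draws // n_walkers))  # ceil division
    rng = np.random.default_rng(seed)
    slope_chains, scale_chains = [], []
    for _ in range(chains):
        p0 = np.column_stack([
            1.0 + 0.1 * rng.standard_normal(n_walkers),
            np.log(0.5 + 0.5 * rng.random(n_walkers)),
        ])
        sampler = emcee.EnsembleSampler(
            n_walkers, 2, _log_posterior, args=(x, y, scale),
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31 - 1))
        ).get_state()
        sampler.run_mcmc(p0, warmup + steps_post, progress=False)
        chain = sampler.get_chain(discard=warmup, flat=True)[:draws]
        slope_chains.append(chain[:, 0])
        scale_chains.append(np.exp(0.5 * chain[:, 1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(arviz.rhat(np.asarray(slope_chains))) if chains > 1 else 1.0
    converged = np.isfinite(rhat) and rhat < 1.01
    if not converged:
        warnings.warn(f"slope split-R-hat {rhat:.4f} exceeds 1.01; treat posterior with caution")
    return RegressionPosterior(
        slope=np.concatenate(slope_chains),
        error_scale=np.concatenate(scale_chains),
        converged=bool(converged),
        rhat=rhat,
        n_chains=chains,
        n_draws=chains * min(draws, steps_post * n_walkers),
        notes="" if converged else "split-R-hat above threshold",
    )


def predictive_interval(
    posterior: RegressionPosterior,
    vaf_a: float,
    level: float = 0.95,
    seed: int = 0,
    eps: float = 1e-4,
) -> tuple[float, float]:
    """Posterior-predictive VAF interval for the test assay.

    Simulates logit-scale predictions (one noise draw per posterior draw),
    takes central quantiles and back-transforms, so endpoints always lie in
    (0, 1).
    """
    rng = np.random.default_rng(seed)
    x = logit_clamped(vaf_a, eps)
    preds = posterior.slope * x + posterior.error_scale * rng.standard_normal(posterior.slope.size)
    lo, hi = np.quantile(preds, [(1 - level) / 2, (1 + level) / 2])
    return float(expit(lo)), float(expit(hi))
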