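"""Observation-level precision weights for CLR-transformed counts.

CLR transformation does not stabilize the variance of count data: by the
first-order delta method, if Y_ip ~ Poisson(lambda_ip) then

    Var(Z_ip) ~= ((P-1)/P)^2 * 1/lambda_ip

and for negative-binomial counts Y_ip ~ NB(mu_ip, phi_p)

    Var(Z_ip) ~= ((P-1)/P)^2 * (1/mu_ip + phi_p),

a decreasing function of the mean. Ordinary least squares on Z therefore
mis-weights observations. This module supplies inverse-variance weights
either analytically (from per-population GLM fits, Poisson or NB) or
empirically, by estimating a lowess mean-variance trend across populations
in the style of the voom method for log-counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from statsmodels.nonparametric.smoothers_lowess import lowess

from .compositional import CLRMatrix, CountMatrix, DesignMatrix, ValidationError

logger = logging.getLogger("voomclr")

WEIGHT_SCHEMES = ("empirical", "poisson", "nb")

#: dispersion search cap; above this the observation is effectively noise
MAX_DISPERSION = 100.0


@dataclass
class WeightMatrix:
    values: np.ndarray  # (n, P), strictly positive
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or not np.all(self.values > 0):
            raise ValidationError("weights must be finite and strictly positive")
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValidationError(f"unknown weight scheme {self.scheme!r}")


@dataclass
class DispersionEstimates:
    phi: np.ndarray  # (P,) NB dispersions; zero for the Poisson family
    fitted_means: np.ndarray  # (n, P) fitted count means


def fit_mean_model(
    counts: CountMatrix, design: DesignMatrix, family: str = "nb"
) -> DispersionEstimates:
    """Fit per-population log-link count GLMs to obtain fitted means and dispersions.

    For each population p a Poisson GLM of Y_.p on the design with offset
    ln(total count) is fit; the fitted values estimate mu_ip. For
    ``family="nb"`` a moment (Pearson) dispersion phi_p is then estimated
    from the Poisson fit; for ``family="poisson"`` phi_p = 0. A population
    whose GLM fails to converge falls back to fitted means Y_ip + 0.5 with
    a logged warning.
    """
    if family not in ("poisson", "nb"):
        raise ValidationError(f"family must be 'poisson' or 'nb', got {family!r}")
    n, P = counts.values.shape
    resid_df = n - design.n_coefficients
    if resid_df <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    offset = np.log(counts.totals.astype(float))
    fitted = np.empty((n, P))
    phi = np.zeros(P)
    for p in range(P):
        y = counts.values[:, p].astype(float)
        try:
            with np.errstate(all="ignore"):
                model = sm.GLM(y, design.values, family=sm.families.Poisson(), offset=offset)
                res = model.fit(maxiter=100)
            mu = np.asarray(res.fittedvalues)
            if not res.converged or not np.all(np.isfinite(mu)) or not np.all(mu > 0):
                raise RuntimeError("non-convergence")
        except Exception:
            logger.warning(
                "GLM did not converge for population %r; using fallback fitted means",
                counts.population_ids[p],
            )
            mu = y + 0.5
        fitted[:, p] = mu
        if family == "nb":
            phi[p] = estimate_nb_dispersion(counts.values[:, p], mu, resid_df)
    return DispersionEstimates(phi=phi, fitted_means=fitted)


def estimate_nb_dispersion(
    counts_p: np.ndarray, fitted_means_p: np.ndarray, residual_df: int
) -> float:
    """Pearson moment estimate of the NB dispersion phi for one population.

    Solves sum_i (y_i - mu_i)^2 / (mu_i + phi * mu_i^2) = residual_df by
    bisection on phi in [0, 100]. Returns 0 when the data are already
    under- or equi-dispersed at phi = 0, and the cap (with a warning) when
    no root exists below it.
    """
    y = np.asarray(counts_p, dtype=float)
    mu = np.asarray(fitted_means_p, dtype=float)
    if not np.all(mu > 0):
        raise ValidationError("fitted means must be strictly positive")
    if residual_df <= 0:
        raise ValidationError("residual_df must be positive")
    resid_sq = (y - mu) ** 2

    def pearson(phi: float) -> float:
        return float(np.sum(resid_sq / (mu + phi * mu**2))) - residual_df

    if pearson(0.0) <= 0:
        return 0.0
    if pearson(MAX_DISPERSION) > 0:
        logger.warning("dispersion estimate capped at %g", MAX_DISPERSION)
        return MAX_DISPERSION
    return float(brentq(pearson, 0.0, MAX_DISPERSION, xtol=1e-10))


def analytic_weights(counts: CountMatrix, disp: DispersionEstimates) -> WeightMatrix:
    """Delta-method inverse-variance weights.

    Var(Z_ip) = ((P-1)/P)^2 * (1/mu_ip + phi_p); the Poisson case is
    phi = 0. Weights are the reciprocal variances.
    """
    P = counts.n_populations
    factor = ((P - 1) / P) ** 2
    var = factor * (1.0 / disp.fitted_means + disp.phi[None, :])
    scheme = "poisson" if np.all(disp.phi == 0) else "nb"
    return WeightMatrix(values=1.0 / var, scheme=scheme)


def _lowess_frac(P: int) -> float:
    # heavier smoothing for few populations
    return max(0.5, min(1.0, 10.0 / P))


def empirical_voom_weights(
    clr: CLRMatrix, counts: CountMatrix, design: DesignMatrix
) -> WeightMatrix:
    """Empirical mean-variance trend weights, estimated across populations.

    The recipe follows voom, re-targeted from genes to cell populations:
    fit unweighted least squares of Z on the design per population, regress
    the square-rooted residual standard deviations on mean log2 counts with
    lowess, then interpolate that trend at each observation's predicted
    log2 count (recovered from the fitted CLR value plus the sample's log
    geometric mean) and take the inverse fourth power.
    """
    n, P = counts.values.shape
    if P < 5:
        raise ValidationError(
            "empirical mean-variance trend needs at least 5 populations; "
            "use analytic ('poisson'/'nb') weights instead"
        )
    C = design.values
    Z = clr.values
    beta, *_ = np.linalg.lstsq(C, Z, rcond=None)
    fitted = C @ beta
    resid = Z - fitted
    d = n - design.n_coefficients
    if d <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    s = np.sqrt((resid**2).sum(axis=0) / d)  # per-population residual sd
    x = np.log2(counts.values + 0.5).mean(axis=0)  # mean log2 count per population

    frac = _lowess_frac(P)
    trend = lowess(np.sqrt(s), x, frac=frac, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    # predicted log2 count per observation, from the fitted CLR value
    log2_yhat = (fitted + clr.log_geomeans[:, None]) / np.log(2.0)
    t = np.interp(log2_yhat, tx, ty)  # constant extrapolation at the ends
    t = np.clip(t, 1e-6, None)
    w = t**-4.0
    return WeightMatrix(values=w, scheme="empirical")


def compute_weights(
    scheme: str,
    counts: CountMatrix,
    clr: CLRMatrix,
    design: DesignMatrix,
) -> WeightMatrix:
    """Dispatch on the weight scheme (``empirical``, ``poisson`` or ``nb``)."""
    if scheme == "empirical":
        return empirical_voom_weights(clr, counts, design)
    if scheme in ("poisson", "nb"):
        disp = fit_mean_model(counts, design, family=scheme)
        w = analytic_weights(counts, disp)
        return WeightMatrix(values=w.values, scheme=scheme)
    raise ValidationError(f"unknown weight scheme {scheme!r}")
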