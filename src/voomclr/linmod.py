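"""Weighted least-squares fits per population and empirical Bayes variance shrinkage.

Each population's CLR profile is modelled as

    Z_ip = beta_0p + sum_j beta_jp C_ij + e_ip,

fit by weighted least squares with the observation weights from the
mean-variance model. Residual variances are then moderated across
populations by fitting a scaled-F (inverse-chi-square) prior by moments —
the standard moderated-t construction — which borrows strength across
populations and augments the residual degrees of freedom, a substantial
help when sample sizes are small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from .compositional import CLRMatrix, DesignMatrix, ValidationError
from .weights import WeightMatrix

logger = logging.getLogger("voomclr")


def _trigamma(x):
    return polygamma(1, x)


@dataclass
class WeightedFit:
    """Per-population WLS results.

    ``coefficients`` is (P, k+1); ``unscaled_cov`` is (P, k+1, k+1) holding
    (C' W_p C)^-1 so that Var(beta_jp) = residual_variance[p] *
    unscaled_cov[p, j, j].
    """

    coefficients: np.ndarray
    unscaled_cov: np.ndarray
    residual_variance: np.ndarray
    residual_df: int
    fitted_values: np.ndarray
    residuals: np.ndarray
    design: DesignMatrix
    population_ids: list[str]


@dataclass
class ModeratedVariances:
    s2_post: np.ndarray
    d0: float  # prior df; may be inf
    s0sq: float
    total_df: float  # d0 + d; inf when d0 is inf


def fit_wls(clr: CLRMatrix, design: DesignMatrix, weights: WeightMatrix,
            population_ids: list[str] | None = None) -> WeightedFit:
    """Weighted least squares of CLR values on the design, one fit per population."""
    Z = clr.values
    C = design.values
    W = weights.values
    n, P = Z.shape
    k1 = design.n_coefficients
    d = n - k1
    if d <= 0:
        raise ValidationError("need more samples than design coefficients")
    if population_ids is None:
        population_ids = [str(p) for p in range(P)]

    coef = np.empty((P, k1))
    ucov = np.empty((P, k1, k1))
    s2 = np.empty(P)
    fitted = np.empty_like(Z)
    for p in range(P):
        w = W[:, p]
        Cw = C * w[:, None]
        xtwx = C.T @ Cw  # (k1, k1)
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"weighted normal equations singular for population {population_ids[p]!r}"
            ) from exc
        b = xtwx_inv @ (Cw.T @ Z[:, p])
        coef[p] = b
        ucov[p] = xtwx_inv
        zhat = C @ b
        fitted[:, p] = zhat
        e = Z[:, p] - zhat
        s2[p] = float(np.sum(w * e**2) / d)
    return WeightedFit(
        coefficients=coef,
        unscaled_cov=ucov,
        residual_variance=s2,
        residual_df=d,
        fitted_values=fitted,
        residuals=Z - fitted,
        design=design,
        population_ids=list(population_ids),
    )


def squeeze_variances(s2: np.ndarray, d: int) -> ModeratedVariances:
    """Shrink per-population residual variances toward a common prior.

    The sampling model s_p^2 ~ s0^2 * chi^2_d / d (given the true variance)
    implies ln s_p^2 has mean ln s0^2 + psi(d/2) - ln(d/2) and variance
    trigamma(d/2) plus the between-population spread trigamma(d0/2). The
    prior df d0 and prior variance s0^2 are recovered by matching the first
    two moments of e_p = ln s_p^2 - psi(d/2) + ln(d/2); the posterior
    (moderated) variance is the df-weighted average

        s2_post = (d0 * s0^2 + d * s_p^2) / (d0 + d).

    When the observed spread of e is no larger than trigamma(d/2) the
    excess variance is zero: d0 = inf and every s2_post equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float).copy()
    if s2.size < 2:
        raise ValidationError("need at least 2 variances to shrink")
    if np.any(s2 <= 0):
        pos = s2[s2 > 0]
        if pos.size == 0:
            raise ValidationError("all residual variances are zero")
        repl = float(pos.min())
        logger.warning("replacing %d non-positive residual variances with %g",
                       int(np.sum(s2 <= 0)), repl)
        s2[s2 <= 0] = repl

    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1))
    excess = evar - float(_trigamma(d / 2.0))
    if excess <= 0:
        # no excess spread beyond chi-square sampling noise: point prior.
        # s0^2 is the arithmetic mean so identical inputs pass through
        # unchanged (matches limma's fitFDist convention).
        s0sq = float(np.mean(s2))
        s2_post = np.full_like(s2, s0sq)
        return ModeratedVariances(s2_post=s2_post, d0=np.inf, s0sq=s0sq, total_df=np.inf)

    # solve trigamma(d0/2) = excess; trigamma is decreasing so bracket and solve
    def f(half_d0: float) -> float:
        return float(_trigamma(half_d0)) - excess

    lo, hi = 1e-8, 1e8
    half_d0 = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(np.mean(e) + digamma(half_d0) - np.log(half_d0)))
    s2_post = (d0 * s0sq + d * s2) / (d0 + d)
    return ModeratedVariances(s2_post=s2_post, d0=d0, s0sq=s0sq, total_df=d0 + d)
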