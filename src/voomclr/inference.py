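"""Moderated t-tests on bias-corrected coefficients and the full pipeline.

The test statistic for population p and coefficient (or contrast) j is

    T_jp = beta_tilde_jp / sqrt(Var(beta_hat_jp) + Var(mode_j) - 2 Cov)

with Var(beta_hat_jp) the empirical-Bayes moderated variance and the mode
terms from the chosen bootstrap. T is referred to a Student t distribution
with the augmented degrees of freedom d0 + d (standard normal when the
prior df is infinite). p-values are adjusted per coefficient across
populations with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bias import BOOTSTRAP_SCHEMES, DEFAULT_B, BiasCorrection, run_bias_correction, total_variance
from .compositional import (
    CLRMatrix,
    ContrastVector,
    CountMatrix,
    DesignMatrix,
    ValidationError,
    clr_transform,
    validate_inputs,
)
from .linmod import ModeratedVariances, WeightedFit, fit_wls, squeeze_variances
from .weights import WEIGHT_SCHEMES, compute_weights

logger = logging.getLogger("voomclr")

LN2 = np.log(2.0)


@dataclass
class RunOptions:
    """Pipeline options with the method's defaults.

    Defaults: NB analytic weights, parametric bootstrap with B = 4000,
    pseudocount 0.5, empirical Bayes shrinkage on.
    """

    weights: str = "nb"
    bootstrap: str = "parametric"
    B: int = DEFAULT_B
    pseudocount: float = 0.5
    seed: int = 0
    shrink: bool = True

    def __post_init__(self) -> None:
        if self.weights not in WEIGHT_SCHEMES:
            raise ValidationError(f"unknown weight scheme {self.weights!r}")
        if self.bootstrap not in BOOTSTRAP_SCHEMES:
            raise ValidationError(f"unknown bootstrap scheme {self.bootstrap!r}")
        if not self.pseudocount > 0:
            raise ValidationError("pseudocount must be positive")
        if self.B < 2:
            raise ValidationError("B must be at least 2")


@dataclass
class TestResult:
    """Result of one voomCLR run.

    ``table`` has one row per (coefficient/contrast, population) with raw
    and corrected log-fold-changes (natural log and log2), the total
    standard error, t statistic, degrees of freedom, raw and BH-adjusted
    p-values. ``corrections`` maps each tested coefficient/contrast label
    to its :class:`~voomclr.bias.BiasCorrection`.
    """

    table: pd.DataFrame
    corrections: dict[str, BiasCorrection]
    fit: WeightedFit
    moderated: ModeratedVariances
    options: RunOptions
    log: dict = field(default_factory=dict)


def moderated_t_test(
    corrected: float,
    var_beta_moderated: float,
    var_mode: float,
    cov: float,
    df: float,
    scheme: str = "nonparametric",
) -> tuple[float, float]:
    """t statistic and two-sided p-value for one bias-corrected coefficient."""
    if not df > 0:
        raise ValidationError("df must be positive")
    for x in (corrected, var_beta_moderated, var_mode, cov):
        if not np.isfinite(x):
            raise ValidationError("non-finite input to moderated_t_test")
    tv = total_variance(var_beta_moderated, var_mode, cov, scheme)
    t = corrected / np.sqrt(tv)
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _contrast_targets(
    design: DesignMatrix, contrasts: list[ContrastVector] | None
) -> list[ContrastVector]:
    """Default test targets: every non-intercept design coefficient."""
    if contrasts:
        for c in contrasts:
            if c.weights.size != design.n_coefficients:
                raise ValidationError(
                    f"contrast {c.label!r} has length {c.weights.size}, "
                    f"design has {design.n_coefficients} columns"
                )
        return contrasts
    targets = []
    ones = np.all(design.values == 1.0, axis=0)
    for j, name in enumerate(design.column_names):
        if ones[j]:  # intercept column: never bias-corrected or tested
            continue
        L = np.zeros(design.n_coefficients)
        L[j] = 1.0
        targets.append(ContrastVector(weights=L, label=name))
    if not targets:
        raise ValidationError("design has no non-intercept coefficient to test")
    return targets


def run_voomclr(
    counts: CountMatrix,
    design: DesignMatrix,
    contrasts: list[ContrastVector] | None = None,
    options: RunOptions | None = None,
) -> TestResult:
    """Run the full differential-composition pipeline.

    Stages: pseudocount and CLR transform; observation weights (empirical
    trend or analytic delta-method, Poisson/NB); per-population weighted
    least squares; empirical Bayes variance shrinkage; mode-based bias
    correction per coefficient/contrast; bootstrap variance of the bias
    term; moderated t-tests; BH adjustment across populations. Fully
    deterministic given ``options.seed``.
    """
    opts = options or RunOptions()
    validate_inputs(counts, design)
    clr = clr_transform(counts, pseudocount=opts.pseudocount)
    try:
        w = compute_weights(opts.weights, counts, clr, design)
    except ValidationError as exc:
        raise ValidationError(f"weight estimation: {exc}") from exc
    fit = fit_wls(clr, design, w, population_ids=counts.population_ids)
    if opts.shrink:
        mod = squeeze_variances(fit.residual_variance, fit.residual_df)
    else:
        mod = ModeratedVariances(
            s2_post=fit.residual_variance.copy(), d0=0.0,
            s0sq=float(np.median(fit.residual_variance)), total_df=float(fit.residual_df),
        )
    logger.info("variance shrinkage: d0=%.4g, s0^2=%.4g", mod.d0, mod.s0sq)

    targets = _contrast_targets(design, contrasts)
    rows = []
    corrections: dict[str, BiasCorrection] = {}
    for j, L in enumerate(targets):
        est = fit.coefficients @ L.weights  # (P,)
        unscaled = np.einsum("i,pij,j->p", L.weights, fit.unscaled_cov, L.weights)
        var_beta = mod.s2_post * unscaled  # moderated contrast variance, per p
        bc = run_bias_correction(
            est, var_beta, scheme=opts.bootstrap, B=opts.B, seed=opts.seed + j,
        )
        corrections[L.label] = bc
        logger.info("contrast %r: mode=%.4g, var_mode=%.4g", L.label, bc.mode, bc.var_mode)
        t_stats = np.empty(est.size)
        p_vals = np.empty(est.size)
        se_tot = np.empty(est.size)
        for p in range(est.size):
            tv = total_variance(var_beta[p], bc.var_mode, bc.cov_mode[p], opts.bootstrap)
            se_tot[p] = np.sqrt(tv)
            t_stats[p], p_vals[p] = moderated_t_test(
                bc.corrected[p], var_beta[p], bc.var_mode, bc.cov_mode[p],
                mod.total_df, opts.bootstrap,
            )
        padj = adjust_bh(p_vals)
        for p, pop in enumerate(counts.population_ids):
            rows.append({
                "population": pop,
                "coefficient": L.label,
                "logFC_raw": est[p],
                "logFC_corrected": bc.corrected[p],
                "log2FC_raw": est[p] / LN2,
                "log2FC_corrected": bc.corrected[p] / LN2,
                "mode": bc.mode,
                "se_total": se_tot[p],
                "t": t_stats[p],
                "df": mod.total_df,
                "pvalue": p_vals[p],
                "padj": padj[p],
            })
    table = pd.DataFrame(rows)
    return TestResult(
        table=table, corrections=corrections, fit=fit, moderated=mod, options=opts,
        log={"d0": mod.d0, "s0sq": mod.s0sq},
    )
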