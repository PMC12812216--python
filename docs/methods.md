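# Methods

## The problem

Single-cell experiments yield, per sample, the number of cells assigned to
each of P cell populations. These counts are compositional: the library
total is an arbitrary consequence of the experiment, so only relative
abundances are observed, while the scientific question — differential
abundance (DA) — concerns changes in *absolute* abundance between
conditions. An increase in one population mechanically depresses every
other population's relative share, so models applied naively to relative
counts produce false positives.

## Model

Write Y_ip for the observed count of population p in sample i, and X_ip for
the unobserved absolute abundance, assumed to follow a log-linear model
log X_ip = C_i α_p + ε_ip with design matrix C (n × (k+1), intercept
first). The pipeline:

1. **CLR transform.** Z_ip = ln(Y'_ip) − mean_p ln(Y'_ip), with
   Y'_ip = Y_ip + 0.5 (the half-count pseudocount keeps zeros finite and is
   configurable). Rows sum to zero; the transform is invariant to scaling a
   sample's counts, removing the arbitrary total.

2. **Precision weights.** CLR values remain heteroscedastic. By the
   first-order delta method, Var(Z_ip) ≈ ((P−1)/P)² (1/μ_ip + φ_p) for
   NB counts (φ = 0 gives the Poisson case), a decreasing function of the
   mean. Three weight schemes are provided:
   - `nb` (default): per-population Poisson GLM with offset ln(total)
     supplies fitted means μ̂_ip; the NB dispersion φ̂_p solves the Pearson
     equation Σ_i (y_i−μ̂_i)²/(μ̂_i+φμ̂_i²) = n−k−1 by bisection on
     [0, 100] (0 when already equi-/under-dispersed, capped with a warning
     otherwise). Weights w_ip are the reciprocal delta-method variances.
   - `poisson`: the same with φ ≡ 0. Underperforms when counts are
     overdispersed; provided for comparison.
   - `empirical`: a voom-style trend. Per-population OLS residual standard
     deviations (square-rooted) are lowess-smoothed against mean log2
     counts (span max(0.5, min(1, 10/P)) — few populations need heavy
     smoothing), the curve is interpolated at each observation's predicted
     log2 count (fitted CLR value plus the sample's log geometric mean,
     constant extrapolation at the ends), and weights are the inverse
     fourth power. Refused for P < 5, where the trend is unusable; use the
     analytic weights there.

3. **Weighted linear models + empirical Bayes.** Per population,
   β̂_p = (CᵀW_pC)⁻¹CᵀW_p z_p with s_p² = Σ w ê²/d, d = n−k−1 (no
   effective-df adjustment for weights — standard WLS convention).
   Residual variances are moderated by moment-matching a scaled-F prior on
   the log scale: with e_p = ln s_p² − ψ(d/2) + ln(d/2), the prior df d0
   solves trigamma(d0/2) = var(e) − trigamma(d/2) and
   s0² = exp(mean(e) + ψ(d0/2) − ln(d0/2));
   s̃_p² = (d0 s0² + d s_p²)/(d0+d). When the spread of e does not exceed
   the chi-square sampling noise, d0 = ∞ and s̃_p² = s0² = mean(s²) (the
   arithmetic mean, so identical inputs pass through unchanged — the same
   convention as limma's fitFDist, against which the routine is
   cross-checked). Shrinkage can be disabled (`--no-shrink`), reducing to
   unmoderated WLS.

4. **Bias correction.** CLR-scale coefficients are biased:
   β_jp = α_jp − ᾱ_j, with ᾱ_j the mean true effect across populations —
   unidentifiable from relative data. Under the mode-at-zero assumption
   (most populations are not DA), ᾱ_j equals the mode of the β_jp
   distribution, estimated by a Gaussian KDE with Silverman bandwidth
   h = 0.9·min(sd, IQR/1.34)·P^(−1/5) evaluated on a 512-point grid over
   [min−3h, max+3h] (ties to the smallest grid value; median for P ≤ 2;
   the common value when all inputs coincide). The corrected coefficient
   is β̃_jp = β̂_jp − mode. The intercept is never corrected; every
   non-intercept coefficient and every user contrast is corrected
   independently, with the mode recomputed on the contrast estimates.

5. **Bias-term uncertainty.** Var(β̃_jp) = Var(β̂_jp) + Var(mode) −
   2 Cov(β̂_jp, mode). Schemes:
   - `none`: ignore the mode uncertainty (the large-P argument; unrealistic
     for typical cell-type counts).
   - `nonparametric`: resample the P coefficient estimates with
     replacement B times, recompute the mode of each resample, take the
     sample variance. No covariance estimate is available; it is set to 0,
     so the total variance only grows — this scheme is conservative.
   - `parametric` (default): draw β*_jp ~ N(β̂_jp, s̃_p²·[unscaled cov]_jj)
     independently across populations, recompute the mode per draw; this
     yields both the variance of the mode and its covariance with each
     coefficient. The total variance is floored at 0.1·Var(β̂_jp) in the
     (rare, logged) case where covariance subtraction would turn it
     non-positive; the floor fraction is a design choice for a degenerate
     case with no principled value. B = 4000 resamples by default; the RNG
     is seeded per coefficient as seed + coefficient index so contrasts are
     reproducible independently.

   The parametric procedure is this package's own construction of a
   Gaussian parametric bootstrap at the moderated variances; drawing at the
   moderated rather than raw variances keeps the bootstrap consistent with
   the variance actually used in the test statistic.

6. **Inference.** T_jp = β̃_jp / sqrt(total variance), referred to Student
   t with d0 + d degrees of freedom (standard normal when d0 = ∞). No
   Satterthwaite adjustment is made for the bootstrap variance component —
   it has no natural df. Two-sided p-values are BH-adjusted across the P
   populations within each coefficient/contrast.

## Synthetic data generator

The generator emulates two-group cell-count data with between-sample
overdispersion. Group-g absolute means are the baseline abundances times
per-population fold changes (group 1: all 1); true proportions π_g are
their normalisation; per sample, p_i ~ Dirichlet(γ·c0·π_g), a total
N_i ~ lognormal (or fixed), and Y_i ~ Multinomial(N_i, p_i). The true
absolute-scale log-fold-change is α_p = ln(fold change_p) and a population
is DA iff its fold change ≠ 1.

Default scenario (all values chosen once as a realistic medium-variability
two-group study): P = 11 populations, 20 samples per group, γ = 1,
c0 = 300, baseline abundances log-uniform over two orders of magnitude,
3 of 11 populations DA with absolute fold changes {2, 0.5, 3} placed across
the abundance range, totals lognormal with median 5000 cells (sdlog 0.3).
With these effects ᾱ = ln(3)/11 ≈ 0.10, a visible compositional bias,
while the mode of the true effects is zero.

What the generator does *not* emulate: batch or cohort structure, replicate
correlation within donors, cell-type misassignment, and zero-inflation
beyond what the DM produces. Passing benchmarks on these simulations
therefore demonstrates correctness of the statistical machinery under the
stated sampling model, not robustness to those real-data complications.

### Known simulator artifacts

- With c0 = 300 and a two-order-of-magnitude composition, the rarest
  populations have Dirichlet parameters near 1, where E[ln p] deviates
  noticeably from ln E[p] (digamma correction). The true CLR-scale null
  cluster is then slightly heterogeneous and off −ᾱ, leaving a small
  (~0.03) residual deviation in mean corrected effect that is a property
  of the generator, not of the correction. The bias-removal demonstration
  in the acceptance suite therefore uses c0 = 3000, where the log-moment
  approximation is accurate for every population; overdispersion is still
  present.
- The delta-method variance formula keeps only the own-count term of
  Var(Z). It is accurate when no population dominates the geometric mean;
  the validation check uses a factor-2 composition spread (all expected
  counts ≥ 275), where the neglected cross-term stays ≈ 10–15%. Under a
  two-order-of-magnitude spread the formula underpredicts the variance of
  the most abundant populations.

## Benchmarks computed here

`benchmark_voomclr` simulates R datasets, runs the pipeline, and averages
per-run FDP (FP / max(1, discoveries), avoiding 0/0) and TPR at nominal
BH levels. At the default scenario over 250 runs, NB weights + the
non-parametric bootstrap give mean FDP of roughly 1% at the 10% level and
below 1% at the 5% level — conservative control — while the parametric
bootstrap trades a higher (still controlled) FDP for higher sensitivity.
These numbers are recomputed from scratch by `scripts/acceptance.py` and by
the end-to-end tests; none are hard-coded.

## Numerical choices and degenerate inputs

- Pseudocount 0.5 uniformly before the CLR; the geometric mean uses all P
  populations (no abundance filtering — that is upstream's choice).
- All-zero populations are allowed with a warning (their CLR values are
  pure pseudocount); all-zero samples are rejected.
- GLM non-convergence for a population falls back to fitted means
  Y_ip + 0.5 with a logged warning.
- Non-positive residual variances (exactly-fit populations) are replaced by
  the smallest positive one before shrinkage, with a warning.
- Coefficients are reported in natural log (the scale of the model) and in
  log2 for readability; the results header records the convention.
- Weight estimation is single-pass (no re-iteration of weights after the
  first fit).
- Monte Carlo problem sizes in the test suite (250-run benchmark, 50-run
  paired comparisons, 5000-sample null studies) are chosen so each check's
  Monte Carlo error is small relative to the margin being tested.

## Limitations

- The mode-at-zero assumption degrades when many populations are DA or P
  is small; the CLR itself is unreliable for very few populations (e.g. 3),
  where one DA population distorts the geometric mean reference.
- Replicate-correlation structure (repeated samples per donor) and mixed
  models are not supported.
- BH adjustment is applied per contrast across populations; no global
  omnibus test is provided.
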