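# voomclr

Differential cell-type composition analysis for single-cell studies.

Given a sample × cell-type count table (from scRNA-seq, flow/mass
cytometry, or any experiment where cells are assigned to disjoint
populations) and a sample-level design, `voomclr` tests which populations
change in *absolute* abundance between conditions, accounting for the two
statistical problems such data poses:

- **Compositionality.** Observed counts carry only relative information;
  a genuine increase in one population mechanically depresses all others'
  shares, biasing per-population models. `voomclr` fits linear models on
  centered log-ratio (CLR) transformed counts, where the coefficient for
  population p equals α_p − ᾱ: the absolute-scale log-fold-change minus an
  unidentifiable common offset. Assuming most populations are not
  differentially abundant (the mode of true effects is zero), the offset is
  estimated as the mode of the fitted coefficients across populations
  (Gaussian KDE, Silverman bandwidth) and subtracted. Because that mode is
  estimated from few populations, its uncertainty is quantified by a
  bootstrap (non-parametric resampling across populations, or a parametric
  Gaussian bootstrap that additionally yields the coefficient–mode
  covariance) and propagated into the test statistic

      T_p = β̃_p / sqrt( Var(β̂_p) + Var(β̌) − 2 Cov(β̂_p, β̌) ).

- **Heteroscedasticity.** CLR values of counts are not variance-stable:
  by the delta method Var(Z_ip) ≈ ((P−1)/P)² (1/μ_ip + φ_p). Observations
  are weighted by inverse predicted variances — analytically from
  per-population count GLMs (NB by default, Poisson optionally) or from an
  empirically smoothed mean–variance trend across populations — and
  residual variances are moderated by empirical Bayes shrinkage across
  populations, giving moderated t-tests with augmented degrees of freedom.

P-values are BH-adjusted across populations within each tested
coefficient or contrast.

A Dirichlet-Multinomial simulator with known ground truth, plus FDP/TPR
benchmarking utilities, is included (`voomclr.simulate`).

## Worked example

Simulate a two-group study (11 populations, 20 samples per group, three DA
populations with fold changes 2, 0.5 and 3) and analyse it:

```sh
cat > sim.yaml <<EOF
P: 11
n_per_group: [20, 20]
gamma: 1.0
base_concentration: 300
seed: 7
EOF
voomclr simulate --config sim.yaml --out counts.tsv --truth truth.tsv --design design.tsv
voomclr fit --counts counts.tsv --design design.tsv --formula "~ group" \
    --seed 7 --deterministic-header --out results.tsv
```

The log reports the shrinkage prior and the estimated compositional bias:

```
[voomclr] INFO: variance shrinkage: d0=6.98, s0^2=1.892
[voomclr] INFO: contrast 'groupg2': mode=-0.1133, var_mode=0.002619
```

`results.tsv` (selected columns):

```
population  log2FC_raw  log2FC_corrected  se_total       t  pvalue   padj
      pop1      0.2824            0.4459    0.3553  0.8700  0.3889 0.8955
      pop2      0.8728            1.0363    0.2444  2.9387  0.0052 0.0190
      pop3     -0.1190            0.0445    0.2503  0.1233  0.9024 0.9024
      pop4     -0.3138           -0.1503    0.1688 -0.6170  0.5404 0.8955
      pop5     -0.2191           -0.0556    0.1387 -0.2776  0.7826 0.8955
      pop6     -1.3709           -1.2074    0.1589 -5.2661  0.0000 0.0000
      pop7     -0.2245           -0.0610    0.0909 -0.4650  0.6442 0.8955
      pop8     -0.0860            0.0775    0.0780  0.6884  0.4947 0.8955
      pop9     -0.1107            0.0528    0.0850  0.4306  0.6688 0.8955
     pop10      1.4315            1.5950    0.0755 14.6507  0.0000 0.0000
     pop11     -0.1396            0.0239    0.0700  0.2366  0.8140 0.8955
```

The three truly DA populations (pop2: 2×, pop6: 0.5×, pop10: 3×) are
exactly the ones significant at a 10% FDR, with corrected log2
fold-changes near their true values (1, −1, 1.585). Note the raw
coefficients of the eight null populations sit around −0.16 in log2
(the compositional bias, mode ≈ −0.11 in natural log); the correction
re-centres them at zero. `se_total` includes the bootstrap-estimated
uncertainty of the bias term. `df` in the full table is the moderated
residual df (prior + residual).

The same pipeline is available programmatically:

```python
from voomclr import RunOptions, run_voomclr, read_counts_table, read_design

counts = read_counts_table("counts.tsv")
design = read_design("design.tsv", counts.sample_ids, formula="~ group")
result = run_voomclr(counts, design, options=RunOptions(seed=7))
print(result.table.head())
```

Key options (CLI flags / `RunOptions` fields): `--weights
{empirical,poisson,nb}` (default `nb`), `--bootstrap
{none,nonparametric,parametric}` (default `parametric`), `--B` (default
4000), `--pseudocount` (default 0.5), `--no-shrink`, `--seed`. Identical
arguments and seed give byte-identical outputs.

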