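"""Parametric simulation of compositional cell-count data with known truth.

Cell counts for a sample are drawn hierarchically: per-sample proportions
p_i ~ Dirichlet(gamma * c0 * pi_g) around the group's true composition
pi_g, a library total N_i (fixed or lognormal), then
Y_i ~ Multinomial(N_i, p_i). The concentration scaling gamma tunes
between-sample overdispersion: large gamma collapses the Dirichlet onto
its mean and recovers pure Multinomial sampling; small gamma produces
strongly overdispersed counts.

Ground truth is carried on the absolute-abundance scale: group-2 baseline
means are the group-1 means times per-population fold changes, and the true
absolute-scale log-fold-change alpha_p = ln(fold_change_p). A population is
differentially abundant (DA) when its fold change differs from 1. The
CLR-scale coefficient that an uncorrected model targets is
alpha_p - mean(alpha), which exposes the compositional bias.

Also provided: a plain Multinomial null generator for mean-variance
diagnostics, FDP/TPR evaluation against truth, and a benchmark loop that
repeatedly simulates and runs the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import CountMatrix, DesignMatrix, ValidationError
from .inference import RunOptions, run_voomclr

#: default scenario: 11 populations, gamma=1 (medium between-sample
#: variability), baseline abundances spread over two orders of magnitude,
#: 3 of 11 populations DA, lognormal totals with median 5000 cells.
DEFAULT_P = 11
DEFAULT_BASE_CONCENTRATION = 300.0
DEFAULT_DA_FOLD_CHANGES = (2.0, 0.5, 3.0)
DEFAULT_TOTAL_MEANLOG = float(np.log(5000.0))
DEFAULT_TOTAL_SDLOG = 0.3


def default_baseline_abundance(P: int = DEFAULT_P) -> np.ndarray:
    """Baseline absolute abundances log-uniformly spread over two orders of magnitude."""
    return np.logspace(0.0, 2.0, P)


def default_fold_changes(P: int = DEFAULT_P, n_da: int = 3) -> np.ndarray:
    """Fold-change vector with ``n_da`` DA populations and the rest null.

    DA populations are spread across the abundance range (indices evenly
    spaced over 1..P-2 so the extremes stay null), with absolute fold
    changes cycling through {2, 0.5, 3}.
    """
    fc = np.ones(P)
    if n_da > 0:
        idx = np.linspace(1, P - 2, n_da).round().astype(int)
        for i, j in enumerate(idx):
            fc[j] = DEFAULT_DA_FOLD_CHANGES[i % len(DEFAULT_DA_FOLD_CHANGES)]
    return fc


@dataclass
class SimulationConfig:
    """Settings for the Dirichlet-Multinomial generator."""

    P: int = DEFAULT_P
    n_per_group: tuple[int, int] = (20, 20)
    baseline_abundance: np.ndarray = field(default_factory=default_baseline_abundance)
    fold_changes: np.ndarray = field(default_factory=default_fold_changes)
    gamma: float = 1.0
    base_concentration: float = DEFAULT_BASE_CONCENTRATION
    total_count_model: dict = field(
        default_factory=lambda: {
            "kind": "lognormal",
            "meanlog": DEFAULT_TOTAL_MEANLOG,
            "sdlog": DEFAULT_TOTAL_SDLOG,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if self.P < 1:
            raise ValidationError("need at least one population")
        if self.baseline_abundance.size != self.P or self.fold_changes.size != self.P:
            raise ValidationError("baseline_abundance and fold_changes must have length P")
        if np.any(self.baseline_abundance <= 0):
            raise ValidationError("baseline abundances must be positive")
        if np.any(self.fold_changes <= 0):
            raise ValidationError("fold changes must be positive")
        if not self.gamma > 0 or not self.base_concentration > 0:
            raise ValidationError("gamma and base_concentration must be positive")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    group_labels: np.ndarray  # (n,) of {0, 1}
    true_absolute_means: np.ndarray  # (2, P)
    true_alpha: np.ndarray  # (P,) = ln fold_changes
    da_labels: np.ndarray  # (P,) bool

    @property
    def design(self) -> DesignMatrix:
        """Intercept + group-indicator design matching the simulated groups."""
        n = self.group_labels.size
        values = np.column_stack([np.ones(n), self.group_labels.astype(float)])
        return DesignMatrix(values=values, column_names=["Intercept", "group"])


def _draw_totals(rng: np.random.Generator, model: dict, n: int) -> np.ndarray:
    kind = model.get("kind", "lognormal")
    if kind == "fixed":
        return np.full(n, int(model["N"]))
    if kind == "lognormal":
        tot = rng.lognormal(model["meanlog"], model["sdlog"], size=n)
        return np.maximum(np.rint(tot).astype(int), 1)
    raise ValidationError(f"unknown total_count_model kind {kind!r}")


def simulate_dirichlet_multinomial(config: SimulationConfig) -> SimulatedDataset:
    """Draw a two-group Dirichlet-Multinomial dataset with known truth."""
    rng = np.random.default_rng(config.seed)
    means = np.vstack([
        config.baseline_abundance,
        config.baseline_abundance * config.fold_changes,
    ])  # (2, P) absolute means
    pis = means / means.sum(axis=1, keepdims=True)
    alphas = config.gamma * config.base_concentration * pis
    if np.any(alphas <= 0):
        raise ValidationError("Dirichlet parameters must be positive")

    groups = np.repeat([0, 1], config.n_per_group)
    n = groups.size
    totals = _draw_totals(rng, config.total_count_model, n)
    counts = np.empty((n, config.P), dtype=np.int64)
    for i, g in enumerate(groups):
        p_i = rng.dirichlet(alphas[g])
        counts[i] = rng.multinomial(totals[i], p_i)
    cm = CountMatrix(
        values=counts,
        sample_ids=[f"sample{i+1}" for i in range(n)],
        population_ids=[f"pop{p+1}" for p in range(config.P)],
    )
    return SimulatedDataset(
        counts=cm,
        group_labels=groups,
        true_absolute_means=means,
        true_alpha=np.log(config.fold_changes),
        da_labels=config.fold_changes != 1.0,
    )


def simulate_multinomial_null(
    P: int, n: int, pi: np.ndarray, N: int, seed: int = 0
) -> SimulatedDataset:
    """i.i.d. Multinomial(N, pi) samples — the no-overdispersion null."""
    pi = np.asarray(pi, dtype=float)
    if pi.size != P or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValidationError("pi must be a length-P probability vector")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, pi, size=n).astype(np.int64)
    cm = CountMatrix(
        values=counts,
        sample_ids=[f"sample{i+1}" for i in range(n)],
        population_ids=[f"pop{p+1}" for p in range(P)],
    )
    groups = np.zeros(n, dtype=int)
    means = np.vstack([pi * N, pi * N])
    return SimulatedDataset(
        counts=cm,
        group_labels=groups,
        true_absolute_means=means,
        true_alpha=np.zeros(P),
        da_labels=np.zeros(P, dtype=bool),
    )


def evaluate_fdr_tpr(
    results: list[pd.DataFrame],
    truths: list[np.ndarray],
    nominal_levels: list[float],
) -> pd.DataFrame:
    """Per-run FDP and TPR at each nominal level, averaged over runs.

    A discovery is a population with BH-adjusted p <= level. FDP uses the
    max(1, discoveries) convention to avoid 0/0; TPR divides by
    max(1, number of truly DA populations).
    """
    if len(results) != len(truths):
        raise ValidationError("results and truths must have equal length")
    rows = []
    for run_id, (tab, da) in enumerate(zip(results, truths)):
        da = np.asarray(da, dtype=bool)
        if len(tab) != da.size:
            raise ValidationError(f"run {run_id}: result rows != truth length")
        padj = tab["padj"].to_numpy()
        for level in nominal_levels:
            called = padj <= level
            tp = int(np.sum(called & da))
            fp = int(np.sum(called & ~da))
            rows.append({
                "run": run_id,
                "level": level,
                "FDP": fp / max(1, tp + fp),
                "TPR": tp / max(1, int(da.sum())),
            })
    per_run = pd.DataFrame(rows)
    summary = (
        per_run.groupby("level", as_index=False)[["FDP", "TPR"]]
        .mean()
        .rename(columns={"FDP": "mean_FDP", "TPR": "mean_TPR"})
    )
    summary.attrs["per_run"] = per_run
    return summary


def benchmark_voomclr(
    config: SimulationConfig,
    n_runs: int,
    options: RunOptions | None = None,
    nominal_levels: list[float] = (0.01, 0.05, 0.10),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_runs`` datasets, run the pipeline on each, aggregate FDP/TPR."""
    opts = options or RunOptions()
    results, truths = [], []
    for r in range(n_runs):
        cfg = SimulationConfig(
            P=config.P,
            n_per_group=config.n_per_group,
            baseline_abundance=config.baseline_abundance,
            fold_changes=config.fold_changes,
            gamma=config.gamma,
            base_concentration=config.base_concentration,
            total_count_model=config.total_count_model,
            seed=seed + r,
        )
        ds = simulate_dirichlet_multinomial(cfg)
        run_opts = RunOptions(
            weights=opts.weights, bootstrap=opts.bootstrap, B=opts.B,
            pseudocount=opts.pseudocount, seed=seed + r, shrink=opts.shrink,
        )
        res = run_voomclr(ds.counts, ds.design, options=run_opts)
        tab = res.table[res.table["coefficient"] == "group"]
        results.append(tab.reset_index(drop=True))
        truths.append(ds.da_labels)
    return evaluate_fdr_tpr(results, truths, list(nominal_levels))
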