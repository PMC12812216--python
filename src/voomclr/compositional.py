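"""Count/design data model and the centered log-ratio (CLR) transformation.

Cell-type counts from single-cell experiments carry only relative
information: the library total is an arbitrary consequence of the
experiment, so the counts live on a simplex. The CLR transform maps each
sample's count vector out of the simplex by taking the log of each count
relative to the sample's geometric mean, producing rows that sum to zero
and on which least-squares methods are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when counts or design fail a hard validity check."""


@dataclass
class CountMatrix:
    """Sample x population table of observed cell counts.

    Parameters
    ----------
    values
        ``(n, P)`` array of non-negative integer counts.
    sample_ids
        ``n`` unique sample labels.
    population_ids
        ``P`` unique cell-population labels.
    """

    values: np.ndarray
    sample_ids: list[str]
    population_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("counts must be a 2-D sample x population array")
        n, P = self.values.shape
        if n < 2 or P < 2:
            raise ValidationError(f"need at least 2 samples and 2 populations, got {n} x {P}")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=1e-8):
                raise ValidationError("counts must be integral")
            self.values = rounded.astype(np.int64)
        if (self.values < 0).any():
            i, p = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"population {self.population_ids[p]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.population_ids = [str(p) for p in self.population_ids]
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match row count")
        if len(self.population_ids) != P:
            raise ValidationError("population_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        if len(set(self.population_ids)) != P:
            raise ValidationError("population_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_populations(self) -> int:
        return self.values.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total cell count."""
        return self.values.sum(axis=1)


@dataclass
class DesignMatrix:
    """Full-rank n x (k+1) design matrix; first column is the intercept by convention."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("design must be 2-D")
        self.column_names = [str(c) for c in self.column_names]
        if len(self.column_names) != self.values.shape[1]:
            raise ValidationError("column_names length does not match design columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.values.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))


@dataclass
class ContrastVector:
    """Linear combination of design coefficients to test, e.g. a group difference."""

    weights: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValidationError("contrast weights must be 1-D")
        if not np.any(self.weights != 0):
            raise ValidationError("contrast must not be all zero")


@dataclass
class CLRMatrix:
    """CLR-transformed counts; every row sums to zero by construction."""

    values: np.ndarray
    pseudocount: float
    log_geomeans: np.ndarray = field(repr=False)
    # log_geomeans holds ln of the pseudocounted per-sample geometric mean,
    # needed downstream to map fitted CLR values back to the count scale.


def clr_transform(counts: CountMatrix, pseudocount: float = 0.5) -> CLRMatrix:
    """Centered log-ratio transform of a count matrix.

    Each count is offset by ``pseudocount`` (keeping zeros finite), then
    Z_ip = ln(Y'_ip) - mean_p ln(Y'_ip), i.e. the log-count centered at the
    sample's log geometric mean over all P populations.

    Parameters
    ----------
    counts
        Observed counts.
    pseudocount
        Positive offset added to every count; default 0.5 (half-count
        convention for log transforms of counts).
    """
    if not pseudocount > 0:
        raise ValidationError(f"pseudocount must be positive, got {pseudocount}")
    logy = np.log(counts.values + float(pseudocount))
    log_geomeans = logy.mean(axis=1)
    z = logy - log_geomeans[:, None]
    return CLRMatrix(values=z, pseudocount=float(pseudocount), log_geomeans=log_geomeans)


@dataclass
class ValidationReport:
    warnings: list[str]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return True


def validate_inputs(counts: CountMatrix, design: DesignMatrix) -> ValidationReport:
    """Check counts/design compatibility before fitting.

    Hard errors: dimension mismatch, zero-total samples, rank-deficient
    design (the collinear columns are named). Soft warnings: populations
    that are all zero — their CLR values are driven entirely by the
    pseudocount and the result for them is not interpretable.
    """
    msgs: list[str] = []
    if design.n_samples != counts.n_samples:
        raise ValidationError(
            f"design has {design.n_samples} rows but counts has {counts.n_samples} samples"
        )
    zero_tot = np.flatnonzero(counts.totals == 0)
    if zero_tot.size:
        bad = ", ".join(counts.sample_ids[i] for i in zero_tot)
        raise ValidationError(f"samples with zero total count: {bad}")
    if design.rank() < design.n_coefficients:
        # name columns whose removal restores full rank
        collinear = []
        for j in range(design.n_coefficients):
            keep = [c for c in range(design.n_coefficients) if c != j]
            sub = design.values[:, keep]
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(design.values):
                collinear.append(design.column_names[j])
        raise ValidationError(
            "design matrix is rank deficient; collinear columns: " + ", ".join(collinear)
        )
    zero_pops = np.flatnonzero((counts.values == 0).all(axis=0))
    for p in zero_pops:
        msg = (
            f"population {counts.population_ids[p]!r} is zero in every sample; "
            "its CLR values are determined entirely by the pseudocount"
        )
        msgs.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return ValidationReport(warnings=msgs)
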