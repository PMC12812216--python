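"""Reading count and design tables, formula expansion, and results output."""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import patsy

from .compositional import CountMatrix, DesignMatrix, ValidationError


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    try:
        dialect = csv.Sniffer().sniff(header, delimiters="\t,;")
        return dialect.delimiter
    except csv.Error:
        return "\t"


def read_counts_table(path: str | Path, dialect: str | None = None) -> CountMatrix:
    """Parse a TSV/CSV count table: first column sample id, one column per population.

    The delimiter is auto-detected from the header line unless given.
    Negative, missing or non-integer cells are rejected with their
    coordinates named.
    """
    sep = dialect or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample or population identifiers")
    if df.isna().any().any():
        i, p = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing count at sample {df.index[i]!r}, population {df.columns[p]!r}"
        )
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count cells")
    rounded = np.rint(vals)
    if not np.allclose(vals, rounded, atol=1e-8):
        i, p = np.argwhere(~np.isclose(vals, rounded, atol=1e-8))[0]
        raise ValidationError(
            f"{path}: non-integer count at sample {df.index[i]!r}, "
            f"population {df.columns[p]!r}"
        )
    if (rounded < 0).any():
        i, p = np.argwhere(rounded < 0)[0]
        raise ValidationError(
            f"{path}: negative count at sample {df.index[i]!r}, "
            f"population {df.columns[p]!r}"
        )
    return CountMatrix(
        values=rounded.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        population_ids=[str(c) for c in df.columns],
    )


def write_counts_table(counts: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(counts.values, index=counts.sample_ids, columns=counts.population_ids)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def read_covariates(path: str | Path, sample_ids: list[str]) -> pd.DataFrame:
    """Read a sample-level covariate table and align its rows to ``sample_ids``."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValidationError(f"{path}: covariates missing for samples: {', '.join(missing)}")
    if df.isna().any().any():
        raise ValidationError(f"{path}: covariate table contains missing values")
    return df.loc[sample_ids]


def design_from_formula(formula: str, covariates: pd.DataFrame) -> DesignMatrix:
    """Expand an R-style additive formula (e.g. ``"~ group + batch"``).

    Categorical covariates are treatment-coded with the alphabetically
    first level as reference; an intercept column is included unless the
    formula removes it.
    """
    try:
        dmat = patsy.dmatrix(formula, covariates, return_type="dataframe")
    except patsy.PatsyError as exc:
        raise ValidationError(f"cannot build design from formula {formula!r}: {exc}") from exc
    names = [
        n.replace("C(", "").replace(")", "").replace("[T.", "").replace("]", "")
        if "[T." in n else n
        for n in dmat.columns
    ]
    return DesignMatrix(values=dmat.to_numpy(), column_names=names)


def read_design(
    source: str | Path,
    sample_ids: list[str],
    formula: str | None = None,
) -> DesignMatrix:
    """Build the design matrix from a covariate table plus formula.

    ``source`` is a TSV/CSV covariate table keyed by sample id; ``formula``
    (default: additive model over all covariate columns) selects and
    expands terms. Rows are re-aligned to the count-table sample order, so
    shuffled tables give identical results.
    """
    cov = read_covariates(source, sample_ids)
    if formula is None:
        formula = "~ " + " + ".join(cov.columns)
    return design_from_formula(formula, cov)


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    header_fields: dict | None = None,
) -> None:
    """Write the results TSV with a ``#``-prefixed header block recording options."""
    buf = _io.StringIO()
    for key, val in (header_fields or {}).items():
        buf.write(f"# {key}: {val}\n")
    table.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
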