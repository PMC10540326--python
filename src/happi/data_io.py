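"""Reading, validating and aligning pangenome inputs; writing result tables.

Two matrix dialects are supported:

* ``plain`` — a delimited table whose first column holds gene identifiers,
  remaining columns are genome identifiers, and every cell is 0 or 1;
* ``roary`` — a ``gene_presence_absence.csv``-style table where the first
  ``first_genome_col`` columns are gene annotation metadata and any
  non-empty cell in the genome columns means the gene was observed.

Metadata is a per-genome table carrying the covariates of interest and
the genome-quality variables (coverage, completion, ...).  Missing values
are hard errors — the model defines no missingness mechanism for the
covariates or quality variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenePresenceDataset",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_metadata",
    "load_dataset",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "gene_id", "method", "statistic", "p_value", "q_value",
    "converged_alt", "converged_null", "n_iter_alt", "n_iter_null",
]


class AlignmentError(ValueError):
    """Genome identifiers in the matrix and metadata do not match."""


@dataclass
class GenePresenceDataset:
    """Aligned gene presence/absence matrix plus genome-level variables.

    ``Y`` is genes x genomes with entries in {0, 1}; ``X`` (genomes x p,
    first column the intercept by convention) holds covariates of
    interest; ``M`` (genomes x q) holds quality variables.
    """

    gene_ids: list
    genome_ids: list
    Y: np.ndarray
    X: np.ndarray
    M: np.ndarray
    covariate_names: list = field(default_factory=list)
    quality_names: list = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        self.X = np.asarray(self.X, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim == 1:
            self.M = self.M[:, None]
        n = len(self.genome_ids)
        if len(set(self.genome_ids)) != n:
            raise ValueError("genome identifiers must be unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if self.Y.shape != (len(self.gene_ids), n):
            raise ValueError("Y must be genes x genomes")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y entries must be exactly 0 or 1")
        if self.X.shape[0] != n or self.M.shape[0] != n:
            raise ValueError("X and M must have one row per genome")
        if not (np.isfinite(self.X).all() and np.isfinite(self.M).all()):
            raise ValueError("missing or non-finite values in X or M")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       na_values=[])


def read_presence_matrix(path, dialect: str = "plain", sep=None,
                         first_genome_col: int = 14):
    """Read a gene presence/absence matrix.

    Returns ``(gene_ids, genome_ids, Y)`` with ``Y`` of shape
    genes x genomes and dtype int8; input row/column order is preserved.
    """
    df = _read_table(path, sep=sep)
    if dialect == "plain":
        gene_ids = df.iloc[:, 0].tolist()
        genome_ids = list(df.columns[1:])
        cells = df.iloc[:, 1:].to_numpy()
        Y = np.empty(cells.shape, dtype=np.int8)
        for (r, c), val in np.ndenumerate(cells):
            sval = str(val).strip()
            if sval not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell {val!r} at gene {gene_ids[r]!r}, "
                    f"genome {genome_ids[c]!r}"
                )
            Y[r, c] = int(sval)
    elif dialect == "roary":
        if first_genome_col < 1 or first_genome_col >= df.shape[1]:
            raise ValueError("first_genome_col out of range")
        gene_ids = df.iloc[:, 0].tolist()
        genome_ids = list(df.columns[first_genome_col:])
        cells = df.iloc[:, first_genome_col:].to_numpy()
        Y = (np.char.strip(cells.astype(str)) != "").astype(np.int8)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicated gene identifiers in matrix")
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicated genome identifiers in matrix")
    return gene_ids, genome_ids, Y


def write_presence_matrix(gene_ids, genome_ids, Y, path, sep="\t"):
    """Write a plain-dialect presence/absence matrix."""
    df = pd.DataFrame(np.asarray(Y, dtype=int), index=gene_ids,
                      columns=genome_ids)
    df.to_csv(path, sep=sep, index_label="gene_id")


def read_metadata(path, genome_id_col, covariate_cols, quality_cols,
                  genome_order=None, add_intercept: bool = True, sep=None):
    """Read genome metadata and build the covariate and quality matrices.

    Non-numeric covariates are treatment-coded against the
    lexicographically first level; the coding is recorded in the returned
    covariate names (``col[level]``).  If ``genome_order`` is given, rows
    are re-aligned so row ``i`` matches genome ``i`` of the matrix;
    mismatched identifier sets raise :class:`AlignmentError`.

    Returns ``(X, M, covariate_names, quality_names, genome_ids)``.
    """
    df = _read_table(path, sep=sep)
    for col in [genome_id_col, *covariate_cols, *quality_cols]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in metadata")
    ids = df[genome_id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated genome identifiers in metadata")
    if genome_order is not None:
        want = [str(g) for g in genome_order]
        missing = sorted(set(want) - set(ids))
        extra = sorted(set(ids) - set(want))
        if missing:
            raise AlignmentError(
                f"genomes in matrix missing from metadata: {missing}"
            )
        if extra:
            raise AlignmentError(
                f"genomes in metadata missing from matrix: {extra}"
            )
        df = df.set_index(genome_id_col).loc[want].reset_index()
        ids = want

    def numeric(col):
        vals = df[col].replace("", np.nan)
        if vals.isna().any():
            raise ValueError(f"missing values in column {col!r}")
        return pd.to_numeric(vals, errors="coerce")

    x_cols, covariate_names = [], []
    for col in covariate_cols:
        as_num = numeric(col)
        if as_num.notna().all():
            x_cols.append(as_num.to_numpy(dtype=float))
            covariate_names.append(col)
        else:
            levels = sorted(df[col].unique())
            for level in levels[1:]:
                x_cols.append((df[col] == level).to_numpy(dtype=float))
                covariate_names.append(f"{col}[{level}]")
    m_cols = []
    for col in quality_cols:
        as_num = numeric(col)
        if as_num.isna().any():
            raise ValueError(f"quality column {col!r} must be numeric")
        m_cols.append(as_num.to_numpy(dtype=float))

    X = np.column_stack(x_cols) if x_cols else np.empty((len(ids), 0))
    if add_intercept:
        X = np.column_stack([np.ones(len(ids)), X])
        covariate_names = ["(Intercept)", *covariate_names]
    M = np.column_stack(m_cols) if m_cols else np.empty((len(ids), 0))
    return X, M, covariate_names, list(quality_cols), ids


def load_dataset(matrix_path, metadata_path, genome_id_col, covariate_cols,
                 quality_cols, dialect: str = "plain",
                 add_intercept: bool = True, sep=None,
                 first_genome_col: int = 14) -> GenePresenceDataset:
    """Read and align a matrix + metadata pair into one dataset."""
    gene_ids, genome_ids, Y = read_presence_matrix(
        matrix_path, dialect=dialect, sep=sep,
        first_genome_col=first_genome_col,
    )
    X, M, cov_names, qual_names, ids = read_metadata(
        metadata_path, genome_id_col, covariate_cols, quality_cols,
        genome_order=genome_ids, add_intercept=add_intercept, sep=sep,
    )
    return GenePresenceDataset(gene_ids=gene_ids, genome_ids=ids, Y=Y,
                               X=X, M=M, covariate_names=cov_names,
                               quality_names=qual_names)


def write_results(table: pd.DataFrame, path, sep="\t"):
    """Write the per-gene result table (floats kept to 12 significant digits)."""
    if table.empty:
        raise ValueError("result table is empty")
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_results(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
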