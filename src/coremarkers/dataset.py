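"""Expression-matrix container and plain-text readers/writers.

The on-disk dialect is the GEO series-matrix orientation: tab-separated,
UTF-8, first column gene ids, header row of sample ids, numeric body,
genes in rows. Values are log-scale expression (microarray log-intensities
or log-transformed RNA-seq counts); the selection procedure itself is
rank-based and only requires a common monotone scale within a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_labels_table",
    "read_survival_table",
]


def _check_unique(ids: np.ndarray, kind: str) -> None:
    vals, counts = np.unique(ids, return_counts=True)
    dup = vals[counts > 1]
    if dup.size:
        raise DataError(f"duplicate {kind} id(s): {', '.join(map(str, dup[:5]))}")


@dataclass
class ExpressionDataset:
    """A genes-by-samples numeric expression matrix.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers, length G.
    sample_ids : ordered unique sample identifiers, length N.
    values : float array of shape (G, N); must be finite, no missing values.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (self.gene_ids.size, self.sample_ids.size):
            raise DataError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{self.gene_ids.size} genes x {self.sample_ids.size} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                "non-finite expression value at gene "
                f"'{self.gene_ids[bad[0]]}', sample '{self.sample_ids[bad[1]]}'"
                " (missing values are rejected, not imputed)"
            )

    @property
    def n_genes(self) -> int:
        return int(self.gene_ids.size)

    @property
    def n_samples(self) -> int:
        return int(self.sample_ids.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionDataset":
        """Return a dataset restricted to the given sample boolean mask/indices."""
        return ExpressionDataset(
            self.gene_ids, self.sample_ids[keep], self.values[:, keep]
        )


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read a genes-by-samples expression TSV.

    Errors name the offending line (1-based, header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise DataError(f"{path.name}: malformed TSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path.name}: file is empty") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path.name}: no sample columns found")
    gene_ids = df.index.to_numpy(dtype=str)
    vals, counts = np.unique(gene_ids, return_counts=True)
    if (counts > 1).any():
        gid = vals[counts > 1][0]
        line = int(np.where(gene_ids == gid)[0][1]) + 2
        raise DataError(f"{path.name}: duplicate gene id '{gid}' at line {line}")
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy(dtype=str)
        try:
            # numpy's str->float conversion is correctly rounded, so a
            # write/read round trip preserves values bit-for-bit
            body[:, j] = raw.astype(np.float64)
        except ValueError:
            for row, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"{path.name}: non-numeric value '{cell}' for gene "
                        f"'{gene_ids[row]}' (line {row + 2}, column '{col}')"
                    ) from None
    return ExpressionDataset(gene_ids, df.columns.to_numpy(dtype=str), body)


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_expression`.

    Uses 17-significant-digit floats so a write/read round trip is exact.
    """
    dataset.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_labels_table(path: str | Path) -> pd.Series:
    """Read a two-column labels TSV (sample_id, response) as a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{Path(path).name}: expected columns sample_id, response")
    sid, resp = df.columns[0], df.columns[1]
    if df[sid].duplicated().any():
        dup = df[sid][df[sid].duplicated()].iloc[0]
        raise DataError(f"{Path(path).name}: duplicate sample id '{dup}'")
    return pd.Series(df[resp].to_numpy(), index=df[sid].to_numpy(), name="response")


def read_survival_table(path: str | Path) -> pd.Series:
    """Read a two-column survival TSV (sample_id, efs_days) as a float Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{Path(path).name}: expected columns sample_id, efs_days")
    sid, days = df.columns[0], df.columns[1]
    ids = df[sid].astype(str)
    if ids.duplicated().any():
        raise DataError(f"{Path(path).name}: duplicate sample id")
    times = pd.to_numeric(df[days], errors="coerce")
    if times.isna().any():
        row = int(np.where(times.isna())[0][0])
        raise DataError(
            f"{Path(path).name}: non-numeric survival time at line {row + 2}"
        )
    return pd.Series(times.to_numpy(dtype=float), index=ids.to_numpy(), name="efs_days")
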