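"""Reading and writing expression matrices, annotation and phenotype tables.

All expression values are carried on the log2 scale. The universal container
is :class:`ExpressionMatrix`: a probes x samples matrix of log2 intensities
with optional per-sample group labels. Two text dialects are supported, plain
TSV (header row of sample ids, first column of probe ids) and GCT 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "join_matrices",
    "read_annotation",
    "read_phenotypes",
]


class MatrixFormatError(ValueError):
    """Raised when an expression-matrix file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 expression intensities.

    Parameters
    ----------
    data
        DataFrame with probe ids as the index and sample ids as columns.
        Values must be finite log2 intensities.
    sample_groups
        Optional mapping ``sample_id -> group label`` (e.g. ``"HF"``,
        ``"CTRL"``, or a reference-population id).
    """

    data: pd.DataFrame
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise MatrixFormatError(f"duplicate probe ids: {dups[:10]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise MatrixFormatError(f"duplicate sample ids: {dups[:10]}")
        if len(cols) == 0:
            raise MatrixFormatError("matrix has no samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MatrixFormatError("matrix contains non-numeric values")
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise MatrixFormatError(f"matrix contains {n_bad} non-finite values")
        self.data = self.data.astype(float)
        if self.sample_groups is not None:
            unknown = set(self.sample_groups) - set(cols)
            if unknown:
                raise MatrixFormatError(
                    f"sample_groups refers to unknown samples: {sorted(unknown)[:10]}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def samples_in_group(self, group: str) -> list[str]:
        if self.sample_groups is None:
            raise KeyError(f"matrix carries no group labels (wanted {group!r})")
        hits = [s for s in self.sample_ids if self.sample_groups.get(s) == group]
        if not hits:
            raise KeyError(f"no samples labelled {group!r}")
        return hits

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = set(samples) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)[:10]}")
        groups = None
        if self.sample_groups is not None:
            groups = {s: self.sample_groups[s] for s in samples if s in self.sample_groups}
        return ExpressionMatrix(self.data[samples].copy(), groups)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )


def from_linear(
    data: pd.DataFrame,
    sample_groups: dict[str, str] | None = None,
    floor: float = 1.0,
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from linear-scale intensities.

    Values are clipped at ``floor`` (default 1.0) before the log2 transform so
    that zero or near-zero intensities map to a finite baseline.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return ExpressionMatrix(np.log2(data.clip(lower=floor)), sample_groups)


def _read_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.name is None:
        raise MatrixFormatError(f"{path}: malformed header on line 1 (no probe-id column)")
    return df


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise MatrixFormatError(f"{path}: line 1 must be '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise MatrixFormatError(f"{path}: line 2 must hold two dimensions")
        n_rows, n_cols = (int(d) for d in dims)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["Name", "Description"]:
        raise MatrixFormatError(
            f"{path}: line 3 must start with 'Name<TAB>Description'"
        )
    df = df.set_index("Name").drop(columns="Description")
    df.index.name = "probe_id"
    if df.shape != (n_rows, n_cols):
        raise MatrixFormatError(
            f"{path}: declared shape {(n_rows, n_cols)} != body shape {df.shape}"
        )
    return df


def read_matrix(
    path: str | Path,
    dialect: str = "tsv",
    sample_groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a log2 expression matrix from ``path``.

    ``dialect`` is ``"tsv"`` (header of sample ids, first column probe ids)
    or ``"gct"`` (GCT 1.2 with the two-line preamble and Description column).
    Duplicate probe rows and non-numeric cells are rejected.
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_tsv(path)
    elif dialect == "gct":
        df = _read_gct(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            def _bad(v):
                try:
                    float(v)
                    return False
                except (TypeError, ValueError):
                    return True

            mask = df[col].apply(_bad)
            row = df.index[mask.to_numpy().nonzero()[0][0]] if mask.any() else "?"
            raise MatrixFormatError(
                f"{path}: non-numeric cell at probe {row!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    groups = dict(sample_groups) if sample_groups is not None else None
    return ExpressionMatrix(df, groups)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``matrix`` to ``path`` with full float precision (round-trip exact)."""
    if matrix.shape[1] == 0:
        raise ValueError("refusing to write a matrix with no samples")
    path = Path(path)
    df = matrix.data
    if dialect == "tsv":
        out = df.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            body = df.copy()
            body.insert(0, "Description", "na")
            body.index.name = "Name"
            body.to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def join_matrices(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices over an identical probe universe.

    Probe order follows ``a``; ``b`` is re-indexed to match. Sample ids must
    be disjoint. Group labels from both inputs are preserved.
    """
    set_a, set_b = set(a.probe_ids), set(b.probe_ids)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise MatrixFormatError(
            f"probe universes differ by {len(diff)} ids, e.g. {diff[:10]}"
        )
    shared = set(a.sample_ids) & set(b.sample_ids)
    if shared:
        raise MatrixFormatError(f"sample ids not disjoint: {sorted(shared)[:10]}")
    joined = pd.concat([a.data, b.data.reindex(a.data.index)], axis=1)
    groups: dict[str, str] = {}
    for m in (a, b):
        if m.sample_groups:
            groups.update(m.sample_groups)
    return ExpressionMatrix(joined, groups or None)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 2-column (probe_id, gene) or 3-column (gene, term_id, term_name)
    TSV annotation table; duplicate (key, value) pairs are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] not in (2, 3):
        raise MatrixFormatError(f"{path}: annotation table must have 2 or 3 columns")
    return df.drop_duplicates()


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (TSV, first column sample_id, numeric columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise MatrixFormatError(f"{path}: duplicate sample ids")
    return df.astype(float)
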