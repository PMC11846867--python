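"""Count-matrix / covariate-table data model, readers, writers and preprocessing.

Conventions used throughout the package:

* cells are rows, genes are columns, factors are columns of the score matrix;
* all indices are 0-based internally and 1-based (``F1``..``Fk``) in outputs;
* Matrix Market files are coordinate integer with 1-based indices and two
  companion id files ``<path>.rows`` (cell ids) and ``<path>.cols`` (gene ids);
* dense count tables are tab-delimited with a header row of gene ids and a
  first column of cell ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "CovariateTable",
    "CountFormatError",
    "read_counts",
    "write_counts",
    "read_covariates",
    "write_covariates",
    "preprocess",
    "encode_design",
    "library_size",
]


class CountFormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


@dataclass
class CountMatrix:
    """Raw (or filtered) cells x genes count matrix with identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _coerce_int_matrix(np.asarray(self.values))
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise CountFormatError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise CountFormatError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise CountFormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise CountFormatError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def library_size(self) -> np.ndarray:
        return self.values.sum(axis=1)


def library_size(counts: CountMatrix) -> np.ndarray:
    """Total read count per cell."""
    return counts.library_size()


@dataclass
class CovariateTable:
    """Per-cell covariates, each tagged with a role.

    ``roles`` maps column name to ``"technical"`` (regressed out in the GLM
    step) or ``"annotation"`` (matched to factors in the FCA step).  Columns
    with an object/category dtype are treated as categorical, everything else
    as numeric.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        for col, role in self.roles.items():
            if col not in self.data.columns:
                raise KeyError(f"role declared for unknown covariate {col!r}")
            if role not in ("technical", "annotation"):
                raise ValueError(f"unknown role {role!r} for covariate {col!r}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    def is_categorical(self, col: str) -> bool:
        return not pd.api.types.is_numeric_dtype(self.data[col])

    def levels(self, col: str) -> list:
        if not self.is_categorical(col):
            raise TypeError(f"covariate {col!r} is numeric, has no levels")
        return sorted(pd.unique(self.data[col].astype(str)))

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def subset(self, cell_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(cell_ids)].copy(), dict(self.roles))

    def aligned_to(self, counts: CountMatrix) -> "CovariateTable":
        missing = set(counts.cell_ids) - set(self.data.index)
        if missing:
            raise KeyError(
                f"{len(missing)} cells missing from covariate table "
                f"(e.g. {sorted(missing)[:3]})"
            )
        return self.subset(counts.cell_ids)


def _coerce_int_matrix(values: np.ndarray) -> np.ndarray:
    if values.ndim != 2:
        raise CountFormatError(f"count matrix must be 2-D, got shape {values.shape}")
    if values.size and np.issubdtype(values.dtype, np.floating):
        if not np.all(np.isfinite(values)):
            raise CountFormatError("non-finite entries in count matrix")
        rounded = np.rint(values)
        if not np.allclose(values, rounded, rtol=0, atol=1e-8):
            bad = np.argwhere(values != rounded)[0]
            raise CountFormatError(
                f"non-integer count at (cell {bad[0]}, gene {bad[1]}): "
                f"{values[tuple(bad)]!r}"
            )
        values = rounded
    values = values.astype(np.int64, copy=False)
    if values.size and values.min() < 0:
        bad = np.argwhere(values < 0)[0]
        raise CountFormatError(
            f"negative count at (cell {bad[0]}, gene {bad[1]})"
        )
    return values


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise CountFormatError(f"missing {what} id file: {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise CountFormatError(f"empty {what} id file: {path}")
    return ids


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix.

    Parameters
    ----------
    path:
        ``.mtx`` file (with ``<path>.rows`` / ``<path>.cols`` id files) or a
        tab-delimited dense table.
    format:
        ``"matrix-market"`` or ``"dense"``; inferred from the extension when
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise CountFormatError(f"no such file: {path}")
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "dense"
    if format in ("matrix-market", "matrix-market+ids", "mtx"):
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message varies
            raise CountFormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        cell_ids = _read_id_file(path.with_suffix(path.suffix + ".rows"), "cell")
        gene_ids = _read_id_file(path.with_suffix(path.suffix + ".cols"), "gene")
        return CountMatrix(values, cell_ids, gene_ids)
    if format in ("dense", "delimited-dense", "tsv"):
        if path.stat().st_size == 0:
            raise CountFormatError(f"empty count file: {path}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise CountFormatError(f"malformed dense count table {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise CountFormatError(f"dense count table {path} has no gene columns")
        return CountMatrix(
            df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    raise ValueError(f"unknown count format {format!r}")


def write_counts(counts: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a count matrix in one of the two supported dialects."""
    path = Path(path)
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "dense"
    if format in ("matrix-market", "matrix-market+ids", "mtx"):
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.values))
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(counts.cell_ids) + "\n"
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(counts.gene_ids) + "\n"
        )
        return
    if format in ("dense", "delimited-dense", "tsv"):
        df = pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.gene_ids)
        df.to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown count format {format!r}")


def read_covariates(
    path: str | Path,
    technical: Iterable[str] = (),
    annotation: Iterable[str] = (),
) -> CovariateTable:
    """Read a tab-delimited covariate table whose first column is the cell id."""
    path = Path(path)
    if not path.exists():
        raise CountFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    roles = {c: "technical" for c in technical}
    roles.update({c: "annotation" for c in annotation})
    return CovariateTable(df, roles)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.data.to_csv(path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _hvg_order(values: np.ndarray) -> np.ndarray:
    """Genes ordered by decreasing variance of log1p library-normalized counts.

    Ties (and the choice of statistic itself) are resolved deterministically:
    stable sort, so equally-dispersed genes keep their input order.
    """
    lib = values.sum(axis=1).astype(float)
    target = np.median(lib)
    norm = values / lib[:, None] * target
    disp = np.var(np.log1p(norm), axis=0)
    return np.argsort(-disp, kind="stable")


def preprocess(
    counts: CountMatrix,
    n_hvg: int | None = 2000,
    cov: CovariateTable | None = None,
) -> tuple[CountMatrix, CovariateTable]:
    """Filter zero-count cells/genes and keep the top highly variable genes.

    Cells are filtered first, then genes; the library-size covariate is
    recomputed after all filtering and attached to the returned covariate
    table as a technical covariate named ``library_size``.
    """
    if n_hvg is not None and n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    values = counts.values
    keep_cells = values.sum(axis=1) > 0
    values = values[keep_cells]
    cell_ids = [c for c, k in zip(counts.cell_ids, keep_cells) if k]
    keep_genes = values.sum(axis=0) > 0
    values = values[:, keep_genes]
    gene_ids = [g for g, k in zip(counts.gene_ids, keep_genes) if k]
    if values.size == 0:
        raise ValueError("no cells or genes survive zero-count filtering")

    if n_hvg is not None:
        if n_hvg < len(gene_ids):
            order = np.sort(_hvg_order(values)[:n_hvg])
            values = values[:, order]
            gene_ids = [gene_ids[i] for i in order]
        elif n_hvg > len(gene_ids):
            warnings.warn(
                f"n_hvg={n_hvg} exceeds the {len(gene_ids)} genes available; "
                "keeping all genes"
            )

    # HVG filtering cannot create zero-count cells (each kept gene had reads)
    # but guard anyway so the invariant is unconditional.
    keep_cells2 = values.sum(axis=1) > 0
    if not keep_cells2.all():
        values = values[keep_cells2]
        cell_ids = [c for c, k in zip(cell_ids, keep_cells2) if k]

    filtered = CountMatrix(values, cell_ids, gene_ids)
    if cov is not None:
        out = cov.aligned_to(filtered)
    else:
        out = CovariateTable(pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")))
    out.data["library_size"] = filtered.library_size()
    out.roles["library_size"] = "technical"
    return filtered, out


def encode_design(
    cov: CovariateTable, selected: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Build the technical-covariate design matrix.

    Numeric columns pass through (``library_size`` is log-transformed),
    categorical columns are one-hot encoded dropping the first (reference)
    level, and an intercept column is prepended.
    """
    cols: list[np.ndarray] = [np.ones(len(cov.data), dtype=float)]
    names = ["intercept"]
    for name in selected:
        if name not in cov.data.columns:
            raise KeyError(f"unknown covariate {name!r}")
        if cov.is_categorical(name):
            levels = cov.levels(name)
            if len(levels) < 2:
                warnings.warn(
                    f"categorical covariate {name!r} has a single level; dropped"
                )
                continue
            vals = cov.data[name].astype(str).to_numpy()
            for level in levels[1:]:
                cols.append((vals == level).astype(float))
                names.append(f"{name}[{level}]")
        else:
            x = cov.data[name].to_numpy(dtype=float)
            if name == "library_size":
                if np.any(x <= 0):
                    raise ValueError("library_size must be positive to log-transform")
                x = np.log(x)
            cols.append(x)
            names.append(name)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("design matrix is rank deficient")
    return design, names
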