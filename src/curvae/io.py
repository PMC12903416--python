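"""Dataset ingestion: sparse count matrices, id files, marker lists.

Supported count formats: a MatrixMarket directory (``matrix.mtx`` plus
one-id-per-line ``genes.tsv`` / ``barcodes.tsv`` or ``cells.tsv``), a
delimited table (cells in rows, genes in columns, with header and index)
and an AnnData ``.h5ad`` container.  Orientation is normalised to
cells x genes using the id-file lengths.  Marker lists are plain text,
one gene symbol per line, ``#`` comments allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse as sps
from scipy.io import mmread

log = logging.getLogger("curvae")


@dataclass
class Dataset:
    """Counts with ids, per-cell covariates and named marker sets."""

    counts: sps.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    batches: pd.DataFrame | None = None
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    unresolved: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match the matrix")
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != g:
            raise ValueError("ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")

    def marker_indices(self, name: str) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.asarray([lookup[g] for g in self.marker_sets[name]
                           if g in lookup], dtype=np.int64)

    def attach_markers(self, name: str, symbols: list[str]):
        """Resolve symbols against the matrix; report the unresolved."""
        present = set(self.gene_ids)
        kept = [s for s in symbols if s in present]
        missing = [s for s in symbols if s not in present]
        if missing:
            log.warning("marker set %r: %d of %d symbols not in the matrix",
                        name, len(missing), len(symbols))
        if not kept:
            raise ValueError(f"marker set {name!r} resolved to zero genes")
        self.marker_sets[name] = kept
        self.unresolved[name] = missing


def _read_ids(path: Path) -> list[str]:
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def load_counts(path, fmt: str | None = None) -> Dataset:
    """Load a counts matrix; `fmt` in {"mtx-dir", "delimited", "h5-container"}
    (inferred from the path when omitted)."""
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx-dir"
        elif path.suffix in (".h5ad", ".h5"):
            fmt = "h5-container"
        else:
            fmt = "delimited"
    if fmt == "mtx-dir":
        return _load_mtx_dir(path)
    if fmt == "delimited":
        return _load_delimited(path)
    if fmt == "h5-container":
        return _load_h5(path)
    raise ValueError(f"unknown format {fmt!r}")


def _load_mtx_dir(path: Path) -> Dataset:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(mtx)
    try:
        mat = mmread(str(mtx))
    except Exception as e:  # surface parse position when available
        raise ValueError(f"malformed MatrixMarket file {mtx}: {e}") from e
    genes = _read_ids(path / "genes.tsv")
    cells, batches = _load_cells(path)
    mat = sps.csr_matrix(mat)
    if mat.shape == (len(cells), len(genes)):
        pass
    elif mat.shape == (len(genes), len(cells)):
        log.info("transposing %s to cells x genes", mtx)
        mat = sps.csr_matrix(mat.T)
    else:
        raise ValueError("matrix shape matches neither id-file orientation")
    _validate_values(mat)
    return Dataset(mat, cells, genes, batches=batches)


def _load_cells(path: Path):
    """cells.tsv (header; id first, covariates after) or headerless barcodes.tsv."""
    cells_tsv = path / "cells.tsv"
    if cells_tsv.exists():
        df = pd.read_csv(cells_tsv, sep="\t", dtype=str, comment="#")
        ids = [str(v) for v in df.iloc[:, 0]]
        cov = df.iloc[:, 1:].reset_index(drop=True) if df.shape[1] > 1 else None
        return ids, cov
    return _read_ids(path / "barcodes.tsv"), None


def _load_delimited(path: Path) -> Dataset:
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    _validate_values_dense(df.to_numpy())
    return Dataset(sps.csr_matrix(df.to_numpy()),
                   [str(i) for i in df.index], [str(c) for c in df.columns])


def _load_h5(path: Path) -> Dataset:
    import anndata
    adata = anndata.read_h5ad(str(path))
    X = adata.X
    mat = sps.csr_matrix(X) if not sps.issparse(X) else X.tocsr()
    _validate_values(mat)
    batches = adata.obs.astype(str).reset_index(drop=True) if adata.obs.shape[1] else None
    return Dataset(mat, [str(i) for i in adata.obs_names],
                   [str(i) for i in adata.var_names], batches=batches)


def _validate_values(mat: sps.spmatrix):
    if mat.nnz == 0:
        return
    d = mat.data
    if d.min() < 0:
        raise ValueError("negative values in the count matrix")
    if not np.allclose(d, np.round(d)):
        raise ValueError("fractional values in the count matrix")


def _validate_values_dense(arr: np.ndarray):
    if arr.size and (arr.min() < 0 or not np.allclose(arr, np.round(arr))):
        raise ValueError("counts must be nonnegative integers")


def write_counts(path, dataset: Dataset):
    """Write an MTX directory (lossless round trip with `load_counts`)."""
    from scipy.io import mmwrite
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sps.coo_matrix(dataset.counts),
            field="integer")
    (path / "genes.tsv").write_text("\n".join(dataset.gene_ids) + "\n")
    df = pd.DataFrame({"cell": dataset.cell_ids})
    if dataset.batches is not None:
        df = df.join(dataset.batches.reset_index(drop=True))
    df.to_csv(path / "cells.tsv", sep="\t", index=False)


def read_marker_list(path) -> list[str]:
    """One symbol per line; `#` comments and blank lines ignored."""
    return _read_ids(Path(path))


def augment_hvg_with_markers(selected_genes, marker_sets) -> list[str]:
    """Union of a highly-variable-gene selection with every marker gene;
    markers filtered out upstream are added back.  Order: selection
    first, then new markers in their listed order."""
    out = list(selected_genes)
    seen = set(out)
    sets = marker_sets.values() if isinstance(marker_sets, dict) else [marker_sets]
    for s in sets:
        for g in s:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out
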