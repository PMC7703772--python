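"""Readers and writers for count matrices, group labels and recovered output.

Two on-disk layouts are supported:

* MatrixMarket coordinate integer (``matrix.mtx``) with ``genes.tsv`` and
  ``barcodes.tsv`` sidecars in the same directory — the common CellRanger-
  style layout, genes in rows and cells in columns;
* dense TSV/CSV with a header row of cell IDs and the first column holding
  gene IDs.

Integer outputs round-trip bit-exactly through either format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import CountMatrix, RecoveredCounts

__all__ = ["read_counts", "read_groups", "write_counts", "write_recovered"]

_GENES_SIDECAR = "genes.tsv"
_CELLS_SIDECAR = "barcodes.tsv"


def _read_ids(path: Path) -> np.ndarray:
    with open(path) as fh:
        # sidecars may carry extra tab-separated annotation columns; the ID is first
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def read_counts(path, format: str | None = None, *, transposed: bool = False) -> CountMatrix:
    """Read a genes x cells count matrix.

    Parameters
    ----------
    path
        For ``format="mtx"``: the ``.mtx`` file or its directory (sidecars
        ``genes.tsv``/``barcodes.tsv`` must sit next to it).  For
        ``format="tsv"``: a dense TSV/CSV file.
    format
        ``"mtx"`` or ``"tsv"``; inferred from the suffix when omitted.
    transposed
        MTX only: set when the file stores cells in rows; the matrix is
        transposed after reading and the sidecar roles swap accordingly.
        Orientation is never guessed.
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix in (".tsv", ".csv", ".txt"):
            format = "tsv"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}; pass format=")
    if format == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        if not mtx_path.exists():
            raise FileNotFoundError(mtx_path)
        side_dir = mtx_path.parent
        values = sparse.csr_array(spio.mmread(mtx_path))
        if transposed:
            values = values.T.tocsr()
        gene_ids = _read_ids(side_dir / _GENES_SIDECAR)
        cell_ids = _read_ids(side_dir / _CELLS_SIDECAR)
        return CountMatrix(values, gene_ids, cell_ids)
    if format == "tsv":
        if not path.exists():
            raise FileNotFoundError(path)
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(
            df.to_numpy(),
            np.asarray(df.index, dtype=object),
            np.asarray(df.columns, dtype=object),
        )
    raise ValueError(f"unknown format {format!r}")


def read_groups(path, cm: CountMatrix) -> CountMatrix:
    """Attach group/condition labels from a two-column TSV (cell ID, group).

    Every cell of ``cm`` must appear exactly once; labels are returned in
    the matrix's cell order regardless of file order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "group"], dtype=str)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicated cell ID in groups file: {dup!r}")
    mapping = dict(zip(df["cell_id"], df["group"]))
    known = set(map(str, cm.cell_ids))
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"groups file names unknown cells: {sorted(unknown)[:5]}")
    missing = [c for c in cm.cell_ids if str(c) not in mapping]
    if missing:
        raise ValueError(f"groups file missing cells: {missing[:5]}")
    return cm.with_groups([mapping[str(c)] for c in cm.cell_ids])


def _write_ids(ids: np.ndarray, path: Path) -> None:
    path.write_text("".join(f"{i}\n" for i in ids))


def _write_mtx(values: np.ndarray, path: Path) -> None:
    coo = sparse.coo_array(np.asarray(values))
    spio.mmwrite(path, coo, field="integer")


def write_counts(cm: CountMatrix, out_dir, format: str = "mtx") -> Path:
    """Write a count matrix as MTX + sidecars (default) or dense TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        _write_mtx(cm.dense(), out_dir / "matrix.mtx")
        _write_ids(cm.gene_ids, out_dir / _GENES_SIDECAR)
        _write_ids(cm.cell_ids, out_dir / _CELLS_SIDECAR)
        return out_dir / "matrix.mtx"
    if format == "tsv":
        df = pd.DataFrame(cm.dense(), index=cm.gene_ids, columns=cm.cell_ids)
        out = out_dir / "matrix.tsv"
        df.to_csv(out, sep="\t", index_label="gene_id")
        return out
    raise ValueError(f"unknown format {format!r}")


def write_recovered(rc: RecoveredCounts, out_dir) -> list[Path]:
    """Write recovered counts to ``out_dir``; returns the files written.

    mean    -> ``mean.tsv`` (dense, real-valued)
    map     -> ``map.tsv`` + ``map.mtx`` (+ sidecars)
    samples -> one ``sample_<s>.mtx`` per posterior draw + ``manifest.json``
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    _write_ids(rc.gene_ids, out_dir / _GENES_SIDECAR)
    _write_ids(rc.cell_ids, out_dir / _CELLS_SIDECAR)
    written += [out_dir / _GENES_SIDECAR, out_dir / _CELLS_SIDECAR]
    if rc.mode == "mean":
        df = pd.DataFrame(rc.values, index=rc.gene_ids, columns=rc.cell_ids)
        out = out_dir / "mean.tsv"
        df.to_csv(out, sep="\t", index_label="gene_id", float_format="%.6g")
        written.append(out)
    elif rc.mode == "map":
        df = pd.DataFrame(rc.values, index=rc.gene_ids, columns=rc.cell_ids)
        out_tsv = out_dir / "map.tsv"
        df.to_csv(out_tsv, sep="\t", index_label="gene_id")
        _write_mtx(rc.values, out_dir / "map.mtx")
        written += [out_tsv, out_dir / "map.mtx"]
    else:
        slices = []
        for s in range(rc.values.shape[2]):
            name = f"sample_{s + 1:03d}.mtx"
            _write_mtx(rc.values[:, :, s], out_dir / name)
            written.append(out_dir / name)
            slices.append(name)
        manifest = {
            "mode": "samples",
            "n_genes": int(rc.values.shape[0]),
            "n_cells": int(rc.values.shape[1]),
            "n_samples": int(rc.values.shape[2]),
            "slices": slices,
            "genes": _GENES_SIDECAR,
            "barcodes": _CELLS_SIDECAR,
        }
        man_path = out_dir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2) + "\n")
        written.append(man_path)
    return written


def read_recovered_samples(out_dir) -> RecoveredCounts:
    """Re-assemble a samples-mode result written by :func:`write_recovered`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    gene_ids = _read_ids(out_dir / manifest["genes"])
    cell_ids = _read_ids(out_dir / manifest["barcodes"])
    stack = np.stack(
        [np.asarray(sparse.csr_array(spio.mmread(out_dir / name)).todense()) for name in manifest["slices"]],
        axis=2,
    )
    return RecoveredCounts("samples", stack, gene_ids, cell_ids)
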