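"""Core container types for count recovery.

The central object is a genes-by-cells matrix of non-negative integer
transcript counts.  Rows are genes, columns are cells, and an optional
per-cell group vector records conditions or batches.  Recovered output is
either a point estimate per (gene, cell) — posterior mean (real-valued) or
maximum a posteriori count — or a stack of posterior draws (3D array with
the draw index last).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import sparse

Mode = Literal["mean", "map", "samples"]
PriorScope = Literal["global", "local"]

__all__ = ["CountMatrix", "RecoveredCounts", "RunConfig", "Mode", "PriorScope"]


def _check_ids(ids: np.ndarray, n: int, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if ids.ndim != 1 or ids.shape[0] != n:
        raise ValueError(f"{what}: expected {n} identifiers, got shape {ids.shape}")
    if len(set(ids.tolist())) != n:
        raise ValueError(f"{what}: duplicate identifiers")
    return ids


def _validate_counts(values):
    """Accept dense or sparse input, reject negative / non-integer entries."""
    if sparse.issparse(values):
        data = values.data
    else:
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError(f"count matrix must be 2-D, got ndim={values.ndim}")
        data = values
    if data.size and np.issubdtype(np.asarray(data).dtype, np.floating):
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite count")
        if np.any(np.asarray(data) != np.floor(data)):
            raise ValueError("non-integer count")
    if data.size and np.any(np.asarray(data) < 0):
        raise ValueError("negative count")
    return values


@dataclass
class CountMatrix:
    """Genes x cells matrix of raw transcript counts.

    ``values`` may be dense (ndarray) or scipy sparse; it is validated to be
    non-negative and integer-valued.  ``groups``, when present, assigns each
    cell to exactly one condition/batch label.
    """

    values: np.ndarray | sparse.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _validate_counts(self.values)
        p, q = self.values.shape
        if p < 1 or q < 1:
            raise ValueError("count matrix must have at least one gene and one cell")
        self.gene_ids = _check_ids(self.gene_ids, p, "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, q, "cell_ids")
        if self.groups is not None:
            g = np.asarray(self.groups, dtype=object)
            if g.shape != (q,):
                raise ValueError("groups must assign exactly one label per cell")
            self.groups = g

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense integer ndarray (copy only when sparse)."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel().astype(float)

    def with_groups(self, groups) -> "CountMatrix":
        return replace(self, groups=np.asarray(groups, dtype=object))

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        vals = self.values[:, idx] if not sparse.issparse(self.values) else self.values.tocsc()[:, idx]
        groups = None if self.groups is None else self.groups[idx]
        return CountMatrix(vals, self.gene_ids, self.cell_ids[idx], groups)


@dataclass
class RecoveredCounts:
    """Recovered original counts: a point estimate or posterior draws.

    mode="mean"    -> values is P x Q real
    mode="map"     -> values is P x Q integer
    mode="samples" -> values is P x Q x S integer, draw index last
    """

    mode: Mode
    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mode not in ("mean", "map", "samples"):
            raise ValueError(f"unknown mode {self.mode!r}")
        want_ndim = 3 if self.mode == "samples" else 2
        if self.values.ndim != want_ndim:
            raise ValueError(f"mode={self.mode} requires {want_ndim}-D values")
        if self.mode == "samples" and self.values.shape[2] < 1:
            raise ValueError("samples mode requires S >= 1")
        p, q = self.values.shape[:2]
        self.gene_ids = _check_ids(self.gene_ids, p, "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, q, "cell_ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[2] if self.mode == "samples" else 1


@dataclass
class RunConfig:
    """Run-wide knobs for the normalization pipeline.

    beta_bar       mean capture efficiency of the protocol (fraction of
                   original transcripts observed in an average cell)
    mode           output flavour: posterior mean, MAP, or posterior draws
    n_samples      number of posterior draws when mode="samples"
    prior_scope    estimate gene priors over all cells or per cell group
    seed           root seed; every random draw flows from it
    """

    beta_bar: float = 0.06
    mode: Mode = "mean"
    n_samples: int = 5
    prior_scope: PriorScope = "global"
    seed: int = 0
    # numerical guards
    beta_eps: float = 1e-4
    beta_cap: float = 0.95
    phi_min: float = 1e-3
    phi_max: float = 1e3
    trim_fraction: float = 0.05
    shrink_weight: float = 0.5
    mle_refine: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.beta_bar < 1.0:
            raise ValueError("beta_bar must lie in (0, 1)")
        if self.mode not in ("mean", "map", "samples"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.prior_scope not in ("global", "local"):
            raise ValueError(f"unknown prior scope {self.prior_scope!r}")
        if not 0.0 < self.beta_eps < self.beta_cap < 1.0:
            raise ValueError("require 0 < beta_eps < beta_cap < 1")
        if not self.beta_bar < self.beta_cap:
            raise ValueError("beta_bar must be below beta_cap")
        if not 0.0 < self.phi_min < self.phi_max:
            raise ValueError("require 0 < phi_min < phi_max")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if not 0.0 <= self.shrink_weight <= 1.0:
            raise ValueError("shrink_weight must lie in [0, 1]")
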