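"""Per-cell capture efficiencies.

Each cell observes only a fraction of its transcripts; that fraction is the
capture efficiency beta_j, the success probability of the binomial capture
model.  Relative differences between cells are read off global scaling
factors s_j (total counts, optionally trimmed of the most abundant genes),
which are then calibrated so that their mean equals the experiment-wide
mean capture efficiency beta_bar supplied by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import CountMatrix

logger = logging.getLogger(__name__)

BETA_EPS = 1e-4
BETA_CAP = 0.95
DEFAULT_BETA_BAR = 0.06
DEFAULT_TRIM_FRACTION = 0.05

__all__ = [
    "CaptureEfficiencies",
    "scaling_factors_total_count",
    "scaling_factors_trimmed",
    "calibrate_beta",
    "estimate_beta",
]


@dataclass
class CaptureEfficiencies:
    """Calibrated per-cell capture probabilities.

    beta      Q values in (0, 1); mean equals beta_bar unless clipping bit
    beta_bar  mean capture efficiency used for calibration
    source    how the underlying scaling factors were obtained
    """

    beta: np.ndarray
    beta_bar: float
    source: Literal["total_count", "trimmed", "user"] = "user"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise ValueError("beta must be a 1-D vector")
        # beta = 1 (exact full capture) is admitted as the degenerate case;
        # calibration itself always clips strictly below 1
        if np.any(self.beta <= 0.0) or np.any(self.beta > 1.0):
            raise ValueError("every capture efficiency must lie in (0, 1]")
        if not 0.0 < self.beta_bar < 1.0:
            raise ValueError("beta_bar must lie in (0, 1)")

    @property
    def n_cells(self) -> int:
        return self.beta.shape[0]


def scaling_factors_total_count(cm: CountMatrix) -> np.ndarray:
    """Global scaling factor of each cell: its total count.

    Zero-total cells are an error — filtering empty cells is the caller's
    decision and should happen before normalization.
    """
    totals = cm.column_totals()
    if np.any(totals == 0):
        bad = [str(c) for c in np.asarray(cm.cell_ids)[totals == 0][:5]]
        raise ValueError(f"cells with zero total count: {bad}; filter them before normalization")
    return totals


def scaling_factors_trimmed(cm: CountMatrix, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> np.ndarray:
    """Column totals after discarding the most abundant genes.

    The top ``trim_fraction`` of genes ranked by overall mean expression is
    removed — the same gene set for every cell — so a handful of very highly
    expressed genes cannot dominate the scaling factors.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    dense = cm.dense()
    n_trim = int(np.floor(cm.n_genes * trim_fraction))
    if n_trim >= cm.n_genes:
        raise ValueError("trimming removes all genes")
    if n_trim == 0:
        totals = dense.sum(axis=0).astype(float)
    else:
        gene_means = dense.mean(axis=1)
        keep = np.argsort(gene_means, kind="stable")[: cm.n_genes - n_trim]
        totals = dense[keep].sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [str(c) for c in np.asarray(cm.cell_ids)[totals == 0][:5]]
        raise ValueError(f"cells with zero total count after trimming: {bad}")
    return totals


def calibrate_beta(
    s: np.ndarray,
    beta_bar: float,
    *,
    cap: float = BETA_CAP,
    eps: float = BETA_EPS,
    source: str = "user",
) -> CaptureEfficiencies:
    """Turn relative scaling factors into capture probabilities.

    beta_j = beta_bar * s_j / mean(s), clipped into [eps, cap].  Clipping
    keeps beta a valid binomial probability: beta >= 1 is meaningless under
    the capture model and beta = 0 makes the posterior improper for x > 0.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scaling factors must be strictly positive")
    if not 0.0 < beta_bar < 1.0:
        raise ValueError("beta_bar must lie in (0, 1)")
    if not beta_bar < cap < 1.0:
        raise ValueError("require beta_bar < cap < 1")
    beta = beta_bar * s / s.mean()
    n_clip = int(np.sum((beta < eps) | (beta > cap)))
    if n_clip:
        logger.warning("calibrate_beta: clipped %d of %d capture efficiencies", n_clip, beta.size)
    beta = np.clip(beta, eps, cap)
    return CaptureEfficiencies(beta=beta, beta_bar=beta_bar, source=source)  # type: ignore[arg-type]


def estimate_beta(
    cm: CountMatrix,
    beta_bar: float = DEFAULT_BETA_BAR,
    method: Literal["total", "trimmed", "user"] = "total",
    *,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    user_factors: np.ndarray | None = None,
    cap: float = BETA_CAP,
    eps: float = BETA_EPS,
) -> CaptureEfficiencies:
    """One-stop scaling-factor estimation + calibration."""
    if method == "total":
        s, source = scaling_factors_total_count(cm), "total_count"
    elif method == "trimmed":
        s, source = scaling_factors_trimmed(cm, trim_fraction), "trimmed"
    elif method == "user":
        if user_factors is None:
            raise ValueError("method='user' requires user_factors")
        s, source = np.asarray(user_factors, dtype=float), "user"
        if s.shape != (cm.n_cells,):
            raise ValueError("user_factors length must equal the number of cells")
    else:
        raise ValueError(f"unknown beta method {method!r}")
    return calibrate_beta(s, beta_bar, cap=cap, eps=eps, source=source)
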