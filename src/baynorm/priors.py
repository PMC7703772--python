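"""Empirical-Bayes estimation of gene-specific negative-binomial priors.

Each gene's original (pre-capture) count per cell is modelled as
NB(mean=mu_i, size=phi_i).  Because observed counts are a binomial thinning
of the originals with per-cell probability beta_j, the observed counts of
gene i in cell j follow NB(mean=mu_i*beta_j, size=phi_i); in particular
E[x_ij] = mu_i*beta_j, so scaled counts x_ij/beta_j are unbiased for mu_i.

Estimation proceeds in three steps:

1. method of moments for mu_i from scaled counts;
2. method of moments for phi_i after subtracting the extra variance that
   thinning injects into the scaled counts;
3. shrinkage of the noisy per-gene dispersions towards a log-log trend of
   dispersion on mean, fitted across genes — the usual borrowing of
   strength for NB dispersion estimation.

An optional refinement pass replaces the moment estimates with a per-gene
numerical maximum-likelihood fit of the thinned NB marginal, initialized at
the moment estimates.

"Global" priors pool all cells; "local" priors are estimated within each
cell group, which sharpens group differences in downstream comparisons.
Capture efficiencies are always calibrated on the full dataset, never
re-derived per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .capture_efficiency import CaptureEfficiencies
from .core import CountMatrix

logger = logging.getLogger(__name__)

PHI_MIN = 1e-3
PHI_MAX = 1e3
DEFAULT_SHRINK_WEIGHT = 0.5
_MIN_GENES_FOR_SHRINKAGE = 10

__all__ = [
    "GenePriors",
    "GroupedPriors",
    "mme_mu",
    "mme_phi",
    "shrink_phi",
    "mle_refine",
    "estimate_priors",
]


@dataclass
class GenePriors:
    """Per-gene NB prior parameters.

    mu       prior mean original count per cell (> 0 for retained genes)
    phi      NB size/dispersion, clamped into [PHI_MIN, PHI_MAX]
    flagged  genes whose prior could not be estimated (all-zero genes);
             they are carried through recovery unchanged, never dropped
    """

    mu: np.ndarray
    phi: np.ndarray
    scope: str = "global"
    group: str | None = None
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.mu.shape != self.phi.shape or self.mu.ndim != 1:
            raise ValueError("mu and phi must be 1-D vectors of equal length")
        if self.flagged is None:
            self.flagged = np.zeros(self.mu.shape, dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        ok = ~self.flagged
        if np.any(self.mu[ok] <= 0) or np.any(self.phi[ok] <= 0):
            raise ValueError("retained genes require mu > 0 and phi > 0")

    @property
    def n_genes(self) -> int:
        return self.mu.shape[0]


@dataclass
class GroupedPriors:
    """One :class:`GenePriors` per cell group, identical gene order."""

    by_group: dict[str, GenePriors]

    def __post_init__(self) -> None:
        if not self.by_group:
            raise ValueError("GroupedPriors requires at least one group")
        sizes = {gp.n_genes for gp in self.by_group.values()}
        if len(sizes) != 1:
            raise ValueError("all groups must cover the same genes")

    @property
    def n_genes(self) -> int:
        return next(iter(self.by_group.values())).n_genes


def _scaled(cm: CountMatrix, ce: CaptureEfficiencies) -> np.ndarray:
    if ce.n_cells != cm.n_cells:
        raise ValueError("capture efficiencies do not match the number of cells")
    return cm.dense() / ce.beta[np.newaxis, :]


def mme_mu(cm: CountMatrix, ce: CaptureEfficiencies) -> np.ndarray:
    """Moment estimate of the prior mean: average of beta-scaled counts."""
    return _scaled(cm, ce).mean(axis=1)


def mme_phi(
    cm: CountMatrix,
    ce: CaptureEfficiencies,
    mu_hat: np.ndarray,
    *,
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
) -> np.ndarray:
    """Thinning-corrected moment estimate of the NB size parameter.

    Scaled counts have variance mu/beta + mu^2/phi per cell, i.e. the NB
    variance mu + mu^2/phi inflated by mu*(1-beta)/beta; averaging over
    cells, subtracting that inflation leaves the original NB variance, and
    phi = mu^2 / (var - mu).  Genes whose corrected variance does not exceed
    the mean look Poisson and are clamped to ``phi_max``.
    """
    scaled = _scaled(cm, ce)
    mu_hat = np.asarray(mu_hat, dtype=float)
    v_scaled = scaled.var(axis=1, ddof=1)
    inflation = np.mean((1.0 - ce.beta) / ce.beta)
    v_hat = v_scaled - mu_hat * inflation
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = mu_hat**2 / (v_hat - mu_hat)
    bad = ~np.isfinite(phi) | (phi <= 0)
    if np.any(bad):
        logger.debug("mme_phi: %d genes clamped to phi_max (Poisson-like)", int(bad.sum()))
    phi[bad] = phi_max
    return np.clip(phi, phi_min, phi_max)


def shrink_phi(
    mu_hat: np.ndarray,
    phi_raw: np.ndarray,
    *,
    weight: float = DEFAULT_SHRINK_WEIGHT,
    retained: np.ndarray | None = None,
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
) -> np.ndarray:
    """Shrink per-gene dispersions towards a log-log mean-dispersion trend.

    Ordinary least squares of log(phi_raw) on log(mu_hat) over retained
    genes gives the trend; each gene's final dispersion is the blend
    ``weight * fitted + (1 - weight) * raw`` on the log scale, then
    back-transformed and re-clamped.  With fewer than 10 retained genes the
    trend is unidentifiable and the raw estimates are returned unchanged.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    phi_raw = np.asarray(phi_raw, dtype=float)
    if retained is None:
        retained = (mu_hat > 0) & np.isfinite(phi_raw) & (phi_raw > 0)
    retained = np.asarray(retained, dtype=bool)
    if weight == 0.0:
        return phi_raw.copy()
    if int(retained.sum()) < _MIN_GENES_FOR_SHRINKAGE:
        logger.warning(
            "shrink_phi: only %d retained genes (<%d); returning raw dispersions",
            int(retained.sum()),
            _MIN_GENES_FOR_SHRINKAGE,
        )
        return phi_raw.copy()
    log_mu = np.log(mu_hat[retained])
    log_phi = np.log(phi_raw[retained])
    slope, intercept = np.polyfit(log_mu, log_phi, deg=1)
    out = phi_raw.copy()
    fitted = intercept + slope * np.log(mu_hat[retained])
    blended = weight * fitted + (1.0 - weight) * log_phi
    out[retained] = np.exp(blended)
    return np.clip(out, phi_min, phi_max)


def _nb_marginal_negloglik(log_params: np.ndarray, x: np.ndarray, beta: np.ndarray) -> float:
    mu, phi = np.exp(log_params)
    m = mu * beta
    # NB(mean=m, size=phi) log pmf
    ll = (
        special.gammaln(x + phi)
        - special.gammaln(phi)
        - special.gammaln(x + 1.0)
        + phi * np.log(phi / (phi + m))
        + x * np.log(m / (phi + m))
    )
    return -float(ll.sum())


def mle_refine(
    cm: CountMatrix,
    ce: CaptureEfficiencies,
    mu0: np.ndarray,
    phi0: np.ndarray,
    *,
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene numerical MLE of the thinned NB marginal, seeded at (mu0, phi0)."""
    dense = cm.dense().astype(float)
    mu = np.asarray(mu0, dtype=float).copy()
    phi = np.asarray(phi0, dtype=float).copy()
    for i in range(cm.n_genes):
        if mu[i] <= 0:
            continue
        res = optimize.minimize(
            _nb_marginal_negloglik,
            x0=np.log([mu[i], np.clip(phi[i], phi_min, phi_max)]),
            args=(dense[i], ce.beta),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if res.success or res.fun < _nb_marginal_negloglik(np.log([mu[i], phi[i]]), dense[i], ce.beta):
            mu[i], phi[i] = np.exp(res.x)
    return mu, np.clip(phi, phi_min, phi_max)


def _estimate_one(
    cm: CountMatrix,
    ce: CaptureEfficiencies,
    *,
    scope: str,
    group: str | None,
    shrink_weight: float,
    refine: bool,
    phi_min: float,
    phi_max: float,
) -> GenePriors:
    mu_hat = mme_mu(cm, ce)
    flagged = mu_hat <= 0.0
    phi_raw = mme_phi(cm, ce, mu_hat, phi_min=phi_min, phi_max=phi_max)
    phi = shrink_phi(
        mu_hat, phi_raw, weight=shrink_weight, retained=~flagged, phi_min=phi_min, phi_max=phi_max
    )
    if refine:
        mu_hat, phi = mle_refine(cm, ce, mu_hat, phi, phi_min=phi_min, phi_max=phi_max)
    return GenePriors(mu=mu_hat, phi=phi, scope=scope, group=group, flagged=flagged)


def estimate_priors(
    cm: CountMatrix,
    ce: CaptureEfficiencies,
    scope: str = "global",
    *,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
    refine: bool = False,
    phi_min: float = PHI_MIN,
    phi_max: float = PHI_MAX,
) -> GenePriors | GroupedPriors:
    """Estimate gene priors over all cells (global) or per cell group (local)."""
    if scope == "global":
        return _estimate_one(
            cm, ce, scope="global", group=None, shrink_weight=shrink_weight,
            refine=refine, phi_min=phi_min, phi_max=phi_max,
        )
    if scope != "local":
        raise ValueError(f"unknown prior scope {scope!r}")
    if cm.groups is None:
        raise ValueError("local priors require group labels on the count matrix")
    by_group: dict[str, GenePriors] = {}
    for g in dict.fromkeys(cm.groups):  # first-appearance order
        mask = cm.groups == g
        if int(mask.sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        sub = cm.subset_cells(mask)
        sub_ce = CaptureEfficiencies(ce.beta[mask], ce.beta_bar, ce.source)
        by_group[str(g)] = _estimate_one(
            sub, sub_ce, scope="local", group=str(g), shrink_weight=shrink_weight,
            refine=refine, phi_min=phi_min, phi_max=phi_max,
        )
    return GroupedPriors(by_group=by_group)
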