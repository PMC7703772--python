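"""Closed-form posterior of original transcript counts.

Given an observed count x with capture probability beta and an NB(mu, phi)
prior on the original count x0, the posterior of x0 is a *shifted* negative
binomial: x0 = x + zeta, where the lost count zeta follows

    zeta ~ NB(mean = mu*(1-beta)*(x+phi) / (mu*beta+phi), size = x+phi).

Everything downstream — posterior mean, variance, pmf, mode (MAP) and
sampling — follows from this closed form; no numerical integration is ever
needed.  The marginal of the observed count is NB(mean=mu*beta, size=phi),
i.e. binomial thinning of an NB stays NB with a thinned mean.

All pmf evaluations run in log space through log-gamma, so large counts and
extreme parameters cannot overflow.  Sampling uses the Gamma-Poisson mixture
representation of the NB, which is exact for arbitrary real size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .capture_efficiency import CaptureEfficiencies
from .core import CountMatrix, RecoveredCounts, RunConfig
from .priors import GenePriors, GroupedPriors

__all__ = [
    "PosteriorParams",
    "lost_count_params",
    "posterior_mean",
    "posterior_var",
    "posterior_pmf",
    "posterior_map",
    "posterior_sample",
    "marginal_pmf",
    "normalize",
    "scale_non_umi",
]


def _check_domain(x, mu, phi, beta) -> None:
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a non-negative integer count")
    if np.any(np.asarray(mu) <= 0) or np.any(np.asarray(phi) <= 0):
        raise ValueError("mu and phi must be positive")
    beta = np.asarray(beta)
    if np.any(beta <= 0) or np.any(beta > 1):
        raise ValueError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class PosteriorParams:
    """Lost-count NB parameters for one (gene, cell) entry."""

    x: int
    zeta_mean: float
    zeta_size: float
    mu: float
    phi: float
    beta: float


def _zeta_params(x, mu, phi, beta):
    zeta_mean = mu * (1.0 - beta) * (x + phi) / (mu * beta + phi)
    zeta_size = x + phi
    return zeta_mean, zeta_size


def lost_count_params(x: int, mu: float, phi: float, beta: float) -> PosteriorParams:
    """NB parameters of the lost count zeta = x0 - x."""
    _check_domain(x, mu, phi, beta)
    zeta_mean, zeta_size = _zeta_params(x, mu, phi, beta)
    return PosteriorParams(x=int(x), zeta_mean=float(zeta_mean), zeta_size=float(zeta_size),
                           mu=float(mu), phi=float(phi), beta=float(beta))


def posterior_mean(x, mu, phi, beta):
    """E[x0 | x] = [x*(mu+phi) + mu*phi*(1-beta)] / (mu*beta + phi)."""
    _check_domain(x, mu, phi, beta)
    x, mu, phi, beta = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, mu, phi, beta)))
    out = (x * (mu + phi) + mu * phi * (1.0 - beta)) / (mu * beta + phi)
    return out if out.ndim else float(out)


def posterior_var(x, mu, phi, beta):
    """Var[x0 | x] = (x+phi) * mu*(1-beta)*(mu+phi) / (mu*beta + phi)^2."""
    _check_domain(x, mu, phi, beta)
    x, mu, phi, beta = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, mu, phi, beta)))
    out = (x + phi) * mu * (1.0 - beta) * (mu + phi) / (mu * beta + phi) ** 2
    return out if out.ndim else float(out)


def _nb_logpmf(k, mean, size):
    """log NB(k; mean, size), safe at mean == 0 (point mass at zero)."""
    k = np.asarray(k, dtype=float)
    mean = np.asarray(mean, dtype=float)
    size = np.asarray(size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_q = np.log(mean) - np.log(size + mean)      # -inf when mean == 0
        log_p = np.log(size) - np.log(size + mean)
        ll = (
            special.gammaln(k + size)
            - special.gammaln(size)
            - special.gammaln(k + 1.0)
            + size * log_p
            + k * log_q
        )
    # mean == 0: pmf is 1 at k == 0, 0 elsewhere
    ll = np.where(mean == 0.0, np.where(k == 0.0, 0.0, -np.inf), ll)
    return ll


def posterior_pmf(n, x, mu, phi, beta):
    """Pr(x0 = n | x): zero below the observed count, shifted NB above it."""
    _check_domain(x, mu, phi, beta)
    n = np.asarray(n, dtype=float)
    if np.any(n != np.floor(n)) or np.any(n < 0):
        raise ValueError("n must be a non-negative integer count")
    zeta_mean, zeta_size = _zeta_params(
        np.asarray(x, dtype=float), np.asarray(mu, dtype=float),
        np.asarray(phi, dtype=float), np.asarray(beta, dtype=float),
    )
    k = n - np.asarray(x, dtype=float)
    out = np.where(k < 0, -np.inf, _nb_logpmf(np.maximum(k, 0.0), zeta_mean, zeta_size))
    out = np.exp(out)
    return out if out.ndim else float(out)


def marginal_pmf(x, mu, phi, beta):
    """Pr(x | mu, phi, beta): NB with mean mu*beta and size phi."""
    _check_domain(x, mu, phi, beta)
    x, mu, phi, beta = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, mu, phi, beta)))
    out = np.exp(_nb_logpmf(x, mu * beta, phi))
    return out if out.ndim else float(out)


def _nb_mode(mean, size):
    """Mode of NB(mean, size); ties between adjacent integers break low.

    The pmf ratio P(k)/P(k-1) = q*(k-1+size)/k with q = mean/(mean+size)
    crosses 1 at t = q*(size-1)/(1-q); the mode is floor(t) (0 when t <= 0).
    To be robust to floating error at integer crossings, the log pmf is
    evaluated at floor(t) and its two neighbours and the smallest argmax
    wins.
    """
    mean = np.asarray(mean, dtype=float)
    size = np.asarray(size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = mean / (mean + size)
        t = q * (size - 1.0) / (1.0 - q)
    t = np.where(np.isfinite(t), t, 0.0)
    base = np.maximum(np.floor(t), 0.0)
    cand = np.stack([np.maximum(base - 1, 0.0), base, base + 1], axis=0)
    ll = _nb_logpmf(cand, mean[np.newaxis], size[np.newaxis])
    # argmax with ties to the smaller candidate: np.argmax picks first max,
    # and candidates are ascending
    best = np.argmax(np.isclose(ll, ll.max(axis=0), rtol=0, atol=1e-12) * 1, axis=0)
    mode = np.take_along_axis(cand, best[np.newaxis], axis=0)[0]
    return mode


def posterior_map(x, mu, phi, beta):
    """Maximum a posteriori original count: x plus the lost-count NB mode."""
    _check_domain(x, mu, phi, beta)
    x_arr, mu, phi, beta = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, mu, phi, beta)))
    zeta_mean, zeta_size = _zeta_params(x_arr, mu, phi, beta)
    out = x_arr + _nb_mode(zeta_mean, zeta_size)
    out = out.astype(np.int64)
    return out if out.ndim else int(out)


def posterior_sample(x, mu, phi, beta, size: int, rng: np.random.Generator):
    """Draw ``size`` posterior original counts x + zeta.

    zeta is drawn through the exact Gamma-Poisson mixture:
    rate ~ Gamma(shape=zeta_size, scale=zeta_mean/zeta_size), zeta ~ Poisson(rate).
    Every draw is >= x by construction.
    """
    _check_domain(x, mu, phi, beta)
    if size < 1:
        raise ValueError("size must be >= 1")
    x_arr, mu, phi, beta = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, mu, phi, beta)))
    zeta_mean, zeta_size = _zeta_params(x_arr, mu, phi, beta)
    shape = (size,) + x_arr.shape
    rate = rng.gamma(shape=np.broadcast_to(zeta_size, shape),
                     scale=np.broadcast_to(zeta_mean / zeta_size, shape))
    zeta = rng.poisson(rate)
    return (x_arr.astype(np.int64) + zeta).reshape(shape)


def _per_entry_priors(
    cm: CountMatrix, priors: GenePriors | GroupedPriors
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand priors to per-entry (mu, phi) P x Q arrays + flagged-gene mask."""
    p, q = cm.n_genes, cm.n_cells
    if isinstance(priors, GenePriors):
        if priors.n_genes != p:
            raise ValueError("priors do not match the number of genes")
        mu = np.repeat(priors.mu[:, np.newaxis], q, axis=1)
        phi = np.repeat(priors.phi[:, np.newaxis], q, axis=1)
        flagged = np.repeat(priors.flagged[:, np.newaxis], q, axis=1)
        return mu, phi, flagged
    if cm.groups is None:
        raise ValueError("grouped priors require group labels on the count matrix")
    mu = np.empty((p, q))
    phi = np.empty((p, q))
    flagged = np.empty((p, q), dtype=bool)
    for g, gp in priors.by_group.items():
        if gp.n_genes != p:
            raise ValueError("priors do not match the number of genes")
        mask = np.asarray([str(lbl) == g for lbl in cm.groups])
        mu[:, mask] = gp.mu[:, np.newaxis]
        phi[:, mask] = gp.phi[:, np.newaxis]
        flagged[:, mask] = gp.flagged[:, np.newaxis]
    missing = set(map(str, cm.groups)) - set(priors.by_group)
    if missing:
        raise ValueError(f"no priors for groups: {sorted(missing)}")
    return mu, phi, flagged


def normalize(
    cm: CountMatrix,
    ce: CaptureEfficiencies,
    priors: GenePriors | GroupedPriors,
    cfg: RunConfig,
) -> RecoveredCounts:
    """Recover original counts for a whole matrix.

    Flagged (all-zero) genes pass through unchanged: a gene never observed
    anywhere is unidentifiable and stays zero rather than being imputed
    from an arbitrary prior.
    """
    if ce.n_cells != cm.n_cells:
        raise ValueError("capture efficiencies do not match the number of cells")
    x = cm.dense().astype(float)
    mu, phi, flagged = _per_entry_priors(cm, priors)
    beta = np.broadcast_to(ce.beta[np.newaxis, :], x.shape)
    # placeholder parameters for flagged genes; their output is overwritten below
    mu_safe = np.where(flagged, 1.0, mu)
    phi_safe = np.where(flagged, 1.0, phi)
    if cfg.mode == "mean":
        vals = posterior_mean(x, mu_safe, phi_safe, beta)
        vals = np.where(flagged, x, vals)
        return RecoveredCounts("mean", vals, cm.gene_ids, cm.cell_ids)
    if cfg.mode == "map":
        vals = posterior_map(x, mu_safe, phi_safe, beta)
        vals = np.where(flagged, x.astype(np.int64), vals)
        return RecoveredCounts("map", vals, cm.gene_ids, cm.cell_ids)
    if cfg.mode == "samples":
        s_total = cfg.n_samples
        out = np.empty(x.shape + (s_total,), dtype=np.int64)
        for s in range(s_total):
            # deterministic per-slice substream: the first S slices are
            # identical whatever the total number of draws requested
            rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(s,)))
            draw = posterior_sample(x, mu_safe, phi_safe, beta, size=1, rng=rng)[0]
            out[:, :, s] = np.where(flagged, x.astype(np.int64), draw)
        return RecoveredCounts("samples", out, cm.gene_ids, cm.cell_ids)
    raise ValueError(f"unknown mode {cfg.mode!r}")


def scale_non_umi(cm: CountMatrix, amplification: float) -> CountMatrix:
    """Rescale non-UMI read counts to molecule scale.

    Without unique molecular identifiers each original molecule is read
    roughly ``amplification`` times after PCR; dividing by that constant
    (round half up) makes the counts compatible with the binomial capture
    model.
    """
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    vals = np.floor(cm.dense() / float(amplification) + 0.5).astype(np.int64)
    return CountMatrix(vals, cm.gene_ids, cm.cell_ids, cm.groups)
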