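"""Generative simulator: NB ground truth thinned by per-cell capture.

The generative model mirrors the recovery model exactly: original counts
x0_ij ~ NB(mean=mu_i, size=phi_i) independently per gene and cell, and
observed counts x_ij ~ Binomial(x0_ij, beta_j).  Cell-specific capture
efficiencies beta_j are drawn from a Gamma distribution with mean
``beta_bar`` and coefficient of variation ``beta_dispersion`` — the
minimal positive family with a controllable spread — and clipped into a
valid probability range.

Gene means default to a log-normal across genes and dispersions follow a
log-log trend on the mean with noise, producing the familiar mean-variance
fan of droplet scRNA-seq data.  An optional two-group design multiplies the
means of a chosen number of genes in the second group by a fold change, for
differential-expression benchmarking with known ground truth.

Closed-form dropout predictions accompany the simulator: under the model a
gene with observed mean m and size phi is zero in a cell with probability
(phi/(phi+m))^phi, which tends to exp(-m) as phi grows (the Poisson limit);
exp(-mean) is the parameter-free approximation that real UMI data track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capture_efficiency import BETA_CAP, BETA_EPS, CaptureEfficiencies
from .core import CountMatrix
from .priors import GenePriors, GroupedPriors

__all__ = [
    "SimSpec",
    "SimulatedDataset",
    "simulate_true_counts",
    "simulate_beta",
    "thin_binomial",
    "simulate_dataset",
    "expected_dropout_nb",
    "dropout_approx_exp",
]

# gene-parameter defaults: log-normal means, dispersion trend phi ~ mu^0.5
MU_LOGMEAN = 1.0
MU_LOGSD = 1.5
PHI_TREND_INTERCEPT = 0.0
PHI_TREND_SLOPE = 0.5
PHI_TREND_SD = 0.5
DEFAULT_BETA_DISPERSION = 0.3


@dataclass
class SimSpec:
    """Parameters of one simulated experiment.

    n_genes, n_cells   matrix dimensions (P, Q)
    mu, phi            per-gene NB parameters; drawn from the defaults above
                       when omitted
    beta_bar           mean capture efficiency across cells
    beta_dispersion    coefficient of variation of beta across cells
                       (0 = identical capture in every cell)
    group_split        fraction of cells assigned to group "B" (None = one group)
    lfc_genes          number of genes whose group-B mean is shifted
    lfc                log2 fold change applied to those genes in group B
    seed               root seed for every draw in the simulation
    """

    n_genes: int = 2000
    n_cells: int = 1000
    mu: np.ndarray | None = None
    phi: np.ndarray | None = None
    beta_bar: float = 0.1
    beta_dispersion: float = DEFAULT_BETA_DISPERSION
    group_split: float | None = None
    lfc_genes: int = 0
    lfc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be >= 1")
        if not 0.0 < self.beta_bar < 1.0:
            raise ValueError("beta_bar must lie in (0, 1)")
        if self.beta_dispersion < 0.0:
            raise ValueError("beta_dispersion must be >= 0")
        if self.group_split is not None and not 0.0 < self.group_split < 1.0:
            raise ValueError("group_split must lie in (0, 1)")
        if self.lfc_genes < 0 or self.lfc_genes > self.n_genes:
            raise ValueError("lfc_genes must lie in [0, n_genes]")
        for name in ("mu", "phi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.n_genes,):
                    raise ValueError(f"{name} must have length n_genes")
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be positive")
                setattr(self, name, v)


def _gene_params(spec: SimSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mu = spec.mu
    if mu is None:
        mu = rng.lognormal(mean=MU_LOGMEAN, sigma=MU_LOGSD, size=spec.n_genes)
    phi = spec.phi
    if phi is None:
        log_phi = (
            PHI_TREND_INTERCEPT
            + PHI_TREND_SLOPE * np.log(mu)
            + rng.normal(0.0, PHI_TREND_SD, size=spec.n_genes)
        )
        phi = np.exp(log_phi)
    return np.asarray(mu, dtype=float), np.asarray(phi, dtype=float)


def _group_layout(spec: SimSpec, rng: np.random.Generator):
    """Group labels and the per-group mu multiplier matrix."""
    if spec.group_split is None:
        return None, None, np.zeros(spec.n_genes, dtype=bool)
    n_b = int(round(spec.n_cells * spec.group_split))
    n_b = min(max(n_b, 1), spec.n_cells - 1)
    groups = np.asarray(["A"] * (spec.n_cells - n_b) + ["B"] * n_b, dtype=object)
    de_mask = np.zeros(spec.n_genes, dtype=bool)
    if spec.lfc_genes:
        de_idx = rng.choice(spec.n_genes, size=spec.lfc_genes, replace=False)
        de_mask[de_idx] = True
    mult_b = np.where(de_mask, 2.0 ** spec.lfc, 1.0)
    return groups, mult_b, de_mask


def simulate_true_counts(spec: SimSpec, rng: np.random.Generator) -> CountMatrix:
    """Draw the ground-truth (pre-capture) count matrix x0."""
    mu, phi = _gene_params(spec, rng)
    groups, mult_b, _ = _group_layout(spec, rng)
    mu_mat = np.repeat(mu[:, np.newaxis], spec.n_cells, axis=1)
    if groups is not None:
        mu_mat[:, groups == "B"] *= mult_b[:, np.newaxis]
    # NB as Gamma-Poisson: rate ~ Gamma(shape=phi, scale=mu/phi)
    rate = rng.gamma(shape=np.repeat(phi[:, np.newaxis], spec.n_cells, axis=1),
                     scale=mu_mat / phi[:, np.newaxis])
    x0 = rng.poisson(rate)
    gene_ids = np.asarray([f"g{i:05d}" for i in range(spec.n_genes)], dtype=object)
    cell_ids = np.asarray([f"c{j:05d}" for j in range(spec.n_cells)], dtype=object)
    return CountMatrix(x0, gene_ids, cell_ids, groups)


def simulate_beta(spec: SimSpec, rng: np.random.Generator) -> CaptureEfficiencies:
    """Draw per-cell capture efficiencies.

    Gamma with mean beta_bar and CV beta_dispersion, clipped into
    (BETA_EPS, BETA_CAP) and re-centred so the post-clipping mean is
    beta_bar.  ``beta_bar * (1 + 3*beta_dispersion) < 1`` keeps clipping
    rare.
    """
    if spec.beta_dispersion == 0.0:
        beta = np.full(spec.n_cells, spec.beta_bar)
    else:
        cv = spec.beta_dispersion
        shape = 1.0 / cv**2
        beta = rng.gamma(shape=shape, scale=spec.beta_bar * cv**2, size=spec.n_cells)
        beta = np.clip(beta, BETA_EPS, BETA_CAP)
        beta = np.clip(beta * spec.beta_bar / beta.mean(), BETA_EPS, BETA_CAP)
    return CaptureEfficiencies(beta=beta, beta_bar=spec.beta_bar, source="user")


def thin_binomial(x0: CountMatrix, ce: CaptureEfficiencies, rng: np.random.Generator) -> CountMatrix:
    """Observe x ~ Binomial(x0, beta_j): the capture step of the model."""
    if ce.n_cells != x0.n_cells:
        raise ValueError("capture efficiencies do not match the number of cells")
    dense = x0.dense()
    x = rng.binomial(dense, ce.beta[np.newaxis, :])
    return CountMatrix(x, x0.gene_ids, x0.cell_ids, x0.groups)


@dataclass
class SimulatedDataset:
    """Ground truth plus observation: everything a recovery test needs."""

    truth: CountMatrix
    observed: CountMatrix
    ce: CaptureEfficiencies
    priors_true: GenePriors | GroupedPriors
    de_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def simulate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Full generative run: gene params -> x0 -> beta -> thinned x."""
    rng = np.random.default_rng(spec.seed)
    mu, phi = _gene_params(spec, np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,))))
    spec_fixed = SimSpec(**{**spec.__dict__, "mu": mu, "phi": phi})
    rng_counts = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    truth = simulate_true_counts(spec_fixed, rng_counts)
    ce = simulate_beta(spec_fixed, np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,))))
    observed = thin_binomial(truth, ce, np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(3,))))
    _, mult_b, de_mask = _group_layout(spec_fixed, np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,))))
    if truth.groups is None:
        priors: GenePriors | GroupedPriors = GenePriors(mu=mu, phi=phi, scope="global")
    else:
        priors = GroupedPriors(by_group={
            "A": GenePriors(mu=mu, phi=phi, scope="local", group="A"),
            "B": GenePriors(mu=mu * mult_b, phi=phi, scope="local", group="B"),
        })
    return SimulatedDataset(truth=truth, observed=observed, ce=ce, priors_true=priors, de_mask=de_mask)


def expected_dropout_nb(mean_obs, phi):
    """Zero probability of NB(mean_obs, phi): (phi/(phi+mean))^phi."""
    mean_obs = np.asarray(mean_obs, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mean_obs < 0):
        raise ValueError("mean_obs must be >= 0")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    # compute via exp(phi * log1p(-m/(phi+m))) for accuracy at large phi
    out = np.exp(phi * np.log1p(-mean_obs / (phi + mean_obs)))
    return out if out.ndim else float(out)


def dropout_approx_exp(mean_obs):
    """Parameter-free dropout approximation exp(-mean); the Poisson limit."""
    mean_obs = np.asarray(mean_obs, dtype=float)
    if np.any(mean_obs < 0):
        raise ValueError("mean_obs must be >= 0")
    out = np.exp(-mean_obs)
    return out if out.ndim else float(out)
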