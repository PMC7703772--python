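# Methods

## Model

A scRNA-seq experiment is a P × Q matrix of non-negative integers: P genes,
Q cells, entry x_ij the number of transcripts reported for gene i in cell
j (UMI counts, or read counts divided by an amplification constant for
non-UMI protocols — see "Non-UMI data" below). The generative model has
two levels:

* **Capture (likelihood).** Given the original number of transcripts
  x⁰_ij present in the cell, each transcript is observed independently
  with probability β_j, the cell's capture efficiency:
  x_ij | x⁰_ij ~ Binomial(x⁰_ij, β_j). This is the minimal model of
  losing a random fraction of a cell's transcriptome and deliberately has
  no zero-inflation term: dropouts are what binomial thinning at small β
  produces anyway.
* **Expression (prior).** x⁰_ij ~ NB(mean = μ_i, size = φ_i),
  gene-specific, shared across cells. The NB is the stationary law of
  bursty transcription and the standard count model in RNA-seq.

Two identities make the model practical:

* **Marginal.** The observed count is marginally NB(μ_i β_j, φ_i) —
  thinning an NB keeps it NB with a thinned mean.
* **Posterior.** x⁰_ij = x_ij + ζ_ij with the lost count
  ζ_ij ~ NB(mean = μ(1−β)(x+φ)/(μβ+φ), size = x+φ): a shifted NB. The
  posterior mean is [x(μ+φ) + μφ(1−β)]/(μβ+φ) and the variance
  (x+φ)·μ(1−β)(μ+φ)/(μβ+φ)². When φ → 0 the mean tends to x/β (global
  scaling is the small-dispersion limit of the posterior mean); when
  β = 1 the posterior is a point mass at x.

All pmf evaluations are done in log space through log-gamma functions; the
combinatorial derivation of the marginal is never used as a computation
path, so large counts cannot overflow. Posterior support is always ≥ x:
means, MAP counts and draws never fall below the observed count.

## Output modes

* `mean` — posterior mean, real-valued, left unrounded (rounding is the
  caller's choice; MAP exists for users who want integers).
* `map` — posterior mode. The lost-count NB mode sits at
  floor(q(r−1)/(1−q)) with q = m/(m+r); at exact integer crossings two
  adjacent counts tie and the smaller is returned — deterministic, and
  conservative for imputation. Implementation evaluates the log pmf at the
  candidate and its neighbours to be robust to floating error.
* `samples` — S posterior draws per entry (P × Q × S). ζ is drawn through
  the exact Gamma–Poisson mixture (Gamma(shape = size,
  scale = mean/size) → Poisson), valid for arbitrary real size. Each draw
  slice s uses a dedicated substream of the run seed, so requesting S = 3
  reproduces the first three slices of an S = 20 run bit for bit.

Point estimates deliberately discard posterior spread: a posterior-mean
matrix is the right input for mean-level analyses, but per-gene
variability statistics (CV, Gini) computed on it understate true
variability, increasingly so for low-expression genes whose posterior is
dominated by the prior. Distribution-level evaluation therefore always
uses the draw stack (see "Validation designs").

## Capture efficiencies

Relative cell scaling factors s_j are estimated as column totals
(optionally after removing the top `trim_fraction` of genes by overall
mean, default 0.05, so a few dominant transcripts cannot drive the
factors), or supplied by the user (covering spike-in- or
housekeeping-based estimates). They are calibrated to probabilities by
β_j = β̄ · s_j / mean(s), then clipped into [10⁻⁴, 0.95]: β ≥ 1 is
meaningless under a binomial capture model and β = 0 makes the posterior
improper for x > 0. Exact β = 1 is admitted as an explicit degenerate
case (full capture, identity recovery). Without clipping, mean(β) = β̄
exactly; calibration is scale-invariant and order-preserving in s.

β̄ — the fraction of an average cell's transcripts that are observed — is
a protocol property the user should supply; the default 0.06 is typical
droplet-protocol sensitivity. Misspecifying β̄ rescales all posteriors
coherently, which is why group comparisons are insensitive to a 2-fold β̄
error (measured in the validation suite: the null DE called fraction moves
by < 0.03 absolute).

Cells with zero total count are an error, never silently dropped: cell
filtering is an explicit upstream decision.

## Prior estimation

Because E[x_ij] = μ_i β_j, scaled counts x_ij/β_j are unbiased for μ_i;
their average over cells is the mean estimate. The scaled-count variance
equals the NB variance μ + μ²/φ plus a thinning inflation
μ · mean_j((1−β_j)/β_j); subtracting the inflation and inverting
φ = μ²/(var − μ) gives a method-of-moments dispersion. Genes whose
corrected variance does not exceed the mean are Poisson-like and clamp to
φ_max; dispersions are kept in [10⁻³, 10³], outside which the NB is
numerically degenerate or Poisson.

Raw per-gene dispersions are noisy, so they are shrunk toward an OLS
log–log trend of dispersion on mean fitted across genes:
log φ_final = w · log φ_fitted + (1−w) · log φ_raw with w = 0.5 by
default — an equal-information compromise, exposed as `shrink_weight`.
With fewer than 10 retained genes the trend is unidentifiable and raw
estimates are returned with a warning. The mean is not shrunk by default
(mean shrinkage across genes is uncommon and the unbiased estimator is
already well-behaved at typical Q); the weight is configurable for users
who want to experiment.

An optional refinement (`mle_refine`) replaces the moment estimates with
a per-gene Nelder–Mead maximization of the exact thinned-NB marginal
likelihood, initialized at the moment estimates; it never degrades the
likelihood but costs one optimization per gene.

All-zero genes are flagged, carried through recovery unchanged (output
zero), and excluded from shrinkage: imputing a gene never observed
anywhere is unidentifiable.

**Global vs local priors.** Global priors pool all cells; local priors are
estimated within each cell group (condition/batch), with β always
calibrated on the full dataset. Global priors make the two groups
exchangeable a priori and so suppress capture-bias false positives; local
priors let group differences enter the prior and raise DE sensitivity.
Which is appropriate is a design decision, not a tuning knob.

## Simulator

`simulate_dataset` draws gene means from log-normal(log-mean 1.0,
log-sd 1.5) and dispersions from log φ = 0.5 · log μ + N(0, 0.5) —
a realistic droplet-data mean–variance fan — then NB truth, then per-cell
β from a Gamma with mean β̄ and CV `beta_dispersion` (default 0.3; the
minimal positive family with a controllable spread), clipped to a valid
probability range and re-centred on β̄, then binomial thinning. An
optional two-group design multiplies the group-B means of a chosen number
of genes by 2^lfc, providing ground-truth DE labels.

What the simulator emulates: NB expression heterogeneity, cell-to-cell
capture variability, the dropout–mean relationship ((φ/(φ+m))^φ per gene,
approaching exp(−m) for large φ), and group mean shifts. What it does not:
gene–gene correlation (priors are independent per gene — the recovery
model shares this assumption and correspondingly underestimates gene–gene
correlations), batch structure beyond β differences, cell-cycle or
cell-size covariates, and amplification noise. Tests passing on this
simulator therefore demonstrate internal consistency of the model and
pipeline, not robustness to every failure mode of real data.

## Differential expression over posterior draws

The per-sample two-sample test is pluggable (default: Wilcoxon rank-sum,
asymptotic, two-sided; all-tied genes get p = 1). For each draw s,
gene-wise p-values are Benjamini–Hochberg adjusted across genes; each
gene's final score is the median of its S adjusted p-values, called at
< α. With S = 1 (or a 2-D point-estimate input) this reduces to plain
test + BH. Aggregating over draws propagates recovery uncertainty:
low-β entries get wide posteriors, their draws disagree, and the median
adjusted p stays large — which is what suppresses capture-bias false
positives.

## Validation designs

The test suite and `scripts/acceptance.py` recompute these end to end;
all sizes below are the defaults used there, chosen to make each design
statistically informative at desk scale.

* **Posterior exactness** — the closed-form shifted-NB posterior against
  a brute-force truncated Bayes sum (binomial likelihood × NB prior,
  normalized) on a 54-point (x, μ, φ, β) grid; numerical pmf moments
  against the closed-form mean/variance.
* **Marginal GOF** — 10⁵ draws of the NB→binomial hierarchy against
  NB(μβ, φ) by chi-square with tail pooling.
* **Parameter recovery** — P = 2000, Q = 1000, β̄ = 0.1; Pearson
  correlation of log μ̂ vs log μ and Spearman of φ̂ vs φ.
* **Capture-bias null** — two groups of 250 cells from identical priors,
  β̄ = 0.10 vs 0.05; global priors, S = 5 draws; any DE call is a false
  positive. The same test on raw counts shows the bias the recovery
  removes. Repeating with β̄ misspecified 2-fold both ways probes
  robustness.
* **Sensitivity** — 10% of 2000 genes shifted 2-fold, 200 cells per
  group, S = 5; AUC of the median adjusted p against ground truth, local
  vs global priors.
* **Distribution recovery** — P = Q = 500; per-gene CV and Gini computed
  per draw and averaged, compared as |log2 ratio| to the simulated truth,
  against x/β scaling.

## Numerical and edge-case choices

* NB pmfs via log-gamma; mean = 0 handled as an exact point mass at 0.
* Gini uses the mean-absolute-difference definition
  Σ_ij |v_i − v_j| / (2Q²·mean) with no Q/(Q−1) correction (variants
  differ by that factor); computed by the sorted-rank identity.
* CV uses the sample (Q−1) standard deviation; zero-mean genes yield NaN
  (flagged), not 0.
* Non-UMI data: counts are divided by a constant amplification factor
  (average reads per original molecule) with round-half-up before
  recovery; `amplification = 1` is the identity.
* Counts may be held sparse; recovery densifies, since imputing x = 0
  entries is the point.
* All randomness flows from one integer seed; simulation stages and draw
  slices use named substreams, so partial re-runs are reproducible.

## Known limitations

* Independent-gene priors: recovered gene–gene correlations are biased
  toward zero; the package does not attempt to correct this.
* The NB prior is unimodal; truly bimodal expression (e.g. on/off mixture
  across a heterogeneous population under a global prior) is smoothed.
* β estimation from totals inherits composition bias when a few genes
  dominate; the trimmed variant mitigates but does not remove it.
* MAP output of a heavily shrunk low-count gene can sit at the prior mode
  for many cells, understating variability — use draws for any
  distribution-level analysis.
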