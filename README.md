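# baynorm

Bayesian recovery, imputation and normalization of single-cell RNA-seq
counts.

scRNA-seq library preparation captures only a small fraction of each cell's
transcripts, and that fraction — the *capture efficiency* — varies from
cell to cell. The result is sparse count matrices full of dropouts (zeros
for genes that were expressed but not captured) and spurious cell-to-cell
variability. Scaling normalization divides each cell by a size factor, but
a zero divided by anything stays zero: scaling cannot impute.

This package treats recovery as Bayesian inference. For gene *i* in cell
*j*, the observed count x<sub>ij</sub> is a binomial draw from the cell's
original count x⁰<sub>ij</sub> with cell-specific capture probability
β<sub>j</sub>, and the original count carries a gene-specific negative
binomial prior estimated empirically across cells:

    x_ij | x⁰_ij ~ Binomial(x⁰_ij, β_j)
    x⁰_ij        ~ NB(mean = μ_i, size = φ_i)

The posterior of the original count is then a *shifted* negative binomial
in closed form: x⁰ = x + ζ with

    ζ ~ NB(mean = μ(1−β)(x+φ) / (μβ+φ), size = x+φ),

so posterior means, modes (MAP), probabilities and samples are all exact
and cheap — no numerical integration. Marginally the observed count is
NB(μβ, φ): binomial thinning keeps NB counts NB, which is also why the
bundled simulator (NB truth thinned binomially) reproduces the
mean–variance and dropout–mean statistics of real UMI data without any
zero-inflation component.

Outputs are a posterior-mean matrix (real-valued), a MAP matrix (integer),
or a genes × cells × S stack of posterior draws that propagates recovery
uncertainty into downstream tests. Priors can be estimated from all cells
("global", robust against capture-bias false positives) or within each
cell group ("local", sensitive for differential expression).

## Worked example

```python
import numpy as np
import baynorm as bn

# synthetic experiment: 300 genes x 400 cells, 10% mean capture efficiency
spec = bn.SimSpec(n_genes=300, n_cells=400, beta_bar=0.1, seed=42)
ds = bn.simulate_dataset(spec)
print("observed dropout fraction:", round(float((ds.observed.dense() == 0).mean()), 3))
print("true dropout fraction:    ", round(float((ds.truth.dense() == 0).mean()), 3))

cfg = bn.RunConfig(beta_bar=0.1, mode="mean", seed=42)
rc, ce, priors = bn.recover_counts(ds.observed, cfg, beta_method="total")

truth = np.log1p(ds.truth.dense()).ravel()
r_bay = np.corrcoef(np.log1p(rc.values).ravel(), truth)[0, 1]
r_scale = np.corrcoef(np.log1p(ds.observed.dense() / ce.beta).ravel(), truth)[0, 1]
print(f"corr(log1p recovered, log1p truth): {r_bay:.3f}")
print(f"corr(log1p x/beta,    log1p truth): {r_scale:.3f}")
```

prints

```
observed dropout fraction: 0.679
true dropout fraction:     0.28
corr(log1p recovered, log1p truth): 0.891
corr(log1p x/beta,    log1p truth): 0.761
```

Thinning at β̄ = 0.1 turns 28% true zeros into 68% observed zeros; the
posterior-mean recovery tracks the simulated truth markedly better than
dividing by capture efficiencies (which cannot touch the dropouts). A
single entry illustrates the imputation: with prior μ = 10, φ = 2 and
β = 0.1, an observed count of 1 has posterior mean
`bn.posterior_mean(1, 10, 2, 0.1) == 10.0` — the method infers that about
nine transcripts were lost.

## Command line

```sh
baynorm simulate  --genes 2000 --cells 1000 --beta-bar 0.1 --seed 1 --out sim/
baynorm normalize --counts sim/observed --format mtx --beta-bar 0.1 \
                  --mode samples --n-samples 5 --seed 1 --out norm/
baynorm evaluate  --truth sim/truth --recovered norm/sample_001.mtx --out report.tsv
baynorm de        --a normA/ --b normB/ --alpha 0.05 --out de.tsv
```

Counts are read as MatrixMarket MTX with `genes.tsv`/`barcodes.tsv`
sidecars or as dense TSV (header = cell IDs, first column = gene IDs). All
flags can live in a TOML file passed via `--config`; explicit flags win.

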