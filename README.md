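# tfnoise

Tools for studying how transcription-factor (TF) binding shapes
gene-expression noise — the cell-to-cell variability of expression,
quantified as the coefficient of variation CV = σ/μ.

The package covers an end-to-end pipeline for the question *"how well do
promoter and TF-binding features predict a gene's noise, and what binding
dynamics generate high noise?"*:

* **Noise statistics** (`tfnoise.noise`) — per-gene CV, a *mean-adjusted
  noise* statistic defined as the vertical distance of CV from a polynomial
  trend fitted to CV vs ln μ (order chosen by 10-fold cross-validation),
  and stratification into noise bins with open-ended extremes.
* **Promoter features** (`tfnoise.motifs`) — exact motif scanning with up
  to 2 mismatches on both strands (consensus/IUPAC/weight-matrix motifs),
  binding-site overlap statistics (competition), positional site counts in
  100-bp windows, nucleosome-occupancy window averages, and the tRNA
  adaptation index over codon prefixes.
* **Co-expression** (`tfnoise.coexpression`) — activator/repressor
  classification from significant gene–TF Pearson correlation, regulation
  strength as the OLS slope, and the ≥3-partner co-expressing-TF rule.
* **Regression protocol** (`tfnoise.regression`) — z-scored features,
  lasso/ridge selection plus bidirectional stepwise-AIC refinement, and
  repeated 80/20 splits reporting the *fraction of variation explained*
  (training R²) and *predicted R²* (1 − SSE/SST on the held-out split) as
  mean ± sd, for the model

  noise = β₀ + β₁·feature₁ + … + βₙ·featureₙ + ε.

* **Telegraph simulator** (`tfnoise.simulate`) — a stochastic two-state
  promoter (off→on at rate λ_on, on→off at λ_off; transcription at β_m
  while on; translation β_p; removal α_m, α_p) under four binding
  scenarios: a single TF, k independent TFs, k cooperative TFs (all must be
  bound) and k competitive TFs sharing one site (the bound TF is drawn at
  random and its strength multiplier scales β_m). Populations of cells are
  simulated and protein mean, CV and burst frequency reported; `match_mean`
  calibrates λ_off so scenarios are compared at equal means.
* **Parameter-space search** (`tfnoise.mcmc`) — a greedy accept/reject walk
  that drives the simulated mean into a target window, used to compare
  noise across binding scenarios over many sampled parameter sets (with a
  burst-frequency feasibility filter and Mann–Whitney tests).
* **Synthetic data** (`tfnoise.synthetic`) — generators for every input
  above with known ground truth: NB count matrices with a planted CV trend
  and excess noise, promoters with planted motif sites, feature tables with
  sparse planted effects, and co-expression panels with planted slopes.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Compare expression noise across binding scenarios at matched mean protein
levels (1000 cells, cooperative λ_off calibrated automatically):

```python
from tfnoise import SimParams, compare_scenarios

df = compare_scenarios(SimParams(n_cells=1000, total_time=40, seed=1),
                       k_tfs=2, matched=True, seed=1)
print(df[["scenario", "k_tfs", "mean_protein", "cv_protein",
          "burst_frequency"]].round(4).to_string(index=False))
```

```
   scenario  k_tfs  mean_protein  cv_protein  burst_frequency
     single      1     9912.9071      0.3995           0.4956
independent      2     9906.0975      0.2813           0.7466
cooperative      2    10197.8969      0.4327           0.5106
competitive      2     9997.4195      0.4644           0.5002
```

At the same mean (~10⁴ protein molecules), two *independent* TFs lower the
noise relative to a single TF (the gene is active more often, burst
frequency 0.75 vs 0.50), while *cooperative* and *competitive* binding both
raise it — the noise orderings that make TF-binding dynamics, not the mere
number of TFs, the driver of high noise.

Fit the noise-prediction protocol on synthetic features with a planted
sparse effect (population R² = 0.4 over 5 of 50 features):

```python
from tfnoise.synthetic import SyntheticFeatureSpec, gen_feature_table
from tfnoise.regression import NoiseRegression

spec = SyntheticFeatureSpec(n_genes=2000, n_features=50, seed=1,
                            orthogonalize=True)
spec.noise_sd = spec.noise_sd_for_r2(0.4)
X, y, beta = gen_feature_table(spec)
res = NoiseRegression(X, y).fit(select="lasso", stepwise=True,
                                n_repeats=100, seed=1)
print(res.summary())
```

```
Noise regression (repeated 80/20 splits)
  engine                 : linear
  n repeats              : 100
  selected features (9) : f000, f001, f002, f003, f004, f009, f012, f023, f027
  fraction of variation explained : 0.3910 ± 0.0091
  predicted R²           : 0.3811 ± 0.0365
```

The five planted features (f000–f004, coefficients ≈ 1) are recovered and
the explained fraction matches the planted R² up to sampling error; the
remaining small-coefficient features are stepwise-AIC stragglers with
negligible weight.

Everything is also reachable from the `tfnoise` CLI
(`synth`, `noise`, `scan`, `coexpr`, `regress`, `simulate`, `mcmc`), each
subcommand taking `--seed` and writing deterministic plain-text output; see
`tfnoise --help`.

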