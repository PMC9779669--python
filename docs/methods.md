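# Methods

This note documents the models and procedures implemented in `tfnoise`, the
parameters that matter, the design choices made where the underlying
protocol leaves them open, and what the synthetic-data tests do and do not
demonstrate.

## Expression noise and the mean-adjusted statistic

Noise of a gene is the coefficient of variation of its expression across
cells, CV = sd/mean, with the sample (n−1) standard deviation. CV falls
systematically with mean expression, so raw CV confounds noise with
abundance. The package removes this dependence by fitting a polynomial of
CV on ln(mean) and defining the *mean-adjusted noise* of a gene as the
vertical distance of its CV from the fitted curve. By least-squares
construction the adjusted values sum to zero over the fitting set and are
uncorrelated with ln(mean).

**Order selection.** Candidate polynomial orders (default 1–7) are scored by
10-fold cross-validated mean squared error. The selected order is the
smallest whose CV-MSE lies within one standard error of the minimum. The
plain argmin is a near coin-flip among the true order and higher orders at
large n (all fit the signal; the differences are CV noise), whereas the
one-SE parsimony rule makes the choice stable; per-order scores are kept in
the results object for audit. A 95% pointwise confidence band of the fit is
available (ordinary-least-squares theory on the polynomial design).

**Binning.** Genes are stratified into `n_bins` (default 20) noise bins.
The n_bins−1 interior edges are equally spaced over the central
[2.5th, 97.5th]-percentile range of the noise values; the first and last
bins are open-ended so extreme genes are retained without creating
near-empty interior bins. The percentile range is configurable.

**DM convenience.** `running_median_dm` computes a vertical distance from a
running median of CV vs mean (window fraction 0.1). It mimics the shape of
the classic distance-to-median protein-noise measure but is *not* the
published procedure; externally computed DM values should be supplied as a
response column when available.

**Open choice.** CV is regressed untransformed on ln(mean) (log of the mean
only). The alternative of log-CV can be emulated by passing log-transformed
CV values to `NoiseTrendModel`; nothing in the package assumes which is
"correct".

## Synthetic data generators

Each generator is a pure function of a spec dataclass and a seed
(bit-reproducible) and returns ground truth alongside the data.

* **Expression matrices** are negative-binomial counts. Per gene the mean is
  log-uniform over `mean_range` (default 5–1000 counts, matched to the trend
  definition range) and the target CV is trend(ln mean) + planted excess.
  The NB dispersion r solves CV² = 1/mean + 1/r, so the target CV is exact
  in expectation; genes whose target falls below the Poisson floor 1/√mean
  are clipped to (near-)Poisson and flagged. The default trend is a
  degree-5 polynomial specified in the Legendre basis on the scaled
  ln-mean interval with coefficients (1.2, −0.40, 0.15, 0.20, −0.25, 0.30):
  a decaying, yeast-scRNA-like mean–CV relationship in which every order up
  to 5 carries substantial orthogonal variance, so the trend order is
  genuinely identifiable from 5000 genes. Default planted excess noise is
  N(0, 0.12²), small against the trend (≈0.9–1.5) but large against CV
  sampling error at 300 cells.
  *Not emulated:* read-level artifacts (capture efficiency, dropout beyond
  NB sampling, doublets), normalization effects, cell-cycle structure. A
  passing recovery test shows the statistic recovers planted structure
  under NB sampling — not that real scRNA-seq noise is NB.

* **Promoters** are i.i.d. background at a given GC fraction (default 0.38,
  yeast-like intergenic) of length 1010 bp, representing −1000..+10 around
  the start codon; planted motif instances (consensus mutated at exactly
  the requested number of positions; minus-strand instances
  reverse-complemented) overwrite the background. Overlapping planted sites
  are allowed; on conflicting bases the later site wins. No higher-order
  background composition is modelled.

* **Feature tables** are equicorrelated (optionally QR-orthogonalised)
  standard-normal features with a sparse linear effect,
  y = Xβ + N(0, σ²); the spec computes the implied population R² and the σ
  achieving a requested R² in closed form.

* **Co-expression panels** plant gene–TF slopes and TF–TF correlation
  blocks (common-factor construction) over i.i.d. normal condition effects.

## Promoter features

**Scanning.** Motifs are represented as per-position allowed-base sets,
built from exact/IUPAC consensi or from weight matrices (a base is allowed
when its weight is nonzero, or above a configurable fraction of the column
maximum; expansion is capped at 10⁶ variants). Because such variant sets
are products over positions, the minimal Hamming distance of a window to
*any* variant equals the number of positions holding a disallowed base, so
the scan is exact without enumeration. Default mismatch tolerance is 2.
Both strands are scanned (TFs bind double-stranded DNA); a double hit on
the same interval is reported once with the minimal distance, preferring
the forward call on ties. Non-ACGT characters mismatch every base, with a
warning.

**Overlaps.** Two sites overlap when their intervals share ≥1 bp,
strand-agnostic; same-TF pairs count unless excluded by flag. Reported:
pair count, pairs per site, fraction of sites in ≥1 overlap, mean overlap
length, per-window pair counts (a pair belongs to the window containing its
overlap midpoint), and activator/repressor pair-category fractions given a
role map.

**Positional counts** attribute each site by its start to 100-bp upstream
bands plus the −0..+10 tail; **occupancy windows** average a track over the
twelve promoter windows (100-bp bands from −1000 to −200, 50-bp bands to
−50, then −50..+10). "Occupied" positions are those above a configurable
threshold; at the default 0 the average is a plain mean over covered
positions — what counts as occupied in the original averaging is not fully
specified, so the threshold is an explicit stand-in.

**tAI** is the geometric mean of codon adaptiveness weights over prefixes
of 5, 10, 15, 20, 25, 30, 40, 50 codons and the full gene; internal stop
codons are excluded with a warning, and prefixes longer than the gene fall
back to the full-gene value with a flag.

## Co-expression

Pearson correlation with two-sided p-values; a significant (p < 0.05)
positive/negative gene–TF correlation classifies the TF as
activator/repressor, and the OLS slope of gene on TF is the regulation
strength (reported only when significant). A TF co-expresses when it has
≥3 significant same-sign partners among the gene's TFs. Raw p-values are
the default (matching the protocol); Benjamini–Hochberg is available by
flag. Linear-scale expression is used for slopes; a log1p flag exists.

## Regression protocol

Features are z-score standardized (training statistics reapplied to test
splits). Selection: lasso at the 10-fold-CV penalty — `rule="min"`
(CV-minimum, the default) or `rule="1se"` (sparsest within one SE; the
standard choice when support recovery rather than prediction is the goal,
since the CV-minimum penalty provably admits spurious predictors) — or
ridge with coefficient t-tests on the ridge fit's effective degrees of
freedom (an approximation; the lasso path is the default). Stepwise
bidirectional AIC search then refines the candidate set; the search runs
from both the empty and the full model and returns the better endpoint, so
the result is never worse than the full candidate model and ties are broken
by feature name (deterministic).

Scoring is over `n_repeats` (default 1000) random 80/20 splits:
*fraction of variation explained* = training R², and
*predicted R²* = 1 − SSE/SST on the held-out split with SST taken around
the held-out mean. Predicted R² can be negative; the squared-correlation
alternative would differ and is not used. Missing values: complete-case for
the linear engine, optional median imputation for the random-forest engine.
A master seed drives all splits, making reports bit-reproducible.

## Telegraph simulator

The promoter is a two-state process: off-durations ~ Exp(λ_on),
on-durations ~ Exp(λ_off), giving stationary active fraction
λ_on/(λ_on+λ_off). (The rate-to-duration convention is ambiguous in the
usual notation; a flag swaps it.) While active, transcription runs at
β_m and expression follows the forward-Euler updates

    mRNA += (β_m_eff − α_m·mRNA)·Δt,  P += (β_p·mRNA − α_p·P)·Δt,

whose fixed points are the deterministic steady states β_m/α_m and
β_m β_p/(α_m α_p). Defaults: λ_on = λ_off = 1, β_m = 100, β_p = 100,
α_m = 1, α_p = 0.5 (rates per arbitrary time unit), Δt = 0.05, horizon 30
time units, 10 000 cells. Δt·α > 1 raises an instability error.

Scenarios: *independent* k TFs each carry their own telegraph process at
the single-TF rates with per-TF transcription rate β_m/k (rate sums over
bound TFs, so the mean transcription rate matches the single-TF case);
*cooperative* requires all k simultaneously bound (all-or-none activation
regardless of any Hill exponent), each TF binding at the single-TF rates —
burst frequency therefore falls ≈ geometrically with k and `match_mean`
restores the mean by bisection on λ_off (mean is monotone in λ_off);
*competitive* TFs share one site: a single telegraph process whose combined
binding rate equals the single-TF rate, with the bound TF drawn uniformly
at each activation and its strength multiplier scaling β_m for that
on-interval. Default multipliers are evenly spaced around 1 with half-range
0.3 — (1.3, 0.7) at k = 2 — and "no variation in strength" is all-ones,
which makes the competitive process distributionally identical to the
single-TF process (a null check used in the tests).

**Numerics.** Binding events are realized at their exact exponential times;
the Euler integrator uses the promoter state prevailing at the start of
each Δt step. This keeps every scenario (including k-TF intersection
states) exact and fully vectorized across cells; the induced bias is
O(Δt·λ) and far below the Monte-Carlo error at the defaults. Statistics
pool protein values across cells and retained time points after a burn-in
of max(5/α_m, 5/α_p) (initial-condition transients decay to < e⁻⁵).
Burst frequency is the retained-time active fraction averaged over cells.
Monte-Carlo standard errors for CV comparisons come from splitting cells
into 10 disjoint groups. A per-cell trajectory view (`simulate_state` +
`integrate_expression`) exposes the bound/active/rate/mRNA/protein series.

An exact integer-copy-number Gillespie engine (`run_population_ssa`,
single-TF only) serves as a validation cross-check: it reproduces the
default engine's mean and burst frequency, while its CV additionally
carries intrinsic birth-death shot noise — which the concentration-update
equations deliberately omit, isolating promoter-switching noise.

## Greedy parameter-space search ("MCMC")

Despite the name this is a hill-climbing accept/reject walk, not a
likelihood-targeting sampler; no detailed balance is claimed. A chain
starts from parameters drawn log-uniformly within bounds, rejection-sampled
until the simulated mean is within 5× of the target (ratio in [1/5, 5]).
Each iteration perturbs one parameter multiplicatively by 10%; a move is
accepted iff the simulated mean gets strictly closer to the target (the
window midpoint), in which case the same parameter and direction are
retried. On rejection the move is reverted; if the rejected move landed
beyond 2× the target window the parameter to perturb is re-drawn, otherwise
the same parameter is retried in the flipped direction (the mild-reject
case is unspecified in the original description; this is the package's
choice). A move that would cross a bound is rejected without evaluation.
Chains stop when the mean enters the target window or after 50 iterations;
terminal runs are *feasible* only if burst frequency lies in (0.2, 0.8) —
outside that the gene is effectively always-off/always-on.

Canonical target windows are 1.0–1.1, …, 1.4–1.5 ×10⁶ protein molecules,
reached at canonical rates λ_on = λ_off = 1, β_m = 100, β_p = 10⁴,
α_m = 1, α_p = 0.5. **Bounds** default to ±0.3 decades (≈2× either way)
around the canonical values. This is a deliberate design choice: the
comparison across binding scenarios is meant to be mathematically
controlled — identical parameter regime, only the binding process varying.
With decade-wide bounds the between-replicate spread of terminal CVs is
dominated by where in parameter space each chain lands, drowning the
binding-process effect at any feasible replicate count; the ±0.3-decade
default keeps replicates in comparable burst regimes (consistent with the
burst-frequency feasibility window) so the scenario contrast is the signal.
Wider exploration is available via `default_bounds(decades=...)`.

`compare_noise` runs replicate chains per scenario (default 200 at 1000
cells per evaluation; the package's desk-scale default — the original
protocol's 10 000 replicates are supported by configuration), keeps
converged + feasible terminals, and reports median terminal CVs and
two-sided Mann–Whitney tests per scenario pair.

## Problem sizes used by tests and the acceptance script

Simulation checks use 1000 cells (5 for deterministic limits, 800–1500 for
orderings), horizons of 30–40 time units, and 200 replicates × 200 cells
for the parameter-search comparison in the first target window; the noise
statistic uses 5000 genes × 300 cells; the regression protocol 2000 genes ×
100 features with 100 repeats. These sizes put every Monte-Carlo check
several standard errors clear of its threshold while keeping a full run in
a few minutes.

## Known limitations

* The NB generator is a stand-in for real scRNA-seq noise structure, not a
  claim about it; recovery tests validate the statistics, not the biology.
* Ridge "significance" uses an effective-degrees-of-freedom approximation.
* The occupancy "per occupied site" averaging threshold is a configurable
  stand-in for an under-specified definition.
* The competitive scenario models one shared site; spatial arrangements,
  partial overlap geometries, TF diffusion and nucleosome dynamics are out
  of scope.
* Scenario comparisons are reproduced as orderings with Monte-Carlo error
  bars, not as point values: the original figures' exact rate settings are
  not published.
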