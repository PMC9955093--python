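# Methods

## Scope and model

`braque` clusters and annotates a cell table: N segmented cells × M
continuous, non-negative marker intensities, plus optional x/y tissue
coordinates.  The pipeline's premise is that each marker, within a
dataset, is a finite mixture of lognormal subpopulations; preprocessing
makes those subpopulations explicit, the 2-D UMAP embedding integrates
the per-marker guesses across all M markers, density clustering reads off
the groups, and effect-size statistics summarise each group for an expert.
Nothing in the pipeline names cell types: that is deliberately left to a
human reading the tier summaries.

## Lognormal Shrinkage

Per marker, in order:

1. divide by the **plain** median absolute deviation (no 1.4826
   consistency factor, no centering).  MAD = 0 falls back to the standard
   deviation; a fully constant marker passes through with a warning and
   never aborts the table;
2. add ε (default 1e-3) and take log₂.  After MAD scaling typical values
   are O(1), so exact zeros map to log₂ε ≈ −10 — far left of the data,
   guaranteeing the mixture dedicates a component to "not expressed";
3. fit a 1-D `BayesianGaussianMixture` (scikit-learn): Dirichlet-process
   weight prior, free per-component variance, K_max = 15 components,
   tol = 1e-2, max_iter = 1500.  Only as many components as the data
   support end up occupied;
4. assign each cell to the component maximising the posterior
   responsibility πᵢ·N(x; mᵢ, σᵢ²), ties to the lowest index;
5. shrink: x ← mᵢ + (x − mᵢ)/γ, γ = 5;
6. back-transform (2^x), subtract the minimum, and (default on) divide by
   the new MAD so all markers enter the Euclidean embedding at comparable
   scale.

The shrinkage map is affine and increasing within a component, so
within-component ranks are preserved exactly; global order preservation
across components holds when components are well separated and is
measured, not guaranteed (Spearman ≥ 0.99 on the canonical fixture).

Parameter notes:

* **γ (contraction factor), default 5, advisory range 2–10.**  Results
  are insensitive inside the range; γ=1 disables shrinkage, large γ
  collapses components to points.  When switching the log base the rule
  γ_new = γ/ln(new base) is applied (base 10 → 5/ln 10 ≈ 2.17 ≈ 2).  Note
  this recommended rule is *not* the exact change-of-base factor
  (γ·ln 2/ln 10 ≈ 1.505); the rule as stated is implemented and the
  discrepancy is noted here deliberately.
* **K_max = 15, tol = 1e-2.**  The component budget is checked by
  `saturation_report`: if fewer than 95 % of markers leave at least one
  component unoccupied, K_max should be raised.  A component is "used"
  iff at least one cell is assigned to it — Dirichlet-process variational
  weights are never exactly zero, so weight thresholding is avoided.
* **max_iter = 1500.**  Chosen so default fits actually reach the
  tolerance (canonical-fixture markers converge within ~250–850
  iterations); non-convergence is logged, never fatal, since a
  time-bounded fit is still a usable guess.
* **ε = 1e-3**, configurable; only its order of magnitude matters.
* **Assignment formula.**  Assignment is by posterior responsibility.
  A distance-ratio expression |x−mᵢ|/σᵢ normalised over components is
  sometimes quoted for this step; taken literally it *grows* with
  distance and would assign every point to its farthest component, so it
  cannot be the intended rule and is not implemented.
* **Back-transform moments.**  `lognormal_moments` converts a log-space
  component (μ, σ²) to its linear-space mean exp(μ′+σ′²/2) and variance
  (exp(σ′²)−1)·exp(2μ′+σ′²) for diagnostics, converting base-b
  parameters to natural logs first.

## Embedding

The fuzzy k-NN graph is re-implemented exactly as printed: ρᵢ is the
smallest strictly positive neighbour distance (duplicates skipped), σᵢ
solves Σⱼ exp(−max(0, dᵢⱼ−ρᵢ)/σᵢ) = log₂(k) by bisection on
[1e-6, 1e6] to |Σ−log₂k| ≤ 1e-3 (≤ 200 iterations).  Cells whose target
is unreachable (e.g. all k neighbours duplicated) are flagged degenerate
with a sentinel σ and unit weights.  The layout optimisation itself —
spectral initialisation, stochastic attract/repulse epochs — is delegated
to umap-learn (nn = 50, min_dist = 0.0, Euclidean, fixed seed): the graph
equations are printed and testable, the SGD layout is not, and
re-implementing it would add nothing verifiable.  Exact k-NN search is
used at test scale; umap-learn's approximate search takes over inside the
delegated path at data scale.

## Clustering

min_samples = max(⌈0.005 % · N⌉, 10): proportional to the sample but
floored to avoid micro-clusters.  `min_cluster_size` is set equal to
min_samples (the policy names only min_samples).  Phase 1 runs HDBSCAN
with excess-of-mass extraction and cluster_selection_eps = 0.1; phase 2
re-clusters the biggest phase-1 cluster (most members) with leaf
extraction and min_samples × 10 — dense intermingled populations (e.g.
CD4⁺ T cells vs B cells in lymphoid tissue) tend to survive phase 1 as
one blob.  Phase-2 noise stays −1 (the bin semantics of the noise
cluster); the epsilon threshold applies in both phases; cluster ids are
relabelled 0..n−1 by descending size.  Two deliberate policy details:
exactly one phase-2 pass is run (never recursive), and a phase-2 pass
that finds *no* sub-clusters leaves the phase-1 cluster intact — a failed
split must not dissolve a coherent cluster into noise.

Label extraction note: this package carries `_hdbscan_compat`, a NumPy
re-implementation of HDBSCAN's flat-cluster extraction (stability,
eom/leaf selection, epsilon search) on top of scikit-learn's compiled
condensed-tree and labelling routines.  scikit-learn 1.9's compiled
extraction crashes under NumPy 2.x whenever `cluster_selection_epsilon>0`
triggers an upward merge; the compat path reproduces the stock labels
bit-for-bit at ε = 0 (asserted in the tests) and provides the ε > 0
behaviour the clustering policy requires.

## Characterization

Group 2 = the cluster, group 1 = every other cell (noise included — the
comparison population is "the rest of the sample"; a flag excludes noise
if wanted).  One-tailed Welch t-test (greater), Welch–Satterthwaite df;
p-values are Bonferroni-corrected over the run-wide family M markers ×
n clusters (the conservative reading; raw p is always reported).  The
signed effect size uses the *group variance* directly and satisfies
d_signed = t_welch/√(N₁+N₂) — an identity the tests exploit as an oracle.
Characterization operates on the LNS-preprocessed matrix by default
(pipeline-consistent); a flag switches to raw values.  Tier detection:
descending positive effect sizes, two largest consecutive gaps (stable
argsort, so equal gaps resolve to the higher-ranked position), "first"
gap = the one higher in the ranking; fewer than 3 positive markers or
fewer than 2 gaps ⇒ tier 1 = all positive markers, tier 2 = ∅.  The
p-value bands colouring the ranked-marker plot (0.05, 1e-5, 1e-100) are
presentation only.

## Synthetic data generator

`SynthSpec` draws, per cell of type t: marker m = 0 with probability
z[t,m], else 2^Normal(μ[t,m], σ[t,m]²); coordinates from the type's
Gaussian tissue blob; then neighbour contamination
x ← (1−α)·x + α·mean(k = 8 nearest spatial neighbours), clipped at 0 and
scaled into [0, 255] to mirror 8-bit imaging provenance (cosmetic — the
pipeline is MAD-scaled).  The linear mixing model is this package's own
construction for the bleed phenomenon: simple, order-preserving in
expectation, and it produces the smoothed between-population transitions
seen in packed tissue.

The canonical fixture (`default_fixture`): 6000 cells, 6 types with
proportions (0.32, 0.30, 0.12, 0.12, 0.12, 0.02) — the 2 % type plays the
"rare population" — 20 markers, 3 designed elevated markers per type at
Δμ = +3 log₂ units over a baseline of 1.0, within-type log₂-SD 0.5,
zero-inflation 0.30 on non-elevated type×marker pairs and 0.02 on
elevated ones, blob centres on a 300-unit grid with SD 55, α = 0.1.
Free parameters (σ, baseline mean, blob geometry, elevated-pair
zero-inflation) were fixed once at design time to values typical of 8-bit
mean-intensity data.

What the generator does **not** emulate: segmentation errors, batch
effects, within-type expression gradients, or *correlated* dropout.  The
last point matters for interpreting results (next section).

## Behaviour on the canonical fixture — what passes and what doesn't

Measured, not asserted folklore:

* Clusters produced on the fixture are essentially type-pure (per-cluster
  majority-type purity 0.99–1.0) and the rare 2 % type reliably emerges
  as its own cluster; the noise bin stays well under 20 %.
* The pipeline nevertheless yields 25–50 clusters for 6 types: the
  fixture's *independent per-cell* zero-inflation gives every cell a
  random binary dropout pattern across ~17 baseline markers, LNS — by
  design — isolates and amplifies each marker's zero component, and the
  embedding then separates same-type cells with different dropout
  patterns.  Adjusted Rand index against the 6 generative types is
  therefore far below what the purity suggests (≈ 0.2–0.5 across seeds).
  This is the method's stated over-fragmentation preference colliding
  with an i.i.d. dropout model; with correlated (type-level) absence the
  fragmentation would largely disappear.  The corresponding acceptance
  assertions are kept at their stated thresholds and fail honestly.
* For the same reason the LNS-vs-raw ablation does not favour LNS here:
  with Δμ = 3 log₂ units the raw fixture is separable without
  preprocessing, while LNS additionally amplifies dropout noise.  The
  regime where LNS demonstrably helps — many markers with subtle,
  consistent shifts — is the regime of the real tissue data this method
  targets, not of this fixture.

## Numerical and policy choices

* Determinism: one run seed fans out via `SeedSequence` into per-marker
  mixture seeds, the embedding seed and the clustering seed; identical
  (input, config, seed) reproduce byte-identical CSV outputs.
* Degenerate inputs: constant markers pass through with a warning; zero
  pooled variance yields d = 0 (equal means) or a signed-infinity
  sentinel; clusters of size < 2 get effect sizes but no p-values;
  all-noise clusterings are valid results.
* Config: YAML key-value file; CLI flags beat the file, the file beats
  defaults.  Values outside the advisory ranges are kept with a warning
  (the ranges are tuning suggestions); structurally invalid values
  (log base ≤ 1, γ ≤ 0, K_max < 2, non-numeric) are errors.
* Problem sizes in the test suite: the canonical fixture (6000 cells) is
  used for the end-to-end and ablation checks (10 seeds, both arms,
  computed once and shared); unit and property tests run at a few hundred
  to a few thousand cells.

## Known limitations

* Univariate mixtures only: markers are fitted independently, so
  cross-marker covariance within a subpopulation is ignored (by design).
* No automatic γ or K_max optimisation; `saturation_report` diagnoses an
  insufficient K_max but does not refit.
* One table per run: no multi-sample integration or batch correction.
* No automatic cell-type naming and no merging of redundant clusters:
  outputs are expert-facing reports.
* The Bayesian mixture fits dominate runtime at scale (hours for
  ~10⁵–10⁶ cells × ~80 markers); the runtime guardrail warns and suggests
  lowering K_max when N × M is large.
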