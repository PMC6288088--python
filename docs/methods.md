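# Methods

## Model and estimator

Counts are treated as compositional: sample j's reads are a multinomial
draw of size N_j from latent fractions, and the fractions are the closure
of latent absolute ("basis") abundances. The object of inference is the
correlation matrix ρ of the *log basis abundances*. The estimator works on
the log-ratio variation matrix

    t_ij = Var_s[ ln(f_is / f_js) ],

which is closure-invariant (the normalizer cancels inside the ratio) and
satisfies t_ij = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j with ω_i² the basis
log-variance of taxon i. Assuming most ρ_ij ≈ 0 ("sparsity"), summing over
the active partners of each taxon gives the linear system

    Σ_{j : (i,j) active} t_ij = m_i ω_i² + Σ_{j partners} ω_j² ,

with m_i the number of active partners. The K×K system is solved directly
(least squares on rank deficiency); negative variance solutions — possible
in a least-squares solve — are floored at 1e-10 and flagged instead of
raising, so one degenerate posterior draw cannot abort a 100-draw run.
ρ is then (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j), clipped to [−1, 1]. At least 4
taxa are required for identifiability.

Count uncertainty is propagated by a Bayesian resampling step: per sample,
posterior fractions are Dirichlet(counts + α) with uniform prior α = 1
(configurable). Each of n_draws = 100 posterior fraction matrices runs
through the full variation-matrix → refinement → solve chain, and the
per-draw correlation matrices are combined element-wise by mean (median
available). The combiner choice matters little at typical depths (the
Dirichlet scatter is small relative to cross-sample variance); the mean is
the default because it keeps the aggregation linear.

## Iterative covariance exclusion

Strongly associated pairs violate the sparsity assumption and bias the ω²
solve. They are removed iteratively: fit, rank active pairs by the signed
basis covariance c_ij = ρ_ij ω_i ω_j (ties broken by lexicographic index
pair, so runs are exactly reproducible), exclude the top `batch` positive
and top `batch` negative pairs with batch = ceil(0.025% of active pairs,
min 1), refit. Excluded pairs leave the least-squares system only; their ρ
is still reported from the final variances. A ranking by |c| alone is
available as a config switch (`ranking="absolute"`). The batch fraction is
applied to the pairs still active at each iteration.

**Stopping rule.** The trace statistic is C_k = Σ|c_ij| over active pairs.
The loop should stop once C "no longer decreases significantly over the
last 10 iterations". A subtlety makes a naive tolerance unusable: every
exclusion removes that pair's |c| from C *mechanically*, so over a
10-iteration window C always drops by at least roughly the fraction of
pairs removed (empirically 4–8% on null data — orders of magnitude above
any small fixed tolerance, which therefore never fires and would push
every run to the active-pair floor). The default rule instead compares the
windowed relative decrease of C with the windowed fraction of active pairs
removed — the decrease expected if the excluded pairs carried merely
average weight — and stops when the ratio falls below `excess_factor`
(default 3). Empirically this ratio starts at 3.5–5+ while genuinely
extreme pairs are being removed and settles at ~2.5 once the tails are
exhausted, so the rule stops exactly when exclusions stop hitting
covariance outliers. A literal fixed-tolerance rule
(`stop_rule="fixed"`, rel_tol = 1e-3) is kept for comparison. Hard
guards: `max_iter` (500) and an active-pair floor of 3(K−1) below which
the system approaches underdetermination.

## Permutation significance

The null of "no cross-taxon structure" is simulated by independently
permuting every taxon's counts across samples, which preserves each
taxon's marginal count distribution and the per-sample depth scale.
Permuted tables are re-estimated with a single posterior draw and no
refinement (a fidelity/runtime trade; `full_pipeline=True` reruns
everything per permutation). Two-sided pseudo-p with add-one correction:
p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm), bounded below by
1/(n_perm+1); n_perm defaults to 100. No multiple-testing correction is
applied by default — network edge selection deliberately mirrors a raw
per-pair p < 0.05 rule — but a Benjamini–Hochberg switch exists on the
network config.

## TINA similarity and ordination

The taxon association-similarity matrix correlates row i and row j of ρ
(each taxon's profile of associations to all taxa, diagonal included;
excluding the i, j entries is a flag) and rescales by s = (1 + r)/2 so the
index's quadratic forms stay positive. Zero-variance profiles carry no
information: their similarities are set to 0.5 and the taxon flagged.
The weighted TINA index is the S-weighted cosine
p_aᵀS p_b / √((p_aᵀS p_a)(p_bᵀS p_b)); it is exactly 1 for identical
compositions, reduces to cosine similarity for S = I, and is sample-depth
invariant. TINA is computed from the *refined* correlation matrix by
default (switchable by passing any matrix).

Ordination embeds d = 1 − TINA (√(1−TINA) available; the transform choice
is an open design point, and 1−s is the simplest monotone option) by
SMACOF: Guttman-transform majorization, which guarantees a non-increasing
raw-stress sequence within each run; the best of `n_init` random starts is
kept. Full-fidelity settings are 200 restarts, 20,000 iterations,
ε = 1e-8; tests and the analysis scripts use 8–32 restarts and shorter
iteration caps, which suffice at n = 34 samples. Embeddings are identified
only up to rotation/reflection, so all comparisons use distances, never
raw coordinates. Group separability is decided exactly by an LP
feasibility problem (exists (w, b) with y_i(w·x_i + b) ≥ 1), avoiding
iterative classifiers.

## Diversity indices

Chao1: S_obs + f1²/(2 f2), with the bias-corrected
S_obs + f1(f1−1)/(2(f2+1)) when f2 = 0. "Nonparametric Shannon" is the
Chao–Shen coverage-adjusted Horvitz–Thompson estimator with coverage
Ĉ = 1 − f1/n, which is the standard meaning of the phrase in the SpadeR
tradition; the plug-in entropy is exposed alongside. All entropies are in
nats, so the effective number of OTUs is exactly exp(H) — the identity the
per-sample table verifies. The estimator is undefined when every read is a
singleton (Ĉ = 0); that case raises. Diversity is computed on the
*unfiltered* table: the abundance filter is a preprocessing step for
correlation and similarity analyses only.

## Abundance filter

"Abundance higher than 0.1%" is read as *mean relative abundance across
all samples strictly greater than 0.001* — one global filter yielding one
global taxon list; a per-sample-maximum variant is exposed
(`mode="max"`). The boundary is exclusive. Filtering is idempotent and
never changes the sample set.

## Synthetic communities

Per sample: z ~ N(μ_g, D ρ D) on the log scale (D = diag of per-taxon
log-sd, drawn once per truth from U(√0.5, √1.5)); fractions by softmax;
depth uniform on 10,000–122,000; counts multinomial. This is exactly the
data-generating model under which the basis estimator is consistent, and
the softmax closure reproduces the compositional artefacts the estimator
must remove. Planted structure: requested pairs set to ±strength
(taxon-disjoint whenever possible, which keeps the matrix PSD without
projection; otherwise eigenvalue clipping at 1e-8 with diagonal
re-normalization, and an error if a planted entry moves by more than 0.2).

Presets:

* **Recovery preset** — K = 50, one group, n = 200 samples, five planted
  pairs at ρ = 0.8: the estimator benchmark.
* **Study preset** — K = 100; 27 "ciliate" + 7 "gut" samples. Taxa 0–4 are
  ciliate-associated, 5–9 gut-associated; each block is up-shifted by 4
  log units in its home group so it dominates that group's composition
  (jointly ~0.5–0.8 of reads), matching the dominance contrast between
  the two community types this design emulates. The basis correlation
  carries +0.7 within each block and −0.7 across blocks (smallest
  eigenvalue 0.3, PSD by construction). Baseline log-means are N(0, 1).

What the generator does *not* emulate: taxonomic misassignment, chimeras,
depth-dependent extraction bias, overdispersion beyond multinomial, and
phylogenetic correlation of abundances. Passing recovery tests therefore
demonstrates correctness of the inferential chain under its own model
assumptions, not robustness to those real-data complications.

Two measured properties of the generator worth knowing: (i) the softmax
normalizer induces a small positive correlation between log-fractions of
independent taxa (up to ~0.2–0.3 at K = 20, shrinking with K), so
log-fraction correlations of independent taxa are bounded by a
closure/noise floor rather than by pure sampling noise; (ii) at n = 200
samples the basis-correlation estimator's null-pair noise is sd ≈ 0.065,
so the maximum over ~1200 null pairs concentrates near 0.23–0.25 —
reducing it materially requires more samples (n ≈ 500 brings the maximum
under 0.2), not more posterior draws, because draw-averaging cannot remove
cross-sample sampling noise.

## Numerical and interface choices

* All randomness flows from integer seeds through `numpy` `SeedSequence`
  substreams (per posterior draw, per stage in the pipeline); identical
  configs reproduce every artifact bit-exactly, which the pipeline
  manifest verifies by SHA-256.
* Matrices are kept aligned by preserving input taxon/sample order
  everywhere; nothing is silently re-sorted.
* Network thresholds are strict inequalities on both |ρ| and p. Group
  abundance ratios use a symmetric pseudocount (1e-6) so group-absent taxa
  stay finite; log2 ratios are stored alongside for colour mapping.
* Problem sizes in tests and analysis scripts (e.g. 5–100 posterior draws,
  8–32 MDS restarts, K = 40–100) are scaled-down defaults chosen to keep
  the full suite fast while leaving every statistical conclusion
  unchanged; full-fidelity settings (100 draws, 200 restarts, 20,000
  iterations) remain the library/CLI defaults.

## Known limitations

* The sparsity solve is biased when a large fraction of pairs is truly
  correlated; the exclusion loop mitigates but cannot repair dense
  dependence.
* Permutation nulls use the reduced (single-draw, unrefined) estimator;
  p-values are slightly conservative for the refined observed estimate.
* The refinement stopping constant (excess factor 3) is an empirical
  choice validated on this package's generative model; other data regimes
  may warrant retuning.
* Chao1 and Chao–Shen variants follow the classical formulas; tool-specific
  variants of either estimator can differ in small samples.
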