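# Methods

This note records the models implemented in `multifuse`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Sparse CCA by penalized matrix decomposition

For standardized, row-aligned views X (n×p) and Z (n×q) the solver
maximizes `uᵀXᵀZv` subject to `‖u‖₂ ≤ 1, ‖u‖₁ ≤ c₁` (and likewise for v).
The inner step — maximize `wᵀa` under joint L2/L1 constraints — has the
closed form `w = S(a, Δ)/‖S(a, Δ)‖₂` with `S` the soft-threshold operator
and Δ the smallest value making the L1 constraint feasible, located by
bisection to 1e-10. Alternating these updates from the leading right
singular vector of `M = XᵀZ` converges to a fixed point; components 2…K
come from deflating `M ← M − (uᵀMv)·uvᵀ`.

Covariance treatment. The default treats within-view covariances as
identity — the classical penalized-matrix-decomposition simplification
that keeps the L1 constraint acting on the original features and is the
standard practice for n ≪ p data. This maximizes cross-covariance, not
correlation, so with non-binding bounds it does **not** reduce to
classical CCA (we measured first-correlation gaps of ~0.03 on random
30×4/30×3 instances). A `whiten=True` mode whitens each view by
`(XᵀX)^{-1/2}` first; with non-binding bounds this is exactly the
generalized-eigenvalue CCA solution (verified to 1e-6 in the tests and
the acceptance script) and is the bridge used for oracle checks. Whitening
requires full column rank (n > p), and the L1 bound then acts in whitened
coordinates, so the sparse default remains the analysis mode.

Parameterization and conventions. Pairwise bounds are fractions
f ∈ (0, 1] mapped to `c = max(1, f·√p)`; the multi-view extension takes
absolute penalties `c_i ∈ [1, √p_i]`, matching the two scales such tuning
tables conventionally print. Each canonical column's largest-magnitude
coordinate is made positive (CCA is sign-indeterminate). Convergence:
max coordinate change < 1e-6, at most 50 iterations (oracle-equivalence
tests tighten both). Deflation yields only approximately uncorrelated
components; the tests assert |corr| ≤ 0.15 on well-conditioned instances
and exact orthogonality in the whitened mode.

Multi-view CCA maximizes `Σ_{i<j} w_iᵀX_iᵀX_j w_j` by cyclic block ascent;
each block update is the same constrained-argmax, so the objective is
monotone — provided the start is feasible, which is why the
singular-vector initializer is first projected onto the constraint set.

Permutation tuning. For each candidate bound the first canonical
correlation is recomputed under row permutations of Z (the same
permutation set across grid points, reducing between-grid variance).
Correlations are Fisher-transformed, `z(r) = atanh(r)`, and the z-statistic
is `(z_obs − mean z_perm)/sd z_perm`; ties in the best z go to the
smallest bound (prefer sparser models). The p-value at the winning grid
point is `(1 + #{r_perm ≥ r_obs})/(1 + n_perm)`, so its resolution is
1/(n_perm+1); the default is 100 permutations. For three or more views the
statistic is the sum of Fisher-z pairwise correlations and each view except
the first is permuted independently. Degenerate permutation spread (sd = 0)
reports z = 0 with a warning. Under independent views the nominal-0.05
rejection rate of this p-value is calibrated (measured within [0.02, 0.09]
over 200 simulations in the acceptance checks).

## Cooperative learning

The gaussian objective is

    (1/2n)‖y_c − Σ_m X_m β_m‖² + (ρ/2n) Σ_{m<m'} ‖X_m β_m − X_{m'} β_{m'}‖²
        + λ(α‖β‖₁ + ((1−α)/2)‖β‖²),

with y centered and the intercept unpenalized. The agreement weight ρ ≥ 0
spans the fusion continuum: ρ = 0 is exactly a single elastic net on the
concatenated features (early fusion; verified against scikit-learn to
1e-6), and growing ρ forces the per-view linear predictions together. The
quadratic agreement term is realized by data augmentation: one row block
per unordered view pair holding `−√ρ·X_m` and `+√ρ·X_{m'}` with response
zero, stacked under the observation block. The augmented least-squares
objective is algebraically identical to the direct one (checked to 1e-10),
so a single elastic-net coordinate descent solves the whole family.

The solver is a numba-compiled coordinate descent with active-set cycling
(periodic full sweeps refresh the active set and confirm convergence at
1e-7 on coefficient change), warm-started along a λ path of 50 values
log-spaced from λ_max (the smallest λ zeroing every coefficient, inflated
by 1e-8 so the path head is exactly sparse) down by 1e-3. For α = 0 the
path is built as if α were 1e-3, since ridge has no finite λ_max.

Binomial outcomes use penalized IRLS: each step builds the weighted,
weight-centered working response on the observation block and reuses the
*unweighted* agreement blocks, so the agreement penalty acts on linear
predictors; the intercept is updated in closed form from the weighted
means. IRLS stops at 1e-6 coefficient change or 25 iterations. At ρ = 0
this matches scikit-learn's saga logistic elastic net to ~1e-4, and at
ρ > 0 the achieved objective matches an independent convex oracle — the
split-variable bound-constrained quadratic program solved by L-BFGS-B —
to 1e-6.

ρ is applied uniformly to all view pairs and is not rescaled by the pair
count for M > 2; a single reported ρ then means the same thing at any M.
Late fusion is provided as the other end of the continuum: one CV-tuned
per-view elastic net, predictions averaged.

## Nested cross-validation

The outer loop (default 5 stratified folds) estimates generalization; each
outer-training fold runs an inner loop (default 10 stratified folds)
grid-searching (α, ρ) by mean binomial deviance, with λ chosen at the
minimum-deviance point of its path (the convention of the major penalized
regression software; the one-standard-error rule is not used). The winning
triple is refit on the outer-training fold and scored on the outer-test
fold by AUC (Mann-Whitney formulation, ½ credit for ties) and accuracy at
threshold 0.5. The whole procedure is repeated (default 30 times) with
fresh outer splits — the repetition wraps the entire nested procedure, not
just the outer loop — and per-repeat scores (means over outer folds) are
summarized as mean ± sd. Standardization parameters are re-estimated
inside each outer-training fold and applied unchanged to the held-out
fold; an instrumentation hook lets the tests assert that tuning only ever
sees training rows.

Default grids are α ∈ {0, 0.2, 0.4, 0.6, 0.8, 1.0} and
ρ ∈ {0, 0.1, 0.25, 0.5, 1.0}. Benchmark runs (the acceptance script, the
end-to-end pipeline default) use the subset α ∈ {0.2, 1.0},
ρ ∈ {0, 0.5} and a 30-value λ path, sized so the repeated protocol
completes in minutes; the grid subset does not materially change the
attainable AUC on the synthetic scenarios (we measured 0.726 vs 0.727 for
reduced vs full grid at one repeat).

Model comparison across per-repeat score groups follows the
heteroscedasticity-robust chain: Bartlett's test for equal variances,
Welch's ANOVA, and Games-Howell pairwise post-hoc tests (Welch ANOVA and
Games-Howell via pingouin; for two groups Welch's F equals the squared
Welch t, which the tests verify).

## Viral encodings

Mutation tokens follow `<gene>:<ref><pos><alt>` and are validated on
catalog construction. Binary encoding produces one 0/1 column per distinct
token, ordered by first appearance. Before embedding, strains with
mutation counts outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed
(quartiles by linear interpolation, the type-7 convention of mainstream
statistical software).

The skip-gram model (negative sampling, 5 negatives, unigram^0.75 sampling
table, learning rate 0.025 decaying linearly, min-count 1) treats each
strain's token list as a sentence ordered by genomic coordinate (gene,
then position). The original analysis design calls for dimension 300 and
context window 115 — the maximum observed mutations per strain — which
makes the window cover every sentence entirely; with a full window the
sentence ordering is immaterial, so the coordinate ordering is just a
determinism device. Tests and benchmarks use d = 16 and a window
exceeding the longest synthetic sentence (a scaled-down but structurally
identical setting). Training is single-threaded and seeded:
reruns are bit-identical. Strain vectors are the arithmetic means of their
in-vocabulary token vectors; strains with zero in-vocabulary tokens are
excluded and reported. Strain spaces are compared by cosine dissimilarity
(entries in [0, 2]) and projected to 2-D by metric MDS
(stress-majorization/SMACOF with a precomputed dissimilarity, 4 random
starts, convergence 1e-13); the reported stress is normalized,
`sqrt(raw_stress / (Σ d²/2))`.

## Synthetic generators

`gen_multiview` draws latent scores S (n×K standard normal), per-view
sparse loading matrices with unit-norm columns and a seeded support of
`sparsity` non-zeros, and emits `X_m = snr·S·W_mᵀ + ε` with standard-normal
noise (so a feature with loading w carries variance snr²·w² + 1); the
outcome is Bernoulli(logistic(outcome_strength·S₁)). One shared factor
drives both the cross-view correlation and the outcome. Defaults: n = 200,
two 50-feature views, K = 1, sparsity 5, snr = 1, strength 2. A consequence
worth knowing: with two views at snr = 1 the best possible linear score
from the views correlates with S₁ at √(2·snr²/(2·snr²+1)) ≈ 0.816, which
caps the achievable AUC near 0.79 — the prediction benchmarks on this
scenario measure estimation quality against that ceiling, not against 1.

`gen_phylogeny` builds a uniform-depth clade tree by balanced random
splits (all clades separated provided n_clades ≤ 2^(depth−1); a unary
chain pads branches once a clade is isolated). Every branch contributes
`mutations_per_branch` novel tokens; a strain inherits its root-to-leaf
tokens, each dropped with probability `dropout`, plus Poisson(private_rate)
private tokens. Optional outliers gain `outlier_size` extra tokens;
optional recombinants merge the inherited sets of two clades. Defaults
(6 clades, depth 4, 6 tokens/branch, dropout 0.05, private rate 2) put the
median mutation count near 24, echoing the low-tens counts of real
SARS-CoV-2 catalogs. What the generator does *not* emulate: homoplasy
(each token arises once), within-clade substructure, uneven clade sizes,
and sequencing artifacts — so clade-separability results on it are
best-case and real catalogs will be harder.

`gen_cohort` draws a two-group table of Bernoulli comorbidities and normal
covariates at stated group rates, for exercising the descriptive-table
machinery. All three generators are pure functions of (scenario, seed).

## Cohort statistics

Percentages are rounded half-away-from-zero to one decimal (clinical-table
convention). The 2×2 chi-square applies the Yates continuity correction by
default — this is what reproduces conventional published tables — and
Fisher's exact test uses the probability-mass two-sided rule. Fisher is
substituted automatically when any expected cell is below 5. The t-test
pools variances by default (Welch available by flag); the Mann-Whitney U
uses the normal approximation with tie correction. No multiple-testing
adjustment is applied across table rows.

## Pipeline and determinism

`run_pipeline` executes simulate → embed → sparse CCA → multi-view CCA →
cooperative fit → nested CV from a validated YAML configuration, writing
CSV/JSON artifacts plus a manifest (configuration hash, seed, versions).
One global seed is fanned out to per-stage seeds through
`numpy.random.SeedSequence`, so each stage's randomness is independent of
stage order and identical configurations rerun bit-identically (floats are
serialized with shortest-round-trip `repr`). The pipeline default
simulates three views (n = 150) so the multi-view stage applies, and uses
the benchmark CV settings above; the full repeated protocol is available
through configuration.

## Limitations

- The PMD default optimizes cross-covariance; its "canonical correlations"
  are evaluated, not maximized, quantities. Exact CCA requires the
  whitened mode and n > p.
- Deflation does not enforce orthogonality of components under binding L1
  constraints.
- The binomial IRLS clips working weights at 1e-5; separable data yield
  large but finite intercepts rather than divergence.
- The skip-gram trainer is deliberately minimal (no subsampling of
  frequent tokens, no hierarchical softmax, single worker); it targets
  catalogs of 10²–10⁴ strains, not corpus-scale training.
- Synthetic phylogenies are noise-free in topology; see above.
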