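# Methods

## The model

The analysis treats questionnaire subscale scores as observations of a
Gaussian graphical model (GGM).  For p variables with correlation matrix
Σ, the precision matrix K = Σ⁻¹ encodes conditional dependence: the
partial correlation between variables i and j given all others is

    ρ_ij = -K_ij / sqrt(K_ii K_jj),

and ρ_ij = 0 exactly when i and j are conditionally independent.  A
*network* here is the weighted undirected graph whose edge weights are
these regularized partial correlations.

### Estimation

The chain is the standard one in network psychometrics:

1. **Correlation matrix.** Pearson by default (subscale sums are
   quasi-continuous); Spearman available.  A correlation matrix that is
   not numerically PSD is repaired by eigenvalue clipping at zero and
   re-standardization, with the repair recorded in metadata and warned
   about loudly — a silent repair would hide data problems.
2. **Graphical lasso path.** For each penalty λ on a 100-point
   log-spaced grid from λ_max = max_{i≠j}|S_ij| down to 0.01·λ_max, the
   ℓ1-penalized Gaussian likelihood

       max_K  log det K − tr(S K) − λ Σ_{i≠j} |K_ij|

   is solved (off-diagonal penalty only).  The per-λ solve is delegated
   to scikit-learn's coordinate-descent implementation; solutions are
   warm-started from the previous (larger) penalty, which keeps the
   dense end of the path fast and stable.  If coordinate descent stalls
   (it occasionally converges to a slightly wrong point at near-zero
   penalties), an ADMM solver — eigendecomposition-based K update plus
   off-diagonal soft-thresholding — is run and the iterate with the
   smaller duality gap is kept; a residual gap below 1e-2 is accepted.
   On rank-deficient inputs (p > n) the path is truncated at the last
   stable penalty with a warning, because the unpenalized end of the
   path does not exist for singular matrices.
3. **EBIC selection.** Each path point is scored by the extended BIC

       EBIC(λ) = −2 L(λ) + E(λ) log n + 4 E(λ) γ log p,

   with L = (n/2)(log det K − tr(S K)) (likelihood uses the sample
   covariance with denominator n, consistent with the glasso objective),
   E the number of edges with |weight| > 1e-8, and γ = 0.5 by default —
   the sparsity-favoring hyperprior used throughout.  Ties are broken
   toward the larger penalty (sparser model).  No refitting of the
   selected graph is done by default; a `refit` option fits the
   unpenalized Gaussian MLE restricted to the selected edge support (by
   iterative proportional scaling) for users who need unbiased weights.

### Edge-weight accuracy

Nonparametric case-resampling bootstrap: subjects are resampled with
replacement and the *entire* chain — correlation, grid, glasso, EBIC
selection — is re-run per replicate, so intervals reflect
model-selection variability as well as sampling noise.  Per edge we
report the full-data estimate, bootstrap mean, percentile CI (default
2.5%/97.5%) and the proportion of replicates in which the edge survived
selection.  The production default is B = 2500 replicates; per-replicate
random streams are counter-based (`SeedSequence(master, spawn_key=(b,))`)
so any replicate is reproducible independently of execution order.
Replicates drawing a zero-variance column are redrawn (counted, capped
at 10·B).

A known property worth stating plainly: percentile CIs of *penalized*
edge weights are biased toward zero by roughly the selected λ.  When
planted weights (~0.3) are large relative to their sampling SE (~0.035
at n = 500), the CI sits systematically below the unpenalized truth and
covers it far less often than nominally (we measure ≈50–60% in the
validation study below, versus ≈96% when the `refit` option removes the
shrinkage).  The intervals quantify the *stability* of the regularized
estimate, not unbiased uncertainty about the population partial
correlation.

### Shortest pathways

Edge weight w becomes traversal distance 1/|w| — strong conditional
associations of either sign are short steps; absent edges are
non-traversable.  Single-source shortest routes are computed with
Dijkstra's algorithm (networkx), keeping predecessor *sets* so that all
co-optimal routes are recoverable; for each maltreatment (CTQ) source
and each ED-specific target (body dissatisfaction, bulimia) every
co-optimal route is reported in deterministic node-index order, along
with the union "shortest-pathway network" whose edges are flagged
`on_shortest_path`.  Signed weights are kept on reported edges so
positive/negative association claims can be checked.  The phrase
"minimum number of steps" has an unweighted reading; an `unweighted`
flag switches distances to hop counts for users who want it.

### Group descriptives

Per variable: group means ± SD and the Mann–Whitney test in the group-1
U convention (pairs with x > y plus half-ties); p exact by enumeration
when n1·n2 ≤ 400 and the pooled sample is tie-free, otherwise the tie-
and continuity-corrected normal approximation.  Maltreatment occurrence
uses the standard CTQ cut-offs (inclusive ≥): emotional neglect 15,
emotional abuse 10, sexual abuse / physical neglect / physical abuse 8;
occurrence rates are compared by the uncorrected 2×2 Pearson
chi-squared (Yates correction optional).

## Synthetic data

No participant-level data accompany the study this package emulates, so
every stage is validated on data generated from a *known* sparse GGM.
Generation is latent-Gaussian-then-round: draw multivariate normal
vectors whose partial correlations equal the planted graph (precision
built with unit conditional variances — the canonical representative of
the equivalence class — then standardized to unit marginal variances),
scale to the target means/SDs, round half-away-from-zero, clip to the
scale bounds.  Output is a pure function of the spec, including its
seed.

`paper_topology_spec` provides ready-made 16-node generating models for
the two clinical groups (BN n = 181, BED n = 144), with marginal
means/SDs set to the published group descriptives (e.g. BN
ineffectiveness 12.85 ± 7.89).  The planted graphs route all five
maltreatment nodes into emotional abuse (weight 0.25), then into the
symptom network through the group-specific bridge — ineffectiveness in
BN (0.30), impulsivity in BED (0.30) — and on to body dissatisfaction
(via ineffectiveness, 0.35) and bulimia (via interoceptive awareness,
0.30/0.35).  Six filler edges of weight 0.15 are planted among the
remaining symptom nodes (fixed internal seed) for realistic density
without disturbing the planted shortest routes: any detour over filler
edges costs at least 1/0.15 ≈ 6.7 per step versus ≤ 1/0.30 ≈ 3.3 on the
planted chain.  Score bounds default to [5, 25] for the five CTQ
subscales (5 items, 1–5 each) and [0, 3 × nominal item count] for the
EDI-2 subscales; the instrument's item counts and scoring are not fixed
by the source material, so bounds are configuration, not fact.

What the generator does *not* emulate: item-level response processes,
floor/ceiling-induced skew beyond clipping, missing data, test–retest
error.  Recovery results on this generator therefore show that the
pipeline recovers a known conditional-dependence structure from
integer-valued, realistically scaled data — not that any specific
clinical dataset has that structure.

## Validation studies and problem sizes

The validation suite (also re-run by `scripts/acceptance.py`) uses
scaled problem sizes chosen to exercise each property with useful power
at interactive runtimes:

- glasso vs direct inversion at λ = 1e-6: 20 random well-conditioned
  6-node problems, tolerance 1e-4.
- Dijkstra vs exhaustive simple-path enumeration: 200 random connected
  graphs (≤ 7 nodes), half with discrete tie-inducing distances;
  distances and complete co-optimal route sets must match.
- Edge recovery: p = 16, n = 1000, 15 planted edges with |ρ| ∈
  [0.25, 0.35], 20 seeds — pooled sensitivity ≥ 0.8, false-positive
  rate ≤ 10%.
- Null sparsity: empty truth, p = 16, n = 500, 100 seeds — network
  empty in ≥ 95% of runs.
- Bootstrap coverage: fixed p = 8 truth (6 edges), n = 500, B = 200 (a
  scaled-down surrogate for the production B = 2500), 100 datasets;
  replicates use a 25-point grid with min_ratio 0.02, which keeps the
  EBIC optimum interior to the grid at this size.  See the shrinkage
  discussion above for why percentile coverage of strong planted
  weights falls short of nominal under the no-refit default.
- Pathway recovery: group-topology data at n = 2000; estimated shortest
  routes must reproduce the planted routing through emotional abuse and
  the group-specific bridge symptoms.
- Pipeline determinism: the full driver run twice from one
  configuration must reproduce every artifact byte-for-byte (B = 25,
  40-point grid).

## Numerical choices

- Edge presence threshold 1e-8 on |weight| (strict zero is
  solver-dependent).
- Dual-gap acceptance 1e-2 for stalled glasso solves; PD of every
  returned precision is verified.
- Rounding is half-away-from-zero (numpy's default rounds half to
  even); deterministic and scale-symmetric.
- Percentile (not BCa) bootstrap intervals.
- All randomness flows from explicit integer seeds; the pipeline driver
  derives stage streams from the single config seed.

## Known limitations

- Pearson correlations on ordinal sums ignore polychoric alternatives;
  with 5+ categories the difference is small but real.
- No network-comparison test between groups and no centrality indices —
  out of scope by design.
- Shortest-pathway results have no stability measure; re-running the
  pathway analysis over bootstrap replicates would be an extension, not
  a reproduction of the emulated analysis.
- The refit MLE (iterative proportional scaling) assumes the selected
  support admits a positive-definite MLE; for p close to n with dense
  selections it may be slow to converge.
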