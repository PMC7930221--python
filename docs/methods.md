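# Methods

## Model

A Gaussian Bayesian network over variables X₁…X_n is a DAG G plus, per
node, a linear-Gaussian conditional

    f(x_i | pa(x_i)) = N(x_i; β_i0 + β_iᵀ pa(x_i), σ_i²),   σ_i² > 0.

Jointly the variables are multivariate normal. With W the n×n matrix whose
row i holds node i's parent coefficients and S = diag(σ_i²):

    μ = (I − W)⁻¹ β₀,      Σ = (I − W)⁻¹ S (I − W)⁻ᵀ,
    Ω = Σ⁻¹ = (I − W)ᵀ S⁻¹ (I − W).

The Ω identity is purely algebraic, so the parameter route gives a valid
precision matrix even when the empirical covariance is singular (N ≤ n) —
this is the point of estimating dependence structure through a network
rather than by inverting Σ̂ directly. Partial correlations are
ρ_XY|Z = −Ω_XY/√(Ω_XX Ω_YY); under Gaussianity ρ_XY|Z = 0 iff X ⟂ Y given
all other variables, and equals the correlation of the residuals of X and Y
after regressing each on the rest (used as the test oracle).

Markov blankets are read off the DAG (parents ∪ children ∪ co-parents).
Markov-equivalent DAGs (same skeleton and v-structures) are summarized by
the CPDAG; conversion orients v-structures and closes under the Meek rules,
with a brute-force equivalence-class enumeration kept as a test oracle.

## Estimation

*Parameters.* Node-wise OLS, computed from the sample mean vector and the
MLE covariance (denominator N). σ_i² is the MLE residual variance — the N
denominator (not N−p−1) keeps the BIC an exact penalized log-likelihood.
This differs from regression-software defaults on purpose.

*Score.* Decomposable Gaussian BIC in nats, per node
logL_i − (k_i/2)·log N with k_i = |Pa(i)| + 2 (intercept + coefficients +
variance). Other parameter-count conventions shift every structure's score
by a structure-independent constant only for fixed |Pa|-sums; the
convention is fixed for reproducibility. The score is verified
score-equivalent across enumerated equivalence classes.

*Standardization.* Columns are z-scored (mean 0, SD 1, denominator N−1)
once per group before learning and before Ω. Structure learning is
invariant to affine column scaling, so this only pins down the parameter
and Ω scale; marginal Pearson correlations are unaffected.

*Search.* Tabu local search from the empty graph over single-arc
add/delete/reverse moves, blacklist enforced in both directions, ties
broken lexicographically by variable name (deterministic, no randomness in
the search itself). Defaults: tabu list 30, stop after 30 consecutive
accepted moves without improving the best-seen score; best-seen structure
returned. Family scores are memoized, so the bootstrap's thousands of
searches share no redundant regressions within a search.

Two numerical choices here were forced by failure modes observed during
development:

- **Tabu memory is keyed on visited structures**, not on "undoing
  operators": an add → reverse → delete three-cycle returns to an earlier
  structure without ever undoing a single recent move, and with
  operator-keyed memory the search oscillated and missed exhaustive optima
  on ~7% of small problems. Barring any structure visited in the last 30
  iterations (with score aspiration) removes the cycle; recovery of the
  exhaustive optimum's class on 3–4-variable problems is 40/40 after the
  change.
- **The running score is recomputed from cached per-node scores after every
  move** rather than accumulated incrementally. Accumulated round-off
  (~1e-13/move) can make a revisited structure appear better by more than
  the improvement epsilon, resetting the stopping counter forever;
  recomputation makes identical structures score bit-identically, so the
  search provably terminates.

An exhaustive search (max over variable orderings of per-node best parent
sets) provides the global optimum for n ≤ 5 as an oracle.

## Bootstrap arc confidence

B full-size resamples with replacement; tabu search (no blacklist) on each;
confidence p(X→Y) = fraction of replicate networks containing the arc. A
pair is blacklisted when p(X→Y) + p(X←Y) ≤ t — the threshold is
**inclusive**. Defaults B = 2000, t = 0.7. Standardization is computed once
on the original sample; resamples are not re-standardized (scale does not
affect the learned structure and replicates stay comparable). A resample
that leaves a column constant — realistic at N ≈ 21 — is logged and redrawn
from the replicate's next derived seed; letting BIC handle a zero-variance
node was rejected as numerically fragile. Replicate seeds derive from the
master seed by hashing named paths, so results are independent of
evaluation order and adding consumers never perturbs existing streams.

## Group comparison

Hellinger distance between the two implied Gaussians,

    H² = 1 − det(Σ₁)^¼ det(Σ₂)^¼ / det((Σ₁+Σ₂)/2)^½,

computed via Cholesky log-determinants and clipped to [0, 1]. Before
comparing, the parameters of group A's *structure* are re-fitted on group
B's data (and vice versa), so both compared distributions are estimated
from the same data set and share a mean exactly; a guard asserts mean
equality to 1e-8 and the distance is then a function of the covariances
only. Two distances are reported, one per data set. H(B,B) = 0 holds
*exactly* in floating point (the three log-determinants coincide
bit-for-bit), which is what the acceptance target checks.

Structural overlap is reported as CPDAG arcs common to both groups — an
adjacency counts only if its orientation class matches (same head, or
undirected in both) — plus per-variable Markov-blanket equality.

Auxiliary comparisons: thresholded marginal-correlation networks (edge iff
|ρ| strictly > τ; τ defaults 0.4/0.5 per group), per-variable two-sided
Welch t-tests (the unequal-variance form was chosen because group SDs can
differ several-fold; pooled-variance is the plausible alternative),
and correlations with a target variable within subgroups split at a
covariate cutpoint (e.g. rel_depth < 0.28 vs ≥ 0.28), which exposes
Simpson-style sign reversals between pooled and within-subgroup trends.

## Morphometry

SWC text is parsed with strict validation (ids unique and positive,
parents defined before children, exactly 7 columns, `#` comments).
Branches run between topological events (insertion at the soma,
bifurcation, terminal) and partition the arbor's compartments. Decisions
where the feature definitions left room:

- "Averaged over all bifurcation points" for mean branch length is read as
  *averaged over branches*, consistent with the feature's name; the
  alternative (bifurcation-count weighting) is isolated behind one function
  and would change only this feature.
- Soma-attached segments are excluded from branch geometry; the arbor
  insertion point is the first dendritic node. Consequently a cell's arbor
  extent (max−min of node coordinates) and its branch lengths are measured
  over dendritic nodes only.
- Branch diameter is the compartment-length-weighted mean of 2×(mean
  endpoint radius); the within-branch weighting is otherwise undefined.
- Multiple arbors of one class are pooled before averaging (one value per
  cell per class); path distances are measured from each arbor's own
  insertion point.
- Bifurcation angle uses vectors from the fork to the *end nodes of the
  daughter branches* ("remote" angle); at multifurcations the smallest
  pairwise angle is taken.
- Features with an empty averaging population (no bifurcation, absent
  arbor) are NaN; downstream table loading drops incomplete rows with a
  logged warning rather than imputing.
- Coordinates are taken as micrometers in the reconstruction frame; no
  pia-alignment rotation is applied, so extents are axis-dependent by
  design. All other features are translation-invariant; lengths scale
  linearly and tortuosity/angles are scale-invariant (property-tested).

## Synthetic data

The generator states a world and is not tuned to any empirical data set:

- `random_dag(n, edge_prob, seed)`: random permutation order, each forward
  arc included with probability `edge_prob`.
- `random_parameters`: intercepts 0 (structure learning and partial
  correlations are location-invariant), coefficients uniform on
  `coef_range` excluding a dead zone (−0.1, 0.1) so no true arc is
  vacuous, variances uniform on a positive `var_range`.
- `make_confidence_scenario(n, N, seed)`: edge probability 0.25,
  coefficient magnitudes uniform in [0.5, 1.5] with random sign, variances
  in [0.5, 1.5] — a strong-signal regime in which true arcs are clearly
  recoverable at large N, chosen once and documented here.
- Toy SWC fixtures with closed-form feature values live next to their
  documented ground truth (`TOY_SWC_FEATURES`).

What a green test establishes: the machinery — scoring, search, bootstrap,
distances, morphometrics — is correct on data whose generating process is
known exactly. What it does not establish: anything about real neurons.
The generator makes no attempt to mimic empirical means, SDs, or
inter-feature correlation patterns of any cell-type database; real
feature tables enter through the pipeline as user-supplied CSVs.

## Known limitations

- Exact Gaussianity is assumed throughout; heavy-tailed electrophysiology
  features would need transformation upstream.
- The bootstrap refits the whole search per replicate (no approximations);
  B = 2000 on 30 variables is minutes of CPU, not seconds.
- CPDAG conversion relies on Meek rules R1–R3 (sufficient without
  background knowledge); verified exhaustively against enumeration for
  n ≤ 4 and on random 6-node DAGs.
- No significance testing on structural differences: distances and overlap
  counts are reported descriptively.
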