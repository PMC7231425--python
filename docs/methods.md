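# Methods

## Model

All algorithms in this package solve the exemplar-based clustering
problem: choose an assignment `E` of every point to an exemplar drawn from
the data so as to maximize

    J(E) = Σ_i S(i, E(i)),

subject to *validity* — whatever is chosen as someone's exemplar must be
its own exemplar (`E(i) = j  ⇒  E(j) = j`).  The similarity is the
negative squared Euclidean distance, and every diagonal entry carries the
same *preference* `p`.  Exemplars contribute `p` through their
self-assignment, so `p` prices cluster creation: the more negative it is,
the fewer exemplars survive.  Following common practice, `p` defaults to
the median of the off-diagonal similarities, computed once over the
unordered pairs of the whole dataset and reused unchanged for every
matrix derived from it, so the compressed problem feels the same
model-selection pressure as the full one.

Validity is commonly written as an infinite pairwise penalty added to
`J`.  Here it is enforced structurally — every search move is constructed
so the result is valid — which is equivalent and immune to overflow.

## Missing features

The dataset container carries a boolean observedness mask; a row missing
at least one feature is *incomplete*.  Two distances are used:

* **Rescaled partial squared distance** `(D/|O|) · Σ_{d∈O} (x_d − y_d)²`
  over the shared observed features `O`.  This is the classical
  partial-distance strategy; it is the distance behind the ENERGY index.
  A pair with `O = ∅` has no defined value and raises an error — it is
  never silently zero.
* **Variance-penalized partial distance** (used to build all similarity
  matrices): `Σ_{d∈O} (x_d − y_d)² + Σ_{d missing in x} σ̂_d² +
  Σ_{d missing in y} σ̂_d²`, with `σ̂_d²` the marginal variance of feature
  `d` over its observed entries.  Both reduce to the squared Euclidean
  distance for complete pairs.

The surcharge in the second form is the load-bearing choice.  During
assignment it is constant across candidate exemplars, so every point is
assigned by its observed coordinates alone — which is also the maximum
a-posteriori rule when nothing is known about the missing coordinate.
During exemplar selection, however, it charges an incomplete candidate
`σ̂_d²` per blind feature *for every point it would represent*.  Without
this charge the plain partial distance has a severe failure mode that we
measured directly: a candidate blind to feature `y` sits "close" to every
point that matches it on `x`, so one such candidate can represent two
`x`-aligned clusters separated only in `y`, and merging them *raises* the
objective by a full preference term.  On the 788-point benchmark below
this merging costs ~0.13 NMI; the surcharge removes it entirely and the
resulting assignments match a Bayes-oracle (true generating centres) per
seed.  A side benefit: a pair of rows with no shared features gets the
finite, deliberately large value `Σ_d σ̂-terms`, so the degenerate-overlap
case is well defined everywhere.

The surcharge deliberately overstates within-cluster dissimilarity (the
marginal variance includes between-cluster spread).  That is acceptable
because it only needs to be an *eligibility* price; assignments never see
it differentially.

## Search moves

The move engine visits each candidate `α` in ascending row order:

* `α` is an exemplar → **removal**: every member of `α`'s cluster
  (including `α`, which surrenders its preference) falls back to its
  best remaining exemplar ("second exemplar", ties to the lowest row
  index).  The gain is clamped at zero.
* `α` is not an exemplar → **addition**: `α` claims its preference, and
  each existing cluster chooses the best of three options — *dissolve*
  (exemplar and members leave for their best remaining exemplar or `α`),
  *migrate* (exactly the members preferring `α` switch), or *stay*.  A
  `global` combination rule that forces one collective option across all
  clusters is available as `r2_combination="global"`; the per-cluster
  rule is the default as it is strictly more general.

When several clusters dissolve in one addition, a member's nominal
fallback exemplar may itself be dissolving; final targets are therefore
re-computed against the exemplars that actually survive.  Every
`MoveEvaluation` reports the exact objective delta of its final
assignments (self-certifying to 1e−9), moves are accepted only when the
delta is strictly positive (ruling out cycles between tied
configurations), so the objective trace is non-decreasing and the search
terminates; the sweep cap (default 200) is a safety net never reached at
tested sizes.  The search starts from the best single-exemplar
configuration — deterministic, cheap, and additions then grow the
exemplar set greedily.  All tie-breaks go to the lowest index, making
runs bit-reproducible; the `seed` argument is recorded for provenance
only.

On instances small enough to enumerate every valid configuration (N ≤ 8),
the search attains the global optimum in ~90% of random instances and
never exceeds it; affinity propagation under the same check lands on the
optimum less often, consistent with its message-passing approximation.

## Two-stage scheme

For data that is mostly complete (`N_c ≫ N_l`), clustering the complete
rows first costs `O(N_c²)` and yields `c_c` exemplars; these plus all
`N_l` incomplete rows form the candidate list, and the optimization stage
then touches only the `N × c` similarities (`c = c_c + N_l`).  The
optimization stage starts from the hand-off configuration: compression
exemplars and incomplete rows self-assigned, every other complete row at
its best compression-stage candidate.  Incomplete rows are candidates but
not protected — moves may (and usually do) absorb them into complete-data
clusters.  With the candidate list forced to the full index set the
two-stage runner is bit-identical to the plain search, which is asserted
in tests.  More than 50% incomplete rows triggers a warning: the scheme's
premise no longer holds.

## Synthetic data

`make_clusters` draws isotropic Gaussian clusters (σ = 1) with centres
rejection-sampled pairwise at least `separation·σ` apart inside a box
sized `separation·(⌈K^(1/D)⌉+1)`; sizes are as equal as possible.  The
default shape — 788 points, 2 features, 7 clusters, separation 8 —
mirrors the planar aggregation-style benchmark this family of methods is
usually demonstrated on.  `inject_missing` masks exactly
`round(fraction·N)` rows (default 20%), removing `k_missing` (default 1)
uniformly chosen features per row; values are never altered, only the
mask.

With 2 features and 1 masked, an incomplete point is a 1-D projection,
and 7 cluster centres crowd a line: whenever two centres nearly align in
the observed coordinate, points from either cluster that lost the other
coordinate are irreducibly ambiguous.  A Bayes oracle given the true
generating centres mislabels ~20% of the incomplete rows (≈35 of 788
points per seed), capping mean NMI near 0.90 and accuracy near 0.96 at
these settings; the two-stage clustering reproduces that ceiling.  The
package therefore recovers everything the data still determines — the
complete-row structure is recovered essentially perfectly — and the
residual error is a property of the masking scenario, not of the
algorithm.

`make_synthetic_eeg` emulates a five-group epilepsy-archive structure:
two oscillation-only "healthy" groups (10 Hz at different amplitudes),
two oscillation-plus-spike "interictal" groups (5 and 7 Hz with sparse
spike trains) and one high-amplitude ~3 Hz spike-wave "seizure" group,
at 173.6 Hz for 23.6 s (4097 samples) by default.  Segments within a
group share a phase reference with small jitter.  This is deliberate and
*not* physiological: kernel PCA here operates on raw traces, and
random-phase oscillations of equal frequency are mutually distant in L2,
so phase-locking is what makes the groups recoverable from raw-signal
geometry.  Passing pipeline tests on these segments demonstrates the
plumbing (loading → KPCA → clustering → scoring) and the clustering's
behaviour on well-separated five-group data; it says nothing about
separability of real EEG, which would require spectral features and is
out of scope.

## Kernel-PCA front end

Whole segments are observations.  The RBF kernel width defaults to the
median pairwise squared distance between segments (median heuristic);
`n_components` defaults to 6.  Eigenvector signs are fixed by making each
component's largest-magnitude dual loading positive, so repeated runs are
bit-identical.  Kernel choice and width are configurable; a linear kernel
reproduces classical PCA scores up to sign (tested).

## Evaluation indices

* ENERGY: `Σ_k Σ_{i∈cluster k} d(x_k, x_{k,i})` with unsquared
  (partial, rescaled, square-rooted) Euclidean distance by default; a
  squared variant is exposed (`energy_mode="squared"`) since either
  convention appears in practice.  The exemplar's own term is zero.
* NMI with geometric-mean normalization, natural logarithms and the
  `0·ln 0 = 0` convention.  Trivial edges: two single-group partitions →
  1; single-group vs non-trivial → 0.
* Accuracy: optimal one-to-one cluster→class mapping on the zero-padded
  square contingency table (Hungarian algorithm), matched fraction.

## Numerical choices and degenerate inputs

Distances are clipped at zero against round-off; objectives of invalid
configurations are `−∞` sentinels (or an error on request).  A single
candidate yields one cluster without invoking removals.  Affinity
propagation uses damping 0.5, at most 1000 iterations, and declares
convergence after 50 sweeps with an unchanged exemplar set; if the
exemplar set never stabilizes the best configuration seen (by the
exemplar objective) is returned with a warning flag.  Empty rows, rows
with no observed features, non-numeric inputs, and mask/value conflicts
are rejected with explicit errors.

## Known limitations

* The variance surcharge assumes features on comparable scales; an
  opt-in z-score flag exists, but no automatic standardization is done.
* The missing-data rules are moment-based, not model-based: no
  imputation, no conditional distributions.  Accuracy on incomplete rows
  is bounded by what the observed coordinates determine.
* The synthetic EEG generator is a plumbing fixture, not a physiological
  model (see above).
* Wall-clock comparisons between the two-stage and plain searches are
  asserted as an ordering only; absolute times are hardware-dependent and
  never tested.
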