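# Methods

## The model

`simcompare` compares two (dis)similarity matrices `Y1` (reference) and `Y2`
(target) defined over the same `d` labelled subjects.  Both are symmetric,
non-negative `d x d` matrices: Euclidean distances between feature rows or
covariance-style similarities, or any externally supplied matrix of that
shape.

The reference is represented at every complexity `k = 1..k_max` by the
quadratic low-rank model

    Y1 ≈ A_k X1(k) A_kᵀ,

with the *structure* `A_k` (`d x k`) and the *relationship* `X1(k)`
(`k x k`) chosen to minimise the Frobenius loss `||Y1 − A_k X A_kᵀ||_F`.
Two structure families are implemented:

* **svd** — unconstrained.  For symmetric `Y1` the optimum is the truncated
  spectral decomposition: `A_k` holds the top-k eigenvectors (ordered by
  absolute eigenvalue, signs fixed so each vector's largest-magnitude entry
  is positive, ties kept in stable order) and `X1(k)` is the diagonal block
  of eigenvalues.  The fit loss at `k` is exactly
  `sqrt(sum_{j>k} sigma_j^2)`.
* **mixture** — rows of `A_k` constrained to the probability simplex, so the
  columns act as latent clusters and each subject is a mixture over them.
  `X1(k)` stays unconstrained and plays the role of the similarity between
  latent clusters.

The *structural comparison* keeps `A_k` and refits only the relationship on
the target: for full-column-rank `A`,

    X2(k) = A⁺ Y2 (A⁺)ᵀ,   so   A X2 Aᵀ = P_A Y2 P_A,

the orthogonal projection of `Y2` onto the reference's structure (for
orthonormal svd structures this reduces to `Aᵀ Y2 A`).  Differences in scale
or in the strength of relationships — e.g. all branch lengths of an
underlying tree changing — are absorbed by `X2`; genuine structural
differences are not.  The residual matrix `R2(k) = Y2 − A_k X2(k) A_kᵀ` is
summarised per subject by the **residual persistence**
`P_ik = sum_j R2(k)_ij²`: subjects whose persistence stays high across a
wide band of `k` carry structure in the target that the reference does not
contain at any modest complexity.

## The mixture solver

Minimising `||Y − A X Aᵀ||` over simplex-constrained `A` is a quartic
problem solved by alternating

1. a multiplicative update of `A` with numerator `Yᵀ A X + Y A Xᵀ` and
   denominator `A X Aᵀ A Xᵀ + A Xᵀ Aᵀ A X` (entrywise ratio, a small
   `1e-12` floor added to the denominator and to the entries of `A`, which
   keeps exact zeros — absorbing under multiplicative updates — out of the
   iteration), followed by row renormalisation onto the simplex;
2. an exact least-squares solve for `X` via the pseudo-inverse of `A`
   (falling back to a multiplicative `X` update with numerator `Aᵀ Y A` and
   denominator `Aᵀ A X Aᵀ A` if `A` loses full column rank).

The multiplicative step is not provably monotone for this objective, so
iterates are accepted greedily: the best iterate seen is retained and the
reported `loss_trace` contains the accepted (strictly improving) losses,
which makes it non-increasing by construction while the internal iteration
is free to wobble.  Termination is by relative accepted improvement below
`tol` (default `1e-8`), by `patience` (default 20) consecutive
non-improving iterations (status `stalled` — a poor model fit can prevent
the multiplicative rule from locating a local optimum), or by `max_iter`
(default 5000).

**Initialisation.**  The loss contains nothing that pushes `A` towards the
simplex boundary, and the model is identifiable only up to an invertible
mixing of the latent clusters: from a random interior start the solver
happily converges to an equally good but uninterpretable representative.
The scan therefore solves each `k` from several candidate starts and keeps
the lowest loss: (i) a warm start grown from the `k−1` solution, with the
new column seeded on the subject with the largest fit residual (floor
`1e-3`, rows renormalised); (ii) a near-vertex start obtained by k-means on
the top-k spectral embedding; (iii) `restarts` (default 3) symmetric
Dirichlet(1) random rows.  Among candidates whose losses tie within `1e-6`
relative, the one whose rows sit closest to the simplex vertices is
preferred — the interpretable member of the equivalence class.  All
randomness derives from per-candidate streams spawned from one seed, so the
scan is reproducible and order-independent.

## Self-similarity (the diagonal)

A subject's raw self-(dis)similarity usually carries excess similarity that
no low-rank structure should be asked to explain — for a distance matrix,
the zero diagonal is a full-rank `−cI` deficit in the matrix's expectation.
Two treatments are provided:

* `remove_diagonal` replaces each diagonal entry by the row's next most
  extreme off-diagonal value (largest for similarities, smallest for
  dissimilarities), then re-symmetrises by averaging with the transpose.
  The extreme is taken **per row** rather than globally because it
  preserves each row's scale; off-diagonal entries are never changed.
* the diagonal model fits `Y ≈ A X Aᵀ + D` by alternating the structure fit
  on `Y − D` with `D ← diag(Y − A X Aᵀ)` (outer tolerance `1e-8`, up to 100
  outer iterations; the alternation converges linearly, so exact planted
  instances reach machine-level loss well within the budget).  When a scan
  carries a diagonal model, target prediction refits a target diagonal the
  same way and persistence is computed on the off-diagonal residuals, which
  are all the model is asked to explain.

## Significance by split-half resampling

The test asks: is the target predicted *worse* than a matrix that merely
resamples the reference?  Each of `n_bs` replicates (about 200 are needed
to resolve the 0.05 level; regularised p-values are floored at
`1/(1+n_bs)`) splits the reference's `L` features into disjoint halves,
builds a *sampled reference* and *sampled target*, and down-samples the true
target's features to half so noise levels match.  Both comparison matrices
are affinely aligned to the sampled reference (mean and sd over
**off-diagonal** entries only, since the diagonal is governed by the
self-similarity policy), the sampled reference is scanned, and both aligned
matrices are predicted.  The per-cell persistence of the sampled target is
the null statistic; that of the true target the observed one.  The
regularised empirical p-value

    p = (1 + #{replicates: null ≥ observed}) / (1 + n_bs)

is small when the target's persistence exceeds what reference resampling
alone produces; small p = significant, which is the direction in which the
0.05/0.01 thresholds are applied throughout.  All built similarities have
their diagonals removed by default (`drop_diagonal=True`); without this the
shared diagonal deficit lets every extra eigendirection improve held-out
prediction regardless of structure.

Because resampling alone cannot tell whether complexity `k` reflects signal
at all, a cross-validated complexity estimate of the *target* is
bootstrapped alongside: each replicate splits the target's features in
half, scans fold 1, and predicts the aligned fold-2 similarity using the
fold-1 structure **and relationship**.  Keeping `X` fixed is essential —
refitting it on fold 2 makes the error non-increasing in `k` by
construction and the estimate degenerates to `k_max`; with `X` fixed the
error is minimised near the true complexity (pure-noise data select
`k ≈ 1`, the ten-cluster simulation selects `k = 10`).  `k̂` is the argmin
(ties to the smallest k), `p(k)` is the fraction of replicates with
`k̂ ≥ k`, and the combined p-value per cell is

    p_c = 1 − p(k) · (1 − p),

close to 0 only when complexity `k` describes structure *and* the
persistence is extreme.  No multiple-testing correction is applied: the
p-values are strongly correlated and are meant to annotate the persistence
chart, not to test a global hypothesis; a more powerful global statistic
(the Frobenius norm of the whole residual) is computed alongside.

Replicates own RNG streams derived from `(seed, replicate index)`, so runs
are reproducible, replicate-order independent, and identical under any
degree of thread parallelism.

## Simulators

### Tree-structured subjects

The hierarchical simulator draws a neutral coalescent tree on `k` cluster
tips (waiting times Exponential with rate `m(m−1)/2`, mergers uniform; the
expected height is `2(1 − 1/k)`), evolves `L` features down the tree by
Brownian motion with unit rate from a root value of 0 (tip covariance =
shared root path length), assigns `d` subjects to clusters as evenly as
possible (remainders to the lowest-indexed clusters), and samples subject
features `Normal((aᵢᵀ D0)_l, σ0²)`.  Similarities are Euclidean distances
between subject rows.  Defaults follow the study conditions `d=100`,
`k=10`, `L=2000`, `σ0=0.05`.

Targets come in three flavours: **null** re-simulates profiles and noise on
the same tree; **scenario A** multiplies every branch length by an
independent `U(0.1, 2)` draw (a relationship change — same clusters,
different geometry) and re-simulates; **scenario B** additionally plants
one mixture edge: a uniformly chosen recipient tip `i`, a donor tip `j`
uniform among tips at least the median patristic distance from `i` (ties
inclusive), and a fraction `r` (rounded half-up, subjects chosen at random)
of cluster `i`'s subjects get the row `(1−β)` on `i` and `β` on `j`.
`r ∈ {0, 1}` would move the whole cluster — a relationship change, not a
structural one — and is rejected.  Cluster profiles are re-simulated on the
target tree rather than reused, matching the idea that both datasets are
fresh draws from their (possibly different) generating processes.

What the simulator does *not* emulate: non-Gaussian features, missing data,
unequal feature informativeness, or more than one mixture edge.  Passing
tests therefore show that the method separates relationship from structural
change under clean tree-mixture generative conditions, not that it is
robust to arbitrary real data.

### Methylation / expression case-control

Loci (the subjects of the downstream comparison) are 300 "hypo"-methylated
(baseline mean `μ_i ~ U(0.1, 0.4)`) and 700 "hyper"-methylated
(`μ_i ~ U(0.55, 0.85)`).  Tumour samples draw methylation
`U(μ_i − w, μ_i + w)` with half-width `w = μ_i/2` (hypo) or `(1 − μ_i)/2`
(hyper); controls use the same class rule around a mean shifted towards 0.5
by 0.2 (deterministic when `μ_i < 0.3` or `μ_i > 0.7`, random sign
otherwise, the sign drawn per realisation).  Draws are clamped to `[0, 1]`
(only the shifted supports can exceed it; clamp counts are recorded).

Expression is measured on an *independent* cohort sharing only the loci.
Each expression sample receives a fresh latent methylation realisation
under the same locus parameters, and expression is
`e' ~ Normal(−m, σ_i²)` with `σ_i ~ U(0.5, 0.9)`, then centred and scaled
per locus.  The negated mean encodes the biology — methylation silences
transcription, so the assays are negatively coupled — and is what makes
the simulator's emergent cross-assay correlation come out negative.  Both
cohorts use the same case-control design (50 tumour then 50 control), so
matched sample indices share status; that status alignment is the only
channel through which the assays correlate, and it produces a weak average
per-locus correlation of about −5% to −6% (computed per locus across
matched indices, then averaged over loci).  With independently shuffled
statuses the expected correlation is exactly zero.

Anomalies reverse the relationship for two disjoint segments of 10
consecutive loci: in one segment tumour samples' expression is replaced by
`−2e`, in the other control samples'.  Segment indices are ground truth for
the anomaly-detection checks.

## Numerical choices

* Symmetry of inputs is required to `1e-10` relative; asymmetric targets
  beyond `1e-8` trigger a warning, and residuals are reported as computed.
* Full rank is *not* enforced on construction (simulated distance matrices
  are routinely near-deficient numerically); rank is checked where it
  matters, at pseudo-inverse time, with tolerance
  `max(d, k) · ε_machine · σ_max`, and rank-deficient structures produce a
  warning rather than an error.
* Feature standardisation scales to unit variance without centring
  (centring is a modelling decision, off by default and explicit), caps
  values at 10 standard deviations, drops features with ≥ 40% missingness
  or zero variance, and mean-imputes (means computed before capping).
* The stability guarantees for the svd structure (residual-norm shifts
  bounded by `2ε` under target perturbation and `2^{5/2}ε/δ_k` under
  reference perturbation, with `δ_k` the eigengap) carry additive constants
  that are meaningful at unit matrix scale; the property suite verifies
  them on matrices standardised to unit Frobenius norm, which is the scale
  the alignment step produces in practice.  At arbitrary scale the
  structure-side bound must be read with an extra `||Y2||` factor.
* Chart rendering is deliberately simple: one colour map, monotone in
  persistence, and two size classes (full-size when `p < α`, shrunk and
  desaturated otherwise).

## Problem sizes in the test suite

The replication checks run at reduced but structurally faithful sizes
chosen once: the cluster-recovery and scenario-discrimination regimes use
`L = 500` features (study condition `d = 100`, `k = 10` retained), 20–50
replicates per check, and `n_bs = 99` for the calibration probe.  The
methylation/expression checks run at the full published sizes (1000 loci,
50 + 50 samples per assay).

## Known limitations

* The mixture solver's interpretability depends on its initialisation; the
  near-vertex candidate makes cluster-like optima reliably reachable, but
  for data far from any mixture structure the returned `A` is just one
  member of an equivalence class.
* Persistence p-values flood towards the floor whenever the target differs
  globally from the reference (the power-dominated regime); in that regime
  the persistence values and group residual summaries, not the p-values,
  carry the discrimination.
* The hierarchical solver family does not include a strict-tree-constrained
  structure; trees are handled through the mixture representation.
* No asymmetric-input theory: asymmetric matrices are accepted with a
  warning but all guarantees assume symmetry.
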