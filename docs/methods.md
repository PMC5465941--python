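# Methods

## The estimation problem

Given an n x p table of item responses (binary primary, small ordinal
scales secondary), how many latent dimensions underlie the items?  The
package implements exploratory graph analysis (EGA), which answers by
counting communities in an estimated partial-correlation network, and six
classical retention rules it is compared against, plus the Monte Carlo
harness that does the comparing.

## Generating model

Synthetic data come from the common-factor model

    Sigma = Lambda Psi Lambda' + Theta,

with simple structure (each of the p = M q items loads on exactly one of
the M factors), equicorrelated factors Psi = (1 - rho) I + rho J, and
diagonal Theta (local independence).  Defaults are unit loadings, unit
factor variances and unit residual variances, so each latent item has
variance 2, two items of the same factor have latent correlation 1/2, and
items of different factors have latent correlation rho/2.  Latent
multivariate-normal draws are dichotomized at their theoretical mean of
zero, giving Bernoulli(1/2) items; ties have probability zero and map
to 1.  Because thresholding at the mean is scale-free, standardizing the
latent items before cutting would change nothing; the generator therefore
works with the raw covariance.

The condition grid crosses M in {2, 4}, q in {5, 10}, n in {100, 500,
1000, 5000} and rho in {0, .2, .5, .7} — 64 conditions.  One RNG seed per
dataset is derived deterministically from (study seed, condition index,
replicate index), so any condition can be regenerated in isolation.

A key structural fact drives EGA: the precision matrix K = Sigma^{-1} is
block diagonal whenever the factors are orthogonal, so the implied
Gaussian graphical model consists of unconnected clusters, one per
factor; with correlated factors the cross-block entries are small relative
to within-block entries.  Property tests verify the exact block
diagonality numerically rather than symbolically.

## Tetrachoric / polychoric correlations

Latent correlations are estimated by two-step maximum likelihood:
thresholds fixed at normal quantiles of the observed margins, then a
one-dimensional ML search for rho.  For binary pairs the ML equation is
Phi2(h_i, h_j; rho) = p11, solved simultaneously for all p(p-1)/2 pairs by
a safeguarded Newton iteration (the bivariate density is the exact
derivative, and Phi2 is monotone in rho so bracketing makes every step
safe).  Phi2 is evaluated by 48-point Gauss-Legendre quadrature of the
correlation-integral identity, accurate to ~1e-10 away from |rho| = 1.
Estimates are clipped to [-0.999, 0.999]; a table with an empty cell gets
a +0.5 continuity correction on every cell; missing data use
pairwise-complete observations (a strict mode rejects them); a constant
column is an explicit error naming the item.  If the assembled matrix has
an eigenvalue below -1e-8 it is repaired to the nearest correlation
matrix by Higham alternating projections (Dykstra-corrected PSD and
unit-diagonal projections, final eigenvalue floor 1e-6 relative to the
largest), with a `smoothed` flag set.  A plain eigenvalue clip followed
by rescaling to unit diagonal was evaluated first and rejected: the
rescaling attenuates every off-diagonal entry, which at p = 40 and
n = 100 weakens the block signal enough to flip the EBIC selection to the
empty graph.

The tolerance of the 1-D solver is 1e-8.  Ordinal columns with 3+
categories route to a general polychoric (rectangle probabilities,
bounded scalar minimization); continuous data fall back to Pearson.

## Network estimation

The Gaussian graphical model is estimated by the graphical lasso: maximize
log det K - tr(SK) - lambda * sum_{i!=j} |k_ij| with the diagonal
unpenalized.  The solver is an ADMM splitting whose smooth update is an
eigenvalue shrinkage and whose penalty update is an element-wise soft
threshold, so returned precision matrices carry exact zeros; convergence
is declared at primal/dual residuals below 1e-6 (scaled).  Warm starts
carry the ADMM state along the path, which keeps a full path cheap (a
100-value path on 40 items runs in ~0.2 s).  At lambda = 0 the solution
is taken directly as inv(S).

Model selection follows the extended BIC for graphs,

    EBIC = -2 l + E log n + 4 gamma E log p,   l = (n/2)(log det K - tr(SK)),

with gamma = 0.5 by default, over 100 logarithmically spaced penalties
from lambda_max = max |S_offdiag| (empty graph) down to 0.01 lambda_max.
Ties resolve to the larger penalty (sparser graph).  These constants —
gamma, the 4*gamma*E*log p form, the path length and ratio, the
unpenalized diagonal, no post-selection refit — are the conventional
defaults of EBIC-selected glasso in psychometric network practice; all are
exposed as arguments.

## Community detection

Communities of the selected network are found by walktrap on the absolute
partial correlations (the detector requires nonnegative weights; absolute
value is the standard transform for signed psychometric networks).  The
algorithm follows Pons-Latapy: t-step random-walk profiles (t = 4),
Ward-style agglomeration of adjacent communities minimizing the increase
in mean squared walk distance, and a cut of the merge tree at maximal
weighted Newman-Girvan modularity.  Two implementation details matter:

* Each vertex receives a self-loop equal to its mean incident edge weight
  before walk probabilities are computed.  This makes the short walk
  aperiodic; without it, near-bipartite weight patterns distort the
  4-step profiles and dense noisy networks collapse into a single
  community.  With it, partitions agree with igraph's reference
  implementation on essentially all tested graphs (39/40 random weighted
  graphs; residual disagreements trace to tie-breaking inside igraph's
  lazily updated minima).
* Merging is restricted to adjacent communities, so disconnected
  components are never merged and zero-strength items remain singleton
  communities (a warning is emitted; singletons still count toward the
  dimension estimate, matching the principle that the estimator reports
  the detector's output verbatim).

An empty network therefore yields ndim = p with a warning, which is the
honest answer for independent items.

## EGA

ega() chains the three stages and retains every intermediate object
(correlation matrix, selected fit with its lambda/EBIC/edge list,
partition with merge tree, item-to-dimension table).  The pipeline is
deterministic: identical inputs give identical results, and permuting the
item order permutes the result identically.  ega_from_correlation()
enters the pipeline at a known correlation matrix, which is how the
population-level identities (community count = number of factors for
every grid design) are tested.

## Classical retention methods

All six comparison methods consume the same latent correlation matrix the
EGA pipeline estimates (tetrachoric for binary items).

* Kaiser-Guttman: count of eigenvalues of the unreduced correlation
  matrix strictly greater than 1.  (The unreduced choice is deliberate:
  the worked-example eigenvalue trace used in the tests sums to about the
  number of items, which reduced eigenvalues would not.)
* Parallel analysis: observed eigenvalues versus the mean eigenvalues of
  20 column-wise independently permuted copies of the data (margins
  preserved, inter-item correlation destroyed; the correlation matrix is
  re-estimated on every copy).  Retained dimensions = length of the
  initial run of observed > reference ("consecutive exceedance").
* Velicer's MAP: for m = 0..k_max partial the first m principal
  components out of R, record the mean squared off-diagonal partial
  correlation, take the argmin (ties to smaller m).
* VSS (complexity 1): for each k, an ML factor fit, varimax rotation,
  simplification to the single largest loading per item; the statistic is
  the proportion of off-diagonal correlation sum-of-squares reproduced;
  the estimate is the smallest k attaining the maximum.
* BIC / EBIC: ML factor fits for k = 1..10 (clipped to nonnegative
  degrees of freedom), Bartlett-corrected chi-square
  (n - 1 - (2p+5)/6 - 2k/3) F_ML, BIC(k) = chi2 - df log n, EBIC(k) =
  BIC(k) + 2 gamma q_k log p with q_k = p(k+1) - k(k-1)/2 free
  parameters; argmin over converged fits, ties to smaller k.  The ML
  fits and varimax rotation are delegated to statsmodels.

Every estimate keeps its per-k trace so the decision rule can be
re-applied to the stored statistics (a self-consistency test does this).

## Monte Carlo harness

For each condition and method the harness records accuracy (exact
recovery of M), mean bias error (mean of k_hat - M; positive =
overfactoring) and mean absolute error.  Method failures count as
inaccurate, are excluded from MBE/MAE, and are tallied.  A full-factorial
ANOVA on replicate-level 0/1 accuracy (factors: correlation, sample size,
items per factor, number of factors; all interactions) yields partial
eta-squared = SS_effect / (SS_effect + SS_residual); the balanced design
makes the decomposition orthogonal, and unbalanced input is rejected.
Treating the binary accuracy as a numeric ANOVA outcome mirrors common
practice in simulation studies of this kind.

## Problem sizes and determinism

The shipped acceptance script reruns the study at desk scale: 100
replicates for the single headline condition, 15 replicates per condition
for each 32-condition half-grid, 25 for the MAP subset — all seeded from
one command-line seed, with per-dataset seeds below 2^31.  Full-scale
(500-replicate) runs use the same code path via `egadim study --reps 500`.

## Known limitations

* The generator emulates exactly the idealized conditions above: equal
  loadings, no cross-loadings, no missingness, no guessing/difficulty
  structure.  Passing tests show recovery under those conditions, not
  robustness to violations (non-normal latents, unequal loadings, single
  factors) — the same caveats that apply to any simple-structure
  simulation.
* MAP here is the classical Velicer procedure; on the simulated grids it
  recovers the orthogonal four-factor structures nearly always, and its
  population statistic has a clean minimum at the true dimension.  Other
  software lineages ship MAP variants whose traces differ; users comparing
  against them should compare the traces, which is why traces are stored.
* Tetrachoric estimation at n = 100 with 20+ items is intrinsically noisy
  and usually needs the PSD repair; dimension estimates in that corner are
  the least stable of the grid, for every method.
* Only walktrap is provided as a detector, and only complexity-1 VSS;
  scree heuristics, bootstrap stability, polyserial correlations and
  confirmatory follow-ups are out of scope.
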