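# Methods

## Measures

**Relative node strength.** For a symmetric, non-negative weighted
adjacency matrix `W` with strengths `s_i = Σ_j W_ij`, the uncorrected
relative strength is `r_i = s_i / mean_{j∈N(i)} s_j`. The edge-corrected
form (the default) subtracts the connecting edge from both strengths
inside each neighbour term and inverts the mean ratio:
`r_i = [ mean_{j∈N(i)} (s_j − W_ij)/(s_i − W_ij) ]⁻¹`. The correction
removes the inflation that a single strong reciprocal edge produces in
both its endpoints' strengths; with the subtraction disabled the two
forms coincide exactly. Both forms are invariant under a global rescale
`W → cW`.

Degenerate terms: `s_i − W_ij ≤ 0` can occur only at degree-1 nodes
(whose entire strength is the one connecting edge), and then *every*
term of that node is degenerate, so the corrected measure is undefined
there. The default `skip` policy drops degenerate terms with a warning
and raises when a node has no valid term; `strict` raises at the first
degenerate term. Group-thresholded connectomes are dense enough that
this never triggers in practice; it matters for toy graphs with leaves.

**RSV** is the sample standard deviation (n − 1 denominator) of the
`r_i` over all nodes. The squared value — the variance form — is exposed
as `RSVResult.variance` so both conventions are available; the SD is the
canonical value throughout this package.

**hRSV.** Nodes are sorted ascending by an ordering basis, windows of
`w` consecutive ranks are taken (`n − w + 1` of them, requiring
`w ≥ 2` for the SD), and the within-window sample SDs of `r` are
averaged. Windows slide by *rank*, not by strength-value bands — that
is what makes the window count exact. Ties in the basis are broken by
node label order, deterministically. For cohort analyses the basis is
the cohort-mean strength vector, so every subject's windows cover the
same anatomical hierarchy; for single networks it is the node's own
strengths. At `w = n` there is a single window and the value equals RSV
exactly (the implementation routes that case through the same
estimator, so the equality is bit-exact, not just within rounding).
Default windows are 4 (the statistical-complexity regime: variability
among similar-strength nodes) and 21 (a quarter of an 85-node
parcellation: broad hierarchy bands).

**Tiers.** Nodes rank descending by a strength basis and split into
contiguous blocks whose sizes differ by at most one, larger blocks
first, tier 1 = top strengths (85 nodes → 22/21/21/21). `tier_hrsv`
computes `r` on the full network and slides windows within each tier's
ranked nodes; whether truncated tiers should instead reweight windows is
an open representational choice — this restriction-based reading is
documented rather than claimed canonical.

## Comparison graph measures

* Strength variance: sample variance of `s`. Scales as `c²` under
  `W → cW`.
* Assortativity: the moment-ratio over ordered pairs `(i, j)` with
  `w_ij > 0`, which equals the Pearson correlation between the
  strengths at the two ends of an edge (each undirected edge counted in
  both directions). When all endpoint strengths are equal the ratio is
  0/0; the implementation returns NaN with a warning instead of a
  misleading 0.
* Normalised clustering `γ = C/P`: `C` is the Onnela weighted
  clustering coefficient averaged over nodes, with weights normalised
  by the network maximum and degree-< 2 nodes contributing 0 (the
  standard toolbox convention); `P = 2M/(n(n−1))` is density.
* Routing efficiency: mean inverse weighted shortest-path length over
  ordered pairs, with edge length `ℓ = 1/w` — the dominant connectomics
  convention for strength-like weights, applied uniformly to all
  weightings and recorded in the run parameters. Unreachable pairs
  contribute 0 (disconnection-tolerant by construction).
* Diffusion efficiency: mean inverse mean-first-passage time of the
  weight-proportional random walk (`P_ij = W_ij/s_i`). MFPTs come in
  closed form from the fundamental matrix
  `Z = (I − P + 1πᵀ)⁻¹`, `t_ij = (Z_jj − Z_ij)/π_j`, with stationary
  distribution `π_j = s_j/Σ_k s_k`; a dense solve is cheap at n = 85.
  Disconnected input is refused (MFPTs are infinite) with a pointer to
  largest-component restriction — deliberately asymmetric to the
  routing-efficiency convention, because the 0-contribution trick has
  no analogue for first-passage times.

## Thresholding

An edge survives if its weight is nonzero in at least the stated
fraction of subjects ("at least" inclusive; ≥). One mask is derived
from a designated reference weighting — streamline count when present,
since all weightings of a subject share the streamline-defined edge
support — and applied to every weighting of the same subjects;
`mask_scope="per_weighting"` switches to independent masks where that
assumption is wrong for a dataset. Thresholding is idempotent and
monotone in the threshold.

## Synthetic generators

The network families exist to exercise the measures' contrasting
behaviour at matched size and density (defaults n = 85, density 0.6,
matching a group-thresholded Desikan-Killiany-scale connectome;
lognormal weights with σ = 0.5):

* `er` — G(n, M) random graphs (low RSV, low hRSV);
* `geometric` — unit-square geometric graphs, the M shortest pairwise
  distances kept (exact density control);
* `hetero_geometric` — geometric with Pareto(α = 2) per-node reach:
  pairs ranked by `d_ij/(ρ_i + ρ_j)`, yielding heterogeneous degrees
  (the high-statistical-complexity family);
* `star_like`/`core_periphery` — a 15% hub set whose incident pairs are
  filled first (high RSV);
* `lattice`/`regular` — ring lattices and random regular graphs
  (uniform weights give RSV = hRSV = 0 identically). Densities that no
  even lattice degree can realise within 10% raise an error rather than
  silently drifting.

Cohorts add per-subject multiplicative lognormal weight noise and
Bernoulli edge dropout around a shared base network, plus reproducible
age/sex/site metadata. What these generators do **not** emulate:
spatially embedded anatomy, distance-dependent weight profiles,
hemispheric symmetry, or realistic inter-measure covariance — passing
tests on them demonstrates the measures' mathematical behaviour, not
performance on real connectomes.

The cognitive battery generator draws 10 unit-variance tasks from a
one-factor model `x_j = λ_j g + √(1−λ_j²) ε` with signed loadings
spanning |λ| = 0.42–0.75 (negative loadings mark lower-is-better tasks)
and masks entries completely at random. Real batteries have structured
missingness and task-specific distributions; the transform table hook
(`sign_convention`) is the extension point.

## Cognition: completion and g

Subjects missing strictly more than `max_missing` tasks (default 7 of
10) are excluded. Remaining gaps are filled by alternating truncated-SVD
projection: initialise at column means, project to rank r, restore
observed entries, iterate until the RMS change of imputed cells falls
below `tol` (default 1e-8, relative to the RMS of observed scores) or
`max_iter` (500) sweeps — non-convergence is flagged, not raised.
Observed entries are preserved exactly. The rank defaults to 1 for a
10-task battery; `choose_rank` picks it by cross-validated masked RMSE
over ranks 1–5 when in doubt.

g is the first unrotated principal component of the z-scored battery
(correlation PCA — the tasks are on incommensurate scales), z-normalised;
loadings are the correlations of each z-scored task with g. The
component sign is anchored so the higher-is-better task with the
largest absolute loading loads positively. One caveat the test suite
encodes explicitly: the population loadings of a first principal
component are inflated relative to the generating factor loadings
(most at small |λ|), so parameter-recovery checks compare against the
closed-form population PC1 loadings, not against λ itself, except where
uniform loadings keep the inflation inside the tolerance.

## Incremental variance decomposition

Predictors are ordered by convention priority (covariates — age, sex
dummies, site dummies, in that fixed documented order, since the
procedure is order-dependent — then mean edge weight, then common graph
measures, then the focal measure). Classical Gram–Schmidt runs exactly
as the textbook pseudo-code: sequential projection removal, unit
normalisation, then z-normalisation of all columns; a column whose
residual norm falls below 1e-12 of its original norm raises a
collinearity error naming it. No re-orthogonalisation pass is applied
by default, to stay faithful to the classical procedure; at p ≤ ~10
predictors the orthogonality loss is far below the 1e-10 test bound.

With the outcome z-scored, each orthogonalised column's OLS coefficient
is a standardised beta, its square is that predictor's incremental R²,
and the increments sum to the joint fit's R² (an identity the tests
assert at 1e-10). p-values are the joint-fit t-tests, equivalent under
orthogonality to 1-df sequential F-tests. Association scans residualise
measure and outcome on the covariates and report the residual
correlation as the standardised beta, with Benjamini–Hochberg
adjustment across the scanned family (the FDR procedure is BH by
decision; it is recorded per run).

## Verification battery and problem sizes

`rsvnet replicate` / `scripts/acceptance.py` recompute, per run:
exact identities (machine precision); brute-force oracle equivalence on
1,000 random connected graphs with n ≤ 6, integer weights, minimum
degree 2 (1e-12); Floyd–Warshall routing equivalence (1e-12); a
100,000-walker-per-pair Monte-Carlo cross-check of diffusion efficiency
on a 6-node graph (aggregate within 3 SE); archetype separation and complexity ordering at n = 85,
density 0.6, 100 seeds (win rate ≥ 95/100; one-sided Mann–Whitney
p < 0.01; full-window rank correlation > 0.99); loading recovery at
n = 5,000 (±0.05); rank-1 completion at 20% missingness (RMSE < 1e-6);
Gram–Schmidt orthogonality and the R² decomposition (1e-10); a 500-rep
null simulation of the focal test (size within the binomial 95% band of
0.05); injected effects of 0.3 (±0.02, n = 10,000) and −0.08 (±0.02,
n = 10,000 subjects at 40–85 nodes); and a 50-subject end-to-end
pipeline reproduced byte-identically under a fixed seed. These sizes
keep the whole battery under a minute on one CPU while leaving each
statistical bound comfortably powered.

## Known limitations

* The corrected relative strength is undefined at degree-1 nodes; use
  the uncorrected form for tree-like graphs.
* hRSV window ordering on a single network uses own strengths; two
  networks are only comparable when ranked against a common population
  basis.
* The assortativity NaN convention propagates into measure tables;
  downstream scans skip NaN columns rather than imputing them.
* Generators target density exactly (edge-count construction) except
  lattice/regular, where the nearest feasible even degree is used and
  a > 10% shortfall is an error.
* The completion algorithm is a hard-rank alternating projection;
  nuclear-norm or weighted variants are out of scope.
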