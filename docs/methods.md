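# Methods

This note records the models, numerical choices, and design decisions
behind each component, and what the synthetic-data experiments do and
do not establish about real data.

## Data model

Trait tables carry five morphological traits with explicit scale tags:
rhizome type (categorical, codes 0–3), laminar dissection (ordinal,
0–2), laminar texture (ordinal, 1–3), laminar length (continuous, cm,
> 0), hydathode presence (binary). Values outside the declared domains
are rejected at read time — missing traits are an error, not imputed,
because imputation would silently change every downstream
dissimilarity. Community matrices are binarized on read: all analyses
are presence/absence, so species carry equal weight everywhere.

Plots are pooled into half-open elevational intervals [lower, upper):
[0, 400), [400, 900), [900, 1400), … — the first band is narrower, the
rest are 500 m. Half-open edges guarantee a partition; a plot at
exactly 400 m belongs to the second interval. This boundary convention
is ours; field datasets rarely place plots exactly on a bin edge.

## Morphospace

**Gower dissimilarity.** Equal trait weights (1/5 each). Ordinal traits
are scored on their integer class codes normalized by the declared code
range, not re-ranked within the realized sample — the codes are the
measurement scale, and re-ranking would make dissimilarities depend on
which species happen to be sampled. Continuous traits are normalized
by the observed min–max range (a zero-range trait contributes 0 and is
flagged). Binary traits are treated symmetrically by default (joint
absence counts as similarity); an asymmetric variant is available via
a flag. Laminar length is not log-transformed by default; a flag
exposes the transform. Gower values need not embed in Euclidean space,
so the triangle inequality is not asserted anywhere.

**PCoA.** Classical scaling: double-center −D²/2, eigendecompose, and
scale eigenvectors by √eigenvalue. Negative eigenvalues are discarded
without Cailliez/Lingoes correction, and variance fractions are
reported relative to the positive eigenvalues only; the discarded
count is kept in the result so users can audit how non-Euclidean their
matrix is. Eigenvalues below 10⁻¹⁰ of the leading one are treated as
zero. Requests for more axes than exist return fewer axes with a
truncation flag rather than failing. Coordinates are reproducible only
up to axis sign; tests therefore compare reconstructed distance
matrices, never raw coordinates.

## Diversity indices

All indices operate on an assemblage's rows of the ordination, by
default the first five axes.

- **FRic** (convex hull volume, qhull). When S ≤ k the hull is
  undefined, so the axes are truncated to min(k, S−1) and the
  reduction is recorded per assemblage; affinely degenerate point sets
  return volume 0 with a degeneracy flag rather than raising. For a
  single retained axis the "volume" is the coordinate range.
- **Hyp** (2-axis kernel hypervolume). Gaussian KDE with Silverman
  bandwidth, evaluated on a 200×200 grid spanning the data padded by
  three bandwidths per axis; the reported area is the highest-density
  region enclosing 95% probability mass. Grid refinement changes the
  area by under 2% (asserted in tests). Both the mass threshold and
  the grid are configuration, not science: the published
  kernel-hypervolume algorithm (box kernels, importance sampling) is
  deliberately simplified to a density-contour estimate, which is
  adequate in two dimensions. Caveat: a Silverman bandwidth is
  computed from the global covariance, so widely separated clusters
  inflate the kernel and the estimated area is *not* additive across
  distant modes — a property shared by the covariance-based bandwidth
  estimators in standard hypervolume software.
- **FEve** over the Euclidean minimum spanning tree with equal species
  weights (presence/absence). Coincident points create zero-length
  branches; these contribute zero partial evenness and are handled
  explicitly (the sparse MST drops them, so the branch list is padded
  back to S−1).
- **mNND/sdNND**: each species' distance to its nearest neighbor; the
  standard deviation uses the n−1 divisor. The choice of divisor is
  internal-consistency only — observed and null values use the same
  estimator, so the SES is unaffected.

## Trait-shuffle null model

The null randomizes species labels on the trait table: community
membership, richness patterns, and the pool's trait co-variance are
untouched. One global permutation is drawn per replicate and shared by
every assemblage in the pool, preserving cross-assemblage structure.
The label pool defaults to each transect's realized species set
(matching per-transect analyses) and can be switched to the global
table. Classical community-matrix swap algorithms are intentionally
not implemented: the randomization here acts on the trait table.

Because Gower + PCoA depend only on trait rows, a label shuffle is
exactly a row permutation of the observed ordination; the ordination
is computed once and nulls are generated by index permutation. The
test suite verifies this equivalence against the literal
recompute-from-shuffled-traits route, and the mNND/sdNND nulls are
evaluated vectorized from a precomputed distance matrix.

SES = (obs − null mean)/null sd. A null whose spread is zero up to
summation order (an assemblage containing the entire pool) flags the
SES as undefined. The two-sided p counts the observation into both
tails, so p ≥ 2/(n_reps+1) > 0. Replicate permutations are drawn
serially from a single seeded generator; runs are deterministic given
the seed (there is no parallel execution that could reorder draws).
Default replicate counts are 5,000 (500 for Hyp, which is far more
expensive); the pipeline driver and examples use smaller counts, noted
inline, chosen so a full run completes in seconds to minutes.

## Phylogenetic signal

Blomberg's K uses the Brownian covariance matrix V (shared root-to-MRCA
path lengths): with phylogenetic mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1),

    K = [(x−â)ᵀ(x−â) / (x−â)ᵀV⁻¹(x−â)] / [(tr V − n/(1ᵀV⁻¹1))/(n−1)]

K is invariant to affine trait transforms and equals 1 in expectation
under Brownian motion (verified by simulation; the implementation also
matches picante's `Kcalc` to 6 significant figures on shared input).

Significance comes from shuffling tip labels and comparing the
variance of standardized independent contrasts: low observed variance
relative to the null indicates signal. Contrasts are linear in tip
values for fixed topology and branch lengths, so the Felsenstein
pruning recursion is run once to produce a coefficient matrix and the
whole null distribution is a single matrix product. Both tail
probabilities are reported (signal and overdispersion) because a
near-zero K with a "significant" test can mean either tail depending
on the convention; users see both. Polytomies are resolved arbitrarily
with zero-length branches before contrast computation; a constant
trait short-circuits to p = 1 (every contrast is exactly zero,
observed and null). Signal is tested on PCoA axes 1 and 2 by default,
each axis separately.

## Packing vs expansion

Adjacent interval pairs are oriented richer → poorer walking from each
elevational extreme toward the richness peak. Pairs with no richness
change are emitted with status `none`; richness decreases against the
walking direction are `inverted` and not decomposed.

The decomposition seeks the maximum-cardinality subset of E1 whose
hull volume is ≤ V2·(1+tol), tol = 0.01 by default ("equivalent or in
a vicinity" is a tolerance band; the width is configuration).
Expansion = species removed, packing = retained − S2; the two sum to
ΔS by construction. Axes are shared at k = min(k_config, S2−1) so both
hulls are defined. Packing can be negative when E2's species are not
nested inside E1's occupied region; this is flagged, not clamped,
since turnover between bands is real data behavior.

The search is a multi-start randomized greedy: repeatedly delete the
hull vertex whose removal most reduces volume, immediately accepting
any removal that satisfies the ceiling; with small probability an
arbitrary hull vertex is removed instead (escaping configurations
whose optimum is a thin, near-degenerate subset), and a final
augmentation pass re-adds removed species that still fit. The best of
n_starts runs is kept. On 200 random 2-D instances with S1 ≤ 12 the
result is within one retained species of exhaustive search (asserted
in tests); exact optimality is not claimed — the problem is a
combinatorial volume-constrained subset search.

## Richness estimation and model comparison

Chao2 (incidence form, plots as sampling units), bias-corrected:
S_chao = S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1)). With fewer than two
plots the estimator returns S_obs with an insufficiency flag.
Downstream analyses always use observed richness; the Chao layer is a
sampling-completeness diagnostic (obs-vs-est OLS R²).

The model-selection layer operates on fitted-model summaries
(log-likelihood, parameter count, variance components): AICc, Akaike
weights, summed-weight importance over the ΔAICc < 2 set (weights
renormalized within the retained set by default; the raw convention is
a flag), mean marginal R² over retained models, and
Nakagawa–Schielzeth R². Mixed-model fitting itself is statsmodels
(`MixedLM`, ML not REML so likelihoods are comparable across
fixed-effect structures); the fixed-effect variance for marginal R² is
the variance of the fixed-effects linear predictor. The packing ~ log
richness contrast is a binomial GLM on packing fractions with the
pair's richness surplus as weights, tested by likelihood ratio χ²(1).

## Synthetic data generator

The generator reproduces the statistical structure the analyses
assume, at the scale of one field campaign: a pool of 100 species per
transect, 500-m intervals with four plots each, and a Gaussian
richness hump (10 at the extremes to 40 at mid-elevation — richness is
*imposed* per interval, not emergent, because the scientific questions
condition on richness). Trait marginals are fixed at plausible
fern-flora frequencies (e.g. 70% of species without hydathodes;
log-normal laminar lengths with median 30 cm truncated to 1–600 cm).
Phylogenies are constant-rate pure-birth trees with pendant edges
extended by the exponential time to the next unobserved event (the
simulator otherwise stops exactly at the n-th birth, leaving a
zero-length cherry and a singular covariance matrix); traits evolve by
Brownian motion from root value 0.

Environmental filtering interpolates assembly weights between uniform
(φ = 0) and a Gaussian trait–elevation match kernel of width τ
(φ = 1, τ = 250 m default, 100 m for "strict sorting"). Each species'
optimal elevation is its rank position on the *first principal
coordinate of the trait Gower matrix*, mapped onto the elevation span.
We tie the latent to the dominant morphospace axis rather than to a
subset of traits deliberately: filtering on one or two raw traits
leaves the remaining axes randomly assorted, and even strict sorting
then produces almost no nearest-neighbor clustering in the full
five-axis space — the filtering signature would be undetectable by
construction, not by biology. With the dominant-axis latent, strict
sorting yields mean SES(mNND) ≈ −3.3 and ~88% detection at |SES| >
1.96, while φ = 0 worlds remain exactly null-calibrated (mean SES
≈ 0, sd ≈ 1, ~5% rejection).

What the generator does *not* emulate: dispersal limitation,
speciation/extinction dynamics, abundance structure, intraspecific
trait variation, spatial autocorrelation among plots, or realistic
climatologies (climate covariates are smooth deterministic curves plus
noise). Passing calibration on these worlds shows the statistical
machinery is correct under its own assumptions; it does not show that
real assemblages satisfy those assumptions.

## Problem sizes and determinism

Default experiment sizes — 200 worlds × 999 permutations for SES
calibration, 500 Brownian simulations for K, 400 × 199 shuffles for
the test's type-I rate, 200 instances for the packing oracle — were
chosen as the package's standard validation batch; the full suite and
the acceptance script each run in a few minutes on one CPU. Every
stochastic component takes an explicit seed or generator;
`run_pipeline` writes all outputs with fixed float formatting and is
byte-identical across reruns with the same seed.

## Known limitations

- Hyp is limited to two axes and a grid contour; no n-dimensional
  kernel hypervolume.
- No abundance-weighted index variants.
- The packing search is heuristic (bounded against the oracle, not
  exact), and its "grid search" interpretation — species removal to a
  volume ceiling — is one reading of a procedure whose published
  description leaves the objective underdetermined.
- Chao2 variance/confidence intervals and rarefaction curves are out
  of scope.
- Mixed-model R² uses the Nakagawa–Schielzeth variance decomposition
  for random-intercept Gaussian models only.
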