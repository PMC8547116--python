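# Methods

This note documents the statistical models the package implements, the
choices made where the methods literature leaves latitude, and what the
synthetic-data generator does and does not emulate.

## Genotype model and containers

Genotypes are diploid codominant calls — two integer allele sizes (base
pairs) per individual per locus — with 0 as the missing sentinel and a
both-or-neither rule for missing alleles within a call. All statistics
operate on non-missing gene copies, so sample sizes vary per
(population, locus) cell. GenePop input is restricted to the 3-digit-per-
allele dialect; 2-digit files are rejected with an explicit message rather
than guessed at.

## Diversity statistics

* **Hₒ** is the fraction of genotyped individuals carrying two distinct
  alleles.
* **Hₑ** uses Nei's unbiased small-sample correction
  n/(n−1)·(1 − Σp²) over n observed gene copies, clipped to [0, 1];
  cells with fewer than 2 gene copies are undefined (NaN) rather than zero.
* **Rarefied allelic richness** is the exact hypergeometric expectation
  AR(g) = Σₐ [1 − C(n−nₐ, g)/C(n, g)] of the number of distinct alleles in a
  subsample of g gene copies. The default g is the smallest non-zero
  (population, locus) gene count — the convention of the common R
  implementations — so every defined cell is comparable. Cells with fewer
  than g copies are excluded from the per-population mean with a NaN.
* **Garza–Williamson M** = k/(r+1) with the allele-size range r expressed in
  repeat units. Repeat units are a user input (they are locus chemistry, not
  inferable from the data); the synthetic generator uses 2 bp throughout.
  Sizes that are not a whole number of repeat units apart raise an error
  naming the locus, because a silent floor would shift M.
* **F_IS** is the Weir–Cockerham within-population f computed from the
  (b, c) variance components summed over alleles and loci — the
  ratio-of-sums, not a mean of ratios. This matches the variance-components
  framework used for θ̂ below; the alternative 1 − Hₒ/Hₑ moment estimator
  differs at small n. Confidence limits are percentile intervals from 1000
  bootstrap resamples of loci (the only exchangeable unit available for a
  single population), and the two-sided p-value is the bootstrap tail
  probability of f crossing zero with the add-one rule. With one informative
  locus the point estimate is reported with NaN limits.

## Hardy–Weinberg and linkage tests

The HWE test is an exact conditional test with the probability-based
rejection region (Fisher-style: the p-value sums the probabilities of all
tables no more probable than the observed one under Levene's distribution).
Biallelic loci with ≤ 50 individuals are fully enumerated over heterozygote
counts. Otherwise a Markov chain is run over the assignments of the 2n
allele copies to the 2n gamete positions: a step swaps two uniformly chosen
positions and is always accepted, which makes the chain uniform over
arrangements and the induced genotype tables exactly Levene-distributed — no
Metropolis correction is needed, and the estimator is simply the fraction of
visited states at or below the observed table's probability (default 10⁶
steps). The chain starts at the observed table; no burn-in is applied, which
biases the p-value upward by at most a few steps' worth of correlation and
is invisible at 10⁶ steps (agreement with full enumeration is ~10⁻³).

Linkage disequilibrium between locus pairs uses the log-likelihood-ratio G
of the joint two-locus genotype table, with a null built by permuting one
locus's genotypes across individuals within the population (add-one
p-values; pairs with < 5 jointly genotyped individuals are skipped).

## Pairwise differentiation

θ̂ follows the Weir–Cockerham method-of-moments derivation for two
populations with unequal sample sizes: per locus and allele, components
a (among populations), b (among individuals within) and c (within
individuals) are computed from allele frequencies, heterozygote frequencies,
n̄ and n_c; the multilocus estimate is Σa/Σ(a+b+c). Negative estimates are
reported as-is and deliberately not clamped before the Rousset
linearization θ̂/(1−θ̂), which is monotone for θ̂ < 1 and therefore
preserves the rank information the permutation tests use. θ̂ = 1 (fixed
differences) makes the linearized distance infinite and raises an error
naming the pair.

## Geographic and resistance distances

Coordinates are projected with a **spherical** transverse Mercator (central
meridian −51°, scale 0.9996, false easting 500 km, false northing
10 000 km — the UTM 22S convention). The spherical-vs-ellipsoidal error is
a few parts in 10⁴ at these latitudes, far below the raster discretization
error, and keeps the projection dependency-free; the forward/inverse pair
round-trips to 10⁻⁶ degrees.

Least-cost distances are shortest paths (Dijkstra on a sparse graph) over a
conductance raster with 8-neighbour connectivity. The step cost between
adjacent cells is the great-circle distance between their centres divided by
the mean conductance of the two cells, so a uniform conductance-1 raster
returns metres. The octile metric overestimates straight-line distance by at
most 8.24 % (bearings 22.5° off-axis); tests assert this bound. Two raster
models mirror standard practice: *continuous* (all cells 1, water included —
the null model) and *water bodies* (land 1, water nodata, i.e. an absolute
barrier). A population on a nodata cell is an error by default; `snap=True`
assigns the nearest passable cell and logs the offset, because silent
snapping changes distances invisibly.

### Wind connectivity

Wind input is a time series of (speed m/s, meteorological direction) raster
pairs; direction is the bearing the wind blows FROM, converted to the
blowing-toward bearing with +180°. For the directed edge i→j with bearing φ
and the wind at the source cell blowing toward θ at speed s, the conductance
is

    g = max(ε, β·s, s·cos(θ − φ)),   ε = 10⁻⁴ m/s,  β = 0.05.

Tailwinds help in proportion to speed; head- and cross-winds retain a
residual mobility of β times the local speed, with the absolute floor ε only
for calm air. The residual term is this package's own modelling choice, and
it matters: with an absolute floor alone, the adverse direction of **every**
pair costs distance/ε, which dominates the arithmetic slice average, so the
time-averaged symmetrized matrix degenerates to a constant multiple of plain
path distance and wind strength carries no information whatsoever. β = 0.05
says dispersal against the wind is twenty-fold harder than with a direct
tailwind of the same speed — strong anisotropy that still lets local wind
speed shape the symmetric matrix. Passing `adverse_fraction=0` recovers the
pure-floor behaviour.

Per-slice directed least-cost matrices are averaged arithmetically over the
time series (costs, not conductances), and the symmetrization (M + Mᵀ)/2 is
what Mantel/MMRR consume, since those tests require symmetric inputs; the
directed average is also returned for inspection.

## Matrix tests

Both tests vectorize the lower triangle (i > j). The **Mantel** statistic is
the Pearson correlation of the two triangles; the null jointly permutes the
rows and columns of Y (10 000 permutations by default, add-one p, upper tail
by default). **MMRR** regresses the response triangle on predictor triangles
with an intercept; each permutation re-labels the response matrix and
recomputes every t and the overall F, with two-sided p-values on |t|.
Permuting the response only (not the predictors) is the published procedure
for regression on distance matrices. Tie handling uses ≥ with a 10⁻¹²
tolerance, which is conservative. With a single predictor, MMRR's R² equals
the Mantel r² exactly (same triangles), a relationship the tests assert to
10⁻¹⁰. Predictor triangles correlated above 0.999 raise a collinearity error
naming the pair; the IBD/IBE suite converts that error into a flagged report
row instead of aborting (a perfectly linear climate gradient along a linear
coast *is* collinear with distance).

The suite runs, with linearized θ̂ as response: the Mantel IBD test against
log-transformed geographic distance (the log follows lattice-model theory
for one-dimensional habitats); single-predictor MMRR per resistance model;
MMRR per climate variable with raw geographic distance as covariate (raw,
because regression coefficients per metre are the interpretable scale; a
`log_geo_mmrr` switch exists); and single-predictor MMRR for the symmetrized
wind matrix. Wind-versus-distance comparisons are made between the two
single-predictor fits (compared on |t|), not inside one joint model, because
the wind matrix remains strongly distance-like by construction.

## DAPC

Allele dosages (0/1/2 copies per allele column) are mean-imputed at missing
calls, centred, and transformed by PCA with all components retained for
clustering. k-means (10 restarts) is scored by
BIC(k) = n·ln(WSS_k/n) + k·ln(n). On discrete dosage data this curve has a
long, slowly decreasing tail — additional clusters keep isolating
single-locus genotype classes and rare-allele carriers, each worth slightly
more than the k·ln(n) penalty — so the raw argmin systematically
over-splits. The default selection criterion (`"diffNgroup"`, following the
reference implementation of the method) therefore Ward-clusters the
successive BIC differences into a sharp-drop group and a plateau group and
keeps the last k of the sharp-drop group; `criterion="min"` gives the plain
argmin. The discriminant step then uses a reduced number of PCs chosen by
the a-score (observed reassignment rate minus its permutation expectation,
10 label permutations per candidate), guarding against discriminant
overfitting.

## sPCA

Individuals get their population's coordinates plus Gaussian jitter
(sd 0.2°, seed-controlled) so co-located samples are distinct nodes of the
connection network (k-nearest-neighbour, Gabriel, or distance-band;
row-normalized). The analysis eigendecomposes C = Xᵀ H X / n with H the
symmetrized weight matrix, which makes each eigenvalue exactly
var(score)·I(score) — asserted to machine precision. Positive eigenvalues
capture global structure (clines, patches), negative ones local
(neighbour-contrast) structure. The global/local Monte-Carlo tests use the
largest positive eigenvalue and the largest-magnitude negative eigenvalue as
statistics, permuting genotype rows against locations (add-one p). This
max-eigenvalue statistic is a simplification of the spectral-ratio statistic
used by the method's reference implementation; it targets the same
alternative and calibrates correctly under the null in our tests. The knn k
must be large enough to bridge jittered population clusters (k of at least
the largest co-located sample size; the pipeline default is 20, and 25–30
suits the study-shaped layout).

## Synthetic scenarios

The generator is a forward-time drift–migration recursion on population
allele frequencies: p′ = M·p (row-stochastic mixing matrix M) followed by
multinomial resampling of 2N gene copies per deme, then Hardy–Weinberg
sampling of diploid individuals, allele indices mapped onto a 2-bp size
ladder, and missing calls dropped independently (rate 0.02 by default).
Defaults: deme size N = 200, total migration 0.05 per generation, 200
generations, 10 loci with 7–17 alleles drawn from a flat Dirichlet ancestral
frequency. Scenario graphs: island (all pairs), stepping-stone (chain along
the coast axis), barrier (one chain link at 10⁻³ of its rate, matching a
lagoon channel that severs the water-bodies raster), wind-biased (chain with
downwind migration following the local wind-speed profile and upwind at a
quarter of it), environment-driven (migration proportional to environmental
similarity exp(−|Δe|/2) between all pairs, with an alternating high/low
environment so environmental distance is nearly orthogonal to geographic
distance), and study-shaped (15 populations with the coastal study's sample
sizes and coordinates: 253 individuals, chain migration 0.02, 300
generations).

Landscapes are a ~6° (≈600 km) coastal strip at 0.09° resolution with an
elongated interior lagoon (population cells are always kept on land, as
sampling sites are lakeside); wind slices share a mean meteorological
bearing of 45° (from the NE, blowing SW) with per-slice speed and direction
noise; the climate surface linearly interpolates the per-population
environment along the coast axis plus cell noise.

What the generator does **not** emulate: microsatellite mutation (stepwise
or otherwise — allele ladders are static, so Garza–Williamson values reflect
drift-induced allele loss only), selection, overlapping generations, spatial
structure within demes, null alleles, allele dropout and genotyping error.
Passing tests therefore demonstrate estimator and inference correctness
under drift–migration ground truth, not robustness to the technical
artefacts of real microsatellite data.

## Verification problem sizes

The verification suite uses sizes chosen to make each property sharp yet
quick: exhaustive-path oracles on grids up to 4×4; type-I calibration with
500 replicate pairs of independent 15-label distance matrices at 999
permutations; island-model recovery with 8 demes of N = 100 at m = 0.01
(expected θ̂ ≈ 1/(1+4Nm), tolerance 30 % — the closed form ignores the
finite-island correction and sampling noise); 50 stepping-stone runs for IBD
detection; 10 runs each for the wind and environment scenarios; and a
study-shaped pipeline smoke run at 199 permutations for byte-identical
determinism. `scripts/acceptance.py` recomputes all of these from a single
seed.

## Known limitations

* Wind conductance is a phenomenological definition (see above), not a
  mechanistic dispersal kernel; β is not calibrated to any species.
* The Mantel test inherits the general caveats of distance-matrix
  correlation under spatial autocorrelation; the suite mitigates but does
  not eliminate them by reporting MMRR alongside.
* DAPC's BIC curve on dosage data rarely has a clean minimum; the
  sharp-drop criterion is a heuristic and k should be read together with the
  curve itself (`bic_` is exposed for that reason).
* Least-cost distances depend on raster resolution through the octile
  bound; matrices from different resolutions should not be mixed.
* The GenePop reader assigns sequential population names (`pop_1`, ...);
  coordinates arrive separately via CSV and are joined by those names.
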