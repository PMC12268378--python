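# Methods

This note documents the statistical machinery implemented in `airineq`,
the design choices that were genuinely open, and what the synthetic
province does and does not emulate.

## Exposure

`exposure.decay_adjust` implements the distance-decay adjustment of the
concentration surface as a kernel mean over all cells whose centers lie
within a buffer distance of the target cell (default 1 km, matching the
1-km grid). The functional form of a "distance decay factor" is not
canonical; we read it as a neighbourhood aggregation that folds nearby
pollution sources into each pixel, make the kernel explicit, and offer
two: `uniform` (default) and `inverse_distance` with weight
1/(d + cell/2), finite at the center. A zero buffer is the identity.
Nodata cells are excluded from every kernel and stay nodata. For the
uniform kernel on a 1-km grid the buffer covers a cell and its four
rook neighbours, so a unit spike spreads to 1/5.

`compute_ape` is the population-weighted mean of the decayed surface
over the county's pixels (pixel-center zonal assignment). Counties with
zero total population are reported as undefined (NaN plus an explicit
list), never silently dropped or zeroed: the weighted mean does not
exist there. The combined-pollution indicator sums the three PM
surfaces; the decay adjustment is applied per pollutant before summing,
which for linear kernels is identical to decaying the sum.

## Inequality

`inequality.spatial_gini` evaluates exactly
Σ_ij w_ij |x_i − x_j| / (2N²x̄) with binary symmetric w. Two properties
matter in practice and are enforced by tests: it is invariant to
positive rescaling of x, and it is bounded above by the classical Gini
(complete w) since the numerator sums over a subset of pairs. A
consequence of the 2N² normalisation worth knowing: at fixed surface
roughness the statistic shrinks roughly like 1/N as the number of
sub-units grows, because adjacent pairs grow linearly while the
denominator grows quadratically. SGI values are therefore comparable
across counties of similar pixel count, and should be read as a
relative, not absolute, inequality scale.

SGI is computed within each county over its pixels (rook adjacency by
default, queen optional), on the decayed concentration by default; a
configuration switch computes the population-weighted variant
(x_i = P_i·C_i^d, inequality of *exposure* rather than of
concentration) and reports both. One-pixel counties get SGI = 0;
all-nodata counties are flagged undefined.

`dissimilarity_index` uses the low-income count P_i against the *total*
tract population Q_i. Under this denominator convention complete
segregation yields DI = 1 − P/Q, not 1; DI → 1 only as the low-income
share becomes small. Counties with no low-income individuals are
flagged undefined.

## Urban form

The local coefficient treats k_i as POI *shares* (counts normalised to
proportions): with raw counts the 1/N reference term is dimensionally
meaningless and the statistic unbounded. V = kᵀDk uses tract-centroid
Euclidean distances in the projected plane, self-distance 0.

V_max is the true maximum of the quadratic form over the probability
simplex. (The common verbal description — POIs "optimally distributed
in a single central location" — describes the *minimum*: a point mass
gives V = 0.) For up to 12 tracts the maximum is found exactly by
support enumeration: the optimum lies in the relative interior of some
face, where stationarity gives D_S s = μ1; every support is tried and
infeasible or singular systems are skipped (a singular face's optimum
is attained on a sub-face, which the sweep also visits). Above 12
tracts, multi-start projected gradient ascent seeded at the uniform
point, every pairwise split and random draws; the best two-point value
max_ij D_ij/2 is always a lower bound. Note the maximiser is often
interior: for three equidistant tracts the barycenter attains 2d/3,
strictly above any pairwise split's d/2. Identical tract templates
share one cached maximisation.

Densities are counts (or totals) divided by county area in km². The
conversion-pressure index is the fuzzy sum (probabilistic OR)
1 − (1−HM2030)(1−DSI); only the combination operator is in scope — its
ingredient surfaces are synthetic inputs.

## Driver analysis

Indicator assembly is an inner join on county id; counties lost to any
undefined metric are logged by name. The log transform applies the
natural log to exactly {GDP, poi_density, pop_density, MAP, SAP, VC} —
the columns whose scale dwarfs the rest — with zeros offset by half the
smallest positive value in the column (warned). Bivariate OLS reports
the exact R², the two-sided slope p-value and a 90% confidence
interval, the interval convention used throughout.

PCA operates on the correlation matrix of the standardised indicators
(mixed units make covariance-PCA meaningless); APE and SGI are never
PCA inputs, only regression targets for the component scores. The sign
convention makes each component's largest-|loading| entry positive, so
a "development density" component points toward denser counties.

## Partial-correlation networks

The network over the target (APE or SGI) plus the twelve indicators is
a Gaussian graphical model estimated by graphical lasso on the Pearson
correlation matrix of the standardised (log-transformed) columns, along
a λ path log-spaced over two decades from λ_max (the largest absolute
off-diagonal correlation, the smallest penalty giving the empty graph)
with 100 steps by default. Model selection minimises

    EBIC(λ) = −2·loglik(Θ̂_λ) + E·log n + 4·E·γ·log p

with loglik = (n/2)(log det Θ − tr(SΘ)), E the selected edge count and
γ = 0.5 (γ = 0 reduces to BIC; larger γ never yields a denser
selection). EBIC is evaluated at the penalized estimate itself —
standard EBIC-glasso practice — rather than at a refit restricted MLE;
the penalized variant is known to admit somewhat denser graphs when
partial correlations are strong, which is visible in the chain-recovery
tests at high edge strength. Edges are structural zeros of the selected
precision matrix, not thresholded partial correlations; reported
weights are pcor_ij = −Θ_ij/√(Θ_ii·Θ_jj). The per-λ solves use
scikit-learn's graphical-lasso solver with a 200-sweep cap; lambdas
that hit the cap are reported in one consolidated warning (duality gaps
there are near tolerance and do not move the EBIC minimum in our
tests). At vanishing penalty the partial correlations agree with
direct precision-matrix inversion to 1e−3, a dual-route check in the
test suite.

Node strength is Σ|pcor| over incident edges and expected influence the
signed sum. The bootstrap reports per-edge inclusion frequencies over B
case-resampling replicates (B ≥ 100) and centrality stability as the
mean correlation of subsample strength vectors with the full-sample
strengths at case-dropping proportions {0.1, 0.25, 0.5}; replicates
with a degenerate constant column are redrawn with a cap of 10.

## The synthetic province

The generator is the package's test bed: a rectangular lattice of
square counties (default 10×10 counties of 10 km, 1-km cells, 16 tracts
each) whose data streams all derive from one seed through fixed
sub-stream seeds, so adding a stream never perturbs the others.

**Concentration.** log-Gaussian surfaces sharing one latent field with
exponential covariance (range 25 km by default; exact Cholesky up to
2500 cells, circulant embedding with clipped negative eigenvalues
above), scaled by fraction base levels 21/33/54 μg/m³ so PM1 < PM2.5 <
PM10 cell-wise.

**Latent county factors.** Two independent unit-variance factors over
the county lattice, themselves spatially smooth (range 12 km): F1
"development density" drives population scale, POI and road counts,
temperature (MAT = 19 + 1.2·F1 + ε °C) and depresses NDVI; F2 "economic
activity and segregation" drives GDP, the conversion-pressure
ingredients and the per-county segregation intensity. Spatial
smoothness keeps neighbouring counties similar, as in a real province,
which matters because county-border steps in the concentration surface
would otherwise leak into the adjacency-based SGI. The 12-km range is a
compromise: long enough for smooth borders, short enough that a 10×10
province still contains many effectively independent counties.

**Population.** Log-normal marks (μ = 5, σ = 1 per 1-km cell) times a
per-county Gaussian density peak whose sharpness interpolates with
`centrality_level`, times exp(0.8·F1).

**Income.** County low-income share near one half ("below the median
income"); tract allocation is a convex mixture of the proportional
allocation and the fully packed allocation with weight equal to the
county's segregation intensity s_c. DI(s) is exactly 0 at s = 0 and
convex, hence monotone, in s. Counts are real-valued: the DI does not
need integers, and rounding would break the exact s = 0 limit.

**POIs and roads.** POI counts are Poisson with rate proportional to
county population times independent log-normal noise (log-sd 0.4 — kept
deliberately so POI density is not a copy of population density);
positions mix a uniform component with a Gaussian cluster at the county
center (sd 1 km) with weight given by the county's centrality. Road
counts are proportional to population with log-normal noise.

**Planted effects.** Log county-mean concentration is tilted by
Σ_k β_k·z(covariate_k) + noise (default β: pop_density +0.3, MAT +0.3,
NDVI −0.3; noise sd 0.1), with z-scores taken on the log scale for the
heavy-tailed covariates — the scale on which the driver analysis
operates. The tilt field is blurred with a 2-km Gaussian so the surface
stays continuous across county borders. Within-county inequality is
planted separately: a short-range roughness field (range 3 km, log-sd
0.35) enters with per-county amplitude 0.5 + 2·s_c and the log-normal
Jensen term removed, a mean-preserving spread. County-mean exposure and
within-county inequality are therefore controlled by independent
factors, which is exactly the decoupling property the acceptance tests
verify.

**What the generator does not emulate.** Real coastline/terrain
geometry, irregular county shapes and sizes, measurement error in the
concentration product, temporal structure, and any dependence between
the environmental covariates beyond the two-factor structure. Passing
tests demonstrate that the pipeline recovers known structure under
these idealised conditions; they do not certify recovery under real
spatial confounding. SGI magnitudes in the synthetic province (~1e−3)
are much smaller than values computed over counties with few, coarse
sub-units, as expected from the 1/N behaviour discussed above.

## Problem sizes and numerics

Default analyses run on the 10×10-county province (100×100 grid, 1 600
tracts); Monte-Carlo recovery checks use 50–100 replicate seeds for OLS
and PCA properties and 50 seeds for the network edge property, sizes at
which every planted sign is recovered with margin. Grid oracles for
V_max use a 1/250-resolution simplex lattice (grid undershoot O(h²) ≈
1e−4). The correlation-at-lag test for the random field allows ±0.15
around exp(−1), the Monte-Carlo scatter of a single 100×100
realisation. All tolerances on hand-computed index values are exact to
double precision except where stated.

## Known limitations

* No reprojection: inputs must already share one equal-area, km-unit
  projection; the GeoTIFF reader validates georeferencing tags but not
  CRS semantics. Vector input is GeoJSON only.
* SGI inference (standard errors, decompositions) is out of scope.
* The EBIC is computed on the penalized estimate (see above); users
  wanting Foygel–Drton refit-EBIC selection will get sparser graphs
  than this implementation on strong-edge data.
* The bootstrap refits with a shortened λ path (≤ 50 steps) for
  tractability; edge frequencies are insensitive to this in testing,
  but exact λ selections may differ from the full-path fit.
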