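# Methods

`lanterneye` implements the computational chain used in quantitative visual
ecology of deep-sea fishes: stereological estimation of photoreceptor
numbers from retinal wholemounts, kernel-smoothed topographic density maps,
optical-sensitivity calculations for extended and point light sources, and
phylogenetic comparative statistics. Every stage can be exercised
end-to-end on synthetic inputs with known ground truth; this note records
the models, the defaults, and the choices made where the methodology left
room.

## Stereology (optical fractionator)

A flattened wholemount is a single section (ssf = 1) holding a single rod
layer (tsf = 1), so the only sub-sampling is areal: counting frames of
`frame_w x frame_h` um placed on a systematic `grid_dx x grid_dy` um grid
with a uniform random start. The total estimate is

    N = sum(Q_i) / (ssf * asf * tsf),    asf = frame area / grid-cell area.

The reference design is a 10x10 um frame on a 320x320 um grid
(asf = 1/1024), which yields ~200 sites on a 17–21 mm^2 wholemount. `1/asf`
is held as an exact rational, so on integer counts the estimate is exact
integer arithmetic (e.g. sum(Q) = 8970 gives exactly 9,185,280).

**Schaeffer CE.** The coefficient-of-error formula behind stereology suites
is rarely printed; we use the simple-random-sampling ratio-estimator form

    CE = sqrt(s^2 / n) / qbar

(qbar the mean per-site count, s^2 the n−1 sample variance). On Poisson
counts with mean ~50 at n ~ 200 this gives CE ~ 0.01, consistent with the
0.024–0.060 magnitudes reported for real retinas, and well below the 0.1
acceptability rule. Alternative systematic-sampling variance estimators
(Gundersen–Jensen style) give different values on identical counts; this
package deliberately uses the simplest defensible estimator and documents
it, rather than guessing which variant a particular software release used.

**Counting rule.** Sites are retained when the frame centre lies inside the
outline, and a point is counted if inside the half-open frame
[x, x+w) x [y, y+h). The unbiased-counting-frame forbidden-line rule is not
modelled: at simulation level counts are drawn from the field directly, so
the rule has no bite.

**Densities.** Mean density is the unweighted mean of per-site densities
`Q_i / frame area` over interior sites (edge frames are not area-corrected);
peak density is the maximum site density, reported both raw and rounded to
the nearest 10x10^3 mm^-2 (the granularity used in published tables). Note
that the site-level peak is upward-biased by counting noise; the smoothed
map peak (below) is the stabler summary.

## Topographic maps

Site densities are interpolated onto a raster by a normalised
(Nadaraya–Watson) Gaussian kernel:

    map(c) = sum_i w_i d_i / sum_i w_i,   w_i = exp(-||c - s_i||^2 / 2 sigma^2)

with bandwidth `sigma` equal to the sampling grid step by default — the
convention of the kernel-smoothing workflow these maps follow. Cells
outside the outline are masked, and normalisation uses in-mask sites only,
which keeps edge cells unbiased. A normalised smoother (rather than an
unnormalised intensity estimate) returns density units directly and is
bounded by the observed site densities, a property the tests assert.

Raster resolution defaults to 256 cells along the longer bounding-box axis;
map summaries move by well under 1% between 128 and 512. Contour levels
default to six equal steps between the in-mask minimum and maximum.
Specialisation shape is reported only as descriptive geometry (does the top
iso-density band form an annulus? where is the peak?), not as an automatic
classification.

## Optical sensitivity

Extended sources (downwelling spacelight), per photoreceptor, in um^2 sr:

    S = (pi/4)^2 (d/F)^2 (1 - e^{-k l})

Point sources (a bioluminescent flash of E photons at range r), in photons:

    N = E (A^2 / 16 r^2) e^{-alpha r} (1 - e^{-k l})

Fixed constants: k = 0.035 um^-1 (vertebrate-average pigment absorption),
E = 1e10 photons, r = 1 m, alpha = 0.05 m^-1. Matthiessen's ratio
(f = 2.55 x lens radius) pins F = f/A at 1.275 for any fish lens, making S
independent of eye size while N grows as A^2. Unit discipline: A and r are
converted to metres inside the geometric term; k·l is computed in um.

Caveats inherited from the method itself: the lens diameter proxies the
pupil (aphakic gaps are not modelled); S is per-receptor, so true scene
sensitivity is set by rod-to-ganglion-cell convergence (`summation_ratio`
expresses this, e.g. 2286e3 / 7.4e3 ≈ 309:1); N ignores background
spacelight, which in reality limits point-source detection range.

## Phylogenetic comparative statistics

**Tree preparation.** Polytomies (consensus trees resolved only to genus
level) are resolved randomly: each multifurcation repeatedly joins two
uniformly chosen children under a new 1e-6-length branch; the convention is
100 random resolutions with 10 selected for analysis and cross-checked for
consistency. Branch lengths then come from Grafen's transform with
rho = 2.5: node height proportional to (descendant tips − 1), normalised to
root height 1, raised to rho; the result is ultrametric with unit tip
height. Continuous morphometrics are log10-transformed before analysis.

**Pagel's lambda, continuous.** V(lambda) multiplies the off-diagonal of
the Brownian covariance V by lambda. The MVN likelihood with mean mu·1 and
covariance sigma^2 V(lambda) is profiled: mu and sigma^2 in closed form
(GLS mean, mean squared Mahalanobis residual), lambda by a 41-point grid
followed by bounded scalar refinement (tolerance 1e-6), with the boundary
values always evaluated — lambda likelihoods are frequently bimodal near 0
and 1, and the grid-plus-refine scheme agrees with a 1e-3 grid oracle to
2e-3 in the tests. On ultrametric trees V(lambda) = lambda V + (1−lambda) h I
shares V's eigenvectors, so one eigendecomposition makes each likelihood
evaluation O(n^2); non-ultrametric inputs fall back to a Cholesky per
evaluation.

**Pagel's lambda, discrete.** Binary traits use a symmetric 2-state Markov
model with rate q and a uniform root prior, likelihood by Felsenstein's
pruning algorithm on the lambda-transformed tree (internal branches scaled
by lambda, terminal branches stretched to preserve tip height). (q, lambda)
are maximised jointly by profiling q (log-scale bounded search) inside the
lambda search. The symmetric model is the simplest defensible choice where
the original analysis names none.

**LRTs.** Lambda is compared to 0 and 1 by likelihood-ratio tests against
chi-square with df = 1, including at the boundary, where the asymptotics
are formally nonstandard — a deliberate fidelity-over-theory choice
matching the convention of the comparative literature this package mirrors.

**PGLS.** beta = (X' V(lambda)^{-1} X)^{-1} X' V(lambda)^{-1} y with lambda
estimated by ML on the residual covariance; standard errors use the
unbiased scale sigma^2 = RSS_gls / (n − p); two-sided t-tests on n − p df.
Missing data are handled per model by listwise deletion, with the tree
pruned to the remaining species (mirroring an n = 53 → 50 drop when a
partially observed covariate enters). Ordinal depth categories (1 moderate
light, 2 low, 3 none) enter as a single numeric slope. Rank-deficient
designs are rejected naming the collinear columns. At lambda = 0 PGLS
reproduces OLS exactly (asserted to 1e-10). No multiple-testing correction
is applied anywhere, matching the analysis design being replicated.

## Synthetic data: what it emulates, what it does not

The generator produces the three input classes the pipeline consumes.

*Wholemounts.* The outline is a disc with four radial slits (the shape left
by the relief cuts used to flatten a hemispherical retina; default radius
2.6 mm ≈ 20 mm^2, sized so the reference grid yields ~200 sites).  The
density field is background + (peak − background)·exp(−s²/2w²) with s the
distance to an arch / ring / streak locus — the observed specialisation
geometries with deliberately shallow gradients (default 2:1 peak:background,
background 400e3 rods/mm^2, within the published 255–760e3 range for
non-streak species). Per-site counts are Poisson given the field (a
negative-binomial overdispersion knob exists but defaults off). True totals
come from raster quadrature rescaled by the exact polygon area (accurate to
~1% against a closed-form Gaussian-mass oracle at the default resolution).
Not emulated: fixation shrinkage and tearing, cell-boundary ambiguity at
the optical resolution limit, observer miscounts, and the real forbidden-line
counting rule — so passing tests validate the estimator arithmetic and
sampling design, not microscope practice.

*Phylogenies.* Pure-birth trees with unit rate, ultrametric by
construction; polytomies created by collapsing a random fraction of
internal edges (length pushed into the children, preserving tip heights).

*Traits.* Continuous traits are lambda-BM draws (MVN with covariance
sigma^2 V(lambda)). Binary ecological traits threshold a latent lambda-BM
at a configurable prevalence, so high-lambda latents produce clade-constant
patterns like those of luminous organs (the tests verify this via Fitch
parsimony scores). Ordinal depth categories cut the latent at terciles.
Regression datasets add response = X beta + eps with eps ~ MVN(0, sigma^2
V(lambda_res)); the recovery tests use slopes on the published scale (e.g.
a night-depth slope of 0.07) with residual sd 0.05 so the simulated
signal-to-noise resembles the printed t-statistics. Real trait tables are
measured with error, heteroskedastic across labs and fixation methods, and
partially missing; only the last is emulated (missing day-depth values).

*Problem sizes.* Recovery and calibration suites run at n = 53–128 tips
with 200–500 replicates, and stereology properties at ~200 sites over
20–200 seeds — sizes chosen so every property is measured at the scale the
original analyses used while the full suite stays interactive.

## Numerical choices

- Covariance factorisations add a 1e-12-scale jitter before Cholesky;
  eigenvalues are floored at 1e-12 (relevant only at lambda = 0 on trees
  with 1e-6 resolution branches).
- The fractionator holds 1/ssf, 1/asf, 1/tsf as exact `Fraction`s; results
  are returned as `int` when integral.
- Polygon membership (outline masks, site retention) uses shapely
  predicates; specialisation loci are shapely geometries, with arcs
  discretised at 256 segments (locus-distance error < 1e-4 mm at the
  default radii).
- All-zero counting records return total = 0 with CE = NaN (undefined), and
  constant traits are rejected as lambda-unidentifiable, each with explicit
  messages.
- A single run seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence`, so stages are individually reproducible.

## Known limitations

- The CE formula is one of several in use; values are comparable across
  runs of this package but not guaranteed to equal any specific commercial
  stereology suite.
- The kernel smoother's mass consistency (mean map value x area vs
  fractionator total) holds to ~10% on shallow-gradient fields and degrades
  for specialisations narrower than the grid step.
- The discrete-lambda model is the symmetric 2-state chain; asymmetric
  rates and hidden-state models are out of scope.
- PGLS assumes a single lambda for the residuals of each model; no
  Ornstein–Uhlenbeck or rate-shift alternatives are offered.
- Boundary LRT p-values are conservative/anticonservative in the usual ways
  at lambda = 0/1; see above.
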