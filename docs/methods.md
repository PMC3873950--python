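# Methods

`rootarch` implements a full ("deep") phenotyping of 3D-digitized coarse
root systems of container-grown seedlings: the measurement model, the
architectural trait battery, and the treatment statistics, plus a
synthetic generator that stands in for digitized material.

## Measurement model

A digitized root system is a rooted tree of segments, each with 3D base
and tip coordinates, a basal diameter and a count/mean length of
unmeasured "additional fine roots" (basal diameter < 0.7 mm).  Segments
group into axes (roots); the whole first-order path is the stump +
taproot.  All computation happens in a slope-oriented frame: X = north =
upslope (azimuth 0 deg), Z perpendicular to the soil surface, positive
up.

**Solid model.** Diameters are digitized at segment ends, but the solid
connecting them is a modelling choice.  The default treats each segment
as a conical frustum from its basal diameter to the next segment's basal
diameter (cylinder at the axis tip); a `cylinder` option uses the basal
diameter throughout.  All volumes, including partial-segment volumes,
use the exact frustum integral, so every partition of a segment
conserves volume to machine precision.

**Axis length** adds the bearing root's radius (the path from the mother
root's centre to the branch base), zero for the order-1 root.  **Mean
diameter** of a root is the cylinder-equivalent `2*sqrt(V/(pi*L))`.
**Proximal taper** is the % diameter decrease per cm over the first
3.5 cm, with diameters linearly interpolated in curvilinear distance.

**Virtual segments.** Because digitized segments are long relative to
seedling size, every segment is cut into 10 mm virtual slices for all
spatial analyses, each carrying its exact share of length and volume.

**Wall artefact.** Roots that reach the container wall or bottom follow
it.  Axes with a vertex within 2 mm of a face followed by at least two
segments lying within 15 deg of the face plane are virtually re-aimed
along the last pre-contact direction with per-segment lengths preserved;
attached arborescences translate rigidly.  The 2 mm / 15 deg / 2-segment
rule is this package's operationalization (the source method names no
thresholds); all three are configurable.  The correction is idempotent
and exact for straight growth — for a root that grew straight until
deflection, the corrected tip equals the true straight-growth tip, which
is how the generator-based recovery tests can demand sub-millimetre
agreement.

## Compartments and sectors

Eight compartments partition the system: (1) stump = first 45 mm of the
order-1 path (a fixed stump *length*, robust to tilted containers; a
straddling segment is split exactly), (2) taproot, (3) zone of rapid
taper (ZRT), (4) horizontal shallow roots beyond the ZRT, (5) sinkers,
(6) deep, (7) intermediate-depth and (8) oblique roots.  Lateral
arborescences are classified by origin: depth of the initial branching
point on the order-1 root (shallow above -35 mm, deep below -70 mm)
crossed with the direction class of the order-2 axis chord (horizontal
within 30 deg of the surface, vertical beyond 60 deg).  Boundary values
go to the deeper/steeper class for determinism.  Sinkers pool into the
taproot and obliques into the intermediate class for six-class tables
(both are rare in this growth habit); the raw eight-class labels remain
available.

The ZRT/beyond split is spatial: a shallow-horizontal virtual segment is
ZRT when its *relative radial distance* — horizontal distance from the
point on the order-1 root bearing its arborescence — is at most
`zrt_limit`.  The limit is nowhere printed in the source literature;
the default is 50 mm (roughly the taproot-proximal third of a 0.30 m
container) and it is an explicit, documented parameter because all
ZRT-dependent shares move with it.

Sectors about the bearing point: upslope `us` = azimuth [315, 45),
downslope `ds` = [135, 225), perpendicular `pp` = the remaining two
quadrants (half-open bins).  Stump and taproot are the system's centre
and carry no sector.  Fine roots are excluded from sector analysis by
default (their sector was not recorded in the motivating study).
Sector shares are percentages of the scope total; *reinforcement* =
(share - 25%)/25%, the excess over the uniform expectation for one
quadrant.

## Topology and fractal branching

**qb** locates a topology between dichotomous (0) and herringbone (1) by
normalizing the sum of collar-to-exterior-link path lengths Pe between
the extremes attainable with the same number of exterior links n:
`qb = (Pe - Pe_min(n)) / (Pe_max(n) - Pe_min(n))` with
`Pe_min = n*floor(log2 n) + 2*(n - 2^floor(log2 n))` and
`Pe_max = (n-1)(n+2)/2`.  Multifurcations are resolved to binary by
serial splitting; depths are counted in links of the binary-resolved
tree (any uniform offset cancels).  For n < 4 there is a single binary
shape and qb is reported missing.  The closed forms are verified against
exhaustive enumeration of all binary topologies with up to 7 tips.

**Mean branching order (MBO)** is the mean of (topological order - 1)
over lateral axes, so a root bearing only second-order laterals scores
exactly 1; fine roots count at order(bearing axis) + 1 with their
multiplicity.  This convention is the package's own calibration (the
printed formula was not recoverable from the source) and is used for the
per-sector branching comparison where qb is unusable because an
arborescence can straddle sectors.

**Fractal parameters** per branch event: `p_branch` = CSA before /
sum of CSA after (1 under CSA conservation, > 1 under tapering); `q` =
largest post-branch CSA share (0.5 equal dichotomy, -> 1 herringbone);
`p_within` = % CSA decrease per cm between consecutive branch points.
CSA before the branch uses the basal diameter of the segment ending at
the branch point (the diameter digitized just before it).  Because no
diameter is digitized just *after* a branch, when the continuing segment
is longer than 2 cm its CSA is taken 2 cm after the branch point by
linear interpolation.  `p_within` is CSA-based for consistency with
`p_branch`.

## Synthetic generator

The generator samples a final architecture; it is deliberately not a
growth simulator (the phenotyping pipeline measures form, not growth
rules).  It emulates: one gravitropic taproot (direction a configurable
mix of gravity and the surface normal, so tilted containers tilt the
taproot), diameter taper with depth, shallow laterals near-parallel to
the soil surface with configurable origin-depth mixture, higher-order
branching controlled by a herringbone weight `h` (each new tip extends
the main chain with probability `h`, otherwise splits a shallowest leaf;
`h = 1` gives qb = 1, `h = 0` with a power-of-two tip count gives
qb = 0 exactly), daughter diameters set from target `p_branch`/`q`
ratios, Poisson fine roots, and wall behaviour (`deflect` slides along
the container face from the exact contact point, `clip` stops there).
The straight-growth tip of every axis is retained as hidden ground
truth, as are the azimuth-distribution parameters and `h`, enabling
parameter-recovery tests.

Defaults are sized to the study system: a 0.30 x 0.30 x 0.11 m box, a
10 cm taproot of 8 mm basal diameter tapering 6 %/cm, ~12 laterals of
mean length 12 cm and ~1.5 mm diameter, tissue density 0.5 g/cm3 and a
4:1 shoot:root allocation; the stratified azimuth mode (exact spacing
180/n + k*360/n, avoiding sector boundaries) exists to make sector
tests exact rather than stochastic.  The fine-root rate (0.08 per cm of
axis) makes additional fine roots roughly half of the measured-root
count, matching the reported proportions.  What it does **not** emulate:
root mortality, nutrient/water heterogeneity, secondary-growth dynamics,
soil mechanics, and measurement error in digitizing.  Passing tests
therefore certify the measurement and statistics pipeline, not any
biological claim about real seedlings.

## Statistical layer

Per trait, a fixed-effects ANOVA `Y ~ Slope + Flexing + Block +
Slope:Flexing` with sequential (Type I) sums of squares; the interaction
is ordered after the block term (patsy's canonical ordering; for the
balanced cohorts analysed here the sequential tests are
order-independent, and Type II is available for unbalanced data).
Residual normality is checked with the Shapiro test at alpha = 0.05 and
non-normal traits walk a fixed ladder: none -> log (only for strictly
positive traits) -> rank.  Group means and % variation versus the
control are always reported on the untransformed scale.  Significance
stars at 5, 1, 0.1 and 0.01 %.

Circular heterogeneity is tested per compartment and treatment group
with a mixed model: value ~ sector (fixed) + tree (random intercept),
REML.  For additive quantities (volume, length, number) the
perpendicular sector spans two quadrants, so its value is halved before
testing to put all three sectors on the one-quadrant scale.  The sector
factor is a 2-df Wald test; pairwise contrasts are unadjusted normal
tests feeding a compact letter display (a Holm option exists, off by
default, matching the practice of reporting raw contrast p-values).  A
compartment present in no more than half the plants is reported NA.  On
balanced data the REML fixed effects equal the sector means, which the
tests check against that closed form.

PCA runs on centred, unit-variance traits (17 by default, mirroring the
study's selection; root dry weight enters as its cube root as a linear
size proxy); each loading vector is oriented so its largest-magnitude
element is positive.

## Problem sizes and numerical choices

* Simulated cohorts: 4 groups x 8 plants, 2 blocks (the real design's
  scale); conservation properties are checked over 100 generated
  systems; type-I calibration uses 1000 simulated null trait tables plus
  60 generator-backed null cohorts; power checks use 200 ANOVA and 30
  mixed-model simulations — sizes chosen so the whole suite completes in
  well under a minute of statistics while keeping binomial envelopes
  tight (99-99.9% envelopes are asserted, not point values).
* Interpolation along axes is linear in curvilinear distance everywhere
  (coordinates and diameters); no smoothing or spline fitting.
* Conservation assertions use relative tolerance 1e-9; round-trip I/O is
  exact to 1e-6 m (file precision).
* Degenerate inputs: zero-length segments carry no virtual slices; a
  vertical first centimetre has no azimuth (flagged missing); axes
  shorter than the 1 cm azimuth or 10 mm RDD window fall back to the tip
  with a quality flag rather than being dropped; zero-total scopes give
  missing values, never zeros.

## Known limitations

* The ZRT limit and the wall-contact thresholds are conventions; results
  that depend on them should be reported with their values.
* The MBO formula is a documented convention (see above), not a verbatim
  reproduction of the source's unrenderable formula.
* qb for a compartment uses the order-1 path as a connecting spine whose
  own tip is not an exterior link of the scope; other conventions exist.
* The mixed model uses a normal approximation for contrasts; with very
  few trees per group its p-values are optimistic, as in the original
  analysis tradition.
* The generator produces idealized architectures (no measurement noise,
  no mortality); effect sizes configured for power tests are nominal
  constructions, not estimates of real biological effects.
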