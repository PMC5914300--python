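# Methods

## The curation problem

A spacing trial planted in the 1890s and surveyed until the late 1990s
accumulates every failure mode longitudinal measurement data can have:
instrument changes (crosswise calliper → girth tape for diameter; poles,
ladders, several clinometer generations and ultrasonic hypsometers for
height), observer turnover, digit heaping on coarse scales, sparse height
subsampling, missing campaigns, thinning removals, and storm-broken tops
that make a genuine height decrease possible. The target of curation is a
per-tree series of breast-height diameter `d` (mm), height `h` (dm) and
crown-base height `hCr` (dm) that is

* defined at **every** campaign between the tree's first and last
  observation,
* **non-decreasing** (`h` may drop only across a recorded crown break;
  spruce self-prunes, so `hCr` never drops), and
* `hCr ≤ h` everywhere.

Stem analysis supplies the bias reference: discs cut from felled trees at
known heights carry ring-width series that reconstruct the tree's
inside-bark growth for every year of its life, independent of any field
campaign.

## Units and time

Units follow the published tables: `d` in mm, `h`/`hCr` in dm, crown radii
in m, ring widths in 1/100 mm. The unit of `h` in the processed output is
not stated in the published column notes; dm is used by analogy with the
raw height field and is a config option. Time is handled as decimal years,
`year + day_of_year/365.25`, because campaign intervals range from 1 to 6
years and all increment thresholds are per-year rates.

## Diameter stage

1. Crosswise calliper pairs are averaged arithmetically (near-identical to
   the geometric mean for real stems); tape records are taken as diameters
   (a config flag divides by π if a deposited file turns out to hold
   girths).
2. A disc's four directional radii (N/E/S/W cumulative ring sums) combine
   to the equivalent-circle diameter `2·sqrt(mean(r²))`, because the mean
   of the per-radius circle areas approximates the true basal area. Within
   a calendar year the current ring accrues linearly over May 1 – Aug 31
   (123 days) and is flat outside that window. The disc diameter is dry,
   inside bark; multiplying by 1.070 gives the unshrunk outside-bark
   diameter comparable with calliper readings (the analogous tape factor is
   1.082; the ~1.2 % difference reflects non-circular stems, which a tape
   overestimates).
3. **Levelling.** For every campaign group (plot × year) with at least one
   disc-reference tree measured, the relative basal-area difference
   `(BA_meas − BA_ref)/BA_ref` is computed per reference tree and the group
   median is divided out of every measurement of the group (in basal-area
   space). Because the transform is affine and monotone, the post-levelling
   group median is exactly zero. Groups without references keep factor 1
   and are flagged. Basal area (not diameter) is levelled because
   volume-relevant bias is quadratic in diameter; the median (not mean)
   resists the occasional wild reference; both are config options.
4. **Outlier filter.** An increment to the surviving predecessor violates
   if it drops more than 10 mm, drops faster than 5.4 mm/yr, or rises
   faster than 10 mm/yr (the negative rules combine as OR — conservative
   toward cleaning). A violating increment implicates both endpoints; the
   point whose adjacent increments are jointly worst is removed, repeatedly,
   as long as at least 3 observations survive ("enough" = 3, configurable);
   otherwise points are only flagged.
5. **Monotone completion.** Isotonic least squares (PAVA, unit weights)
   over decimal years removes negative increments; calendar gaps interior
   to the observed span are filled by a monotone cubic Hermite interpolant
   through basal area vs time (exact at knots, monotone by construction;
   interpolation only, never extrapolation); a final isotonic pass guards
   the splice, and maximal zero-increment runs bracketed by strictly
   smaller/larger neighbours are linearly re-interpolated in time.

The stage order is: average → level → filter → isotonic → gap fill →
re-check → flat-run interpolation.

## Height stage

Raw heights come either directly (`kh=0`) or from triangulation fields
(`kh=1`): base-bar campaigns use `H = A·C·cos²(WU)(tan WO + tan WU) + K`
with the device constant `C = 1/0.3`, slope-distance campaigns
`H = D·cos(WU)(tan WO + tan WU) + K`, with the mark height `K = 13` dm.
Angles recorded on punch cards are 3-digit tenths of a degree; a leading 9
flags a downslope (negative) angle whose magnitude is the remaining two
digits in tenths — which limits representable positive angles to 89.9°
(steeper sights are invalid anyway).

Filtering drops decreases beyond 10 dm with no crown event recorded at the
later observation, and rises above 10 dm/yr. Levelling mirrors the diameter
stage with the reference being a disc-based height–age function: each disc
pins the age at which the top passed the disc height (the year before its
first ring, plus half a year, since a height is reached mid-season), and a
monotone spline interpolates between discs; the plot × year factor is the
median of reference/measured ratios.

The cross-tree transfer uses the height-age law
`h = c0·log(1 + exp(c2)·age^c3)^c1`, fitted by multi-start bounded
nonlinear least squares to unbroken trees standing at the final survey.
On mature-stand ages alone (≈35–109 yr) the four parameters are only weakly
identified — several parameter vectors produce nearly the same curve on the
data range — which is immaterial here because the fit is used as a scaling
template; parameter-recovery tests sample the full age range, where the
parameters are identified. The ratio `hMon/h_age(age)` (with `hMon` the
levelled, per-break-segment isotonic heights) is smoothed across trees by a
penalized additive model: cubic B-spline terms over age, diameter and stand
position (x, y) for spruce — age and diameter only for admixture species —
plus a per-tree intercept offset estimated with a ridge penalty, falling
back to a per-species offset for trees with fewer than 3 observations.
Ridge-shrunken offsets reproduce the qualitative behaviour of a random
intercept (shrinkage to zero as a tree's record thins) without REML
machinery; smoothing strength is chosen by generalized cross-validation
over a small grid. Spline basis: cubic, 8 knots per covariate by default
(configurable).

Predicted ratios × the height-age curve give `hSmooth` at every calendar
slot; a per-tree isotonic pass removes any negative increments the
smoothing introduced. Finally the smooth curve is **anchored**: at each
observation date the multiplier `hMon/hSmooth` is computed, linearly
interpolated in time between anchors and held constant beyond them, so the
output passes exactly through every retained measurement. Anchoring is done
twice — once with all observations (`h`, the published variant, which may
step down at a recorded break) and once ignoring observations after the
first break (`h_nobreak`, the input to the crown stage). Residual negative
increments are removed by isotonic projection per break segment, and flat
runs are re-dated at their mean date (the run's value is treated as true at
the middle of the constant stretch) before linear re-interpolation.

## Crown stage

Crown-base observations (direct `ka` readings, or the `wka` angle through
the triangulation formula) are clipped to the concurrent height and
isotonic-projected per tree. Two additive-spline estimates are fitted over
age, diameter, the no-break height and position: one of `hCr` directly, one
of the crown ratio `hCr/h` (predictions clipped to [0, 1] and scaled by the
no-break height). Their unweighted average (no information favours either
estimate) is monotonised, anchored to the monotone observations with the
same multiplier scheme as heights (the published description says only
"adjusted to hit"; reusing the height scheme keeps the two stages
symmetric), re-projected, flat-run-corrected, and finally clipped to the
tree height — a violation surviving the clip raises an error.

## Spatial reconstruction

The raster fit alternates nearest-node assignment with a bounded
least-squares update of origin, two spacings and an orientation angle
(|θ| < 5°), until the assignment is stable (a grid-constrained ICP; at most
100 iterations). The orientation parameter is an addition over a pure
spacing adjustment: mapped coordinates live in a national projection, and
without a small rotation nearest-node assignment is ill-posed on long
plots. Corner correction snaps each measured corner to the nearest point
lying exactly between adjacent planting rows in both raster directions
(local coordinates (k+½)·spacing); the plot area is the shoelace area of
the adjusted polygon. Trees removed before the mapping are placed on the
node implied by the serpentine numbering model (rows traversed in
alternating direction; the traversal variant and offset can be inferred
from the mapped trees' numbers); numbers outside the pattern go to random
vacant nodes under a fixed seed. Geographic coordinates go through a
pluggable converter; the built-in converter is a fixed affine stub
(synthetic data only, clearly not a geodetic transformation).

## Stand statistics

Digit preference: the remainders of integer readings modulo 10 are compared
with a uniform expectation by a Pearson chi-square test (df = 9); heaping
on 0/5 mm — the signature of a 1 cm calliper scale read by eye — produces
large statistics. Summaries per plot and campaign: `N/ha`; quadratic mean
diameter `dg = 2·sqrt(mean BA/π)`; dominant diameter `d50`, the
`⌈50·area/ha⌉`-th largest diameter (rank scaled by area, configurable);
basal-area-weighted mean height `hg`; dominant height `h50` analogously;
standing and cumulatively removed basal area; periodic annual increment of
total (standing + removed) basal area over exact decimal-year spans; mean
annual increment as total production over stand age. Only trees inside the
corner polygon are counted when corners are available.

## Synthetic stands

The generator mirrors the trial's structure: four plots at 1×1, 1.5×1.5,
1×2 and 2×2 m spacing, spruce germinated 1888 (admixture species 1892),
campaigns at irregular 1–6 yr intervals from 1923 to 1997, calliper era
through 1973 (crosswise pairs, 1 mm readings heaped on 0/5 with
probabilities 0.5/0.25/0.25, per-campaign observer bias of ±2 %), tape era
from 1978 (finer readings, a ×1.082/1.070 factor over the calliper
convention), heights on ~30 % subsamples until the final surveys, three
campaigns stored as raw angle/distance fields, ~12 % thinning per campaign,
rare crown breaks (hazard 0.002/tree-yr, a lasting 10–25 dm loss, recorded
as a crown code at the next campaign), and stem discs on trees felled at
the final survey whose ring sums equal the inside-bark radius truth
(outside-bark diameter / 1.070) exactly, year by year.

Growth truth: height follows the height-age law (c0=75 dm, c1=1.2, c2=−6,
c3=2 — ≈31 m at age 109 and ≈11 m at age 35, a plausible good spruce site)
times a lognormal tree effect (σ=0.08) and a mild east–west gradient (3 %);
diameter is allometric, `d ∝ h^1.2`, with its own lognormal factor (σ=0.10)
scaled to ≈35 cm dbh at age 109, and accrues within each year by the same
May–August linear ramp the disc evaluation assumes. The crown ratio drifts
from 0.2 toward 0.7 with age (exponential approach, τ=40 yr), bounded by
the (possibly broken) top and kept non-decreasing.

What the generator does **not** emulate: competition and density-dependent
growth, spatially correlated growth shocks, species-specific allometry, bark
thickness varying with age, measurement-error autocorrelation within an
observer. Passing recovery tests therefore demonstrates that the pipeline
inverts the error processes it models — era bias, noise, rounding, gaps,
breaks — not that it corrects every error structure real field data can
contain.

Default problem sizes in the tests and the acceptance experiments are
reduced rasters (6×6 to 12×12 trees per plot) so that multi-seed recovery
loops (50–100 replicates) complete quickly; the generator scales to
trial-size stands (thousands of trees) unchanged.

## Numerical choices

* Isotonic projections use unit weights; ties in time are averaged.
* Monotone interpolation is the cubic Hermite scheme with the
  harmonic-mean (Fritsch–Carlson/Butland) slope limiter, exact at knots.
* The additive smoother solves penalized normal equations with a
  second-difference penalty per spline block, a ridge on group offsets
  (λ=1), and a 1e-8 ridge for conditioning.
* The height-age fit uses bounds c0∈[1e−3,1e5], c1∈[0.05,10], c2∈[−30,10],
  c3∈[0.05,6] and 9 starting points; constant-height data raise instead of
  pretending convergence, and a fitted curve must be positive and
  non-decreasing over the data range.
* Flat-run detection uses exact equality (values come from PAVA pooling);
  monotonicity assertions tolerate 1e-9.
* Degenerate inputs raise: fewer than 4 or collinear points for the raster
  fit, fewer than 2 discs for a height-age function, extrapolation requests
  in gap filling, a crown base above the tree height after all adjustments.

## Known limitations

* Groups (plot × year) without any disc reference are not levelled (factor
  1, flagged); on real data the earliest campaigns may keep their bias.
* The additive smoother is not a full mixed model: offsets are shrunk by a
  fixed ridge rather than an estimated variance component, and smoothing
  parameters are selected by GCV, not REML.
* The published archive's processed table is reproducible only from the
  deposited raw data; tests validate against synthetic ground truth
  instead.
* Tape records are assumed to be stored as diameters; the girth
  interpretation is one config flag away.
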