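# Methods

This note documents the statistical models behind `scabra`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that shape edge-case behaviour.

## Quadrat dispersion test

A survey records counts `x_1, …, x_n` of animals in `n` quadrats of equal
area (the standard field protocol here is 30 quadrats of 4 m² per pen,
with surface and buried individuals counted separately).  Under a
homogeneous Poisson null the variance equals the mean, so the dispersion
index `I = Var/Mean` (sample variance, `n−1` denominator) is centred at 1.
The test statistic

    t = (Var/Mean − 1) / sqrt(2/(n−1))

is referred to Student's t with `n−1` degrees of freedom, upper tail:
large positive `t` indicates overdispersion, i.e. spatial clumping.  The
default `alpha = 0.025` corresponds to flagging `t > t_{0.975, n−1}`,
the convention when only the overdispersed direction is of interest;
every entry point takes `alpha` as a parameter.

The t reference is an approximation.  Simulation at the default survey
scale (30 quadrats, Poisson mean 3) puts the one-sided type-I error at
about 0.036 at nominal 0.025 and 0.062 at nominal 0.05 — slightly
liberal, a known property of the index for skewed counts at moderate
`n`.  The calibration tests therefore assert a band (0.03–0.08 at
alpha 0.05) rather than the nominal point.

Surveys in which no animal was recorded leave the index undefined
(`Mean = 0`); batch runs exclude such surveys with a logged reason and
report them explicitly rather than dropping them.

Two survey-level comparisons accompany the per-survey test:

* **Two-way ANOVA without replication** on a complete pens × months
  matrix, the classical decomposition `SS_total = SS_row + SS_col +
  SS_resid` with `F_row = MS_row/MS_resid` on `(a−1, (a−1)(b−1))` df.
  The response variable is a per-survey aggregation measure; the default
  is the variance/mean ratio (the quantity the dispersion test is built
  on), selectable to the t statistic or a 0/1 significance indicator.
  An exactly additive matrix has zero residual SS and therefore no valid
  F statistic; this is reported as a degenerate-fit error, never as an
  infinite or zero F.  The implementation is the direct SS decomposition
  (cross-checked against a statsmodels OLS fit in the test suite).
* **Paired t-test** between per-pen surface and buried means, two-sided
  (scipy).  Identical vectors return `t = 0, p = 1`; constant non-zero
  differences have zero variance and raise instead of dividing by zero.

## Point patterns in circular tanks

Tank experiments place `n` juveniles in a disk (60 cm diameter;
coordinates in cm, origin at the tank centre, angles counter-clockwise
from the positive x axis).  Spatial randomness is assessed with Ripley's
K:

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} e_ij · 1[d_ij ≤ r]

with isotropic edge correction: `e_ij` is the reciprocal of the fraction
of the circle centred at point `i` with radius `d_ij` that lies inside
the disk.  For a disk window that fraction has the closed form
`arccos(c)/π`, `c = (ρ_i² + d² − R²)/(2 ρ_i d)` (`ρ_i` the distance of
point `i` from the tank centre), clamped to full coverage when the
circle is interior.  Under CSR, `E K̂(r) = πr²`.  The default `r` grid is
50 equally spaced values up to half the tank radius, bounding the
variance inflation of the corrected estimator at large `r`; an
uncorrected variant exists for brute-force cross-checks.

To separate aggregation proper from wall-following, positions are also
projected onto the circumference (polar angle about the centre; a point
exactly at the centre has no angle and is reported as an error naming
the point).  On the circle the analogous statistic uses shorter-arc
distances and needs no edge correction; under uniformity `E K̂(s) = 2s`.

**MAD envelope test.**  The randomness test simulates `n_sim` CSR
patterns with the same `n` in the same window (a fixed-`n` binomial
process — the tanks hold a fixed number of animals), computes every K
curve, and scores each curve by its maximum absolute deviation from a
reference.  The default reference is the pointwise mean of the *other*
curves (leave-one-out), which makes the observed and simulated statistics
exchangeable under the null, so the rank p-value

    p = (1 + #{T_sim ≥ T_obs}) / (n_sim + 1)

is exact and discrete-uniform on multiples of `1/(n_sim+1)`.  A
theoretical reference (`πr²`, or `2s` on the circle) is available by
flag.  `n_sim` defaults to 199 and must be at least 19 (the smallest
value that can resolve `p ≤ 0.05`); calibration decisions use `p ≤ α`,
which is exact for the rank statistic.

**Density heat maps.**  Isotropic Gaussian kernel density on a regular
grid over the disk's bounding square, masked to the disk and renormalised
so the total mass over the disk equals `n` (tail mass outside the tank is
folded back in).  Units are individuals per cm².  The default bandwidth
is 5 cm — roughly one juvenile body length; it is a display parameter,
not part of any test.

## Y-tube assays

Each stimulus is summarised as `moved/total` (percent reported rounded
for display, full precision kept internally) and compared to an explicit
control record via Fisher's exact test on the 2×2 moved/not-moved table
(scipy; two-sided by the point-probability rule — the sum of
probabilities of all margin-consistent tables no more probable than the
observed one, verified in the tests against full hypergeometric
enumeration for every table with total ≤ 40).  The odds ratio is the
sample value `ad/bc`, reported as `inf`, `0` or `NaN` for degenerate
cells.  There is deliberately no default control: a control record must
be supplied from data or simulation.  Only presence/absence of movement
is analysed, not arm choice.

## Saponin profiles

The reference library keys each saponin on its sodiated-ion m/z
(`[M+Na]+`), carrying all isomeric names for that mass (MALDI cannot
separate isomers) and the number of sugar residues.  Raw peak lists are
annotated by nearest-mass matching within a tolerance (default 0.5 m/z,
matching a library quoted to one decimal); when two peaks claim the same
entry the nearer wins and the loser is returned unmatched rather than
cascading to its second choice.

The differential operation returns library entries absent from every
non-attractive sample and present in the attractive samples under one of
two explicit rules — present in *all* attractive samples, or in *at
least one* — optionally restricted to a sugar class and/or to a focal
subset of the attractive samples.  Both rules are first-class because
presence/absence data of this kind does not by itself single out one;
reported results always name the rule used.  On the packaged reference
matrix (five extracts × 16 library entries) the all-attractive rule
yields the two disaccharides at m/z 889.4 and 905.4, and the two-sugar
compounds of the healthy juvenile integument absent from both
non-attractive extracts are m/z 873, 889.4 and 905.4.

## Synthetic data

All statistical machinery is exercised on generated data with known
truth.  The generator produces:

* **CSR patterns** — exactly `n` uniform points in a disk or rectangle
  (polar sampling in the disk, so no rejection loop).
* **Thomas cluster processes** — Poisson parents on the window dilated by
  4 × offspring SD (parents just outside still contribute offspring,
  avoiding edge-thinned clusters), Poisson(`mean_offspring`) broods with
  isotropic Gaussian displacement, clipped to the window.  By
  stationarity the retained count has mean
  `parent_intensity × window area × mean_offspring`.
* **Quadrat surveys** — binned patterns, or i.i.d. Poisson /
  negative-binomial counts; each individual is assigned to the buried
  layer with probability `p_buried = 0.69` (the observed aggregate
  buried fraction; a placeholder, not an estimate — no per-pen burial
  rates are available).
* **Assay outcomes** — Binomial(`n_trials`, `p_move`) per stimulus.
* **Profile sets** — marker compounds present in every attractive and no
  non-attractive sample; every other library compound appears
  independently with probability `p_background` anywhere.  Markers
  therefore always survive the all-attractive differential; with
  `p_background = 0.3` and 3 + 2 samples a non-marker co-survives with
  probability `0.3³·0.7² ≈ 0.013` each, so the differential recovers the
  marker set *exactly* in only ~80 % of runs — recovery is assessed as
  marker containment, which is the generator's guarantee.

Study-scale defaults mirror the field protocol: campaigns of 10 pens ×
7 months, 30 quadrats of 4 m² per survey, Poisson mean 3 per quadrat for
the null (close to the observed mean of 3.37); the clustered alternative
uses parent intensity 0.025 m⁻², mean brood 33 and offspring SD 1 m —
a few tight clusters at a comparable overall density.  Tank experiments
use 10–40 animals in 60 cm tanks; the clustered configuration places the
animals in three Gaussian groups with 2 cm spread, the arrangement seen
once aggregation has formed.  Under these clustered conditions a
campaign occasionally (a few tenths of a percent per survey) produces a
pen-month with no animals at all; batch operations exclude it as
undefined, and the no-replication ANOVA — which needs a complete
pens × months matrix — is then reported as skipped rather than imputed.

A single seed fans out to per-component substreams via
`numpy.random.SeedSequence.spawn`, so identical seeds give bit-identical
bundles and adding a new generator does not disturb existing streams.

What the generator does **not** emulate: movement dynamics over time
(time-lapse frames are drawn independently, not as a trajectory),
mass-spectral signal structure (intensities, isotopes — presence/absence
only), within-survey spatial correlation between the surface and buried
layers, and olfactometer flow physics.  Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated on
data satisfying its assumptions — not that real surveys satisfy them.

## Problem sizes

The test suite runs the calibrations at the scale the analyses use:
1000 null + 100 clustered surveys for the dispersion test, 500 null +
100 clustered tanks (n = 40, `n_sim = 199`) for the MAD test, 500
replicates for the circular-K closed form, exhaustive Fisher enumeration
to total 40, and 200 seeds for profile recovery.  The full suite
completes in a few minutes on one CPU.

## Known limitations

* The dispersion t approximation is mildly liberal at `n = 30` (see
  above); for exact control a Monte-Carlo version of the index would be
  needed.
* The isotropic correction is exact for the disk but the K estimator's
  variance grows near `r = R`; the default grid stops at `R/2`.
* Fisher's test is conditionally exact and therefore conservative for
  small arms; observed null rejection sits below nominal.
* The differential analysis is purely set-algebraic; it does not model
  detection noise (false peak absences) in the reference matrix.
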