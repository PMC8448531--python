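# Methods

This note records the models, conventions and numerical choices behind
chickgait, in the order the pipeline runs. Nothing here states an empirical
result the test suite or `scripts/acceptance.py` does not itself compute.

## Gait model and event definitions

A stride cycle of one leg runs from a toe-off to that leg's next toe-off.
Within the cycle, the **swing** phase is toe-off → foot-contact (foot
airborne) and the **stance** phase is foot-contact → next toe-off (foot
loaded); the duty factor is the stance fraction of the cycle. All times are
in seconds at the video frame rate (default 240 fps), heights in centimetres
above a known side-view ground line.

**Event detection.** Toe-off is the first frame of an airborne bout — toe
height above `ground_y + lift_threshold` — following a stance bout;
foot-contact is the first frame back within the threshold. The lift
threshold defaults to max(0.2 cm, 2 × a robust jitter estimate), where the
jitter SD is estimated from the median absolute deviation of first
differences of the toe-height trace (divided by √2, scaled by 1.4826).
Airborne/stance runs shorter than 3 frames are treated as jitter and
flipped, which suppresses spurious events when tracking noise flickers
around the threshold. On noise-free synthetic data this detector recovers
injected event times to within one frame; at 0.05 cm jitter, ≥ 95 % of
events land within two frames (both properties are tests).

**Collapse rule.** A stride is a whole-body collapse when its minimum knee
height falls *strictly below* 85 % of the stance-phase mean knee height of
that same step. Two points in this rule were genuinely open and are config
switches rather than hard-coded choices:

- *Evaluation window* — default is the full stride cycle (stance + swing);
  `collapse_window: swing` restricts it to the swing phase.
- *Baseline scope* — default is the per-step stance mean ("of the step");
  a session-mean baseline can be selected instead.

The boundary is strict (< 0.85 exactly is required; a ratio of exactly 0.85
is not a collapse), because the defining wording is "below 85 %".

**Overshoot rule.** The study's notion of overextension in leg elevation is
qualitative, so the detector mirrors the collapse rule symmetrically: a
stride is an overshoot when its swing-peak knee height rises strictly above
1.15 × the chick's reference peak, the reference being the mean of that
chick's (per-trace) stride swing maxima. Both the threshold and the
reference are configurable; at least 3 strides are required to form a
reference. Each collapse is then classified against overshoots within a
±1-stride window: `followed_by_overshoot`, `preceded_by_overshoot`, or
`isolated`; if overshoots flank a collapse on both sides the nearer wins and
ties go to "followed".

**Left-right phase.** `((LeftToeOff₁ − RightToeOff₁) / (RightToeOff₂ −
RightToeOff₁)) · 360`, reduced modulo 360 so the result lies in [0, 360);
180° is perfect alternation. The formula is invariant to a common time shift
and to uniform time rescaling of all events (property-tested).

**Swing profiles.** Per-stride knee-height and TMP-angle traces over the
swing are resampled by linear interpolation onto a uniform 101-point
0–100 percent-of-swing grid, with the first and last swing samples pinned to
0 % and 100 %. The per-step variability metric is the profile range
(max − min). Linear interpolation was chosen as the simplest scheme
consistent with percent-of-swing plots; the grid size is configurable.

**Joint angles.** The TMP angle is the interior angle at the TMP joint
between the (TMP → ankle) and (TMP → toe) segments, in degrees [0, 180]: a
straight limb reads 180°, deep flexion reads small. Frames where the vertex
coincides with a neighbour marker return NaN. The landing angle is the angle
between the knee → TMP line and the horizontal ground at the end-of-swing
frame; it is positive when the knee is above the TMP joint and returned
signed (with a warning) otherwise.

**Stride width and swing velocity.** Stride width is the mediolateral
distance between the two toes during double stance (the overlap of the two
legs' stance intervals), reported per bout as the bout maximum so that
session summaries match a "maximum stride width" convention. Swing velocity
is horizontal toe displacement over the swing divided by swing duration; the
toe was chosen as the reference marker (the alternative markers are a
documented unknown).

## Group statistics

Descriptive standard deviations default to the **population** convention
(divisor n). This choice is forced by the published control collapse column:
{2.12, 0, 0, 0} prints as 0.53 ± 0.92, which is the population SD (the
sample SD is 1.06). A config switch restores the sample convention.

Combined group statistics are **unweighted means of per-chick means**, never
step-weighted pools — the published combined knee/TMP columns reproduce only
under this convention (a test demonstrates that step-weighted pooling moves
the control knee combined mean by > 0.1 cm).

Hypothesis tests: Welch's unequal-variance t (with Welch–Satterthwaite df),
the pooled two-proportion z test, and Dunnett's two-sided many-to-one
comparisons via the multivariate-t distribution of the max-|t| statistic
(scipy); a seeded 10⁵-replicate Monte-Carlo oracle in the test suite
confirms the adjusted p values to 0.01. Angular data use circular
statistics: mean direction from the resultant vector, circular
SD = √(−2 ln R̄) in degrees, and the Watson–Williams high-concentration F
test with the standard 1 + 3/(8κ̂) correction, κ̂ estimated from the mean
resultant length by Fisher's three-branch approximation. The implementation
warns when R̄ < 0.7, where the approximation is unreliable, and is
cross-checked against a 10⁴-shuffle permutation null in the tests.

**Trajectory density bands.** At each percent-of-swing point a 1D Gaussian
KDE is taken across profiles; the band is the value interval where the
density exceeds a low (default 20 %) fraction of that point's density range,
with an inner band at the high (80 %) level — mirroring the 2D contour
convention — plus 10–90 % quantile envelopes as a model-free cross-check.
The KDE is evaluated on the observed value range only, so bands are always
nested within the data range; identical values yield a zero-width band.

## Spatial quantification

**Standardisation.** Observed sections are mapped to the template frame by
the least-squares similarity transform (translation, rotation, isotropic
scale; Umeyama solution) over ≥ 3 non-collinear landmark pairs; per-landmark
residuals are returned so poor registrations are visible. Similarity rather
than affine is the default because the density-map comparisons assume shape
is preserved; affine would absorb genuine shape differences.

**Density maps.** 2D KDE with a Gaussian *product* kernel and per-axis
normal-reference (Scott) bandwidths σ̂·n^(−1/6); the bandwidth actually used
is recorded in the output. The grid spans the data (or caller-supplied
bounds) padded by four bandwidths and the field is renormalised to unit
trapezoidal integral (tested to ±1 %). Coincident points trigger a bandwidth
floor with a warning. Contour sets place n levels (default 6) equally spaced
between `low` and `high` fractions (default 0.20–0.80) of the field's value
range — fractions of the *range*, not of the maximum — with figure-specific
ranges available through the arguments. Superlevel regions nest by
construction; the curves are extracted with marching squares.

**Laminar assignment** is point-in-polygon against named lamina polygons,
boundary points going to the first polygon in template order (deterministic
and documented); points in no polygon are "unassigned", and counts are
conserved by construction. The shipped template is a *synthetic schematic*
chick lumbar hemicord (outline plus laminae I–X as horizontal bands
intersected with the outline, in µm) — an editable stand-in, not a measured
atlas; per-lamina fractions computed against it are therefore internally
consistent but not comparable to atlas-derived published fractions.

**Soma size classes.** With an explicit threshold, diameters ≥ threshold are
"large". Automatic mode fits a two-component 1D Gaussian mixture and
thresholds at the posterior crossover between the component means, reporting
the threshold used; if the fitted means are closer than twice the larger
component SD the distribution is treated as unimodal and a single class is
returned with a warning.

**Density overlap** is summarised by the Bhattacharyya coefficient of the
cell-mass-normalised fields plus the IoU of the superlevel regions at a
stated level fraction (default 0.20) of each field's own range. For two
unit-variance Gaussians at offset d, the KDE-smoothed coefficient is
exp(−d²/(8(1+h²))) and the tests verify this closed form.

**Bouton QC.** Volumes below 0.07 µm³ are excluded before any mapping; the
boundary is *inclusive* (≥ 0.07 retained) — the source wording gives no
boundary semantics, so the inclusive choice is made explicit and
configurable. The synaptotagmin-positive fraction is reported with its raw
counts. Contacts use a centre-distance criterion: terminal-to-soma-centre
distance ≤ radius + tolerance (default 1 µm), somata as disks by measured
diameter; the criterion is a proxy for interactive 3D scoring and counts
somatic proximity only, not somatodendritic contacts.

## Synthetic data: what it emulates and what it does not

The gait generator produces kinematic *shapes*, not dynamics: a flat stance
knee plateau with a raised-cosine swing bump (the flat plateau gives the
85 % rule an unambiguous reference), a TMP excursion realised through actual
ankle/TMP/toe marker geometry so the angle code path is exercised end to
end, a cycloidal toe advance, and a toe-lift profile sin(πs)^0.7 whose brisk
lift-off/touch-down lets threshold detectors localise events to the frame.
Collapses are injected by pulling the knee toward
`collapse_depth_fraction × stance height` inside a raised-cosine window
(default centred at 85 % of the cycle, late stance; placement and width are
parameters, since collapses occur in both stance and swing); overshoots
multiply the swing amplitude by `overshoot_gain` (default 1.6, which keeps
an inflated peak detectable above the 1.15 × mean-peak rule as long as
overshoots are a minority of strides). Defaults describe a healthy P8 chick:
0.5 s strides, duty factor 0.6, 3 cm stance knee height, 2 cm swing
amplitude, 50° TMP excursion, 10 cm toe advance per stride (≈ 50 cm/s swing
velocity), 4.2 cm foot separation, 0.05 cm Gaussian marker jitter, and zero
injection probabilities. One `numpy` Generator seeded from the params drives
every draw, so identical parameters give identical recordings.

Not emulated: ground-reaction forces and balance dynamics, marker dropout
bursts, velocity drift within a session, asymmetric left/right morphology,
and slipping. Passing detector tests on this generator therefore shows the
*scoring rules* are implemented correctly and recover what was injected; it
does not validate the rules against real tracked video.

The anatomy generator draws per-label Gaussian-mixture point clouds inside
the template (default: a "small" population in the dorsal aspect of lamina
VII and a "large" population ventrally, 344 and 33 points), soma diameters
from a two-component normal mixture (7 ± 1.5 vs 20 ± 1.5 µm, large fraction
0.09) with the true class retained per point, and bouton volumes lognormal
with log-mean ln 0.2 and log-SD 0.9 (≈ 12 % of mass below the 0.07 µm³
floor), synaptotagmin flags Bernoulli at 0.84. These laws reproduce the
*counts and proportions* structure of labelled hemicords; they do not model
spatial correlation between diameter and position beyond the label means.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make binomial/Monte-Carlo
intervals decisive while keeping the suite quick: 500 strides for
collapse-rate recovery, 1,000 random strides for the detector-vs-oracle
scan, 1,000/2,000 replicates for Welch power and type-I rates, 10⁴ shuffles
for the permutation null, 10⁵ replicates for the Dunnett oracle, 128² grids
for density fields. Tolerances: KDE integral ±1 %, landmark round-trips
1e-6, profile interpolation 1e-6, binomial 95 % intervals for stochastic
recoveries.

## Known limitations

- The overshoot criterion, the collapse evaluation window, the contact
  criterion and the lamina template are explicit design choices where the
  source analysis is qualitative or unpublished; all are configurable and
  none should be treated as a measured fact.
- The Watson–Williams test assumes von Mises samples with common, high
  concentration; the permutation cross-check covers the regimes used here
  but low-concentration data trigger only a warning, not an exact test.
- Welch comparisons at chick-level sample sizes (4–5 per group) have modest
  power at stringent α; the power/type-I tests quantify exactly this on the
  configured effect size.
- Event detection requires a visible ground line and a toe marker; it does
  not handle treadmill (belt-speed) recordings or partial occlusions beyond
  NaN flagging.
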