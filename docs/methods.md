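# Methods

This note documents the models and procedures implemented in `mitoflow`,
the choices made where the design was genuinely open, and what the
synthetic-data results do and do not establish about real recordings.

## Imaging model and calibration

The pipeline assumes single-channel time-lapse stacks of MitoTracker-labelled
neurons from a high-content confocal microscope: 0.108 μm/px at acquisition,
50 frames at 3.5-s intervals, 16-bit intensities. The optical resolution
bound for green emission is the Rayleigh limit 0.61·λ/NA ≈ 341 nm at
NA 0.95, about three binned-pixel widths, which is why mitochondria are
modelled as diffraction-blurred puncta rather than resolved shapes.

All pixel↔micron and frame↔second conversions go through a `Calibration`
object that tracks the acquisition constants together with the cumulative
spatial `bin_factor` and temporal `time_stretch`. After the standard chain
(bin 4×, stretch 2×) the working calibration is 0.432 μm/px and 1.75 s per
frame, so 1 px/frame = 0.247 μm/s and the histogram's upper bound of
e⁴ ≈ 54.6 px/frame corresponds to 13.5 μm/s.

## Preprocessing chain

1. **Average binning 4×** improves the signal-to-noise of fast, faint
   objects and reduces per-frame displacements into the range the flow
   estimator handles. Non-divisible sizes are trimmed at the trailing edge.
2. **Rigid registration** to the first frame removes stage drift.
   Translation is initialized by windowed cross-correlation (a Hann window
   suppresses the bias from border content, which does not translate under
   replicate-edge fill) and refined by Powell minimization of the
   mean-squared difference; rotation is an optional third parameter, off by
   default in the screen configuration since stage drift is translational.
   A dead-band (`min_shift_px` = 0.05 px) passes frames through unresampled
   when the estimated motion is negligible — resampling to correct
   sub-noise shifts only blurs the data and perturbs downstream temporal
   differences.
3. **Temporal stretching 2×** with a quintic B-spline: output frame j
   samples the per-pixel spline at time j/factor (edge-clamped at the final
   half-frame), so a T-frame movie yields exactly 2T frames and
   polynomials of degree ≤ 5 are reproduced exactly. Halving the effective
   frame interval halves per-frame displacements, again helping the flow
   estimator.
4. **Centered cropping** (450 px for the flow branch, 400 px for the
   tracker branch at full scale) removes registration edge artifacts. With
   odd remainders the extra pixel is removed at the bottom/right, so output
   pixel (0,0) maps to input pixel ((H−h)//2, (W−w)//2).

The tracker branch additionally standardizes contrast to 8 bits:
a stack-wide percentile stretch (5% saturated by default) followed by
histogram equalization weighted by the square root of the histogram — the
variant implemented by the image-analysis tool this workflow was built
around, which flattens the histogram while damping the over-amplification
of a dominant background band. Statistics are computed stack-wide, not per
frame, so genuine global flicker is left for the artifact mask to catch
rather than silently normalized away. On synthetic movies, which share one
known intensity scale and have featureless noise backgrounds, the screen
configuration uses the percentile stretch alone
(`contrast_method="none"`): equalization exists to standardize intensity
across real wells with autofocus and exposure variation, and on a flat
noisy background its nonlinear gain pushes sub-pixel jitter at spot flanks
above the difference filter's threshold.

## Dense Lucas–Kanade flow

Gradient volumes Ix, Iy, It are separable Gaussian-derivative filters at
spatial scale Σs and temporal scale Σt (kernel half-width ceil(3σ); the
truncated kernel carries ~1% less than unit derivative mass, a bias far
below the estimator's other error sources). Σs = Σt = 2 is required for the
flow magnitude to be linearly related to velocity; unequal values trigger a
warning. Frames within ceil(3Σt) = 6 frames of either end lack full
temporal support and produce no flow field, so a 100-frame stretched movie
yields 88 usable time points.

Per pixel, the windowed structure tensor G = Σ w²·∇I∇Iᵀ and right-hand side
b = −Σ w²·∇I·It are accumulated over an odd square window of half-width
max(1, ceil(3Σw)) — 3×3 at the default Σw = 0.3 — with squared Gaussian
weights. Where the smaller eigenvalue of G (closed form, no iterative
solver) reaches the gate τ, the 2×2 system is solved in closed form;
everywhere else the pixel reports zero flow and is marked invalid. A
"normal flow" branch (gradient-direction velocity where only the larger
eigenvalue passes) exists behind an option and is off by default: empty
regions should produce no output.

τ thresholds absolute eigenvalues, so its meaning is tied to the intensity
scale of the input. Movies are analyzed at their native 16-bit-like scale;
there, shot and read noise in empty background yields eigenvalues orders of
magnitude below the default τ = 0.02 while structured (spot) regions sit
well above it, reproducing the intended phenomenology: no output in empty
areas, faint small-magnitude flow over stationary mitochondria, bright
hotspots at transported ones.

**Calibration procedure.** `parameter_sweep` evaluates a grid of Σw
(0.1–1.0 in 0.1 steps) × τ (a 20-value geometric ladder from 10⁻⁵ doubling
to 5.24) over a user-chosen foreground ROI (contains moving structure) and
background ROI (empty), recording above-gate pixel counts, total flow and
velocity histograms. `select_parameters` picks the smallest Σw whose
foreground produces flow, then the largest τ at that Σw with zero valid
background pixels and nonzero foreground flow. On spot scenes the Σw choice
is structural: below Σw = 0.3 the 3×3 window's off-center weights are so
small that the structure tensor is effectively rank-1 and nothing passes a
full-flow gate.

**Known bias.** The estimator underestimates speed: temporal smoothing
bleeds pauses into runs and large per-frame displacements violate the
linearization. On synthetic movers at 0.4–1.5 px/frame the mode of the
above-gate speed distribution lands within a few percent of truth, and the
mean over a bounded run comes out ~7% low (slope ≈ 0.93); on real data,
where movers are dimmer and backgrounds structured, the published
underestimate is larger (slope ≈ 0.7–0.85 against manual tracking).

## Velocity histograms, montages and the artifact mask

Speeds √(vx²+vy²) are log-transformed (gated zero-flow pixels are treated
as missing, never as observations) and binned into 140 natural-log bins on
[−10, 4) — bin width 0.1, covering 4.5·10⁻⁵–54.6 px/frame; the log base is
natural because those are the bounds e⁻¹⁰ and e⁴. One histogram row per
time point, stacked in frame order, forms the velocity histogram montage.
Rows are normalized by their own mean, which factors out the total
structure count per frame and leaves the shape of the velocity
distribution.

The artifact score of a time point is the per-bin population SD over rows
{t−1, t, t+1} (truncated 2-row window at the ends), summed over bins.
Global flicker and residual drift change the whole distribution between
adjacent time points and score high. The retention rule rejects rows with
score above median + 3·MAD (MAD scaled by 1.4826), applied on the **log**
scale: the score is a positive, right-skewed statistic whose clean-sample
spread is multiplicative, and the linear-scale rule clips the genuine upper
tail of clean samples. If more than 40% of rows would be rejected the
sample is flagged failed rather than silently masked. The rule and
threshold are recorded with the mask.

Because the temporal Gaussian (Σt = 2) smears a corrupted frame over
±6 neighbouring flow fields, a time point is counted as artifact-touching
when it lies within that support of an injected frame. Five scattered
artifacts in a 100-frame movie would contaminate the majority of rows and
defeat any median-based threshold; the contaminated-well phenomenology this
mask is built for — and the scenario the synthetic tests reproduce — is a
*cluster* of bad frames, which the rule removes completely (100% of
touching rows at ~3% clean-row cost in the shipped scenario).

The flow ratio of a retained time point is the fraction of its histogram
counts in bins at or above the speed threshold (0.25 μm/s by default,
mapped to the nearest bin edge not below it after conversion to log
px/frame). The denominator is all finite counts in the row; gated pixels
never enter. A screen's ratio series are assembled into a time × sample
flow table with per-sample retained-row summaries.

## Difference tracker

The difference filter classifies pixel (t,y,x) as moving when
|I(t) − I(t±offset)| ≥ min_difference for either available direction
(maximum of the two; one-sided at the ends — the source plugin's exact
combination is undocumented, absolute differences are used). With the
defaults (offset 4 frames, threshold 20 on 8-bit data) an object must move
about one effective pixel per 7 s, i.e. ≥ 0.06 μm/s, to register. The
moving-only movie keeps original intensities at moving pixels.

Accumulated statistics: static/moving intensity sums, moving object counts
(8-connected components among pixels ≥ the intensity floor with component
intensity ≥ min_tracked_intensity), and static object counts as intensity
maxima of the static partition with prominence ≥ the floor. The maxima
definition for the static population — the same idea as the
total-mitochondrial-number estimate (`count_maxima`: quintic upscale, then
h-maxima) — is used because stationary mitochondria frequently touch, and
connected components would merge ~250 objects into ~30 blobs, deflating the
denominator of "count percentage moving". The definition in use is recorded
in the report metadata.

Feature detection finds 8-connected clusters (area ≥ 2 px, total intensity
≥ 20) with intensity-weighted centroids. Linking is greedy and
priority-ordered: per frame, active tracks claim features in descending
length order (ties to the older track); a newborn track searches within
10 px of its seed, an established track within 5 px of its
constant-velocity prediction (last step only); every feature joins at most
one track; unclaimed features seed tracks; a track that claims nothing
terminates (no gap closing); tracks shorter than 4 frames are discarded.
On well-separated movers this matches a brute-force globally optimal
assignment; it is not a global optimizer in general.

The motion report mirrors the combined filter/tracker output table
(static/moving intensity and counts with percentages, track count,
per-frame particle count, duration, area, mean and max speed per track in
μm/s via the effective calibration), and `treatment_ratio_report` renders
treated/control ratios to two decimals.

## Screen statistics

The experimental design rescans the same wells before (control) and after
treatment. Control wells are pooled into one reference group and each
treated sample is compared against it with Dunnett's many-to-one procedure
(exact equicorrelated multivariate-t critical points via
`scipy.stats.dunnett`, two-sided, family α = 0.05); a sample is significant
iff its simultaneous CI excludes zero. Observations within a series are the
per-time-point flow ratios of one well; time points within a well are
correlated with each other only through the well, and per-time values are
never pooled across wells as independent replicates except through the
control pooling the procedure defines. With one treated group the interval
reduces to the classical pooled-variance t-interval (agreement ~10⁻⁵,
limited by the quasi-Monte-Carlo quantile integration); under a simulated
global null the family-wise error rate is 0.04–0.05. Pairwise
comparisons use Welch's unequal-variance t-test.

## Synthetic movies: what they emulate and what they do not

A scene is a field of isotropic 2-D Gaussian puncta (σ = 1.5 px at the
binned scale, ~0.65 μm — the size regime the trackers are tuned to) on a
uniform background, with:

* **Density** ~250 spots per 144×144 px field, matching a well-populated
  neurite field where structured signal, not empty background, dominates
  the intensity histogram (this matters for contrast standardization).
* **Movers** (defaults ~1–2% of the population) following piecewise-constant
  run/pause schedules; the screen-well generator gives each mover three
  10-frame bouts of ~14 μm at 0.4 μm/s placed uniformly at random
  (non-overlapping within a mover, independent across movers), so every
  mover is active the same total time — the well's flow ratio is then
  proportional to its mover count — while bout onsets are spread over time
  as they are in real neurites.
* **Jitter** of stationary spots: i.i.d. sub-pixel wobble of 0.02 px
  (~9 nm) per frame at the binned scale. The published static/moving counts
  imply that real anchored mitochondria displace less than the difference
  filter's floor between offset frames; larger jitter floods the filter
  and contradicts those numbers.
* **Noise**: shot noise plus Gaussian read noise. Scenes generated directly
  at the binned working scale carry the noise statistics *after* 4×4
  averaging (16 photons per count-equivalent, read noise 2.5), which is
  what the analysis stages actually see.
* **Artifacts** on demand: global intensity flicker (multiplicative, one
  frame), stage drift (a global sub-pixel shift persisting from its frame
  onward, replicate-edge fill so no dark seam mimics motion), defocus
  (per-frame Gaussian blur).

Ground truth carries every mover's trajectory and speed series and the
artifact frame set; rendering is deterministic given the configuration,
including its seed.

Passing tests on these scenes demonstrate that the algorithms recover known
motion, reject injected artifacts and preserve treatment contrasts under
realistic geometry, counts and noise. They do **not** demonstrate
performance under elongated or touching organelle shapes, curved neurite
paths, structured backgrounds, focus drift, photobleaching, or wobble
regimes between "invisible to the difference filter" and "flooding it". One
published contrast does not transfer: on real data the flow-based percent
moving exceeds the tracker's severalfold (the tracker is the more stringent
instrument there), while on clean synthetic scenes the tracker flags
essentially all movers and the flow percentage — whose denominator is every
above-gate pixel of a densely structured field — comes out lower. The
shipped screen analysis reports both percentages without asserting their
order on synthetic data.

## Problem sizes and numerical notes

The shipped tests and the acceptance script use 144×144 px wells of
60 frames (8 per screen), 100-frame artifact movies, 120–128 px recovery
scenes, and 1000 null replicates for the Dunnett calibration; these sizes
were chosen so a full run completes in about a minute on one core while
keeping ≥100 retained time points per well for inference. Flow fields are
float64 end to end; the 2×2 solves use the closed-form inverse with a
determinant floor of 10⁻¹²; pixels passing the eigenvalue gate with a
numerically singular tensor are gated and counted. Degenerate inputs have
defined behavior throughout: constant movies equalize to mid-gray with a
flag, zero-variance samples raise a dedicated error, montages with fewer
than three rows get zero artifact scores with a warning, and an
over-rejecting mask flags the sample as failed instead of silently
masking.
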