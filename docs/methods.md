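# Methods

This note documents the models, parameter choices and numerical conventions
behind `glenostab`, and what the synthetic-data tests do and do not show
about real data.

## Densitometry

Clinical CT grayscale is converted to hydroxyapatite-equivalent bone mineral
density by a per-scan, phantomless calibration: the mean grayscale of three
internal reference tissues — air, subcutaneous fat and muscle — is pinned to
−840, −80 and +30 mgHA/cm³ respectively, and the grayscale→BMD map is the
piecewise-linear interpolant through those anchors. Outside the anchor range
the terminal segment slopes are continued; this matters because bone lies
well above the muscle anchor, and "linear interpolation" leaves the
extrapolation rule open — continuing the fat–muscle slope is the natural
choice and keeps the map monotone and total. Because the anchors are
re-measured per scan, any affine scanner distortion (gain g > 0, offset b)
cancels identically: the map fitted to distorted references composed with
the distorted image equals the undistorted map (verified exactly in tests).

Reference-tissue masks are supplied by the caller (synthetic ground truth
here; manual segmentation on real scans). Automatic tissue detection is out
of scope.

BV/TV is pure pixel counting: the fraction of VOI voxels whose BMD reaches a
global segmentation threshold. The threshold's published value is not
stated; the default is **100 mgHA/cm³**, chosen between marrow/fat (≈ −80)
and trabecular bone (≳ 150), configurable everywhere and recorded in every
pipeline report. No partial-volume or asynchronous correction is applied.

Note that the *mean BMD* of a VOI is an apparent density: it averages bone
and marrow voxels. With trabecular bone at ~215 mgHA/cm³ and BV/TV ≈ 0.65
the subchondral-cylinder mean sits near 0.65·215 + 0.35·(−80) ≈ 110
mgHA/cm³. Group *differences* in trabecular density propagate through this
mixture, which is what the cohort analysis uses.

## VOI geometry

The scapular axis runs from the glenoid centre to the root of the scapular
spine, oriented lateral→medial. Both cylinders use diameter = 0.5 × the 3–9
o'clock glenoid width at the articular surface. The vault cylinder spans
from the articular surface to the medial cortex along the axis; the
subchondral cylinder keeps the axis and diameter, has depth = vault/3, and
starts a configurable **2 mm** medial of the articular cortex so that a
superficial layer of possibly necrotic bone is excluded (the boundary
convention of the articular cortex is not published; a fixed offset is used
instead of image-based necrosis detection). Rasterization is
voxel-centre-in-solid with a half-open axial interval [start, start+depth),
matching the pixel-counting philosophy; the voxel count converges to
π r² h / voxel volume as spacing → 0 (tested at 0.6 and 0.3 mm — residual
error is dominated by axial quantization when the depth is not an integer
number of voxel layers).

## Planning geometry

A full wedge of angle θ under a circular baseplate of diameter D raises the
far rim by D·tan θ; the lateral offset at the implant axis relative to the
hinged edge is (D/2)·tan θ, which reproduces 2.1 mm (10°) and 4.4 mm (20°)
for the 24 mm baseplate, rounded to 0.1 mm. This trigonometric convention
is adopted as the definition (graft compression effects are ignored).
Corrective reaming removes the same wedge of bone, so the centre of rotation
medializes by the same magnitude (reported negative).

Seating quality: the wedge underside (an inclined plane whose downhill
direction rotates with the wedge) is translated along the implant axis until
it first touches the sampled bone surface; the contact fraction is the share
of footprint sample points with residual gap ≤ **0.1 mm** (configurable).
Wedge orientation is the smallest-magnitude rotation on a 1° grid over
[−180°, 180°) reaching the 80% contact threshold; failure to reach it is a
valid, flagged outcome. The planning software that produced the published
plans is proprietary, so the tolerance and grid are package choices exposed
as config keys. The 3 mm inferior-rim offset, 5° retroversion, 0° target
inclination and 3 mm glenosphere overhang are recorded as placement rules,
not optimized.

## Micromotion

Rigid-body poses per frame come from least-squares orthogonal (Kabsch)
alignment of each body's ≥ 3 labelled markers to the first frame, forced to
a proper rotation; marker correspondence is by persistent label. Micromotion
is the magnitude of the relative translation of the glenosphere with respect
to the glenoid rim, evaluated at a **reference point** — the glenosphere
marker centroid of the first frame, a proxy for the baseplate centre —
because translation of a rotating rigid body is point-dependent; the point
is overridable. Displacement is reported as the 3-D magnitude (the in-plane
ambiguity of a 2-D optical view is noted; a projection switch could be added
but the generator injects 3-D motion). Rotational displacement is the 3-D
angle between the first-to-last marker chords of the two bodies, as change
from the first frame. Both are invariant to any common rigid motion of the
scene (tested).

Shear cycles are segmented at positive-going mean crossings of the shear
channel. Because the bench drives at a known commanded frequency, detected
crossings are snapped to the nominal period at their circular-median phase,
which removes single-frame jitter from channel noise; if the observed period
disagrees with the commanded one by more than 20%, raw crossings are used,
and a constant channel falls back to fixed-length windows. Each outcome is
the mean over cycles of the within-cycle min-to-max range ("mean minimum to
maximum value of each shear load cycle"). Post-cyclic micromotion above
**150 µm** flags the construct as at risk for impaired osseointegration.

For graft-tracked constructs, the same machinery on the glenosphere–graft
and graft–rim pairs partitions the total motion into implant–graft and
graft–glenoid percentages (summing to 100).

**Noise floor.** With zero injected motion and 2.8 µm i.i.d. marker noise,
the mean per-cycle range of the relative-displacement series is positive by
construction (a range of a noisy series). Monte Carlo over 30 seeds gives a
mean ≈ 5.5 µm and maximum ≈ 6.4 µm; the documented noise-floor constant
used in recovery checks is **15 µm**, a deliberately safe upper bound.
Injected amplitudes of 10–200 µm and 0.05–0.5° are recovered within 5% plus
this floor.

## Synthetic data

*Phantoms.* The glenoid is a capped elliptical cylinder along a medial axis
(+x), with a cortical shell ≈ 1.2 mm (≥ 1 voxel) of 800 mgHA/cm³, a
trabecular interior, and three reference-tissue spheres lateral to the
articular face. Trabecular voxels are labelled bone/marrow by thresholding
Gaussian-smoothed white noise at the exact quantile that hits the target
bone fraction (to one voxel) — making BV/TV a nontrivial but countable
truth; bone voxels draw BMD ~ N(mean, 30), marrow ~ N(−80, 15). The true
grayscale field is the exact inverse of the phantom's own calibration
applied to the true BMD, then distorted by gain/offset and voxel noise
(default SD 5 grayscale units). Landmarks are emitted analytically.
Default grid 48³–64³ at 0.6 mm isotropic. The phantom does **not** model
realistic scapular shape, DICOM semantics, beam hardening or scatter, so
passing tests demonstrate correctness of the measurement chain, not
robustness to real-scanner artifacts or to landmarking error.

*Bench recordings.* 25 shear cycles at 1/6 Hz sampled at 5 Hz (750 frames);
430 N compression and 350 N shear amplitude recorded in the channel; six
markers per body on rings sharing angular stations (so first-to-last chords
are parallel at rest). The relative displacement follows a raised cosine,
(A/2)(1 − cos ωt), so each full cycle spans exactly the peak-to-peak
amplitude A and frame 0 is the rigid reference; rotation oscillates about
the implant axis *through the reference point*, so rotation leaks nothing
into displacement and both parameters are exactly recoverable. Post-fatigue
recordings add a constant permanent migration equal to `post_added_um` and
the same amount of extra elastic amplitude; the delta outcome therefore
equals `post_added_um` by construction. Generator defaults (not published
anywhere, chosen once as realistic for a stable construct): elastic
amplitude 40 µm, post-added 15 µm, rotation 0.10° (+0.02° post). These keep
the reference scenario well below the 150 µm limit, consistent with stable
primary fixation.

*Cohorts.* Five design cells (Reference n = 10; MA10/MA20/BIO10/BIO20
n = 5). Subchondral trabecular density per group defaults to the study
cohort's subchondral-cylinder statistics (Reference 238 ± 37, MA 217 ± 34,
BIO 211 ± 16 mgHA/cm³). Micromotion amplitudes are generator choices:
Reference 40 ± 10, MA 45 ± 12, BIO 60 ± 25 µm — BIO wider and higher to
represent the extra graft interface. BIO specimens draw (density,
micromotion) from a bivariate normal with ρ = −0.63; other groups draw
independently. Draws below 1 µm are clipped (rare; negligible effect on the
recovered correlation at the tested tolerance). Per-specimen phantom/bench
seeds derive from the master seed by fixed increments, so reproducibility
does not depend on iteration order.

## Statistics

Gating at α = 0.05: all groups pass Shapiro–Wilk and the Brown–Forsythe
(median-centred Levene) test → one-way ANOVA with Holm–Šidák-adjusted
pairwise t tests; otherwise Kruskal–Wallis with Dunn's pairwise z tests
(standard tie-corrected mean-rank formula, Bonferroni-adjusted; for two
groups Dunn's z² equals the Kruskal–Wallis H, used as a cross-check).
Groups smaller than 3 or with zero spread cannot be assessed for normality
and are routed non-parametrically. The variability-difference test is
Brown–Forsythe (omnibus + Holm-adjusted pairwise) — the variance check
already used in gating; constant groups return p = 1 with a warning.
Observed ANOVA power is the noncentral-F power at Cohen's
f = √(SS_between/SS_within) (via `statsmodels` `FTestAnovaPower`), which a
simulation oracle confirms within Monte-Carlo error; zero effect gives
power ≈ α, zero residual variance returns 1 with a warning. Significance is
inclusive (p ≤ 0.05). Under null simulations the gated pipeline's and
Pearson's type-I error sit inside the 95% binomial CI around 0.05 over
2000 replicates (tested). The small per-cell n (5) of the study design is a
known limitation flagged in report footnotes, not corrected for.

## Problem sizes and determinism

Test and analysis problem sizes are chosen for the package's own fast
feedback loop: phantoms 32³–64³, cohorts of 30, correlation recovery at
n = 5000 (standard error of r ≈ 0.009, comfortably inside the ±0.03
acceptance band), type-I calibration at 2000 replicates (binomial 95% CI
half-width ≈ 0.0096). All randomness flows through `numpy` `default_rng`
seeds; identical spec + seed reproduces outputs bit-for-bit, and the
pipeline writes byte-identical reports on rerun.

## Known limitations

* No contact mechanics, finite elements or bone-ingrowth biology: the bench
  generator *represents* motion outcomes, it does not predict them from
  bone density — the imposed BIO correlation is an input, not a finding.
* Landmarks are analytic; nothing is validated against manual landmarking
  variability.
* The global segmentation threshold and the articular-cortex start offset
  are defaults standing in for unpublished constants; both are config keys.
* The marker-noise model is i.i.d. isotropic Gaussian; real optical systems
  have anisotropic (out-of-focus-plane) and temporally correlated error.
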