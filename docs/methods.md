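# Methods

This note documents the models, conventions and parameter choices behind
`spindlequant`, in the order data flows through the package.

## Coordinate and axial-correction conventions

World coordinates are (x, y, z) in µm with x the spindle (pole-to-pole) axis,
y the transverse in-plane axis, z the optical axis. Arrays are stored
(C, Z, Y, X) or (T, C, Z, Y, X); voxel coordinates are (plane, row, col).

An oil-immersion objective imaging an aqueous sample compresses apparent
depth: a stage step of `z_step` advances the focal plane by only
`axial_scale × z_step` of true sample depth. We use `axial_scale = 0.81`
throughout, as a per-dataset configuration value (it applies to the oil
objective used for the measurements this package targets; set it to 1.0 for
calibrations where it does not apply). Consistency is enforced at both ends:
the renderer places a source of true depth z at plane index
`z / (axial_scale · z_step)`, and every measurement multiplies plane offsets
by `z_step × axial_scale`. The axial round-trip is therefore exact by
construction and is covered by tests rather than assumed.

## Synthetic spindle model

`make_spindle_model` builds a bipolar metaphase spindle: poles at
±length/2 on x; pair midpoints in a transverse disk (diameter ≈ spindle
width) with plate scatter x ~ N(0, 0.4 µm) clipped at ±1.5 µm; sister axes at
half-normal tilts (scale `tilt_spread_deg`, default 10°) with uniform
azimuth, or at an exact tilt when requested; sister separation exactly
`mean_separation` (default 0.98 µm) so recovery experiments have a sharp
planted truth. K-fibers are quadratic arcs pole → kinetochore bowing 0.3 µm
away from the axis; bridging fibers join sisters with a 0.1 µm sag toward
the axis; astral fibers are straight 3 µm rays from the poles. Default
microtubule numbers per fiber class are the electron-tomography-calibrated
values for RPE1 cells: k-fiber 12.6, bridging 3.8, astral 1.0.

`apply_depletion` scales per-class counts by retained fractions and deletes
`round(fraction × n)` randomly chosen bridging fibers. The default preset
encodes the augmin-depletion phenotype: bridging 3.8 → 1.2, k-fiber
12.6 → 9.6, and 41% of pairs left without a bridging fiber.

### Rendering and noise

Photometry is strictly linear: each fiber deposits `mt_count ×
unit_brightness` a.u. per µm of centerline (trilinear sub-voxel deposition at
half-voxel arclength steps), kinetochores deposit `punctum_brightness` as
point masses, and each channel is convolved with an anisotropic Gaussian PSF
(σ_xy, σ_z in true µm, converted to voxels per axis). Background is added
always; Poisson shot noise (at `poisson_gain` photons/a.u.) and Gaussian read
noise only when noise is enabled. All stochastic steps consume a
`numpy.random.default_rng(seed)`, making every generator a pure function of
its arguments.

Modality presets: confocal 0.083 µm pixels, 0.5 µm z-steps, PSF σ_xy 0.11 µm;
STED 0.020 µm pixels, 0.3 µm z-steps, σ_xy 0.035 µm. σ_z is 0.35 µm for both
(STED as used here sharpens laterally only). PSF widths are typical for these
modalities rather than measured values. Detector statistics are likewise a
modeling choice (no raw-image SNR was available to match): defaults
(`unit_brightness` 3000 confocal / 20000 STED a.u. per microtubule per µm,
background 20 a.u., gain 1, read noise 2 a.u.) give a single microtubule a
per-voxel peak SNR of ≈ 4–5, i.e. single MTs are visible but clearly noisy,
which is the realistic regime for these experiments. These constants are
config values, fixed once; tests and acceptance experiments run at these
defaults.

What the generator does **not** emulate: microtubule dynamics and forces,
fiber crossings and clutter beyond the planted geometry, depth-dependent
aberrations, bleaching, or camera fixed-pattern noise. Passing recovery tests
therefore demonstrates correctness of the measurement chain under the stated
optical model, not robustness to every artifact of real data.

### Anaphase trajectories and photoactivation

`make_anaphase_timelapse` generates coordinate tracks (default 30 s cadence):
poles separate at the anaphase B speed, each sister moves along the straight
line toward its pole so its kinetochore–pole distance shrinks at exactly the
anaphase A speed. Planted error classes: *misaligned* pairs sit wholly
outside the plate slab before onset (and optionally both segregate to the
same pole); *lagging* pairs stall one sister centrally with punctum
elongation 2.5 (the "visibly stretched" signal is modeled as a scalar
major/minor axis ratio attribute, not rendered); *other* pairs never
separate. Positional jitter is Gaussian (default σ 0.02 µm).
`make_photoactivation_series` renders a 2D+t series (default 10 s cadence):
a static spindle field with bright poles plus a transverse Gaussian mark
(FWHM 0.5 µm) moving toward the nearer pole at the planted flux speed.

## Measurement conventions

**Square-ROI scheme.** ROI sizes 25×25 px (STED, 0.5 µm) or 5×5 px
(confocal). Background is the mean of per-ROI means over empty areas — 10
random areas in STED, 2 areas flanking the bridging fiber in confocal
(enforced only in strict mode); astral background comes from the empty area
between two astral fibers. Corrected intensities may be negative and flow
into detection: a bridging fiber is "detected" iff `I_b > 0` strictly (an
optional z-score mode `I_b > k·σ_bcg` exists because photon noise makes the
zero threshold stochastic at the boundary).

**Line-profile scheme.** The contour profile (5 px line width) is
background-subtracted by the *minimum* of the midzone profile; the bridge
center is the midpoint of the minimal plateau of the subtracted profile
(plain argmin is ill-defined on flat-bottomed dips); `I_b` is the mean in a
window of total width 500 nm about the center and `I_bk` the mean of windows
at ±1.5 µm; `I_k = I_bk − I_b`. The 500 nm figure is read as total width
(±250 nm); the window half-width is a config knob since "around the center"
admits a ±500 nm reading.

**Localization.** Single puncta: iterative Gaussian-masked,
background-subtracted centroid (mask 1.5× PSF σ). Sister pairs:
`localize_pair` alternates between the two puncta, subtracting a PSF-shaped
model of the sibling (amplitudes solved from the 2×2 mutual-overlap system)
before each masked centroid — without this the sibling's tail biases
axially-oriented pairs by ≫ 0.05 µm; with it the mean recovered separation of
0.98 µm pairs is accurate to < 0.01 µm with residual underestimation only for
pairs nearly parallel to the optical axis.

**End-on transform.** Axis permutation (new stack axis = old x) followed by
1D resampling of the old-z axis by `axial_scale × z_step / pixel_size`;
linear interpolation by default, nearest-neighbor for strict intensity
conservation (exact when voxels are already isotropic). Bundle counting
operates on sum projections of 10 central end-on slices: Gaussian smoothing
(σ 0.08 µm), maxima closer than 0.3 µm merged, maxima below 10% prominence
over the median background discarded. The original analysis counted bundles
by eye; this operationalization is validated against planted counts
(28 planted → 28 ± 1 recovered under default noise).

**Circle fits.** Algebraic (Kåsa) fit seeding a geometric Gauss–Newton
refinement of orthogonal residuals; 3D traces are first projected onto their
total-least-squares plane (traces are made on rotated 2D images). Collinear
traces (transverse singular value < 1e−7 of the span) return an infinite
radius as a flagged result, not an error. Both objectives are available;
geometric is the default since the original script's objective is unknown.

**Rates and onset.** All rates are OLS slopes converted to µm/min; approach
speeds (flux, anaphase A) are reported positive, separation speeds
(anaphase B) positive. "Gradually increasing" is operationalized as the first
run of ≥ 3 consecutive frame-to-frame increases with cumulative rise ≥
0.1 µm; onset is the last frame before that run. Mark and pole peaks are
localized on σ = 2 px blurred profiles (10 px line width) with parabolic
sub-pixel refinement; flux fits use all frames with a detectable mark.

**Error classification.** Precedence misaligned > lagging > other.
Misaligned: both sisters outside the plate slab at the frame nearest
30 s before onset. The slab is center ± half-thickness estimated from the
pair-midpoint x-distribution (median, 2.5 × scaled MAD, floored at 1 µm) —
midpoints, not sister positions, so the interkinetochore distance does not
inflate the plate. Lagging: during anaphase a punctum with elongation > 1.5
inside the central third of the pole-to-pole span. Other: pairs whose final
separation stays below 2 µm, or late central non-stretched stragglers.
Missegregation: misaligned pairs with both sisters nearest the same pole at
the final frame; lagging pairs whose stretched sister ends nearest the pole
opposite its pre-onset side; equidistant endpoints are returned unresolved.
The "central third" reading of "outside the moving kinetochore mass" is this
package's choice and is deliberately parameter-exposed.

**Overlap length.** The "base of the PRC1 peak" is the contiguous interval
around the peak where intensity exceeds background + 10% of the peak height,
with linear interpolation at the crossings; the closed-form tests (Gaussian:
2σ√(2 ln(1/f)); triangle: 2w(1−f)) pin the semantics. The 10% base fraction
is an operationalization of a visual judgement and is exposed; absolute
overlap lengths therefore carry a systematic offset tied to that choice,
while comparisons at fixed fraction do not.

## Problem sizes

The validation experiments use 30 phantom spindles (90 astral fibers), 10
seeds × 28 bundles, 120 separation pairs and 78 tilt pairs — sizes chosen to
match the populations the measurements were designed for while keeping each
experiment in the seconds range; each pair/spindle is rendered in its own
small volume, which also guarantees measurement independence.

## Known limitations

- No fiber tracing or kinetochore detection from raw pixels: ROIs, traces
  and track seeds are inputs (or derived from simulation ground truth).
- The classifier assumes complete sister and pole tracks at a uniform frame
  interval, and its plate/central-region estimates assume a roughly
  axis-aligned spindle.
- The renderer's Gaussian PSF and single-plane ROI measurements idealize
  STED depletion physics and detector behavior.
- Multipolar spindles are out of scope; two poles are assumed everywhere.
- Pairs oriented within ~15° of the optical axis retain a small negative
  separation bias (PSF-overlap residual) that is visible in, but does not
  dominate, population means.
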