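# Methods

## Scope and data model

`rootkin` analyses 4D (3D + time) single-nucleus data from growing roots.
The pipeline is: simulate (or load) per-frame nucleus positions →
optionally render and re-detect voxel stacks → link detections into tracks
→ per-sample kinematics and coordinated motility → zone assignment and
spatiotemporal maps → reporter series → cohort feature matrices and
clustering. All stages operate on tidy tables (pandas DataFrames,
round-tripped as CSV) keyed by `(track_id, frame)`.

Conventions: right-handed µm coordinates, root axis +Y pointing shootward,
tip at y = 0 in the tip frame; display is tip-up (maps record the
orientation in metadata and flip rows only at plot time). Times are hours
internally; the acquisition interval is stored in minutes (8.75 min
default, 40 frames ≈ 6 h) and converted once. Because the acquisition
follows the tip (tip-tracking stage), the simulator's tip is stationary and
the lab and tip frames coincide by default; the tip trajectory is emitted
so either frame can be reconstructed if a moving-tip geometry is
configured. Whether real instruments report lab-frame or tip-registered
velocities is ambiguous in general; both frames are exposed and the default
is the imaged (lab) frame.

## The root-growth simulator

The simulator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

**Geometry and seeding.** `n_nuclei` (default 1000) are placed uniformly in
a cylinder of radius 60 µm over 0–1000 µm from the tip, spanning the three
developmental zones. Zone boundaries default to meristem 0–250 µm,
elongation 250–700 µm, differentiation beyond — the literature does not fix
these numbers and they are configurable.

**Axial velocity field.** v(y) = v_plateau · s((y − y_mid)/width) with s
the logistic sigmoid, v_plateau = 50 µm/h, y_mid = 100 µm, width = 40 µm.
The midpoint and width are chosen so the field has essentially reached the
plateau at the meristem/elongation boundary, consistent with
elongation-zone nuclei moving *steadily* at the plateau speed; the
integration uses RK4 with 6 substeps per frame (positional error ≪ the
0.5 µm detection jitter).

**Meristem skewing.** Nuclei within 250 µm of the tip are advected by a
rigid twist: angular rate ω about an axis tilted 5° from the root axis,
applied about each cross-section's center, giving lateral velocities
(ω cos τ · z, −ω cos τ · x) — anti-parallel on opposite flanks — plus a
small axial shear −ω sin τ · z. This field preserves each nucleus's radial
coordinate exactly, so all positions remain inside the root cylinder. The
default ω = 10√2 / 60 ≈ 0.236 rad/h is calibrated so the quadratic-mean
(RMS) lateral speed of meristem nuclei exceeds the elongation zone's by
10 µm/h (for a uniform disk, RMS radius = R/√2).

**Division.** Meristem nuclei divide as a per-frame Bernoulli approximation
of a Poisson process, default 0.05 events/cell/h (≈ 17 h cycle). A parent's
last frame is immediately followed by two children offset ±3 µm along a
random direction (clipped into the cylinder), with lineage recorded. The
tracker deliberately has no division model, mirroring surface-tracking
practice; its behaviour at divisions (one child continues the parent's
track, the other seeds a new one) is exercised by tests but exact-recovery
oracles run with divisions off.

**Scenarios.** `auxin_induction` multiplies axial velocities by a profile
that ramps up by 30% to a peak at 0.5 h and then declines exponentially
(default 0.5 /h); optional skew suppression decays ω with a 1 h time
constant. `exogenous_IAA(dose)` reuses the same profile with dose-scaled
boost and decay. The scenario also sets a phenomenological auxin level
a(t) = dose · (1 − e^(−t/2 h)) that drives the ratiometric reporter.

**Reporter model.** DR5-like intensity = baseline 10 au + 100 au ·
g(t) · exp(−(y − 400 µm)²/(2 · 150 µm²)), with g = 0 before a 2.5 h onset
delay and a saturating rise (τ = 1.5 h) after it. The DII channel decays as
100 · e^(−a(t)) while mDII stays at 100, so DII/mDII falls monotonically
under induction. These are phenomenological delays, not a signalling
model; no transport, tissue mechanics or wall geometry is simulated.

**Rendering.** Point mode perturbs true positions with isotropic Gaussian
jitter (0.5 µm), drops detections independently (2%), adds Poisson false
positives (0 by default), and attaches channel intensities with additive
Gaussian noise (sd 2 au). Exact bookkeeping (true − dropped + spurious =
detected, per frame) is recorded and asserted. Voxel mode paints nuclei as
3D Gaussian blobs (σ 2.5 µm) on an anisotropic ZYX grid and writes 16-bit
TZYX ImageJ TIFFs.

**What the simulator does not emulate.** Optical anisotropy and depth
attenuation, nucleus shape variability, drift, tissue-mechanical coupling
between neighbours, and realistic division orientation. Passing tests
therefore demonstrate that the *pipeline* recovers the kinematic structure
it is fed through realistic detection noise — not that real roots obey the
configured field.

## Detection

A surface-style pipeline on voxel stacks: Gaussian smoothing with
σ = grain_size/2 (grain 1.5 µm; the published grain size is a length scale,
so the σ conversion factor is explicit and configurable), background
elimination by grey-scale opening with an ellipsoidal ball of diameter
6.23 µm, a manual global threshold (20) on the background-corrected image,
connected components, and watershed region growing from component maxima
separated by at least the estimated nucleus diameter (8.30 µm). Components
failing a minimum voxel count or quality are discarded; *quality* is
defined transparently as the integrated background-corrected intensity of
the component. Published quality/voxel minima from commercial software are
instrument-scale values; the defaults here are scaled to the synthetic
renderings and must be recalibrated per dataset. Whether such voxel-count
thresholds apply to raw or supersampled voxels in the original software is
unknowable from the outside; the threshold is simply configurable.
Centroids are intensity-weighted; ellipsoid semi-axes come from
second moments via the uniform-ellipsoid relation (axis² = 5λ), with
eccentricity √(1 − (b/a)²) of the two largest axes and area the voxel
footprint of the XY projection.

## Tracking

Order-1 constant-velocity ("autoregressive motion" family) prediction from
each track's last two linked samples; cost = Euclidean distance between
prediction and candidate; links gated at max_distance (default 12 µm, the
midpoint of the commonly printed 9–15 µm range), scaled by (gap + 1) while
a track coasts across up to max_gap = 3 missed frames. Per-frame assignment
is Hungarian on a matrix augmented with per-track "miss" and per-detection
"birth" alternatives priced at the gate, so a link forms only when it beats
both; a greedy assignment is available for comparison. Bridged gap frames
are filled by linear interpolation and flagged. Track duration is the frame
*span* times the interval (a 40-frame track at 8.75 min lasts 20 475 s);
tracks under min_duration (3600 s) are dropped. Determinism: fixed
detection order plus Hungarian assignment; ties in cost are broken by the
solver's deterministic ordering.

## Kinematics and features

Central differencing is the default (half the noise variance of forward
differencing: jitter σ enters central-difference velocities with variance
σ²/(2Δt²) vs 2σ²/Δt² forward); forward is offered since real pipelines
vary. Velocity samples whose stencil touches an interpolated gap row are
flagged `from_gap` and excluded from summary statistics (falling back to
them only when a track has no clean samples). Acceleration is the forward
difference of successive velocities; displacement² is referenced to each
track's first sample. Coordinated motility uses 3D neighbourhoods of
radius 200 µm, excludes the center cell and zero-velocity neighbours, and
is undefined below 3 usable neighbours (the neighbourhood minimum is a
package choice; 2D-projected angles are not used).

The per-cell feature vector has 37 entries: {mean, sd, max} over time of
{vx, vy, vz, speed, velocity-total, |a|, θ, CM, displacement², lateral
speed}, plus duration, net displacement, path length, directionality ratio,
MSD log–log slope (first-quarter lags), and mean nuclear eccentricity and
projected area. The canonical list is exported as a machine-readable
manifest; it is a documented stand-in for fuller proprietary feature sets
and is versioned with the package.

## Zones, maps and skewing

Zone labels partition axial distance from the tip at 250/700 µm. The tip is
either taken from configuration (when the geometry is known, e.g. simulated
data) or estimated per frame as the 2nd percentile of detected Y (robust to
stray detections). Spatiotemporal maps are per-(axial bin × frame) means,
default 25 µm × 1 frame.

Skewing is quantified two ways. (1) A least-squares rigid-rotation fit
v ≈ ω × (p − c), solved linearly in (ω, b = −ω×c) with the center recovered
as the minimum-norm point; degeneracy (collinear cells) is caught via the
design-matrix condition number. (2) Model-free: the meristem-vs-elongation
lateral speed excess. Per zone the lateral speed is reported as the RMS of
(vx, vz) samples with the jitter-induced velocity variance subtracted —
jitter is estimated from second differences of positions along contiguous
tracks (variance 6σ² for smooth motion). The headline *excess* is the
quadratic difference √(ms_MZ − ms_EZ) of raw mean squares: measurement
noise (jitter and occasional link errors) loads both zones equally and
cancels exactly, the elongation zone — whose true lateral motion is
negligible — serving as an internal noise reference.

## Reporters

ROI quantification is the mean channel intensity of detections (point mode)
or voxels (image mode) inside an axis-aligned µm box, per frame; background
subtraction is off by default since normalisation conventions vary.
DII/mDII is the ratio of ROI channel means per frame, undefined where the
mDII mean is zero; it is invariant to common scaling of both channels.
Both per-cell and ROI-bulk modes are provided without asserting which a
given published panel used. Onset is operationalised as the first time a
series exceeds its baseline mean + k·sd (k = 3) for a persistence run of
consecutive frames; the recovery benchmark uses a 10-frame baseline and
3-frame persistence, which stabilises the sd estimate and rejects isolated
noise excursions at the cost of ~1 frame of latency.

## Cohort analysis

Replicate movies are pooled with track ids namespaced by movie; per-line
feature averages weight every cell-frame sample equally by default (a
per-track-mean mode is available — the natural reading of "averages over
all nuclei over time" is ambiguous). Features with too few samples in any
line are dropped for all lines. Clustering: Euclidean distance on
column-z-scored line profiles, average linkage (neither choice is canonical
in the source analyses; both are configurable), deterministic leaf order
via label-sorted input, Newick export, cophenetic distances reported, and
flat cuts for group-recovery scoring.

## Problem sizes and numerical choices

Recovery benchmarks run 1000 nuclei × 40 frames (the full study geometry);
unit and property tests use 60–500 nuclei × 10–20 frames, and the cluster-
recovery benchmark 80–120 nuclei × 16–20 frames per line — sizes chosen so
the whole suite exercises every stage end to end in about a minute while
leaving the recovery conditions at full scale. Degenerate inputs follow the
contracts: empty images yield zero detections (not an error); one-sample
tracks, empty framesets, empty ROIs, constant series and single-line
cohorts raise; zero-velocity cells propagate NaN markers rather than
exceptions. Zero-variance feature columns are dropped (with a warning)
before z-scoring.

## Known limitations

The tracker has no lineage model, probabilistic data association or drift
registration; the root axis is assumed straight within a movie (no midline
spline or curvature); reporter dynamics are delays, not signalling models;
and the acceleration magnitudes measured through realistic jitter are
noise-dominated (central-difference jitter propagates to tens of µm/h²),
which is precisely why acceleration-band checks are stated on the measured,
not the true, field.
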