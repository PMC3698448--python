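# Methods

This note documents the models, numerical choices and limitations behind
`presaccade`, a desk-scale simulation-and-analysis pipeline for cortical
source analysis of presaccadic event-related potentials (ERPs) in the
pro-/antisaccade paradigm.

## The phantom and what it emulates

The generator replaces an unavailable human dataset with a fully specified
synthetic one.  The head is a concentric-shell sphere — scalp, skull, CSF,
a thick gray-matter shell (55–78 mm of a 92-mm head) around a white-matter
core, plus two anterior "eye" spheres and a small nasal air cavity — stored
as an integer label volume in RAS head coordinates with the anterior
commissure (AC) at the origin.  A spherical geometry is a deliberate trade:
it gives up anatomical realism in exchange for an *analytic* forward
solution, which turns the numerical solver and the whole inverse chain into
testable code.  Named ROI "blobs" (ventral/dorsal anterior cingulate,
orbital-frontal, posterior cingulate, frontal pole, superior parietal,
pre/post-central; lateral ones in left/right pairs) are planted in the gray
shell at mutually disjoint positions ≥ 20 mm apart so that ROI-level
conclusions are not artifacts of overlapping definitions.

The electrode montage is a mirror-symmetric 128-channel layout on the scalp
sphere with a shipped "virtual 10–20" grouping table (20 groups; four
midline groups FrontalZ/CentralZ/ParietalZ/OccipitalZ and eight
left/right-paired lateral groups).  The mirror pairing — every off-midline
channel has a partner at the x-negated position, paired groups matching
member-by-member — is what makes the contralateral/ipsilateral recoding of
lateral data exact.

### Planted components

Three dipolar components reproduce the morphology of the presaccadic ERP:

| component | source ROI | waveform | alignment |
|---|---|---|---|
| pretarget negative slow wave (CNV) | dorsal ACC (central midline), inward-radial | linear ramp over the last second before target onset, resolving within 200 ms after it | target-locked |
| presaccadic positive slow wave | ventral ACC, radial | ramp from −150 ms to −10 ms before saccade onset | saccade-locked |
| spike potential | ventral ACC, radial | Gaussian pulse at saccade onset, σ = 5 ms | saccade-locked |

Dipole moments are *calibrated*: given the lead field, each component's
peak moment is set so that the noiseless scalp measure at its virtual
group equals a target in μV for the baseline condition (CNV −5.00 μV at
CentralZ when cued; positive slow wave +1.89 μV at ParietalZ for
prosaccades; spike +3.0 μV for prosaccades).  Condition effects are
multiplicative gains with defaults taken from the phenomenology of the
paradigm: the CNV is larger without a spatial cue (×1.13) and, in blocked
runs, larger for antisaccade blocks (pro ×0.88); the positive slow wave is
larger before antisaccades (×1.233); the spike is larger before prosaccades
(anti ×0.667).  With these amplitudes, 40 trials per cell and the default
sensor noise, each planted ordering is separated from its standard error by
roughly 3σ at the group-measure level — detectable in most random seeds but
not trivially so.

### Trials, latencies, artifacts

Trials follow the paradigm's block structure: 2 s pretarget, 2.5 s target,
1–3 s inter-trial interval; mixed-choice blocks run 2 antisaccade :
2 prosaccade : 1 catch per shuffled 5-trial sub-block, blocked runs
4 : 1.  Saccade latencies are lognormal with additive condition effects on
the mean; default cell means (cued pro 409.6, cued anti 461.6, uncued pro
434.5, uncued anti 511.5 ms; sd 90 ms; blocked runs −30 ms) reproduce
cued/uncued marginals of 435.6 / 473.0 ms with a larger cue benefit for
antisaccades.  RTs are snapped to the 4-ms sample grid and clipped to
[152, 900] ms.  Sensor noise is white Gaussian per channel and sample
(default 5 μV), independent across trials; spatially correlated noise is
deliberately not modeled (see limitations).  The EOG is a single bipolar
channel: a ±50 μV step at saccade onset signed by the executed direction.
Error trials (default 3%) execute a direction-flipped saccade; blink trials
(2%) add a 200-ms, 100-μV deflection to frontal channels and the EOG.  Both
are flagged in the ground-truth trial table, and the rejection stage drops
them, mirroring the "incorrect eye movements or blinks excluded" rule.

## ERP conditioning and component windows

Epochs are fixed-length at 250 Hz: target-locked [−1100, +800] ms
(476 samples, baseline mean over [−1100, −1000] ms subtracted per trial)
and saccade-locked [−300, +100] ms (no baseline).  Rectangular storage of
the nominally variable "until the saccade" segment changes no windowed
statistic, since all windows lie inside both epochs.  Referencing is the
algebraic average reference; for lateral analyses left-directed trials have
their mirror-paired channels swapped so the movement is rightward on every
trial.

The three component measures are:

* **pretarget negative slow wave**: mean over [−50, 0] ms minus mean over
  [−1000, −950] ms, target-locked;
* **presaccadic positive slow wave**: mean over [−50, −20] ms,
  saccade-locked;
* **spike potential**: mean over [−8, +8] ms minus mean over
  [−24, −16] ms, saccade-locked.

**Window statistic.** A window mean is computed as the time-average of the
linearly interpolated waveform over the closed window (trapezoidal rule).
For the piecewise-linear signal that samples represent this integral is
exact, and—unlike a plain mean of in-window samples—it is well defined when
a window endpoint (−50, −950 ms) does not fall on the 4-ms grid that
contains t = 0.  It makes the ramp benchmark exact: a ramp from 0 μV at
−1000 ms to −6 μV at 0 ms yields precisely (−5.85) − (−0.15) = −5.70 μV.
A plain sample-mean mode (13 samples per 50-ms window) is available via
configuration for comparison; it yields −5.712 μV on the same ramp because
the in-window sample times average to −24 and −976 ms.

## Forward models

Two engines produce the gain matrix (μV per nAm, free orientation,
average-referenced; columns sum to zero over channels).

**Analytic sphere.**  The potential of a current dipole inside a
multi-layer concentric sphere with insulating outer boundary is computed
from the spherical-harmonic series; for each order *n* a small linear
system imposes continuity of potential and radial current at every
interface and zero current at the outer surface, yielding a radial transfer
factor G\_n (equal to (2n+1)/n in the homogeneous case, verified to machine
precision).  The series is truncated when terms fall below 1e−12 relative
(eccentricity ≤ 0.85 keeps this under ~200 orders).  The central radial
dipole reproduces the closed form V = 3p/(4πσR²) exactly.

**Finite difference.**  On the labeled voxel grid the quasi-static problem
∇·(σ∇V) = ∇·J is discretized with a 7-point finite-volume stencil;
face conductances are harmonic means of the adjacent voxel conductivities,
and the outer boundary is insulating by construction (zero-conductivity
background).  Lead fields are assembled by *reciprocity*: unit current is
injected at each electrode's nearest scalp voxel with the reference
electrode's voxel grounded (one linear solve per electrode), and the gain
for a dipole at a node is the central difference of the reciprocal
potential across the node's neighbor voxels — the discrete equivalent of
two opposing monopoles one voxel apart, exact under the discrete operator's
self-adjointness (verified against direct source solves at 1e−6).
The default solver is one sparse LU factorization shared by all electrode
solves; an iterative option (ILU-preconditioned BiCGStab, relative residual
1e−8, GMRES fallback) exists for larger grids.  Conductivity defaults
(S/m): scalp 0.33, skull 0.0042, CSF 1.79, gray 0.33, white 0.14, eye 0.50,
air cavity 1e−8 — literature-standard values, fully overridable.

**Validation protocol.**  The engines are compared on a homogeneous sphere
via the relative difference measure RDM = ‖l₁/‖l₁‖ − l₂/‖l₂‖‖ per column,
with both engines given the *same* electrode set (positions snapped to
scalp voxel centers); this isolates solver error from electrode
discretization.  At 3-mm voxels the maximum RDM over random source columns
is ≈ 0.08, and the mean RDM shrinks monotonically with voxel size.

## Inverse model

The minimum-norm transfer is T = Kᵀ(KKᵀ + αH)⁺ with H the average-reference
centering operator; the pseudo-inverse uses an eigendecomposition with a
1e−10 relative cutoff.  sLORETA standardizes each node's 3-vector estimate
by its 3×3 block of the resolution form S = T·K, reporting the non-negative
magnitude √(ĵᵀS⁺ĵ).  Default regularization is α = trace(KKᵀ)/(n_ch·SNR²)
with SNR = 10, logged on every kernel build; α = 0 is supported.  Two
consequences are load-bearing and tested: noiseless single sources are
localized *exactly* (the standardized map peaks at the generating node, at
α = 0 and the default alike), and the map is invariant to adding any
constant to all channels (data are explicitly re-centered before applying
T, so the invariance holds to machine precision rather than to the rounding
of T·1 ≈ 0).  Reported units are nAm-equivalent standardized magnitudes;
because orientation is free and the readout is a magnitude, signed source
time courses are not available, and ROI aggregation (below) divides by ROI
volume to give an average current density per mm³.  Raw unstandardized
magnitudes are available via `standardized=False`.

## ROIs

ROI recipes are data (YAML), executed left-to-right over atlas labels:
`union`, `mask_ac` (keep voxels anterior y ≥ 0 and/or superior z ≥ 0 to the
AC, or the complements; inclusive of the AC plane), `dilate` (Euclidean
distance between voxel centers — a true ball element, so 3-mm dilation of
one 1-mm voxel gives the 123 lattice points with ‖x‖ ≤ 3), and `intersect`
with a nested sub-recipe (the idiom for an intraparietal-sulcus ROI as the
overlap of 3-mm-dilated inferior and superior parietal sets).  On the
lattice, composing dilations is *contained in* the summed dilation
(two-step points satisfy the triangle inequality; the converse fails
because intermediate points must be voxels) — the tests check this
containment.  ROI time courses sum member-node CDR per 4-ms slice and
divide by ROI volume; the default source space places one node per gray
voxel so node counts track ROI volumes exactly.  Lateral ROI values can be
re-keyed contralateral/central/ipsilateral by the movement direction.

## Statistics

The analysis unit is the session.  Virtual-group analyses use the
multivariate approach to repeated measures: member channels form the
response vector, within-unit orthonormal contrasts reduce conditions to
scores, and Wilks' Λ = det(E)/det(E+H) with Rao's F tests each effect
(exact for the one- and two-response cases; the single-variable case
reduces to the univariate F identically).  The univariate
repeated-measures ANOVA is built from the same contrast scores; two-level
factors are sphericity-free, and factors with ≥ 3 levels (the
contralateral/central/ipsilateral Side factor) receive Greenhouse-Geisser
correction.  No correction is applied across electrode groups or ROIs by
default.  The degrees of freedom are those implied by this model; they are
reported as computed and are not tuned to match any published table.
Latency summaries report condition means, standard errors and cue-benefit
differences over valid non-catch trials.

## Problem sizes and reproducibility

Default study conditions: 128 channels; 4-mm phantom voxels
(~20,000 gray-voxel source nodes for ROI work; an 8-mm subsample of
~2,500 nodes for localization sweeps); 40 saccade trials per
procedure × cue × movement cell; sensor noise 5 μV; 8 sessions in the
one-command pipeline.  The forward-oracle comparison runs at 3-mm voxels
(~120,000 unknowns, one LU factorization).  The ordering-recovery study
uses 20 independent seeds; the Type-I calibration 2000 null replicates.
Every random draw flows from a single `numpy` Generator seeded from the
configuration, so a fixed config reproduces trial tables and component
tables bit for bit; the pipeline stamps each run with a config hash.

## Limitations

The phantom validates the *machinery*, not anatomical claims: spherical
geometry, radial dipoles and white uncorrelated noise are all favorable to
source reconstruction, so passing the recovery study shows the pipeline
recovers what was planted under its stated conditions — not that effects of
this size are recoverable from real EEG, where correlated background
activity, skull inhomogeneity and co-registration error dominate.  The
generator does not model saccade kinematics beyond onset time, ocular
artifact physics (the EOG step and blink boxcar are schematic), overlapping
components from preceding trials, or participant-level nesting of sessions
(a participant aggregation option exists in the stats layer, and
sessions-per-participant is configuration, not a fixed constant).
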