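# Methods

This note records the models behind `sonoplan`, the parameters that matter,
the choices made where the design was genuinely open, and what the synthetic
experiments can and cannot show.

## Anatomy and gray values

Phantoms are parametric: an ellipsoidal body, an ellipsoidal prostate PTV,
bladder (anterior–superior) and rectum (posterior, elongated cranio-caudally),
capsule/box bone elements (femoral heads, sacrum) and spherical bowel-gas
pockets. Gray values use the offset-1000 scanner convention — air ≈ 0,
water ≈ 1000, soft tissue 1050, bone 1700, gas 100 — because the viewport
thresholds (dense > 1300, gas < 400) are only coherent on that scale; with
signed Hounsfield units every soft-tissue ray would fail the gas rule.
Coordinates are mm in a right-handed patient frame (x left, y posterior,
z superior); a voxel is the closed cell around its center and the volume
origin is the center of voxel (0,0,0).

Two cohort scales exist. `scale="clinical"` draws PTV volumes across
25–120 cm³ in a full-size pelvis. `scale="desk"` draws the small end of that
range (25–45 cm³ generally; the bundled study uses 25–35 cm³) in a compact
pelvis; it is the default for the test suite and the bundled study, chosen so
repeated LP planning runs in seconds on one CPU. The anatomy layout is
identical at both scales.

Shell bands are built from the Euclidean distance transform of the PTV mask:
SHELL3 holds voxels at distance (0, 3] mm to the nearest PTV voxel center,
SHELL9 at (3, 9] mm, both restricted to the body and excluding PTV and
organ-at-risk voxels — every voxel carries exactly one label, priority
PTV > OAR > shell, which the LP's disjoint row blocks require. The planning
grid discretizes all regions at 3 mm by assigning each lattice cell the
region covering its center with the same priority.

## Dose model

Dosimetry is intentionally minimal but physically shaped, and linear in MU:

d(p) = D₀ · Π(ℓ/r) · exp(−μ · r_rad) · (800 / ‖p − s‖)²

inside the collimator cone (lateral distance ℓ of the voxel center from the
beam axis at most the cone radius r = (diameter/2)·‖p − s‖/800) and exactly
zero outside. Sources sit on an 800 mm shell about the target centroid,
sampled uniformly on an anterior–superior cap (half-angle 80°, axis
(0, −1, 0.6)); vendor node geometries are proprietary, so this documented
stand-in is used. Collimator diameters are 10/15/20/30/40 mm.

- μ = 0.005 mm⁻¹ is an effective attenuation for ~6 MV photons.
- r_rad is the water-equivalent depth along the *central axis* from the body
  entry point, interpolated at the voxel's axial projection — the classic
  pencil-beam approximation; one 1 mm midpoint march per beam. Relative
  density is ρ = max(gray/1000, 0) with trilinear interpolation.
- Π is the collimator penumbra: flat at 1 out to 50 % of the cone radius,
  feathering linearly to 0.15 at the geometric edge, zero beyond. Real IRIS
  fields have mm-scale penumbra; a hard top-hat profile makes the narrow
  prescription window (36.25–40.25 Gy on every PTV voxel) unattainable with
  desk-scale candidate counts, which would leave the 95 %-coverage operating
  point out of reach.
- D₀ is calibrated per volume so a single 40 mm beam along the nominal
  anterior-superior axis delivers the 36.25 Gy prescription to the PTV
  centroid at exactly the 300 MU per-beam cap.

The kernel sits behind `compute_dose_matrix` so a more sophisticated model
can be swapped without touching the planners. `radiological_depth` itself
(1 mm trilinear midpoint integration) is exposed separately and is exact to
its quadrature.

## Two-stage planning

Stage 1 solves

min Σ_{i∈PTV} u_i  s.t. u_i ≥ D_rx − d_i, u_i ≥ 0, d ≤ caps, 0 ≤ w ≤ 300,
Σw ≤ 40 000

with hard caps 40.25 Gy (PTV), 36 Gy (bladder/rectum) and the shell bounds.
Coverage — the fraction of PTV voxels with d_i ≥ 36.25 Gy − 10⁻⁹ — is never
inside the LP; it is counted afterwards on the same grid used for
optimization (no resampling separates the two). Stage 2 minimizes Σw subject
to d_i ≥ d_i(stage 1) on PTV voxels plus all stage-1 caps; on numerical
infeasibility the lower bounds are relaxed once by 10⁻⁹ Gy before erroring.
Both stages use HiGHS dual simplex through SciPy with default deterministic
options; vertex solutions keep the weighted subset sparse, which the
imbalance statistics of the learning stage rely on.

Shell calibration bisects a single scale factor s with
(shell3, shell9) = s · (36.25, 21.75) Gy — the 0.6 inner/outer ratio and the
single knob keep the per-case tuning deterministic, since the original
procedure is not specified beyond its 95 % target. The bracket grows/shrinks
by factors of 2 from s = 1, then bisects, at most 12 LP solves in total,
stopping once stage-1 coverage lies in [95 %, 95.25 %]. If even unconstrained
shells cannot reach 95 % the unconstrained bounds are returned with a warning
rather than an error.

## Viewports

Skin points are body-surface voxels (gray ≥ 500, interior holes filled)
subsampled to ~5 mm bins (binned relative to the body centroid, making the
map translation-equivariant) and restricted to an accessible zone — outward
directions that are not posterior (y-component ≤ 0.2) or that face inferior
(perineal). Each point's ray to the PTV centroid is sampled at 1 mm strictly
inside the body; the first 2 mm after the skin are excluded from the gray
tests so air/skin partial-volume interpolation cannot trigger the gas rule.
Feasible means max gray ≤ 1300, min gray ≥ 400 and in-body depth ≤ 120 mm;
rejection reasons report with priority dense > gas > depth.

## Robot proxy and blocking

The arm is a three-capsule chain: upper arm and forearm of 460 mm (60 mm
radius) and a 120 mm probe link whose capsule radius 16 mm wraps the 24×26 mm
transducer footprint. Given a base position and the transducer pose (axial
axis at the target centroid; mounting rolled toward the base, with the
patient-superior fallback when collinear), the wrist point is fixed and the
elbow lies on the self-motion circle of radius √(460² − (d/2)²) in the
bisecting plane — the LIFT angle parameterizes exactly the redundancy that
lets the arm move without moving the probe. Configurations are infeasible
outside a base–wrist distance of [150, 920] mm; infeasibility is a value,
not an error. Base positions live in three axis-aligned boxes (left, right,
between the legs) with fixed base rotation.

Blocking is capsule-versus-cone clearance: blocked iff some capsule segment
passes within (capsule radius + cone radius at the closest axis point +
20 mm motion margin) of the beam's source→target segment. The closed form is
validated in the test suite against a 500-ray Monte-Carlo cone-casting
oracle (≥ 99 % agreement required; residual disagreements must flip within
±0.5 mm of the margin). With k LIFT angles the blocked set is the
intersection over all solvable configurations; the default triplet is
{−30°, 0°, +30°} about the nominal angle (the spacing is a configuration
choice, not a measured quantity).

## Beam scorer

Each candidate beam is summarized on the plane through the PTV centroid
perpendicular to the source→centroid line: a binary aperture image and
min/max radiological-depth projections (water-equivalent mm *from the
source*, so the images encode source distance and tissue) of PTV, rectum and
bladder; no-hit pixels are 0. The reference raster is 150×150 px at 1 mm;
the bundled pipeline renders 32×32 px at 4.7 mm over the same field of view
with 4 mm nearest-neighbor ray sampling (a numba kernel with a bit-identical
NumPy fallback).

The regressor is 3 stride-2 3×3 convolutions (8/16/32 channels), ReLU, dual
global pooling (mean and max per channel) and a 2-layer head with one scalar
output, ~20 k float32 parameters. The net regresses w/300; predictions are
rescaled and clamped to [0, 300] MU. Training recipe:
15 epochs of Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷), learning rate stepped
10⁻³ → 10⁻⁴ → 10⁻⁵ every 5 epochs, under the coverage-weighted piecewise
loss

l = (w_p − w_g)² · c_des/c_p  (w_g = 0),  (w_p − w_g)² · c_p/c_des  (w_g > 0)

with c_des = 0.95 — confident negatives come from low-coverage plans,
confident positives from high-coverage ones; the formula is genuinely
discontinuous in w_g, by design. Per-channel input
standardization is computed on the training fold and stored with the scorer.

Unweighted beams are subsampled before training. The imbalance ratio
w_b = #unweighted/#weighted is measured from the data; each w_g = 0 example
is kept with probability 1/w_b (approximately 1:1 balance). The literal
alternative — *dropping* with probability 1/w_b — barely rebalances and is
available behind `mode="drop"`; keep is the default because rebalancing is
the stated purpose of the step. When the measured ratio is below 1 (small
candidate sets can weight most beams) nothing is dropped.

Two training hyperparameters are not fixed by the recipe and were set by a
held-out-phantom experiment: batch size 8 (the 15-epoch schedule needs the
extra optimizer steps to converge from random initialization — the original
approach starts from pretrained weights instead) and a 20 000-example cap
(seeded uniform subsample after balancing; ~200 examples per plan are
rendered) that keeps single-CPU training near two minutes. Cross-validation
folds, when used, deal phantoms serpentine in PTV-volume order so fold
volume distributions match; a phantom never splits across folds.

CNN-guided candidate generation is plain rejection sampling: draw from the
node-shell sampler, accept with p = w_p/300, repeat until n beams are
accepted (clamping w_p before sampling keeps p ≤ 1). The acceptance rate
roughly equals mean(w_p)/300 — a few percent here, since desk-scale plans
spread modest MU over many beams — and a stall guard errors out if it falls
below 10⁻⁴ over 10⁵ draws.

## Setup annealing and workflows

The annealer is standard Metropolis over (base box + position, viewport
index, LIFT angle): worsening moves accepted with exp(−Δ/Θ), Θ₀ = 10 halved
every 100 iterations, 1000 iterations, best of 5 random restarts. The move
set (paper-silent, therefore an artifact choice, all config-exposed): base
jitter σ = 30 mm clipped to its box, box switch, viewport hop within 25 mm
(uniform with probability 0.1), LIFT jitter σ = 15°, each with probability
1/4, resampled to feasibility at most 50 times. Objectives: BR/BC count
blocked beams; BRW/BCW sum the blocked beams' weights (plan MU for BRW,
predicted weight for BCW) — the weighted versions give the search a more
graded landscape. Workflows compose the stages: candidate generation (random
or CNN), optional setup search with blocked-beam removal (on the scored set,
or — the starred variant — scored on the weighted subset with the found pose
applied to the full set), then two-stage planning.

## The bundled study and its limits

`sonoplan.study.run_desk_study` fixes the package's self-contained
experiment: 10 training phantoms × 10 plans × 500 candidate beams at a fixed
shell scale of 1.5 (placing training plans near the 95 %-coverage operating
condition), scorer training as above, then 5 held-out phantoms where a
random 500-beam set and a CNN-sampled 500-beam set are re-planned after
removing the beams blocked by one BCW-annealed robot setup. Reported
numbers: mean coverage per candidate source, total MU, pooled Spearman
between predicted and plan weights, acceptance rate.

What passing shows: on anatomy with the assumed structure, scorer-guided
candidate generation enriches plannable beams enough to raise coverage at
fixed candidate budget, and the blocking/setup machinery behaves per its
invariants. What it does not show: clinical dose accuracy (the kernel is a
stand-in), real ultrasound visibility (gray-value ray tracing only),
absolute coverage/MU levels of any clinical cohort, or CNN transfer to real
CT texture — phantoms have none.

## Numerical conventions

- Dose comparisons for coverage counting use a 10⁻⁹ Gy tolerance.
- Ray marches: 1 mm midpoint steps with trilinear density for dosimetry;
  feature rendering uses nearest-neighbor sampling at a configurable step.
- Ties in voxel labeling resolve PTV > bladder/rectum > SHELL3 > SHELL9.
- All randomness flows through counter-based child seeds
  (`SeedSequence((master, *key))`, reduced mod 2³¹), so any cohort row or
  plan is reproducible in isolation.
- Degenerate inputs: empty PTV, all-air volumes, beams missing the body,
  unreachable bases and zero-feasible-viewport maps raise typed errors (or
  return documented sentinel values) rather than propagating NaNs.
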