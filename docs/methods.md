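# Methods

## Model and assumptions

The skeletal model is a tree of rigid segments rooted at the pelvis. The hip
is a 3-DOF ball-and-socket (intrinsic X-Y-Z Euler angles); knee, talocrural
and subtalar joints are 1-DOF hinges; a patella, when present, is
pose-coupled to the knee flexion angle through an interpolation table and
adds no degrees of freedom (coupled bodies are treated as massless
attachment frames in the dynamics). The floating base contributes six
coordinates (pelvis translation + intrinsic X-Y-Z orientation). All
quantities are SI in right-handed frames; gravity is 9.81 m/s² along −z;
body-weight normalization happens only at reporting boundaries.

Muscle elements are constant-strength actuators: a strength `N_i` (N)
independent of length and velocity, with activation `a_i = f_i/N_i`. This
"simple muscle model" is adequate for normal gait, where force–length and
force–velocity effects are secondary; it is a stated limitation for more
dynamic activities.

Forward kinematics propagates rotation matrices **and their first and second
time derivatives** analytically through the tree (product rule on the factor
decomposition of each joint rotation), so segment accelerations used by the
inverse dynamics are exact for a given `(q, q̇, q̈)` — no frame-to-frame
differencing inside the dynamics. Rotations are built from plain `sin`/`cos`
matrix products, keeping every kinematic quantity dtype-generic (the test
oracles exploit this).

## Pipeline stages and the choices inside them

**Filtering.** Markers and ground-reaction forces pass a second-order
zero-phase (forward–backward) Butterworth low-pass, cutoff 5 Hz. Zero phase
means the amplitude response is the squared single-pass response, so a
sinusoid at the cutoff emerges at half amplitude — a property the tests
check analytically. NaN gaps must be filled first: linear interpolation up
to 0.1 s, longer gaps drop the marker for those frames with a warning.

**Hip joint centre.** The hip centre in the pelvis frame follows the
three-predictor pelvic-landmark regression (pelvis width = inter-ASIS
distance, pelvis depth = mid-ASIS to mid-PSIS, leg length; coefficients in
millimetres live in one function, `harrington_hjc`, so they can be checked
against the source in one place). The regression frame (x anterior, y
superior, z lateral-right) is mapped into the model's pelvis frame by an
axes block shipped with the model. Leg length is taken as the sum of the
scalable non-pelvis segment lengths — the measurement recipe is a repo
choice, since only the constraint itself is prescribed by the approach being
implemented.

**Calibration.** Segment length scales (and optionally local marker
coordinates) minimize the cumulative weighted squared distance between
measured and model markers over a set of calibration frames, with per-frame
postures solved as an inner weighted nonlinear least squares (Levenberg–
Marquardt, tolerances 1e-14) inside an outer trust-region least squares over
the scales (bounds [0.2, 5], tolerance 1e-10, evaluation cap 200). Markers
on palpable bony landmarks weigh 10, others 1 (configurable; only the
*principle* of higher bony-landmark penalties is prescribed). When a hip
joint is named, its centre is re-pinned to the landmark regression after
every scale update, so the constraint holds throughout. Calibration frames
default to 10 evenly spaced frames of the trial.

**Velocities and accelerations** come from central finite differences of the
filtered joint-angle series (one-sided at the ends) — the inputs are
filtered; differentiation scheme is a repo choice.

**Inverse dynamics** is a leaves-to-root Newton–Euler recursion. Net joint
moments are reported about the joint centre in the child frame; for
recruitment they are projected onto each joint's velocity basis (hinge axis;
for ball joints the columns `e_x, R_x e_y, R_x R_y e_z` rotated by the
parent attitude), which makes them exactly conjugate to the tendon-excursion
moment arms `-∂L/∂q`. Ground reactions are applied at the centre of pressure
to the foot a plate is mapped to, gated by a 20 N vertical threshold; double
support simply yields two simultaneous applications.

**Muscle wrapping.** One cylinder per path span, fixed to one segment, with
an explicit `wrap_side` chirality (automatic side inference is ambiguous at
grazing incidence). The span engages when its projected straight chord
passes closer to the axis than the radius; the wrapped route is the two 2-D
tangent lines plus the geodesic between the tangent points, whose
out-of-plane coordinate advances linearly with unrolled arc length, giving
`L = hypot(l₁ + r·Δφ + l₂, Δz)`. Length is continuous (C⁰) across
engage/disengage on the configured side; popping off the *far* side of an
undersized or misplaced cylinder is discontinuous, which is exactly what the
moment-arm sweep's discontinuity detector (default jump threshold 10 mm
between grid points) is for. Ellipsoids/tori and multi-surface obstacle sets
are out of scope: individual cylinders per element are sufficient, faster,
and cannot let elements slide off.

**Moment arms** use the tendon-excursion definition `-∂L/∂q` by central
differences with one Richardson extrapolation step (base step 1e-5 rad).
Positive arm ⇔ positive generalized moment for positive tension. A muscle
not spanning the dof's joint reports a structural zero (`muscle_spans_joint`
distinguishes it from a true zero arm).

**Recruitment** minimizes `Σ a_i^p` (default p = 3) under `R f = τ, f ≥ 0`.
The KKT conditions give a closed-form monotone map from the equality
multipliers to forces, so the solver is a damped Newton iteration on the
dual (tolerance 1e-9, deterministic start along the least-squares multiplier
direction), with an SLSQP fall-back and a linear-program phase-1 certificate
that reports the violated dofs when no nonnegative solution exists —
infeasible frames fail loudly, never silently clipped. Activations are
unbounded above by default (constant-strength actuators with a polynomial
criterion); an optional `a ≤ 1` cap exists but is off. Muscle length is
invariant to the floating-base coordinates, so base rows decouple exactly:
the six base residual loads are computed directly and *reported* rather than
recruited — same optimum as carrying heavily penalized residual actuator
columns through the solve, but auditable. The constrained dof set ships with
the model (for the toy leg: hip ball, knee, talocrural; the subtalar hinge
is locked in the gait profiles and its small net moment is left to passive
structures). Upper-body and contralateral-limb demands enter only through
the base residuals — a boundary-load treatment, flagged as a repo choice.

**Contact force and decomposition.** `HCF = −(F_inertial + F_gravity + GRF +
Σ f_i u_i)` with `u_i` the line of action of each hip-crossing element,
rotated into the femur clinical frame (origin at the hip centre,
proximo-distal along the hip→knee mechanical axis, antero-posterior from the
femur's anterior reference axis orthogonalized against it, medio-lateral
completing the triad — the construction is a config block in the model) and
divided by body weight. The per-frame closure residual of the balance is
recomputed from the stored terms and reported; the element decomposition
satisfies `Σ F_i = MF_hip` identically.

**Flagging.** Criterion (a): an actuator group whose peak force contribution
reaches ≥ 15% of the peak muscle term while its moment share stays ≤ 5% on
every constrained dof. Criterion (b): a contiguous episode (≥ 5% of the
cycle) where the group's dof-moment contribution exceeds the net moment with
the same sign, by ≥ 2× at the episode peak, counting only frames where the
net moment is meaningful (≥ 5 N·m and ≥ 5% of that dof's cycle peak). The
excess-ratio and floor guards separate anatomically suspicious geometry from
the mild antagonist co-contraction a polynomial criterion produces whenever
a biarticular muscle serves two joints; all thresholds are configurable, and
flagging is monotone (loosening thresholds never removes a flag). Flags are
reported per group and are a prompt for anatomical scrutiny, not a verdict.

**Validation metrics.** Both HCF series are resampled to the 0–100% cycle
grid (101 points, monotone cubic/PCHIP — no overshoot). RMSE is reported per
component (AP/ML/PD), for the total (magnitude) series, and stance/swing
split by the 20 N vertical-GRF event rule. Peaks are the largest local
maxima of the measured magnitude in the 0–30% (loading) and 30–60%
(terminal) windows. Activation on-off uses a threshold of 10% of the
muscle's cycle maximum with 3% cycle debouncing; comparisons to reference
timing windows report onset/offset errors and the interval-set Jaccard
overlap.

## The synthetic trial generator

The generator emulates a single instrumented-patient gait cycle: joint-angle
profiles from a truncated Fourier basis (≤ 3 harmonics, closed-form
derivatives), cadence 120 steps/min (1.0 s cycle), 100 Hz capture, 60%
stance; markers by forward kinematics plus optional i.i.d. Gaussian noise;
vertical GRF as a double-bump profile `sin(πτ)(1+0.35 cos(2πτ))` scaled
analytically so the two-plate cycle average equals body weight; AP/ML shears
as small sinusoids (0.15 / 0.05 BW); centre of pressure travelling
heel-to-toe along the foot's sole line. The reference HCF is produced by
running the pipeline itself on the noise-free trial with the uncorrupted
model — legitimate as ground truth because every stage is independently
oracle-tested (closed forms, symbolic Lagrangian, surface-graph shortest
paths, parameter recovery), and it makes the self-consistency and
reproducibility checks exact.

What the generator does *not* emulate: soft-tissue artefact beyond additive
noise, kinematic-kinetic consistency (the GRF is synthesized, not simulated,
so base residuals absorb the mismatch, as they do for real lab data),
contralateral support and upper-body dynamics, and physiologic moment
sharing across more than 12 elements. Consequently the toy's HCF peaks
(≈ 5.7 and ≈ 10.1 BW at the shipped conditions) are higher than the 2–3 BW
measured in patients; passing tests demonstrate the correctness of the
mechanics and identities, not the clinical realism of the magnitudes. The
problem sizes used throughout — one 101-frame cycle, 12 muscle elements,
50–210 random oracle instances — were chosen as the smallest sets that
exercise every code path meaningfully.

## Fixtures

Three catalogue models ship as YAML (`hipdyn/fixtures/`): `planar-2seg` (one
hinge, antagonist muscle pair, closed-form testable), `hip-abductor-rig`
(ball hip, three wrapped abductor elements for sweep tests), and
`lowerlimb-12m` (right leg, 12 dofs, 12 elements; hip centre
landmark-regression-consistent by construction; two biarticular hamstrings
with individual condyle cylinders placed so that *removing* the wrap leaves
< 5 mm knee arm at full extension — the motivating defect — while the
wrapped arm is ≈ 36 mm). Cylinder placements are repo-chosen; no cadaveric
coordinates are reproduced. A helper (`distribute_origins`) places n element
origins evenly along an attachment polyline for multi-element muscles.

## File formats and reproducibility

Markers travel as TRC (or CSV), forces and all stage outputs as CSV with
17-significant-digit floats, reports as JSON, models and pipeline configs as
YAML. C3D is not supported; TRC/CSV cover the exchange needs here. The
file-based stages (`ik`, `id`, `recruit`, `decompose`, `flag`, `validate`)
are the same functions `run_pipeline` executes, so CLI stage composition is
hash-identical to the end-to-end run; the manifest records a config hash,
the seed and SHA-256 of every output. All randomness flows from explicit
seeds.

## Known limitations

No force–length–velocity muscle dynamics, EMG-driven recruitment, or
co-contraction criteria beyond the polynomial family; no residual-reduction
of the synthesized GRF inconsistency; single-cylinder wrapping only; the
knee as a pure hinge; validation is single-trial by design. The criterion-(a)
force-share scale uses the peak of the muscle term `MF_hip` (the part of the
contact force muscle geometry can influence) rather than the full HCF
magnitude.
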