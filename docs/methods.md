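# Methods

## Model

The knee is treated as two rigid bodies. All measurement geometry is
femoral and static: the posterior condylar axis â = unit(FLCP − FMCP) is the
projection axis for TT-TG, the femoral frame is built from the least-squares
condylar cylinder (X), the femoral head centre (Z, orthogonalised against X)
and their cross product (Y), and the flexion axis FAR is the fitted cylinder
axis. The tibia carries three landmarks (TTP, TAPP, TADP); its long axis TAR
runs through TAPP/TADP, oriented distally. A pose (f, r) maps tibial
landmarks through a composition of two Rodrigues rotations: flexion by f
about FAR, internal rotation by r about TAR. TT-TG at the pose is the signed
projection difference of the posed TTP and the fixed TGCP onto â.

Assumptions inherited from this construction: fixed-axis rotation (no
rolling/gliding/pivoting, no soft-tissue constraint), rigid bones, and a
rotational reference taken at the extended acquisition pose — the true
degree of external rotation in extension is unknown and not estimated, so
all rotations are relative to that pose.

## Composition convention (a genuinely open design point)

Two readings of "concomitant rotation about TAR" differ once the knee is
flexed:

* **extension-fixed** (default): internal rotation acts about the TAR line
  where it sits in the extended pose, applied to the already-flexed tibia.
  The tuberosity's effective anterior lever arm relative to that fixed line
  is `w·cos f − d·sin f` (w = anterior offset, d = distal offset of TTP from
  the knee centre), so |ΔTT-TG| at fixed rotation shrinks as flexion grows.
* **body-fixed**: rotation about the tibia's own flexed long axis
  (equivalently, rotate first, then flex — the conjugation identity is
  asserted by test). Under this convention, with â parallel to FAR, ΔTT-TG
  is exactly flexion-invariant, i.e. no attenuation can occur.

The attenuation of ΔTT-TG with flexion is a central feature of the cohort
pattern this simulation targets, and only the extension-fixed convention
produces it; it is therefore the default, with `convention="body_fixed"`
available on `pose_transform` / `simulate_specimen` / the CLI.

Sign conventions are pinned after mirroring every left knee into right-knee
convention (reflection across the sagittal plane through the frame origin —
an involution that leaves TT-TG unchanged): flexion is rotation by −f about
the medial→lateral FAR (tibia swings posteriorly), internal rotation is
rotation by −r about the distally-oriented TAR (TTP moves medially, TT-TG
decreases).

## Cylinder fit

Orthogonal-distance least squares: minimise Σ(dᵢ − ρ)² over the 4 axis
degrees of freedom and radius ρ, with dᵢ the point-to-line distance.
Parameterisation: two tangent-plane coefficients perturbing the starting
direction (no polar singularity at the solution) plus a 2-D origin offset in
the normal plane through the centroid; Levenberg–Marquardt with an analytic
Jacobian, tolerances 1e-14, iteration cap 1200 function evaluations. Without
a caller-supplied initial axis the fit starts from each of the three
principal directions of the cloud and keeps the lowest-residual solution —
partial-arc clouds (the condyles subtend ~140°) make the principal
directions ambiguous, so a single start is unreliable. The axis sign is
canonicalised against a reference vector (the pipeline uses FLCP→FMCP
medial→lateral). Degenerate inputs (fewer than 8 points, collinear clouds)
raise; non-convergence raises with the last residual attached.

## Synthetic cohort

The generator emulates a 56-knee CT cohort in a canonical right-knee frame
(x medial→lateral, y anterior, z proximal), then mirrors ~half the specimens
to left knees and applies a uniformly random rigid world pose, as segmented
scans would present. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| condyle radius | 22 ± 2 mm | typical adult posterior condylar radius |
| condylar arc / halfwidth | 140° / ±25 mm | posterior arc visible to segmentation |
| surface noise | 0.1 mm | sub-voxel segmentation jitter |
| posterior landmark noise | 0.5 mm | manual FMCP/FLCP placement; tilts â off FAR by ~1°, the realistic source of a small, sign-random flexion effect |
| FHC offset | 400 mm proximal | femoral shaft length to head centre |
| tibial shaft | 300 mm, vertical below knee centre | TAPP/TADP from 1/3–2/3 shaft midpoints |
| TTP anterior offset w | 35 ± 3.5 mm | see below |
| TTP distal offset d | 25 ± 3.5 mm | see below |
| baseline TT-TG target | 14.1 ± 4.0 mm | extended-knee cohort baseline |
| TGCP medial offset | 2.5 mm | places the groove slightly medial of the knee centre |

The TTP *lateral* offset is not drawn independently: it is solved in closed
form from the drawn baseline target (lateral = baseline − TGCP medial
offset), so the cohort baseline distribution is calibrated exactly rather
than tuned by simulation. The (w, d) pair is a derived default, not an
anatomical claim: under the extension-fixed convention the cohort-mean
ΔTT-TG at rotation θ and flexion f is
`(1 − cos θ)·lateral + sin θ·(w cos f − d sin f)`, and (35, 25) reproduces
the target Δ pattern (≈ −2.6 mm at 10°/5° attenuating to ≈ −1.5 mm at
30°/5°, down to ≈ −11 mm at 10°/20°) across the whole grid; the offset SDs
(3.5 mm) likewise reproduce the growth of Δ variability with rotation
(≈ ±0.3 mm at 5° to ≈ ±1.1 mm at 20°).

Cohorts draw from one `SeedSequence` with per-specimen spawned substreams,
so enlarging a cohort never changes earlier specimens. Every draw is stored
in a `GroundTruth`, and `analytic_tttg` computes the per-pose TT-TG in
closed form (scipy rotations, true axes — independent of the fitting
pipeline) for recovery oracles.

What the generator does **not** emulate: real bone surface shape (condyles
are noisy cylinders, not statistical shape models), trochlear dysplasia or
other pathomorphology, correlated anatomy (offsets are drawn independently),
inter-individual variability in screw-home magnitude/timing, and any
soft-tissue behaviour. Passing tests therefore demonstrate correctness of
the geometry, kinematics and statistics on cohorts with the stated
statistical structure — not clinical validity on patient data.

## Statistics

Per-pose descriptives are mean, sample SD (ddof 1) and a 95% CI
(t-quantile by default, `ci_method="normal"` switches to the z
approximation; the t choice is conservative and matters little at n = 56).
The rotation effect is tested per flexion angle with a paired Friedman test
(average-rank ties, tie-corrected statistic, χ² p with k−1 df; an all-tied
matrix is defined as statistic 0, p 1 — the reason the statistic is computed
here rather than delegated; scipy's implementation is the cross-check in the
test suite). Post-hocs are two-sided Wilcoxon signed-rank tests over all
C(5,2) = 10 rotation pairs within a flexion angle, Bonferroni-corrected with
m = 10 per family; the p-value is exact for ≤ 25 untied non-zero
differences, otherwise the continuity-corrected normal approximation.
Because which test produced the published flexion-only p-values is
ambiguous, the isolated-flexion analysis reports both a Friedman test across
flexion levels at rotation 0 and per-flexion Wilcoxon comparisons against
the extended baseline (m = 3), labelled.

Sidedness is two-sided throughout; zero differences are dropped
(`zero_method="wilcox"`); fewer than 5 usable pairs is an error, and
`render_report` degrades gracefully (tables without tests) on cohorts too
small to test.

## Numerical choices and degenerate inputs

Angles enter the API in degrees and are converted once. Rotation matrices
are validated orthonormal/det +1 to 1e-9 at construction. Axis directions
must be unit to 1e-6 and are re-normalised. The TT-TG projection is applied
to raw 3-D points; flattening into the FMCP/FLCP/TGCP plane first is
algebraically identical (the discarded component is orthogonal to â) and is
asserted as a test rather than implemented as a step. Coincident FMCP/FLCP
or TAPP/TADP, an FHC on the condylar axis, missing baseline poses and
incomplete grids all raise typed errors with the specimen id attached.

## Problem sizes

The verification oracles run at: 1000 randomized specimens for the
zero-flexion closed-form check (500 in the acceptance script), 50 draws for
cylinder-fit recovery at 0.1 mm noise, the full 56-specimen default cohort
for pattern and significance checks, and 2000 replicates for type-I
calibration of Friedman/Wilcoxon — sizes at which the sampling error of each
check is far below its tolerance.

## Known limitations

Fixed-axis kinematics and a rigid, landmark-only tibia; the acquisition pose
is the rotational zero; cylinder-fit quality degrades for arcs much narrower
than ~90°; the generator's independence assumptions understate real
anatomical covariance; mesh import samples surfaces inside a caller-given
bounding box and does not segment or label anatomy.
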