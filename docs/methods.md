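# Methods

This note records the models behind `usnav`, the conventions and parameters
that matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was genuinely open. No empirical
number appears here that the test suite or `scripts/acceptance.py` does not
itself compute.

## Frames and conventions

All lengths are millimetres, angles radians. A `RigidTransform` labelled
`A<-B` maps coordinates from frame `B` to frame `A`; composition and frame
checking are explicit, and every chain in the package is one of the two
pose chains of the system (ultrasound: `N<-C<-K<-U`; instrument:
`N<-C<-L<-I`).

* The camera frame is right-handed with +z into the scene (the standard
  computer-vision convention the projection model assumes).
* Marker frames (aid `N`, KeyDot `K`) have x/y in the printed plane and +z
  pointing *away from the camera*, i.e. into the tissue. The tumour centre
  therefore sits at positive z in `N` (its depth below the surface), and the
  virtual viewpoint camera sits at z = −offset looking along +z.
* An ultrasound pixel `(row, col)` maps to the in-plane point
  `(x, y, z) = (col·spacing_col, row·spacing_row, 0)` in frame `U`: x runs
  across the array, y down the beam. None of these conventions is dictated
  by the physical system; they are declared once and enforced by frame
  labels.

## Marker tracking

Detection thresholds the image (Otsu), labels dark blobs, takes
darkness-weighted centroids, and orders them into the grid by trying the
lattice orderings generated from the cloud's principal axes and keeping the
one whose model-to-image homography has the smallest residual. A plain
rows×cols circle grid is symmetric under a 180° rotation and, through a
homography, under axis flips; orderings are therefore filtered to
orientation-preserving homographies (front view) and the 180° ambiguity is
resolved by a fixed convention (the first grid row runs toward +u, ties
toward +v). Asymmetric grid dimensions (default 4×5, 2.5 mm pitch, 1.25 mm
circles) prevent 90° aliasing. The physical markers' true grid dimensions
are not public; these defaults are configuration, not measured values.

Pose estimation undistorts the centroids, fits a normalized-DLT homography,
decomposes it to `R, t` (scale from the mean rotation-column norm, depth
forced positive, SVD orthonormalization), then refines by
Levenberg–Marquardt on the reprojection error (MINPACK, `xtol` 1e-12,
capped evaluations; non-convergence raises). The refined pose is never
allowed to have a larger mean residual than the decomposition it started
from. Fewer blobs than grid points raises a detection failure — the same
signal occlusion produces in the physical system — and the search region
for the next frame is predicted by constant-velocity extrapolation of the
projected bounding box (the motion model is unspecified upstream; constant
velocity is the simplest that exploits two poses).

## Registration and error measures

`fit_rigid` is the closed-form SVD least-squares (Arun) solution with the
reflection guard. FRE is reported as the **mean** Euclidean residual (the
RMS is carried alongside in every result, since the two conventions differ
by √(π/8) ≈ 8% under Gaussian errors and reports often leave the choice
implicit). Degeneracy is collinearity of either cloud (second singular
value < 1e-9 of the largest); coplanar clouds are accepted — the
calibration protocol itself touches a planar grid, and coplanar clouds are
well-posed for the guarded SVD fit.

The FLE→FRE calibration inverts E[FRE²] = (1 − 2/N)·3σ² in closed form and
then refines σ by bisection on the *simulated mean* FRE (1% relative),
because the closed form targets the RMS. For a 0.8 mm mean FRE with N = 12
the calibrated per-axis σ is ≈ 0.55 mm. In the experiments "perturb both
sides" means σ/√2 per side, so the combined per-pair localization noise has
per-axis SD σ.

## Volume reconstruction and the distance field

Compounding is pixel-push with bin averaging: every pixel of every tracked
frame is mapped through its (noisy) chain and averaged into an isotropic
voxel grid (default 0.5 mm). Voxels crossed by no frame get one pass of
6-neighbour mean filling where ≥ 3 neighbours are occupied, else stay
empty. A practical consequence, visible in the tests: the voxel size must
not be finer than the sweep pitch, otherwise entire gap planes remain
unfillable; reconstruction studies therefore use voxel = pitch (1 mm for a
40-frame, 1 mm-pitch sweep).

Segmentation is thresholding (the tumour is dark) plus largest
26-connected component — a deliberate substitution for the manual
segmentation step of the physical workflow, preserving its downstream
contract (a watertight mesh). Marching cubes at level 0.5 on the
zero-padded mask produces the surface; volume and centroid come from the
divergence theorem over signed tetrahedra, and the equivalent radius is
(3V/4π)^(1/3).

The signed distance field samples exact point-to-triangle distances (a
KD-tree over triangle centroids proposes candidates; an all-triangles
brute-force path exists as the test oracle) on the mesh bounding box
dilated by the 10 mm margin. Signs come from ray-crossing parity: one +x
ray per (y, z) grid line classifies the whole line of nodes at once; line
origins are offset by 10⁻³ voxel so rays stay in generic position with
respect to mesh edges (only nodes within ~10⁻³ voxel of the surface could
be mis-signed, where the distance is itself ~0). Negative is inside.
Queries are trilinear; outside the grid is an error at this layer and a
policy decision one layer up.

## Guidance

Proximity bands are half-open and assigned upward: [−∞, 2.5) red,
[2.5, 3.5) yellow, [3.5, 5.0) orange, [5.0, ∞) green — the
yellow-before-orange colour order is the system's convention, overridable
in `ProximityThresholds`. The traffic light uses the **tip** distance (the
shaft is not modelled). The projected path marches the SDF along the tool
axis (step ≤ 0.25 mm) and bisects the first positive-to-negative crossing
to 0.01 mm. An instrument tip outside the field grid is by construction
farther than the margin from the tumour: it is reported green and flagged
out-of-field, never an error; a `stale` flag is passed through for
tracking drop-outs instead of guessing a state. The virtual viewpoint is
data, not pixels: scene vertices and tips projected by a virtual pinhole
camera 50 mm from the aid along the out-of-tissue normal, with per-vertex
depth below the marker plane (the aid is treated as a planar approximation
of the local surface).

Note on accuracy: the projected-path hit agrees with the analytic
ray-sphere intersection to the sum of the bisection tolerance, the
trilinear interpolation error (O(voxel²/r)) and the faceting of the test
mesh; the 0.05 mm acceptance check therefore runs on a finely faceted
sphere at 0.25 mm voxels, while coarser fixtures are checked at
correspondingly coarser tolerances.

## Digital phantom and the Monte-Carlo experiments

The phantom is an implicit block (50×50×50 mm, surface at z = 0) with a
dark spherical inclusion, default radius 10 mm centred at 20 mm depth —
mid-range of the fabricated phantoms' 10–30 mm inclusion diameters.
Intensities are B-mode-like levels (background 0.7, inclusion 0.15) and
speckle is additive Gaussian (SD 0.03): sufficient for threshold
segmentation, deliberately not a physical speckle model (no Rayleigh
statistics, no attenuation, no shadowing), so passing tests say nothing
about segmenting real B-mode texture.

The noise model carries the measured component magnitudes as defaults:
0.4 px marker centroid SD (the camera-calibration reprojection scale),
1.0 mm robot kinematic accuracy and the 0.9 mm probe-calibration channel,
both interpreted as RMS vector errors (per-axis SD = value/√3), plus a
small per-frame metric pose jitter (0.1 mm, 0.002 rad) standing in for
optical pose noise on the reconstruction path. The probe-calibration
channel is a systematic offset, not per-frame jitter, so sweep scans do
not inject it; it enters the total-system experiment's ultrasound-side
comparison.

The registration experiment samples fiducials and targets uniformly in the
stated 45×30×50 mm working volume (the true point layout is unrecorded, so
simulated means are bound-level comparisons, not replications). The
total-system experiment runs the full chain per replicate: a hand–eye fit
from 12 grid-touch events whose optical side goes through an actual noisy
marker-pose estimate, then 10 ball-tip poses located via the instrument
chain and compared with the known ball centre (primary metric) and with an
ultrasound-channel-perturbed centre (secondary, reported in the config
echo). Problem sizes — 1000 replicates for the registration study, 500×10
poses for the total-system study, 2000 replicates inside the FLE
calibration — keep every stochastic estimate's Monte-Carlo error well
below the tolerances while the whole suite stays comfortably runnable on
one CPU. All generators are deterministic given a seed.

## Finite-element co-motion model

The kidney is a 50 mm cube of isotropic linear-elastic material (moduli
10.8 and 15.4 kPa from in vivo medullary/cortical measurements; Poisson
ratio 0.45 as near-incompressible soft tissue — unreported upstream),
meshed with identical 8-node hexahedra (2×2×2 Gauss). The base (the face
opposite the aid) is fixed, the probe load is a uniform traction over a
28×5 mm footprint 10 mm from the aid's edge, and the aid — a 10×10 mm
patch plus its barb column to the leg depth — is condensed into a single
rigid body by a master–slave constraint (a printed plastic implant is
orders of magnitude stiffer than kidney). The tumour centre sits 20 mm
below the aid, matching the rigid prediction the system relies on.

The co-motion error is the distance between (a) the rest tumour-node
centroid carried along by the aid's best-fit **linearized** rigid motion
(u₀ + θ×r, exact for the condensed aid and exactly linear in the
displacement field) and (b) the centroid of the displaced tumour nodes.
Linearity is exploited: one solve per leg length at unit force and
reference modulus, scaled by F·E_ref/E for the 3×3×2 factorial sweep.
Solves use a direct sparse factorization up to ~120k dof and
Jacobi-preconditioned CG above (the 1.25 mm mesh has 207k dof); the
relative residual must be < 1e-8. Full integration of near-incompressible
hexahedra locks mildly (displacements are underestimated); the patch test
is exact and mesh convergence of the co-motion error from h = 2.5 to
1.25 mm is within a few percent, so the sweep maximum is a stable figure
for this simplified model. It is a *bound check*: the upstream simulation's
element type, boundary conditions and tumour material are unreported, so
agreement is expected at the "stays under 1 mm" level, not per-case.

## Known limitations

* No acoustic simulation: the phantom tests geometry and noise
  propagation, not image quality; segmentation of real ultrasound would
  need more than a threshold.
* Monocular planar pose estimation inherits the depth/tilt ambiguity of
  small planar targets; the Monte-Carlo distributions here apply to the
  configured grid and working distance.
* The FEM is small-strain, frictionless, contact-free and
  quasi-static; it cannot capture barb–tissue interaction or large
  indentation.
* Real-time concerns (video capture, rendering, latency) are out of scope;
  the guidance layer emits data, not pixels.
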