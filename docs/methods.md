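# Methods

`srsrescan` quantifies whether the planning CT from an earlier course of
intracranial stereotactic radiosurgery (SRS) can stand in for a fresh CT
when a patient returns for a repeat course.  The question decomposes into
four measurable pieces, each implemented as an independent module and
chained by the pipeline: registration residuals (targeting accuracy),
target-to-skull ray tracing (skull stability), image similarity (scan
information content), and 3D gamma analysis (dosimetric agreement).  All
of them run end to end on digital head phantoms generated in-package, so
the whole analysis is reproducible from a seed with no external data.

## Geometry and conventions

World coordinates are DICOM LPS millimetres (+x left, +y posterior,
+z superior); voxel indices are 0-based with `(i, j, k) -> (x, y, z)` and
world positions refer to voxel centers.  Only axis-aligned grids are
supported; oblique direction cosines are rejected at the I/O layer rather
than resampled silently, because every downstream oracle (ray-quadric
intersections, closed-form dose fields) assumes testable axis-aligned
geometry.  Head scans are acquired near-axial, so this costs little
generality.

Rigid motion is parameterised as three translations (mm) plus roll (about
z, superior-inferior), pitch (about x, left-right) and yaw (about y,
anterior-posterior) in degrees, composed about fixed axes as
`R = R_yaw @ R_pitch @ R_roll`, applied about an explicit rotation center.
Translation components of a decomposed transform depend on that center, so
every transform carries its center and results always state it (the
default is the fixed image's grid center).  The decomposition is unique
for |pitch| < 90 degrees, far beyond the few degrees of head motion the
analysis targets.

## Synthetic study conditions

The phantom is a concentric-ellipsoid skull (outer semi-axes 90/110/80 mm
at full scale, 6 mm shell) holding uniform brain at +40 HU, cortical bone
at +1000 HU, air at -1000 HU, an optional spherical air cavity (sinus
surrogate) and spherical contrast-enhancing targets at brain +60 HU.
Gaussian scanner noise (sigma 3 HU default) is added last and truncated at
-1000 HU.  An isotropic Gaussian of sigma 0.6 mm is applied before the
noise as a point-spread-function surrogate: real CT edges have a finite
partial-volume ramp, and without it sub-voxel edge localization is
dominated by voxelization staircase artifacts no scanner produces.

The compact configuration used by the examples and the test suite
(`example_spec()`) is a 2/3-scale cranium with semi-axes 62/78/48 mm on a
2 mm grid, two targets and an anterior-inferior air cavity.  Two choices
there are deliberate.  First, the semi-axes differ clearly on *every* pair
of axes: an ellipsoid whose left-right and superior-inferior axes nearly
coincide makes yaw almost unobservable to an intensity metric — a phantom
symmetry, not a property of real heads, which the distinct proportions
remove.  Second, the 2 mm grid keeps a full registration + ray-trace +
gamma chain interactive on a single core while leaving every stage inside
its sub-voxel regime; the accuracy statements scale with voxel size, so
they are reported in voxels wherever that is the natural unit.

The repeat CT is the phantom moved by a known rigid transform, resampled
once onto the original grid, given fresh noise, and perturbed by +20 HU
inside a sphere of twice the GTV radius around each (moved) target — the
magnitude and locality of contrast- and edema-driven intracranial HU
changes between scans.  The skull HU is untouched (the skull-stability
premise; violating it deliberately is how the pipeline's warning flag is
tested).  The T1-like MR is a deterministic piecewise-linear HU remap of a
CT (air darkest, bone dark, brain mid, enhancing targets brightest) plus
noise, with geometry unchanged so the ground-truth MR-to-CT alignment is
exactly the identity.

What the generators do *not* emulate: anthropomorphic anatomy, soft-tissue
deformation, MR distortion and bias fields, beam/arc transport, CT
artifacts beyond stationary Gaussian noise.  Passing tests therefore
demonstrate that the *measurement machinery* — registration, edge
tracing, similarity, gamma — is correct and self-consistent at clinical
noise levels, not that real patients would show these numbers.

## Dose surrogate

Each target's plan is `D(r) = Rx` for `r <= r_PTV` and
`Rx * exp(-(r - r_PTV)^2 / (2 sigma^2))` outside, with Rx = 20 Gy,
sigma = 2 mm, on a 1 mm isotropic grid.  This reproduces what the gamma
analysis stresses about SRS dose — a prescription plateau with a steep
penumbra (peak gradient 20·e^(-1/2)/σ ≈ 6 Gy/mm) — in closed form, which provides
exact oracles (e.g. the 10% isodose lies at `r_PTV + sigma*sqrt(2 ln 10)`).
The generator verifies the plan objective (>= 98% PTV coverage at
prescription after voxelization) and refuses grids too coarse to meet it.
It is an isotropic surrogate, not a beam-model calculation; the package
evaluates dose-comparison machinery, not dose calculation.

## Registration

`register_rigid` maximizes normalized mutual information over the six
rigid parameters with a three-level coarse-to-fine pyramid (shrink factors
4/2/1, Gaussian pre-smoothing of sigma = factor/2 voxels) and Powell's
derivative-free method at each level (parameter tolerances 0.05/0.01/0.001
mm-or-degrees, bounded evaluation budgets).  The similarity uses every
overlap voxel — no stochastic subsampling — so the objective and hence the
result are deterministic.  `bone` mode restricts the similarity to a
skull mask (HU >= 200, dilated one voxel) on the fixed image, the standard
recourse when soft tissue cannot be trusted across scans (MR against an
older CT).

Two numerical points matter:

* **Smoothing floor.**  Every pyramid level, including full resolution,
  is smoothed with at least sigma = 0.7 voxel.  Trilinear interpolation
  evaluated exactly on grid points preserves noise entropy while off-grid
  positions average it away, which carves spurious NMI maxima (or twin
  side-lobes) at integer-voxel alignments — the well-known mutual-
  information interpolation artifact.  The floor suppresses it; recovery
  error on the standard conditions drops an order of magnitude.
* **Convergence flag.**  `converged` is decided by an explicit probe: a
  step of one final-level tolerance along each of the 12 signed parameter
  directions must not improve the objective.  This directly certifies "the
  returned parameters are a local maximum within tolerance" independent of
  why the optimizer stopped.

The residual chain composes the three registrations of a repeat-course
image set — rMR to rCT directly (a), rMR to iCT over bone (b), iCT to rCT
(c) — as `R = inv(T_a) . T_c . T_b` about a shared center.  Under the
convention that the CT-CT registration is truth, `R` is the uncertainty of
placing MR-defined targets on the initial CT; it is exactly zero for a
consistent triple, which the tests exploit as a constructed oracle.
Reported translation components depend on the rotation center, so the
report always carries the center used.

## Skull ray tracing

Sixteen unit rays leave each target centroid: eight at 45-degree azimuth
increments in the transverse plane, eight at the same azimuths elevated
45 degrees (superior by default; the elevation sign is configurable to
`-45` or `alternating` since either reading of the geometry is defensible).
HU is sampled every 0.2 mm by trilinear interpolation; the inner-table
edge is the first upward crossing of `hu_cross` whose centered
finite-difference gradient reaches `grad_min` (defaults 300 HU and
100 HU/mm — between brain and cortical bone, steep enough to reject
drifts), refined by linear interpolation between the bracketing samples.
A ray that exits the volume without a qualifying edge returns NaN — a
flag, not an exception, since open geometry (craniectomy, field edge) is a
finding.  More than 4 failed rays marks the profile with a warning.

The crossing level trades robustness against bias: the half-rise point of
a PSF-widened step edge is its unbiased locator, so the analytic-oracle
tests set `hu_cross` to the phantom's brain/bone midpoint (520 HU), while
the clinical default 300 HU sits lower and carries a known
fraction-of-edge-width bias that cancels in iCT-vs-rCT *differences* —
the quantity the analysis actually reports.  On noise-free shells the
traced distances match closed-form ray-ellipsoid intersections to under
half a voxel.

Profile comparison takes per-ray absolute differences over rays valid in
both scans and reports both aggregations — the per-target mean of means
and the pooled per-ray mean — since both are legitimate summaries and they
differ when targets have unequal valid-ray counts.

## Similarity

NMI is `2 I(A;B) / (H(A) + H(B))` from a joint histogram over the voxel
overlap (both images in-field), 64 equal-width bins per image spanning
that image's own overlap range — adequate for 12-bit CT and deterministic.
This normalization satisfies the one anchor every MI implementation
shares: identical image sets score exactly 1 (and PC = 1); independent
images tend to 0.  Constant images raise instead of returning 0/0.
Commercial coefficients live on proprietary scales, so absolute values are
not comparable across software; only the ordering of comparison groups
(same scan > resampled > same-day rescan > different-day rescan >
different patient) transports, and `similarity_context` classifies a
measurement against configurable band floors in exactly that order.  The
default floors are starting-point configuration, not calibrated constants.
Pearson correlation is computed over the whole overlap; whether a clinical
system uses a registration ROI instead is unknowable from outside, and the
whole-overlap choice is stated here for that reason.

## Gamma analysis

For every reference point above the low-dose threshold (10% of the global
maximum of the reference distribution),

    gamma(r) = min_e sqrt( |e - r|^2 / dta^2 + (D_e(e) - D_r(r))^2 / dd^2 )

with dta = 1 mm and dd = 1% of the global max by default, both dose grids
first resampled trilinearly to a 0.2 mm isotropic grid so the discrete
minimum approximates the continuous one (`fine_spacing <= dta/2` is
enforced).  The threshold masks the reference only; the passing rate is
the fraction of evaluated points with gamma <= 1.  The repeat-CT dose is
the reference (it is the ground truth of the comparison) and the
initial-CT dose the evaluated distribution; gamma is asymmetric under that
swap, and the choice is an explicit argument.  The search is capped at a
3-dta radius: beyond it the distance term alone exceeds 3, which cannot
change pass/fail or any gamma <= 3.

The optimized implementation visits integer grid offsets sorted by
physical distance, keeps a running minimum per point, and retires points
whose minimum already beats the distance term of all remaining offsets —
bit-equivalent to the full search (the brute-force oracle `gamma_brute`
verifies agreement to float precision on small grids) while making the
near-agreement case, which dominates in practice, effectively linear.
When a cropped grid is compared, the global maximum of the full
distribution is passed explicitly so normalization does not drift with the
crop.

## Pipeline

`run_case` chains the stages for one case: registrations (a), (b), (c);
residual chain about the rCT grid center; per-target skull profiles on
the rCT and on the iCT resampled into the rCT frame through registration
(c) — the rCT frame is where the MR-derived targets live, and comparing
there is the same measurement as comparing on the registered pair in the
other frame; whole-overlap similarity of the registered CT pair; and
per-target gamma, with the analytic surrogate standing in for any dose
grid not supplied.  A stage failure is recorded by name and the report is
emitted with partial results rather than raising, because a QA run that
dies on stage three of four has destroyed the three answers it had.
Reports embed the full configuration, seeds and input checksums; identical
inputs and configuration yield byte-identical reports.

Correlation of any per-case metric against time between scans uses
Pearson's r with the exact t-transform p-value (n-2 degrees of freedom)
and the conventional strength bands: |r| < 0.4 weak, 0.4-0.7 intermediate,
above 0.7 strong; significance at p < 0.05.

## Known limitations

* Phantoms are piecewise-constant ellipsoids; none of the claims here
  quantify performance on deformable anatomy or real scanner artifacts.
* The registration is a local optimizer: initial misalignments far beyond
  the tested +-5 mm / +-3 degrees range may need an explicit `init`.
* The dose surrogate is isotropic; plan-quality questions (conformity,
  gradient indices, multi-isocenter interplay) are out of scope.
* RTSTRUCT contours are not parsed; targets are spheres given as centroid
  plus radius (CSV or config), which matches how the analysis uses them
  (centroids and margins), and is the declared extension point.
* Sub-voxel skull-distance accuracy assumes a finite-width edge; on
  synthetic data with the PSF disabled the staircase artifact returns.
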