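"""Digital head phantoms and analytic SRS dose surrogates.

The study conditions the rest of the package exercises — a planning head CT,
a repeat CT of the same head under a small rigid motion with fresh noise and
a local contrast/edema perturbation, a post-contrast T1-like MR of the same
anatomy, and a steep-gradient single-target SRS dose — are all generated
here, deterministically from a seed, so every pipeline stage runs with no
external data.

Geometry is a concentric-ellipsoid skull (outer semi-axes 90/110/80 mm,
6 mm shell by default): the simplest shape with a closed-form inner-skull
surface, which gives the ray-trace module an analytic oracle.  The dose
surrogate is a prescription plateau with a Gaussian penumbra — it reproduces
the plateau-plus-steep-falloff structure of SRS dose that the gamma analysis
stresses, again with a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridSpec, RigidTransform, Target, VolumeImage, transform_volume

__all__ = [
    "PhantomSpec",
    "DoseSpec",
    "SphereSpec",
    "example_spec",
    "make_head_phantom",
    "simulate_rescan",
    "derive_mr",
    "make_srs_dose",
    "coverage",
]


@dataclass(frozen=True)
class SphereSpec:
    """A sphere in world coordinates (mm); used for air cavities."""

    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a digital head CT.

    Defaults follow a typical SRS planning scan: ~1 mm voxels
    (0.78 x 0.78 x 1.0 mm), cortical bone near +1000 HU, brain near +40 HU,
    air at -1000 HU, contrast-enhancing targets +60 HU above brain, and a
    few HU of scanner noise.  ``psf_sigma_mm`` is an isotropic Gaussian
    standing in for the scanner's point-spread function: it gives tissue
    interfaces the finite width (partial-volume ramp) that real CT edges
    have, without which sub-voxel edge localization would be dominated by
    voxelization staircase artifacts no scanner produces.
    """

    skull_outer_radii: tuple[float, float, float] = (90.0, 110.0, 80.0)
    skull_thickness: float = 6.0
    hu_air: float = -1000.0
    hu_brain: float = 40.0
    hu_skull: float = 1000.0
    hu_target_enhancement: float = 60.0
    air_cavity: SphereSpec | None = None
    targets: tuple[Target, ...] = ()
    spacing: tuple[float, float, float] = (0.78, 0.78, 1.0)
    shape: tuple[int, int, int] | None = None  # None: auto-fit radii + 8 mm pad
    noise_sigma: float = 3.0
    psf_sigma_mm: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.skull_thickness < min(self.skull_outer_radii)):
            raise ValueError(
                "skull_thickness must be positive and smaller than every outer semi-axis"
            )
        object.__setattr__(self, "targets", tuple(self.targets))

    @property
    def inner_radii(self) -> tuple[float, float, float]:
        return tuple(r - self.skull_thickness for r in self.skull_outer_radii)

    def grid(self) -> GridSpec:
        """Sampling grid centered on the phantom (phantom center = world origin)."""
        if self.shape is not None:
            shape = self.shape
        else:
            pad = 8.0
            shape = tuple(
                int(np.ceil(2 * (r + pad) / s)) + 1
                for r, s in zip(self.skull_outer_radii, self.spacing)
            )
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, self.spacing))
        return GridSpec(shape, self.spacing, origin)


def example_spec(seed: int = 0, spacing: float = 2.0) -> PhantomSpec:
    """A compact two-target head phantom used throughout the examples.

    A 2/3-scale cranium with distinct semi-axes on every pair of axes
    (62 / 78 / 48 mm: wider left-right than tall, longest front-back, the
    proportions that give every rotation axis a geometric signal), an
    anterior-inferior air cavity standing in for the frontal sinus, and two
    contrast-enhancing targets of SRS-typical size.  The 2 mm grid keeps a
    full registration + ray-trace + gamma chain interactive on one core
    while every stage still operates well inside its sub-voxel regime.
    """
    targets = (
        Target((10.0, -5.0, 5.0), 6.0, target_id="t0"),
        Target((-20.0, 15.0, -10.0), 5.0, target_id="t1"),
    )
    return PhantomSpec(
        skull_outer_radii=(62.0, 78.0, 48.0),
        targets=targets,
        air_cavity=SphereSpec((0.0, -45.0, -18.0), 12.0),
        spacing=(spacing, spacing, spacing),
        noise_sigma=3.0,
        seed=seed,
    )


def _ellipsoid_level(pts: np.ndarray, radii) -> np.ndarray:
    """sum((p/r)^2): <1 inside the ellipsoid, =1 on the surface."""
    r = np.asarray(radii, dtype=np.float64)
    q = pts / r
    return np.einsum("...i,...i->...", q, q)


def make_head_phantom(spec: PhantomSpec) -> tuple[VolumeImage, dict[str, np.ndarray]]:
    """Voxelize a head phantom CT plus analytic masks.

    Returns the CT (HU) and a dict of boolean masks: ``"skull"`` (the bony
    shell), ``"brain"`` (inside the inner table, air cavity excluded) and
    ``"gtv:<id>"`` per target.  The PSF blur and the noise are applied
    after the masks are taken, so the masks describe the sharp analytic
    geometry.
    """
    grid = spec.grid()
    pts = grid.voxel_centers()

    outer = _ellipsoid_level(pts, spec.skull_outer_radii) <= 1.0
    inner = _ellipsoid_level(pts, spec.inner_radii) <= 1.0
    skull = outer & ~inner

    hu = np.full(grid.shape, spec.hu_air, dtype=np.float64)
    hu[skull] = spec.hu_skull
    hu[inner] = spec.hu_brain

    brain = inner.copy()
    if spec.air_cavity is not None:
        cav = spec.air_cavity
        d2 = np.einsum("...i,...i->...", pts - np.asarray(cav.center), pts - np.asarray(cav.center))
        cavity = d2 <= cav.radius**2
        hu[cavity & inner] = spec.hu_air
        brain &= ~cavity

    masks: dict[str, np.ndarray] = {"skull": skull, "brain": brain}
    inner_r = np.asarray(spec.inner_radii)
    for t in spec.targets:
        c = np.asarray(t.centroid)
        # strict containment: the whole GTV sphere inside the inner table
        level = _ellipsoid_level(c[None, :], inner_r - t.gtv_radius)[0]
        if np.any(inner_r - t.gtv_radius <= 0) or level >= 1.0:
            raise ValueError(
                f"target {t.target_id!r} at {t.centroid} (r={t.gtv_radius} mm) "
                "is not strictly inside the inner skull surface"
            )
        d2 = np.einsum("...i,...i->...", pts - c, pts - c)
        gtv = d2 <= t.gtv_radius**2
        hu[gtv & brain] += spec.hu_target_enhancement
        masks[f"gtv:{t.target_id}"] = gtv

    if spec.psf_sigma_mm > 0:
        from scipy import ndimage

        hu = ndimage.gaussian_filter(
            hu, sigma=[spec.psf_sigma_mm / s for s in spec.spacing]
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)
        np.clip(hu, -1000.0, None, out=hu)

    ct = VolumeImage(hu, grid.spacing, grid.origin, modality="CT")
    return ct, masks


def simulate_rescan(
    phantom_ct: VolumeImage,
    T: RigidTransform,
    noise_sigma: float = 3.0,
    local_hu_offset: float = 20.0,
    seed: int = 1,
    targets: tuple[Target, ...] = (),
    perturbation_radius_factor: float = 2.0,
) -> VolumeImage:
    """Emulate a repeat CT: rigid motion, fresh noise, local HU change.

    The head is moved by ``T`` and resampled onto the original grid.  Around
    each (moved) target a sphere of radius ``perturbation_radius_factor``
    times the GTV radius receives ``local_hu_offset`` (default +20 HU) — a
    surrogate for the contrast- and edema-driven intracranial HU changes of
    that magnitude seen between scans, which are local to the target.  The
    skull HU is untouched (skull-stability assumption); independent noise is
    drawn from ``seed``.

    With ``T`` identity and zero noise/offset the output is bit-identical to
    the input (the identity resampling path is exact).
    """
    moved = transform_volume(phantom_ct, T, phantom_ct.grid, fill=-1000.0)
    hu = moved.voxels

    if local_hu_offset != 0.0 and targets:
        pts = moved.grid.voxel_centers()
        for t in targets:
            c = T.apply(np.asarray(t.centroid))
            d2 = np.einsum("...i,...i->...", pts - c, pts - c)
            sphere = d2 <= (perturbation_radius_factor * t.gtv_radius) ** 2
            hu[sphere] += local_hu_offset

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sigma, size=hu.shape)
        np.clip(hu, -1000.0, None, out=hu)

    return VolumeImage(hu, moved.spacing, moved.origin, modality="CT")


# Piecewise-linear HU -> T1-like intensity map (control points, HU -> a.u.).
# Orders tissues the way post-contrast T1 does: air darkest, cortical bone
# dark, brain mid-bright, enhancing tumor brightest.
_T1_NODES_HU = np.array([-1000.0, -150.0, 0.0, 40.0, 70.0, 100.0, 300.0, 1000.0, 3000.0])
_T1_NODES_I = np.array([10.0, 60.0, 330.0, 420.0, 560.0, 750.0, 260.0, 70.0, 40.0])


def derive_mr(phantom_ct: VolumeImage, seed: int = 2, noise_sigma: float = 15.0) -> VolumeImage:
    """Derive a post-contrast T1-like MR from a phantom CT.

    A deterministic nonlinear intensity remap sends skull darker than brain
    and contrast-enhancing GTVs brightest, then seeded Gaussian noise is
    added.  Geometry is unchanged, so the ground-truth alignment between the
    MR and its source CT is exactly the identity — which is what makes
    cross-modality registration recovery testable.
    """
    intensity = np.interp(phantom_ct.voxels, _T1_NODES_HU, _T1_NODES_I)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return VolumeImage(intensity, phantom_ct.spacing, phantom_ct.origin, modality="MR")


@dataclass(frozen=True)
class DoseSpec:
    """SRS dose surrogate parameters.

    ``prescription`` (default 20 Gy) fills the PTV; outside, dose falls off
    as a Gaussian with scale ``falloff_sigma`` (default 2 mm — a steep SRS
    penumbra).  The grid defaults to 1 mm isotropic, the dose-grid
    resolution of the plans being emulated.
    """

    prescription: float = 20.0
    falloff_sigma: float = 2.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape: tuple[int, int, int] | None = None  # None: auto-fit around target
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.prescription > 0:
            raise ValueError("prescription must be > 0")
        if not self.falloff_sigma > 0:
            raise ValueError("falloff_sigma must be > 0")

    def grid_for(self, target: Target) -> GridSpec:
        if self.shape is not None:
            origin = self.origin
            if origin is None:
                origin = tuple(
                    c - (n - 1) / 2.0 * s
                    for c, n, s in zip(target.centroid, self.shape, self.spacing)
                )
            return GridSpec(self.shape, self.spacing, origin)
        # auto: cover the PTV plus ~5 sigma of penumbra
        half = target.ptv_radius + 5.0 * self.falloff_sigma
        shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in self.spacing)
        origin = tuple(
            c - (n - 1) / 2.0 * s for c, n, s in zip(target.centroid, shape, self.spacing)
        )
        return GridSpec(shape, self.spacing, origin)


def dose_profile(r: np.ndarray, ptv_radius: float, prescription: float, falloff_sigma: float) -> np.ndarray:
    """Radial dose: prescription plateau inside the PTV, Gaussian tail outside."""
    r = np.asarray(r, dtype=np.float64)
    tail = prescription * np.exp(-((r - ptv_radius) ** 2) / (2.0 * falloff_sigma**2))
    return np.where(r <= ptv_radius, prescription, tail)


def make_srs_dose(target: Target, spec: DoseSpec = DoseSpec()) -> VolumeImage:
    """Analytic single-isocenter SRS dose for one target.

    Delivers the prescription (20 Gy by default) across the PTV with a sharp
    Gaussian falloff outside it, sampled at dose-grid voxel centers.  Raises
    if, after voxelization, PTV coverage at the prescription falls below
    98% — the plan objective the surrogate must satisfy.
    """
    grid = spec.grid_for(target)
    pts = grid.voxel_centers()
    c = np.asarray(target.centroid)
    lo = np.asarray([grid.origin[d] for d in range(3)])
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError("target centroid lies outside the dose grid")
    r = np.sqrt(np.einsum("...i,...i->...", pts - c, pts - c))
    d = dose_profile(r, target.ptv_radius, spec.prescription, spec.falloff_sigma)
    dose = VolumeImage(d, grid.spacing, grid.origin, modality="DOSE")
    cov = coverage(dose, target.ptv_radius, target.centroid, spec.prescription)
    if cov < 0.98:
        raise ValueError(
            f"voxelized PTV coverage {cov:.3f} < 0.98 plan objective "
            "(grid too coarse for this target)"
        )
    return dose


def coverage(dose: VolumeImage, target_radius: float, centroid, rx: float) -> float:
    """Fraction of voxels with center inside the target sphere receiving >= rx."""
    pts = dose.grid.voxel_centers()
    c = np.asarray(centroid, dtype=np.float64)
    d2 = np.einsum("...i,...i->...", pts - c, pts - c)
    inside = d2 <= target_radius**2
    n = int(inside.sum())
    if n == 0:
        raise ValueError("no voxel centers inside the target sphere")
    # tolerate float round-off at the plateau value
    hit = dose.voxels[inside] >= rx * (1.0 - 1e-12)
    return float(hit.sum()) / n
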