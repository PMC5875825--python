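"""Rigid 6-DOF intensity registration and the residual-displacement chain.

The registration maximizes normalized mutual information over translations
and roll/pitch/yaw with a deterministic multi-resolution (coarse-to-fine)
Powell search.  Two modes mirror how repeat-treatment image chains are
built in practice: ``all_anatomy`` uses every overlap voxel (MR to same-day
CT, where soft tissue agrees), ``bone`` restricts the similarity to a
skull mask on the fixed image (MR to an *older* CT, where only bone can be
trusted).  A clinical registration package with manual physicist refinement
plays this role in the clinic; here the optimizer is automated so results
are reproducible and testable.

The residual chain quantifies rMR-to-iCT targeting accuracy: register the
repeat MR to the repeat CT directly (a), to the initial CT (b), and the
initial CT to the repeat CT (c).  Taking the iCT-rCT registration as truth,
the transform left over after routing the MR through the iCT versus going
direct — ``invert(T_a) . T_c . T_b`` — is the registration uncertainty, and
its translation components and magnitude are what gets reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import RigidTransform, VolumeImage, compose, invert, recenter
from .similarity import SimilarityReport, similarity_report

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "ResidualDisplacement",
    "bone_mask",
    "register_rigid",
    "residual_chain",
]


def bone_mask(ct: VolumeImage, hu_threshold: float = 200.0) -> np.ndarray:
    """Binary skull mask: voxels >= ``hu_threshold`` HU, dilated by 1 voxel.

    200 HU separates cortical/trabecular bone from brain and scalp on CT;
    the one-voxel dilation keeps the bone-air and bone-brain interfaces —
    where most of the gradient information lives — inside the mask.
    """
    if ct.modality != "CT":
        raise ValueError(f"bone_mask needs a CT volume, got modality {ct.modality!r}")
    mask = ct.voxels >= hu_threshold
    if not mask.any():
        raise ValueError(f"empty bone mask at threshold {hu_threshold} HU")
    return ndimage.binary_dilation(mask, iterations=1)


@dataclass(frozen=True)
class RegistrationOptions:
    """Knobs for the multi-resolution NMI optimizer.

    ``shrink_factors`` define the pyramid (coarse to fine, in voxels);
    each level is Gaussian-smoothed with sigma = factor/2 voxels before
    decimation.  ``xtol_mm_deg`` are the per-level Powell parameter
    tolerances (shared by mm and degrees, which are commensurate at head
    scale); convergence to 0.01 mm / 0.01 deg at the finest level is far
    below the sub-voxel accuracy the residual analysis needs.
    """

    n_bins: int = 48
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    max_evals: tuple[int, ...] = (250, 200, 80)
    xtol_mm_deg: tuple[float, ...] = (0.05, 0.01, 0.01)
    bone_hu_threshold: float = 200.0

    def __post_init__(self) -> None:
        if not (len(self.shrink_factors) == len(self.max_evals) == len(self.xtol_mm_deg)):
            raise ValueError("per-level option tuples must have equal length")


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a rigid registration (``transform`` maps moving -> fixed)."""

    transform: RigidTransform
    final_similarity: SimilarityReport
    converged: bool
    iterations: int


def _shrink(vol: np.ndarray, factor: int) -> np.ndarray:
    # Smoothing floor of 0.7 voxel even at full resolution: trilinear
    # sampling at on-grid positions otherwise preserves noise entropy
    # exactly, carving spurious NMI maxima (or twin side-lobes) at
    # integer-voxel alignments — the classic MI interpolation artifact.
    sm = ndimage.gaussian_filter(vol, sigma=max(factor / 2.0, 0.7))
    return sm[::factor, ::factor, ::factor]


def _shrink_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    sm = ndimage.gaussian_filter(mask.astype(np.float64), sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor] > 0.25


def _level_image(img: VolumeImage, factor: int) -> VolumeImage:
    vox = _shrink(img.voxels, factor)
    spacing = tuple(s * factor for s in img.spacing)
    return VolumeImage(vox, spacing, img.origin, img.modality)


def _nmi_from_values(fv: np.ndarray, mv: np.ndarray, n_bins: int) -> float:
    fmin, fmax = fv.min(), fv.max()
    mmin, mmax = mv.min(), mv.max()
    if fv.size < 8 or fmin == fmax or mmin == mmax:
        return 0.0
    # equal-width joint histogram via bincount (hot path of the optimizer)
    fi = ((fv - fmin) * (n_bins / (fmax - fmin))).astype(np.intp)
    mi_ = ((mv - mmin) * (n_bins / (mmax - mmin))).astype(np.intp)
    np.clip(fi, 0, n_bins - 1, out=fi)
    np.clip(mi_, 0, n_bins - 1, out=mi_)
    pxy = np.bincount(fi * n_bins + mi_, minlength=n_bins * n_bins).astype(np.float64)
    pxy = pxy.reshape(n_bins, n_bins)
    pxy /= pxy.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def ent(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    hx, hy = ent(px), ent(py)
    return float(2.0 * (hx + hy - ent(pxy.ravel())) / (hx + hy))


class _LevelObjective:
    """Negative NMI of (fixed, moving sampled at T^-1(x)) at one pyramid level.

    Hot path: volumes and sample coordinates are held in float32 (sub-HU
    interpolation noise, far below the similarity's sensitivity) and the
    moving-image voxel indices are computed with one fused affine.
    """

    def __init__(
        self,
        moving: VolumeImage,
        fixed: VolumeImage,
        center: np.ndarray,
        n_bins: int,
        mask: np.ndarray | None,
    ) -> None:
        self.moving_voxels = moving.voxels.astype(np.float32)
        self.moving_origin = np.asarray(moving.origin)
        self.moving_spacing = np.asarray(moving.spacing)
        self.n_bins = n_bins
        self.center = np.asarray(center, dtype=np.float64)
        pts = fixed.grid.voxel_centers().reshape(-1, 3)
        if mask is not None:
            keep = mask.ravel()
            pts = pts[keep]
            self.fixed_values = fixed.voxels.ravel()[keep]
        else:
            self.fixed_values = fixed.voxels.ravel()
        self.points = np.ascontiguousarray(pts)
        self.dims = np.asarray(moving.shape, dtype=np.float64)
        self.evals = 0

    def _sample_indices(self, params: np.ndarray) -> np.ndarray:
        T = RigidTransform.from_params(params, center=tuple(self.center))
        # fused world->world->index affine: idx = (p @ A^T + b)
        Rinv = invert(T)
        A = Rinv.rotation_matrix() / self.moving_spacing[:, None]
        b = (
            Rinv.apply(np.zeros(3)) - self.moving_origin
        ) / self.moving_spacing
        return self.points @ A.T + b

    def infield_fraction(self, params: np.ndarray) -> float:
        idx = self._sample_indices(params)
        ok = np.all((idx >= 0) & (idx <= self.dims - 1), axis=1)
        return float(ok.mean())

    def __call__(self, params: np.ndarray) -> float:
        self.evals += 1
        idx = self._sample_indices(params)
        ok = np.all((idx >= 0) & (idx <= self.dims - 1), axis=1)
        if not ok.any():
            return 0.0
        mv = ndimage.map_coordinates(
            self.moving_voxels, idx[ok].T.astype(np.float32), order=1, mode="nearest"
        )
        return -_nmi_from_values(self.fixed_values[ok], mv, self.n_bins)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    mode: str = "all_anatomy",
    init: RigidTransform | None = None,
    opts: RegistrationOptions = RegistrationOptions(),
) -> RegistrationResult:
    """Rigidly register ``moving`` to ``fixed`` by maximizing NMI.

    Returns the moving-to-fixed transform with rotation center at the fixed
    image's grid center.  Deterministic given inputs and options: the
    similarity uses every overlap voxel (no stochastic sampling) and the
    Powell search has a fixed evaluation order.  In ``bone`` mode the
    similarity is computed only inside :func:`bone_mask` of the fixed image.
    Non-convergence within the evaluation budget returns the best-so-far
    transform with ``converged=False`` rather than raising.
    """
    if mode not in ("all_anatomy", "bone"):
        raise ValueError(f"mode must be 'all_anatomy' or 'bone', got {mode!r}")
    center = fixed.center
    if init is None:
        init = RigidTransform.identity(center=tuple(center))
    elif not np.allclose(init.center, center, atol=1e-9):
        init = recenter(init, tuple(center))

    full_mask = bone_mask(fixed, opts.bone_hu_threshold) if mode == "bone" else None

    params = init.params.copy()
    total_evals = 0
    obj = None
    for factor, maxfev, xtol in zip(opts.shrink_factors, opts.max_evals, opts.xtol_mm_deg):
        mov_l = _level_image(moving, factor)
        fix_l = _level_image(fixed, factor)
        mask_l = _shrink_mask(full_mask, factor) if full_mask is not None else None
        obj = _LevelObjective(mov_l, fix_l, center, opts.n_bins, mask_l)
        if obj.infield_fraction(params) == 0.0:
            raise ValueError(
                "no overlap between moving and fixed fields of view under the "
                "initial transform"
            )
        res = optimize.minimize(
            obj,
            params,
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-7, "maxfev": maxfev},
        )
        params = np.asarray(res.x, dtype=np.float64)
        total_evals += obj.evals

    # converged := the returned parameters are a local NMI maximum at the
    # finest level within its parameter tolerance: no +/- xtol step along any
    # of the 6 axes improves the objective beyond float noise.
    final_xtol = opts.xtol_mm_deg[-1]
    f0 = obj(params)
    converged = True
    for d in range(6):
        for sign in (1.0, -1.0):
            probe = params.copy()
            probe[d] += sign * final_xtol
            if obj(probe) < f0 - 1e-7:
                converged = False
                break
        if not converged:
            break

    transform = RigidTransform.from_params(params, center=tuple(center))
    # final report on the full-resolution fixed grid
    from .core import resample_volume  # local import to avoid cycle at module load

    moved, infield = resample_volume(
        moving, invert(transform), fixed.grid, fill=moving.default_fill(), return_mask=True
    )
    mask = infield if full_mask is None else (infield & full_mask)
    report = similarity_report(moved, fixed, n_bins=64, mask=mask)
    return RegistrationResult(
        transform=transform,
        final_similarity=report,
        converged=converged,
        iterations=total_evals,
    )


@dataclass(frozen=True)
class ResidualDisplacement:
    """Decomposed residual transform left over after a registration loop."""

    tx: float
    ty: float
    tz: float
    roll: float
    pitch: float
    yaw: float

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.tx**2 + self.ty**2 + self.tz**2)

    @classmethod
    def from_transform(cls, T: RigidTransform) -> "ResidualDisplacement":
        return cls(T.tx, T.ty, T.tz, T.roll, T.pitch, T.yaw)


def residual_chain(
    T_a: RigidTransform, T_b: RigidTransform, T_c: RigidTransform
) -> ResidualDisplacement:
    """Residual of routing the repeat MR through the initial CT.

    ``T_a`` maps rMR to rCT (direct), ``T_b`` maps rMR to iCT, ``T_c`` maps
    iCT to rCT.  Under the assumption that the CT-to-CT registration is
    perfect, the residual ``R = invert(T_a) . T_c . T_b`` is the transform
    remaining on the rMR after the indirect route, and is zero exactly when
    the chain is consistent.  All three transforms must share a rotation
    convention and center.
    """
    R = compose(invert(T_a), compose(T_c, T_b))
    return ResidualDisplacement.from_transform(R)
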