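"""Per-case study orchestration and cohort-level correlation.

``run_case`` chains every stage of the repeat-treatment feasibility
analysis for one patient case: the three rigid registrations and their
residual chain (targeting accuracy), per-target skull ray-trace comparison
(skull stability), whole-volume similarity (scan information content), and
per-target 3D gamma between the repeat-CT dose and the dose evaluated on
the registered initial CT (dosimetric accuracy).  The result is a single
``CaseReport`` that is fully recomputable from the inputs plus the
configuration it embeds.

Note the dose-comparison substitution: the clinical study recalculates the
treatment plan on the initial CT in a treatment planning system.  This
package instead compares either a user-supplied initial-CT dose grid or the
analytic dose surrogate evaluated on the registered initial-CT frame — it
exercises the comparison machinery (resampling, gamma), not a beam model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import GridSpec, RigidTransform, Target, VolumeImage, invert, recenter, resample_volume
from .gamma import GammaCriteria, GammaResult, gamma_map, resample_dose_fine
from .phantom import DoseSpec, make_srs_dose
from .raytrace import ProfileComparison, RayTraceParams, profile_difference, skull_profile
from .registration import (
    RegistrationOptions,
    RegistrationResult,
    ResidualDisplacement,
    register_rigid,
    residual_chain,
)
from .similarity import SimilarityReport, similarity_report

__all__ = [
    "CaseConfig",
    "CaseReport",
    "CorrelationVerdict",
    "run_case",
    "correlate_with_time",
    "report_to_dict",
    "save_report_json",
    "config_from_yaml",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class CaseConfig:
    """All tunables of a case run; logged verbatim into provenance."""

    registration: RegistrationOptions = RegistrationOptions()
    raytrace: RayTraceParams = RayTraceParams()
    gamma_criteria: GammaCriteria = GammaCriteria()
    dose: DoseSpec = DoseSpec()
    similarity_bins: int = 64
    # half-width padding (mm) added around the PTV+penumbra when cropping
    # the dose region for the per-target gamma evaluation
    gamma_crop_pad: float = 2.0
    skull_stability_warn_mm: float = 2.0


@dataclass
class CaseReport:
    """All per-case metrics: residuals, skull profiles, similarity, gamma."""

    case_id: str
    schema_version: str
    residual: ResidualDisplacement | None
    registrations: dict[str, RegistrationResult]
    profile_comparisons: dict[str, ProfileComparison]
    similarity: SimilarityReport | None
    gamma: dict[str, GammaResult]
    skull_stability_flag: bool
    errors: dict[str, str]
    provenance: dict

    @property
    def mean_profile_difference(self) -> float:
        """Per-target means averaged over targets (per-patient aggregation)."""
        if not self.profile_comparisons:
            return float("nan")
        return float(np.mean([c.mean_abs_diff for c in self.profile_comparisons.values()]))

    @property
    def pooled_profile_difference(self) -> float:
        """All valid rays of all targets pooled (per-ray aggregation)."""
        diffs = [
            c.per_ray_abs_diff[~np.isnan(c.per_ray_abs_diff)]
            for c in self.profile_comparisons.values()
        ]
        if not diffs:
            return float("nan")
        return float(np.concatenate(diffs).mean())


def _checksum(img: VolumeImage) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(img.voxels).tobytes())
    h.update(np.asarray(img.spacing).tobytes())
    h.update(np.asarray(img.origin).tobytes())
    return h.hexdigest()[:16]


def _dose_crop_grid(target: Target, cfg: CaseConfig) -> GridSpec:
    half = target.ptv_radius + 5.0 * cfg.dose.falloff_sigma + cfg.gamma_crop_pad
    spacing = cfg.dose.spacing
    shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
    origin = tuple(
        c - (n - 1) / 2.0 * s for c, n, s in zip(target.centroid, shape, spacing)
    )
    return GridSpec(shape, spacing, origin)


def run_case(
    ict: VolumeImage,
    rct: VolumeImage,
    rmr: VolumeImage,
    dose_rct: VolumeImage | None,
    targets: list[Target],
    config: CaseConfig = CaseConfig(),
    case_id: str = "case",
    dose_ict: VolumeImage | None = None,
) -> CaseReport:
    """Run the full feasibility analysis for one case.

    Stages: (a) register rMR to rCT over all anatomy, (b) rMR to iCT over
    bone, (c) iCT to rCT, then form the residual chain; trace skull
    profiles per target on the iCT and on the rCT resampled into the iCT
    frame and compare; score iCT-vs-registered-rCT similarity; and run the
    per-target gamma between the rCT-frame dose (reference; the supplied
    ``dose_rct`` or, when None, the analytic surrogate plan per target) and
    the iCT-frame dose (evaluated; ``dose_ict`` or the surrogate
    regenerated at the back-mapped target).  Stage failures are
    recorded by name in ``errors`` and the report is emitted with the
    remaining results rather than raising.

    Targets are given in the rCT frame (they originate from the repeat MR,
    which is aligned to the rCT by registration (a)).
    """
    if not targets:
        raise ValueError("at least one target required")
    errors: dict[str, str] = {}
    registrations: dict[str, RegistrationResult] = {}
    residual = None
    profile_comparisons: dict[str, ProfileComparison] = {}
    similarity = None
    gamma_results: dict[str, GammaResult] = {}
    skull_flag = False

    # --- registrations and residual chain ---------------------------------
    T_c = None
    try:
        reg_a = register_rigid(rmr, rct, mode="all_anatomy", opts=config.registration)
        registrations["rmr_to_rct"] = reg_a
        reg_b = register_rigid(rmr, ict, mode="bone", opts=config.registration)
        registrations["rmr_to_ict"] = reg_b
        reg_c = register_rigid(ict, rct, mode="all_anatomy", opts=config.registration)
        registrations["ict_to_rct"] = reg_c
        T_c = reg_c.transform
        # re-express about a common center (the rCT grid center) before chaining
        center = tuple(rct.center)
        T_a = recenter(reg_a.transform, center)
        T_b = recenter(reg_b.transform, center)
        residual = residual_chain(T_a, T_b, recenter(T_c, center))
    except Exception as exc:  # noqa: BLE001 - stage failures become report entries
        errors["registration"] = str(exc)

    # --- skull ray-trace comparison ---------------------------------------
    # Profiles are measured in the rCT frame: on the rCT itself and on the
    # iCT resampled into the rCT frame through the (c) registration.
    try:
        if T_c is None:
            raise RuntimeError("skipped: registration stage failed")
        ict_on_rct = resample_volume(ict, invert(T_c), rct.grid, fill=-1000.0)
        for t in targets:
            p_r = skull_profile(rct, t, config.raytrace)
            p_i = skull_profile(ict_on_rct, t, config.raytrace)
            cmp_ = profile_difference(p_i, p_r)
            profile_comparisons[t.target_id] = cmp_
            if cmp_.mean_abs_diff > config.skull_stability_warn_mm:
                skull_flag = True
    except Exception as exc:  # noqa: BLE001
        errors["skull_raytrace"] = str(exc)

    # --- similarity --------------------------------------------------------
    try:
        if T_c is None:
            raise RuntimeError("skipped: registration stage failed")
        ict_on_rct, infield = resample_volume(
            ict, invert(T_c), rct.grid, fill=-1000.0, return_mask=True
        )
        similarity = similarity_report(ict_on_rct, rct, config.similarity_bins, mask=infield)
    except Exception as exc:  # noqa: BLE001
        errors["similarity"] = str(exc)

    # --- per-target gamma ---------------------------------------------------
    # Reference = the rCT-frame dose (supplied grid, or the analytic
    # surrogate plan for each target); evaluated = the iCT-frame dose
    # carried into the rCT frame through the (c) registration.
    global_max = float(dose_rct.voxels.max()) if dose_rct is not None else (
        config.dose.prescription)
    for t in targets:
        try:
            crop = _dose_crop_grid(t, config)
            if dose_rct is not None:
                ref_coarse = resample_volume(dose_rct, None, crop, fill=0.0)
                if ref_coarse.voxels.max() <= (
                    config.gamma_criteria.threshold / 100.0
                ) * global_max:
                    errors[f"gamma:{t.target_id}"] = (
                        "supplied rCT dose has no points above threshold near "
                        "this target; gamma skipped"
                    )
                    continue
            else:
                ref_coarse = make_srs_dose(t, dataclasses.replace(
                    config.dose, shape=crop.shape, origin=crop.origin))
            if dose_ict is not None:
                # ev(x_rct) = dose_ict(invert(T_c)(x_rct))
                samp = invert(T_c) if T_c is not None else None
                ev_coarse = resample_volume(dose_ict, samp, crop, fill=0.0)
            else:
                # Surrogate stand-in for a plan transferred to the iCT and
                # recalculated there: the same spherical plan centered on
                # the target's back-mapped iCT-frame position, then brought
                # to the rCT frame.  With a perfect registration this round
                # trip is the identity up to interpolation.
                t_ict = t if T_c is None else t.moved_by(invert(T_c))
                dose_i = make_srs_dose(t_ict, dataclasses.replace(
                    config.dose, shape=None, origin=None))
                samp = invert(T_c) if T_c is not None else None
                ev_coarse = resample_volume(dose_i, samp, crop, fill=0.0)
            fine = config.gamma_criteria.fine_spacing
            ref_fine = resample_dose_fine(ref_coarse, fine)
            ev_fine = resample_dose_fine(ev_coarse, fine)
            gamma_results[t.target_id] = gamma_map(
                ref_fine, ev_fine, config.gamma_criteria, global_max=global_max
            )
        except Exception as exc:  # noqa: BLE001
            errors[f"gamma:{t.target_id}"] = str(exc)

    provenance = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": _config_dict(config),
        "inputs": {
            "ict": _checksum(ict),
            "rct": _checksum(rct),
            "rmr": _checksum(rmr),
            "dose_rct": _checksum(dose_rct) if dose_rct is not None else None,
            "dose_ict": _checksum(dose_ict) if dose_ict is not None else None,
            "targets": [dataclasses.asdict(t) for t in targets],
        },
    }
    return CaseReport(
        case_id=case_id,
        schema_version=REPORT_SCHEMA_VERSION,
        residual=residual,
        registrations=registrations,
        profile_comparisons=profile_comparisons,
        similarity=similarity,
        gamma=gamma_results,
        skull_stability_flag=skull_flag,
        errors=errors,
        provenance=provenance,
    )


def config_from_yaml(path) -> CaseConfig:
    """Build a :class:`CaseConfig` from a YAML file.

    Top-level keys mirror the config dataclasses: ``registration``,
    ``raytrace``, ``gamma_criteria``, ``dose`` (each a mapping of that
    dataclass's fields) plus the scalar fields of ``CaseConfig``.  Omitted
    keys keep their defaults; unknown keys raise.  The loaded configuration
    is logged verbatim into each report's provenance.
    """
    import yaml

    from .gamma import GammaCriteria
    from .phantom import DoseSpec
    from .raytrace import RayTraceParams
    from .registration import RegistrationOptions

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    sections = {
        "registration": RegistrationOptions,
        "raytrace": RayTraceParams,
        "gamma_criteria": GammaCriteria,
        "dose": DoseSpec,
    }
    kwargs: dict = {}
    scalar_fields = {f.name for f in dataclasses.fields(CaseConfig)} - set(sections)
    for key, value in raw.items():
        if key in sections:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            cls = sections[key]
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - known
            if bad:
                raise ValueError(f"unknown {key} option(s): {sorted(bad)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = cls(**coerced)
        elif key in scalar_fields:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return CaseConfig(**kwargs)


# --------------------------------------------------------------------------
# Correlation with time
# --------------------------------------------------------------------------

_STRENGTH_WEAK_BELOW = 0.4
_STRENGTH_STRONG_ABOVE = 0.7
_ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationVerdict:
    """Pearson r with the conventional strength bands and significance.

    ``|r| < 0.4`` is weak, ``0.4 <= |r| <= 0.7`` intermediate and
    ``|r| > 0.7`` strong; significance is a two-sided p below 0.05.
    """

    r: float
    p: float
    strength: str
    significant: bool
    n: int


def correlate_with_time(values, times) -> CorrelationVerdict:
    """Pearson correlation of a metric against time between scans (days).

    The p-value uses the exact t transform with n-2 degrees of freedom.
    Needs at least 3 pairs and non-constant inputs.
    """
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if values.shape != times.shape or values.ndim != 1:
        raise ValueError("values and times must be equal-length 1D sequences")
    if values.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(values) == 0 or np.ptp(times) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(values, times)
    r, p = float(res.statistic), float(res.pvalue)
    a = abs(r)
    if a < _STRENGTH_WEAK_BELOW:
        strength = "weak"
    elif a <= _STRENGTH_STRONG_ABOVE:
        strength = "intermediate"
    else:
        strength = "strong"
    return CorrelationVerdict(r=r, p=p, strength=strength, significant=p < _ALPHA, n=values.size)


# --------------------------------------------------------------------------
# Report serialization
# --------------------------------------------------------------------------

def _config_dict(config: CaseConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def report_to_dict(report: CaseReport) -> dict:
    """JSON-serializable view of a CaseReport (gamma fields summarized)."""
    d: dict = {
        "case_id": report.case_id,
        "schema_version": report.schema_version,
        "errors": report.errors,
        "skull_stability_flag": report.skull_stability_flag,
        "provenance": report.provenance,
    }
    if report.residual is not None:
        r = report.residual
        d["residual"] = {
            "magnitude_mm": r.magnitude,
            "tx_mm": r.tx, "ty_mm": r.ty, "tz_mm": r.tz,
            "roll_deg": r.roll, "pitch_deg": r.pitch, "yaw_deg": r.yaw,
        }
    d["registrations"] = {
        name: {
            "params": list(res.transform.params),
            "center_mm": list(res.transform.center),
            "converged": res.converged,
            "iterations": res.iterations,
            "nmi": res.final_similarity.mi,
            "pc": res.final_similarity.pc,
        }
        for name, res in report.registrations.items()
    }
    d["profile_comparisons"] = {
        tid: {
            "mean_abs_diff_mm": c.mean_abs_diff,
            "max_abs_diff_mm": c.max_abs_diff,
            "n_valid_rays": c.n_valid_rays,
            "per_ray_abs_diff_mm": [
                None if np.isnan(v) else float(v) for v in c.per_ray_abs_diff
            ],
        }
        for tid, c in report.profile_comparisons.items()
    }
    if report.profile_comparisons:
        d["profile_summary"] = {
            "per_target_mean_mm": report.mean_profile_difference,
            "pooled_per_ray_mean_mm": report.pooled_profile_difference,
        }
    if report.similarity is not None:
        s = report.similarity
        d["similarity"] = {
            "mi": s.mi, "pc": s.pc, "n_overlap": s.n_overlap, "n_bins": s.n_bins,
        }
    d["gamma"] = {
        tid: {
            "passing_rate": g.passing_rate,
            "n_evaluated": g.n_evaluated,
            "global_max_gy": g.global_max,
            "criteria": _config_dict_criteria(g.criteria),
        }
        for tid, g in report.gamma.items()
    }
    return d


def _config_dict_criteria(c: GammaCriteria) -> dict:
    return {
        "dta_mm": c.dta,
        "dose_diff_pct": c.dose_diff,
        "threshold_pct": c.threshold,
        "fine_spacing_mm": c.fine_spacing,
        "search_radius_mm": c.search_radius,
    }


def save_report_json(report: CaseReport, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2))
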