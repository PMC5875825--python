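"""File I/O: NIfTI volumes, DICOM CT series, DICOM RTDOSE, targets CSV.

World coordinates throughout the package are DICOM LPS (mm).  NIfTI stores
RAS+ affines, so the x and y axes are sign-flipped on write and flipped
back on read; only axis-aligned (diagonal-affine / identity-orientation)
geometry is supported, and oblique inputs are rejected rather than
silently reoriented.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import RigidTransform, Target, VolumeImage

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_dicom_ct_series",
    "load_dicom_ct_series",
    "save_rtdose",
    "load_rtdose",
    "load_volume",
    "save_targets_csv",
    "load_targets_csv",
    "save_transform_json",
    "load_transform_json",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

def save_nifti(img: VolumeImage, path) -> None:
    """Write a volume as NIfTI (float64; lossless round trip)."""
    dx, dy, dz = img.spacing
    ox, oy, oz = img.origin
    affine = np.diag([-dx, -dy, dz, 1.0])
    affine[:3, 3] = [-ox, -oy, oz]
    ni = nib.Nifti1Image(img.voxels, affine)
    ni.header["descrip"] = img.modality.encode()
    nib.save(ni, str(path))


def load_nifti(path, modality: str | None = None) -> VolumeImage:
    """Load an axis-aligned NIfTI volume into LPS world coordinates."""
    ni = nib.load(str(path))
    affine = ni.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise ValueError(f"oblique NIfTI orientation not supported: {path}")
    diag = np.diag(affine[:3, :3])
    if np.any(np.abs(diag) < 1e-12):
        raise ValueError(f"degenerate NIfTI affine: {path}")
    vox = np.asarray(ni.dataobj, dtype=np.float64)
    t = affine[:3, 3].copy()
    # RAS -> LPS: negate x and y
    scale = np.array([-diag[0], -diag[1], diag[2]])
    origin = np.array([-t[0], -t[1], t[2]])
    for ax in range(3):
        if scale[ax] < 0:  # flip so LPS spacing is positive
            vox = np.flip(vox, axis=ax)
            origin[ax] = origin[ax] + scale[ax] * (vox.shape[ax] - 1)
            scale[ax] = -scale[ax]
    if modality is None:
        descrip = bytes(ni.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
        modality = descrip if descrip in VolumeImage._MODALITIES else "CT"
    return VolumeImage(vox, tuple(scale), tuple(origin), modality)


# --------------------------------------------------------------------------
# DICOM CT series
# --------------------------------------------------------------------------

def _file_meta(sop_class: str, sop_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_ids(ds: Dataset, modality: str) -> None:
    now = datetime.datetime(2000, 1, 1)  # fixed timestamps: byte-stable output
    ds.PatientName = "PHANTOM^SRS"
    ds.PatientID = "SRSRESCAN"
    ds.StudyDate = ds.SeriesDate = now.strftime("%Y%m%d")
    ds.StudyTime = ds.SeriesTime = now.strftime("%H%M%S")
    ds.Modality = modality
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"


def save_dicom_ct_series(img: VolumeImage, out_dir) -> list[Path]:
    """Write a CT volume as one DICOM file per axial slice.

    HU is stored as signed 16-bit with rescale slope 1 / intercept 0, so
    the quantization error is at most 0.5 HU.
    """
    if img.modality != "CT":
        raise ValueError("save_dicom_ct_series expects a CT volume")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = img.shape
    dx, dy, dz = img.spacing
    ox, oy, oz = img.origin
    study_uid = generate_uid()
    series_uid = generate_uid()
    frame_uid = generate_uid()
    stored = np.clip(np.round(img.voxels), -32768, 32767).astype(np.int16)
    paths = []
    for k in range(nz):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(_CT_SOP, sop_uid)
        _common_ids(ds, "CT")
        ds.SOPClassUID = _CT_SOP
        ds.SOPInstanceUID = sop_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]  # row spacing (y), column spacing (x)
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.RescaleType = "HU"
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = out_dir / f"ct_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def load_dicom_ct_series(directory) -> VolumeImage:
    """Load an axial DICOM CT series (one file per slice) as a volume."""
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if not slices:
        raise ValueError(f"no CT slices in {directory}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    orient = np.asarray([float(v) for v in first.ImageOrientationPatient])
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise ValueError("oblique DICOM orientation not supported")
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) < 2:
        raise ValueError("need at least 2 slices")
    dzs = np.diff(zs)
    if not np.allclose(dzs, dzs[0], atol=1e-6):
        raise ValueError("mixed slice spacing in series")
    dz = float(dzs[0])
    ox, oy = (float(v) for v in first.ImagePositionPatient[:2])
    for s in slices:
        if not np.allclose([float(v) for v in s.ImagePositionPatient[:2]], [ox, oy], atol=1e-6):
            raise ValueError("slices are not stacked along z only")
    planes = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(s.pixel_array.astype(np.float64) * slope + inter)
    vol = np.stack(planes, axis=-1)  # (rows=y, cols=x, z)
    vox = np.transpose(vol, (1, 0, 2))  # -> (x, y, z)
    return VolumeImage(vox, (dx, dy, dz), (ox, oy, float(zs[0])), "CT")


# --------------------------------------------------------------------------
# DICOM RTDOSE
# --------------------------------------------------------------------------

def save_rtdose(dose: VolumeImage, path) -> None:
    """Write a dose grid as a multi-frame DICOM RTDOSE (32-bit, Gy)."""
    if dose.modality != "DOSE":
        raise ValueError("save_rtdose expects a DOSE volume")
    nx, ny, nz = dose.shape
    dx, dy, dz = dose.spacing
    ox, oy, oz = dose.origin
    dmax = float(dose.voxels.max())
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    stored = np.round(dose.voxels / scaling).astype(np.uint32) if dmax > 0 else np.zeros(
        dose.shape, dtype=np.uint32
    )
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_RTDOSE_SOP, sop_uid)
    _common_ids(ds, "RTDOSE")
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [dy, dx]
    ds.SliceThickness = dz
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [k * dz for k in range(nz)]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    # frames along z, each frame rows=y cols=x
    ds.PixelData = np.ascontiguousarray(np.transpose(stored, (2, 1, 0))).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def load_rtdose(path) -> VolumeImage:
    """Load a DICOM RTDOSE grid, honoring dose-grid scaling and offsets."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path} is not an RTDOSE file")
    orient = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise ValueError("oblique RTDOSE orientation not supported")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dzs = np.diff(offsets)
    if not np.allclose(dzs, dzs[0], atol=1e-6):
        raise ValueError("non-uniform frame offsets not supported")
    dy, dx = (float(v) for v in ds.PixelSpacing)
    scaling = float(ds.DoseGridScaling)
    frames = ds.pixel_array.astype(np.float64) * scaling  # (z, y, x)
    vox = np.transpose(frames, (2, 1, 0))
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    return VolumeImage(vox, (dx, dy, float(dzs[0])), (ox, oy, oz + offsets[0]), "DOSE")


# --------------------------------------------------------------------------
# Dispatch
# --------------------------------------------------------------------------

def load_volume(path, format: str | None = None, modality: str | None = None) -> VolumeImage:
    """Load a volume, auto-detecting the container when ``format`` is None.

    ``format`` may be ``"dicom_series"`` (a directory of CT slices),
    ``"rtdose"`` or ``"nifti"``.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "dicom_series"
        elif path.suffix == ".dcm":
            format = "rtdose"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "dicom_series":
        return load_dicom_ct_series(path)
    if format == "rtdose":
        return load_rtdose(path)
    if format == "nifti":
        return load_nifti(path, modality=modality)
    raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# Targets CSV and transform JSON
# --------------------------------------------------------------------------

def save_targets_csv(targets, path) -> None:
    rows = [
        {
            "target_id": t.target_id,
            "x_mm": t.centroid[0],
            "y_mm": t.centroid[1],
            "z_mm": t.centroid[2],
            "gtv_radius_mm": t.gtv_radius,
            "margin_mm": t.margin,
        }
        for t in targets
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_targets_csv(path) -> list[Target]:
    df = pd.read_csv(path)
    targets = []
    for _, row in df.iterrows():
        targets.append(
            Target(
                centroid=(row["x_mm"], row["y_mm"], row["z_mm"]),
                gtv_radius=float(row["gtv_radius_mm"]),
                margin=float(row.get("margin_mm", 1.0)),
                target_id=str(row["target_id"]),
            )
        )
    return targets


_CONVENTION = "LPS; fixed-axis R=yaw(y)*pitch(x)*roll(z); degrees; mm"


def save_transform_json(T: RigidTransform, path) -> None:
    payload = {
        "tx_mm": T.tx,
        "ty_mm": T.ty,
        "tz_mm": T.tz,
        "roll_deg": T.roll,
        "pitch_deg": T.pitch,
        "yaw_deg": T.yaw,
        "center_mm": list(T.center),
        "convention": _CONVENTION,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_transform_json(path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    if d.get("convention") != _CONVENTION:
        raise ValueError(f"unsupported transform convention: {d.get('convention')!r}")
    return RigidTransform(
        d["tx_mm"], d["ty_mm"], d["tz_mm"], d["roll_deg"], d["pitch_deg"], d["yaw_deg"],
        center=tuple(d["center_mm"]),
    )
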