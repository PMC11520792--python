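"""File formats: DICOM series, STL meshes, raw volumes, transforms, fields.

Coordinate convention: right-handed, millimetres, volume origin at the
center of the first voxel, volume axis order (x, y, z). DICOM slices are
written along z with ImageOrientationPatient (1,0,0,0,1,0), i.e. pixel
columns run along x and rows along y; HU values are stored as int16 with
rescale slope/intercept applied on read. STL files are written binary
(little-endian, mm); reading welds the triangle soup within 1e-6 mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import trimesh
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .geometry import SurfaceMesh
from .phantom import VoxelVolume

__all__ = [
    "read_dicom_volume",
    "write_dicom_volume",
    "read_stl",
    "write_stl",
    "read_volume_raw",
    "write_volume_raw",
    "read_transform_json",
    "write_transform_json",
    "write_fields_csv",
]


class IOError_(RuntimeError):
    """File-format or consistency error on read/write."""


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

# deterministic UID root for phantom series (UIDs must not depend on time,
# or identical runs would differ byte-wise)
_UID_PREFIX = "1.2.826.0.1.3680043.10.1405."


def write_dicom_volume(vol: VoxelVolume, directory) -> None:
    """Write a volume as a single-series axial DICOM stack.

    HU values are rounded to int16 (slope 1, intercept 0); callers needing
    exact round trips should write integral HU volumes (the phantom's
    noise-free volumes are integral by construction).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = _UID_PREFIX + "1.1"
    study_uid = _UID_PREFIX + "1.2"
    nz = vol.shape[2]
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = _UID_PREFIX + f"1.3.{k + 1}"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(vol.origin[0]),
            float(vol.origin[1]),
            float(vol.origin[2] + k * vol.spacing[2]),
        ]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.InstanceNumber = k + 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        # rows along y, columns along x
        plane = np.round(vol.values[:, :, k]).astype(np.int16).T
        ds.Rows, ds.Columns = plane.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = plane.tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(
            directory / f"slice_{k:04d}.dcm",
            enforce_file_format=True,
        )


def read_dicom_volume(path) -> VoxelVolume:
    """Read one coherent single-frame DICOM series from a directory.

    Slices are sorted by position along the slice normal; pixel spacing and
    the slice interval define the voxel spacing; rescale slope/intercept
    are applied. Mixed series, missing spacing tags and non-uniform slice
    gaps (> 1% deviation) are explicit errors.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.is_file() and p.suffix.lower() == ".dcm"
    )
    if not files:
        raise IOError_(f"no DICOM files in {path}")
    slices = [pydicom.dcmread(f) for f in files]

    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) != 1:
        raise IOError_("mixed series: directory contains multiple SeriesInstanceUIDs")
    for s in slices:
        if "PixelSpacing" not in s or "ImagePositionPatient" not in s:
            raise IOError_("missing PixelSpacing or ImagePositionPatient tags")

    iop = np.array(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    zpos = [float(np.dot(normal, np.array(s.ImagePositionPatient, float))) for s in slices]
    order = np.argsort(zpos)
    slices = [slices[i] for i in order]
    zpos = np.array(zpos)[order]

    if len(slices) > 1:
        gaps = np.diff(zpos)
        if gaps.min() <= 0:
            raise IOError_("duplicate or non-increasing slice positions")
        if (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            raise IOError_("non-uniform slice spacing (> 1% deviation)")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    ps = [float(x) for x in slices[0].PixelSpacing]  # [row (y), col (x)]
    spacing = np.array([ps[1], ps[0], dz])
    origin = np.array(slices[0].ImagePositionPatient, dtype=float)

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    values = np.stack([p.T for p in planes], axis=2)  # (x, y, z)
    return VoxelVolume(values, spacing, origin)


# ---------------------------------------------------------------------------
# raw volume (documented raw + JSON header fallback)
# ---------------------------------------------------------------------------


def write_volume_raw(vol: VoxelVolume, basepath) -> None:
    """Write `<base>.raw` (float64 little-endian, C order, axis (x, y, z))
    plus `<base>.json` holding shape, spacing and origin."""
    basepath = str(basepath)
    vol.values.astype("<f8").tofile(basepath + ".raw")
    header = {
        "shape": list(vol.shape),
        "dtype": "<f8",
        "order": "C",
        "axes": "xyz",
        "spacing_mm": vol.spacing.tolist(),
        "origin_mm": vol.origin.tolist(),
    }
    with open(basepath + ".json", "w") as fh:
        json.dump(header, fh, indent=1)


def read_volume_raw(basepath) -> VoxelVolume:
    basepath = str(basepath)
    with open(basepath + ".json") as fh:
        header = json.load(fh)
    values = np.fromfile(basepath + ".raw", dtype=header["dtype"]).reshape(
        header["shape"]
    )
    return VoxelVolume(values, header["spacing_mm"], header["origin_mm"])


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Binary little-endian STL, units mm."""
    if mesh.n_faces == 0:
        raise IOError_("refusing to write an empty mesh")
    data = trimesh.exchange.stl.export_stl(mesh.as_trimesh())
    with open(path, "wb") as fh:
        fh.write(data)


def read_stl(path, weld_tol: float = 1e-6) -> SurfaceMesh:
    """Read binary or ASCII STL; welds the triangle soup within
    ``weld_tol`` mm so shared vertices are re-identified."""
    try:
        tm = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise IOError_(f"cannot read STL {path}: {exc}") from exc
    v = np.asarray(tm.vertices, dtype=np.float64)
    f = np.asarray(tm.faces, dtype=np.int64)
    if len(f) == 0:
        raise IOError_(f"STL {path} contains no triangles")
    if not np.isfinite(v).all():
        raise IOError_(f"STL {path} contains non-finite coordinates")
    return SurfaceMesh(v, f).welded(weld_tol)


# ---------------------------------------------------------------------------
# transforms and fields
# ---------------------------------------------------------------------------


def write_transform_json(transform, path) -> None:
    """4x4 homogeneous matrix, row-major nested lists."""
    payload = {
        "matrix_4x4_row_major": transform.to_matrix().tolist(),
        "units": "mm",
        "convention": "x' = R x + t, applied to the moving (source) mesh",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_transform_json(path):
    from .registration import RigidTransform

    with open(path) as fh:
        payload = json.load(fh)
    return RigidTransform.from_matrix(np.array(payload["matrix_4x4_row_major"]))


def write_fields_csv(path, mesh: SurfaceMesh, euclidean, normal) -> None:
    """Per-vertex deviation table: vertex_index, x, y, z, euclidean_mm,
    normal_mm, missing. The normal column is empty on missing vertices."""
    with open(path, "w", newline="") as fh:
        fh.write("vertex_index,x,y,z,euclidean_mm,normal_mm,missing\n")
        for i, (v, e, nv, miss) in enumerate(
            zip(mesh.vertices, euclidean.values, normal.values, normal.missing)
        ):
            nrm = "" if miss else f"{nv:.9g}"
            fh.write(
                f"{i},{v[0]:.9g},{v[1]:.9g},{v[2]:.9g},{e:.9g},{nrm},{int(miss)}\n"
            )
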