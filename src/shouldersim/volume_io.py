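"""Volumetric and radiograph containers with NIfTI / DICOM / 16-bit raster I/O.

World coordinates follow the DICOM LPS convention throughout the package:
``x`` increases to the patient's left, ``y`` posteriorly, ``z`` superiorly.
NIfTI files (which use RAS affines) are reoriented on read and get a
matching RAS affine on write, so round trips are exact.

Voxel indexing is 0-based and voxel *centers* sit on the world grid: voxel
``(i, j, k)`` is at ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import tifffile
from PIL import Image
from PIL.PngImagePlugin import PngInfo
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import MetadataError, ShoulderSimError

DEFAULT_AXIS_LABELS = ("right-left", "anterior-posterior", "inferior-superior")


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing (mm) and world origin (mm, LPS)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ShoulderSimError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if any(n < 2 for n in self.voxels.shape):
            raise ShoulderSimError(f"need >= 2 voxels per axis, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ShoulderSimError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ShoulderSimError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_center(self) -> np.ndarray:
        """World coordinates (mm) of the grid center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2 * np.asarray(self.spacing)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (mm) of the voxel grid, half a voxel beyond the centers."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        return o - 0.5 * sp, o + (np.asarray(self.shape) - 0.5) * sp

    def with_voxels(self, voxels: np.ndarray) -> "Volume3D":
        """Copy of this volume with new intensities on the same grid."""
        return Volume3D(voxels, self.spacing, self.origin, self.axis_labels)


@dataclass
class Radiograph2D:
    """A 2D projected image with detector pixel pitch (mm) and view label.

    ``magnification`` is the cone-beam scale factor sdd/sid; 1 for
    parallel (orthographic) projections.
    """

    pixels: np.ndarray
    pitch: float
    view: str = "AP"
    magnification: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShoulderSimError(f"expected a 2D grid, got ndim={self.pixels.ndim}")
        if self.pitch <= 0:
            raise ShoulderSimError(f"pitch must be positive, got {self.pitch}")
        if self.magnification < 1.0:
            raise ShoulderSimError(f"magnification must be >= 1, got {self.magnification}")
        if not np.all(np.isfinite(self.pixels)):
            raise ShoulderSimError("radiograph intensities must be finite")


# ---------------------------------------------------------------------------
# Volume I/O


def _infer_volume_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise MetadataError(f"cannot infer volume format from {path}")


def read_volume(path, format: str | None = None) -> Volume3D:
    """Read a NIfTI file or a DICOM series directory into a :class:`Volume3D`.

    Spacing and origin come from file metadata; intensities are unchanged.
    DICOM series must share orientation and in-plane spacing, and slice
    positions must be uniform within 1% (larger jitter usually means a
    missing slice).
    """
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such file or directory: {path}")
    fmt = format or _infer_volume_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise MetadataError(f"unknown volume format {fmt!r}")


def _read_nifti(path: Path) -> Volume3D:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types on corrupt files
        raise MetadataError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # RAS, axis-aligned
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected 3D data, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    # RAS -> LPS: flip the first two array axes; origin is the LPS position of
    # the new voxel (0, 0, 0), i.e. RAS voxel (nx-1, ny-1, 0).
    data = data[::-1, ::-1, :].copy()
    corner = aff @ np.array([data.shape[0] - 1, data.shape[1] - 1, 0, 1.0])
    origin = (-float(corner[0]), -float(corner[1]), float(corner[2]))
    return Volume3D(data, spacing, origin)


def write_volume(v: Volume3D, path, format: str | None = None) -> None:
    """Write a volume as NIfTI (float64, exact round trip) or a DICOM series
    (uint16 with rescale slope/intercept, round trip within one quantization
    step)."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "dicom_series" if path.suffix == "" else "nifti"
    if fmt == "nifti":
        sx, sy, sz = v.spacing
        ox, oy, oz = v.origin
        affine = np.array(
            [
                [-sx, 0, 0, -ox],
                [0, -sy, 0, -oy],
                [0, 0, sz, oz],
                [0, 0, 0, 1.0],
            ]
        )
        nib.save(nib.Nifti1Image(v.voxels, affine), str(path))
    elif fmt == "dicom_series":
        _write_dicom_series(v, path)
    else:
        raise MetadataError(f"unknown volume format {fmt!r}")


def _base_sc_dataset() -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def _quantize_u16(arr: np.ndarray) -> tuple[np.ndarray, float, float]:
    vmin = float(arr.min())
    vmax = float(arr.max())
    if vmax > vmin:
        u16 = np.round((arr - vmin) / (vmax - vmin) * 65535.0).astype(np.uint16)
    else:
        u16 = np.zeros(arr.shape, dtype=np.uint16)
    return u16, vmin, vmax


def _write_dicom_series(v: Volume3D, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    u16, vmin, vmax = _quantize_u16(v.voxels)
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    series_uid = generate_uid()
    nx, ny, nz = v.shape
    for k in range(nz):
        ds = _base_sc_dataset()
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.Rows = ny
        ds.Columns = nx
        ds.PixelSpacing = [f"{v.spacing[1]:.8g}", f"{v.spacing[0]:.8g}"]  # row, col
        ds.SliceThickness = f"{v.spacing[2]:.8g}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            f"{v.origin[0]:.8g}",
            f"{v.origin[1]:.8g}",
            f"{v.origin[2] + k * v.spacing[2]:.8g}",
        ]
        ds.RescaleSlope = f"{slope:.9g}"
        ds.RescaleIntercept = f"{vmin:.9g}"
        # slice array indexed [row, col] = [y, x]
        ds.PixelData = np.ascontiguousarray(u16[:, :, k].T).tobytes()
        ds.save_as(outdir / f"slice_{k:04d}.dcm", enforce_file_format=True)


def _read_dicom_series(path: Path) -> Volume3D:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if len(files) < 2:
        raise MetadataError(f"{path}: need at least 2 DICOM slices")
    slices = []
    for f in files:
        try:
            slices.append((f, pydicom.dcmread(str(f))))
        except Exception as exc:
            raise MetadataError(f"cannot read DICOM file {f}: {exc}") from exc
    ref = slices[0][1]
    orient = np.asarray([float(x) for x in ref.ImageOrientationPatient])
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise MetadataError(f"{path}: unsupported slice orientation {orient.tolist()}")
    pix = np.asarray([float(x) for x in ref.PixelSpacing])
    for f, ds in slices[1:]:
        if not np.allclose([float(x) for x in ds.ImageOrientationPatient], orient, atol=1e-6):
            raise MetadataError(f"{f}: slice orientation differs from the rest of the series")
        if not np.allclose([float(x) for x in ds.PixelSpacing], pix, rtol=1e-6):
            raise MetadataError(f"{f}: in-plane spacing differs from the rest of the series")
    order = np.argsort([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    slices = [slices[i] for i in order]
    zpos = np.asarray([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    dz = np.diff(zpos)
    dz_med = float(np.median(dz))
    if dz_med <= 0:
        raise MetadataError(f"{path}: non-increasing slice positions")
    bad = np.nonzero(np.abs(dz - dz_med) > 0.01 * dz_med)[0]
    if bad.size:
        f = slices[bad[0] + 1][0]
        raise MetadataError(
            f"{f}: slice spacing {dz[bad[0]]:.4g} mm deviates more than 1% "
            f"from the series median {dz_med:.4g} mm"
        )
    planes = []
    for _, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + inter)
    stack = np.stack(planes, axis=0)  # (z, row=y, col=x)
    voxels = np.ascontiguousarray(stack.transpose(2, 1, 0))
    spacing = (float(pix[1]), float(pix[0]), dz_med)
    first = slices[0][1]
    origin = tuple(float(x) for x in first.ImagePositionPatient)
    return Volume3D(voxels, spacing, origin)


# ---------------------------------------------------------------------------
# Radiograph I/O


def _infer_raster_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".png":
        return "png16"
    if suf in (".tif", ".tiff"):
        return "tiff"
    if suf == ".dcm":
        return "dicom_sc"
    raise MetadataError(f"cannot infer radiograph format from {path}")


def write_radiograph(r: Radiograph2D, path, format: str | None = None) -> None:
    """Write a radiograph as 16-bit PNG/TIFF (pixels rescaled to the full
    uint16 range; the original window and pitch are kept in metadata) or as a
    DICOM Secondary Capture object."""
    path = Path(path)
    fmt = format or _infer_raster_format(path)
    u16, vmin, vmax = _quantize_u16(r.pixels)
    meta = {
        "pitch_mm": r.pitch,
        "view": r.view,
        "magnification": r.magnification,
        "vmin": vmin,
        "vmax": vmax,
    }
    try:
        if fmt == "png16":
            info = PngInfo()
            info.add_text("shouldersim", json.dumps(meta))
            Image.fromarray(u16).save(path, pnginfo=info)
        elif fmt == "tiff":
            dpi = 25.4 / r.pitch
            tifffile.imwrite(
                path,
                u16,
                resolution=(dpi, dpi),
                resolutionunit="INCH",
                description=json.dumps(meta),
            )
        elif fmt == "dicom_sc":
            ds = _base_sc_dataset()
            ds.SeriesInstanceUID = generate_uid()
            ds.Rows, ds.Columns = u16.shape
            ds.PixelSpacing = [f"{r.pitch:.8g}", f"{r.pitch:.8g}"]
            slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
            ds.RescaleSlope = f"{slope:.9g}"
            ds.RescaleIntercept = f"{vmin:.9g}"
            ds.ImageComments = json.dumps(meta)
            ds.PixelData = np.ascontiguousarray(u16).tobytes()
            ds.save_as(path, enforce_file_format=True)
        else:
            raise MetadataError(f"unknown radiograph format {fmt!r}")
    except OSError as exc:
        raise MetadataError(f"cannot write {path}: {exc}") from exc


def read_radiograph(path, format: str | None = None) -> Radiograph2D:
    """Read a radiograph written by :func:`write_radiograph`, undoing the
    uint16 rescale using the stored window (exact up to one quantization
    step)."""
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"no such file: {path}")
    fmt = format or _infer_raster_format(path)
    if fmt == "png16":
        img = Image.open(path)
        u16 = np.asarray(img, dtype=np.float64)
        meta = json.loads(img.text.get("shouldersim", "{}")) if hasattr(img, "text") else {}
    elif fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            u16 = tf.asarray().astype(np.float64)
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    elif fmt == "dicom_sc":
        ds = pydicom.dcmread(str(path))
        u16 = ds.pixel_array.astype(np.float64)
        try:
            meta = json.loads(str(getattr(ds, "ImageComments", "{}")))
        except json.JSONDecodeError:
            meta = {}
        if not meta:
            meta = {"pitch_mm": float(ds.PixelSpacing[0])}
    else:
        raise MetadataError(f"unknown radiograph format {fmt!r}")
    vmin = float(meta.get("vmin", 0.0))
    vmax = float(meta.get("vmax", 65535.0))
    if vmax > vmin:
        pixels = u16 / 65535.0 * (vmax - vmin) + vmin
    else:
        pixels = np.full(u16.shape, vmin)
    if "pitch_mm" not in meta:
        warnings.warn(f"{path}: no pitch metadata found, assuming 1 mm")
    return Radiograph2D(
        pixels,
        pitch=float(meta.get("pitch_mm", 1.0)),
        view=str(meta.get("view", "custom")),
        magnification=float(meta.get("magnification", 1.0)),
    )
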