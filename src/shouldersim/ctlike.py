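"""MR-to-CT-like conversion: mask, invert, CLAHE, 15th power, remask.

On T1-weighted gradient-echo images cortical bone is dark and soft tissue
bright — the opposite of CT. The conversion chain turns such a volume into
a bone-bright, CT-like one in five steps:

1. segment the surrounding background into a binary body mask,
2. invert the intensities (after a percentile-clipped rescale to [0, 1],
   which makes the later power step scale-independent),
3. enhance contrast with contrast-limited adaptive histogram equalization,
4. raise the image to the 15th power, crushing everything but the
   brightest (now bone) voxels, and
5. multiply pointwise with the body mask so the background is exactly
   zero and cannot streak the forward projection.

The mask is computed on the *original* volume but applied after the power
step, so enhancement artifacts in air never reach the projector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters

from .errors import NormalizationError, ParameterError, SegmentationError, ShapeError
from .volume_io import Volume3D


@dataclass
class BinaryMask:
    """Boolean body mask on the same grid as its source volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ShapeError(f"mask must be 3D, got ndim={self.voxels.ndim}")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class CtlikeParams:
    """Tunable knobs of the conversion chain.

    ``power_exponent`` defaults to 15 — strong enough that only near-1
    (bone) intensities survive. ``norm_percentiles`` are the clip points
    of the pre-inversion rescale; (1, 99) ignores outlier voxels.
    ``clahe_tile`` is the tile count per in-plane axis and ``clahe_clip``
    the CLAHE clip limit. ``morph_radius`` (mm) sets the ball used to
    close the thresholded body mask.
    """

    mask_method: str = "otsu"
    mask_threshold: float = 0.1  # fraction of the intensity range, fixed method only
    morph_radius: float = 2.0
    clahe_tile: int = 8
    clahe_clip: float = 0.01
    clahe_3d: bool = False
    power_exponent: float = 15.0
    norm_percentiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self):
        if self.power_exponent <= 0:
            raise ParameterError(f"power_exponent must be positive, got {self.power_exponent}")
        lo, hi = self.norm_percentiles
        if not (0 <= lo < hi <= 100):
            raise ParameterError(f"need 0 <= low < high <= 100 percentiles, got {self.norm_percentiles}")
        if self.clahe_tile < 1:
            raise ParameterError(f"clahe_tile must be >= 1, got {self.clahe_tile}")
        if self.mask_method not in ("otsu", "fixed_threshold"):
            raise ParameterError(f"unknown mask_method {self.mask_method!r}")


def _ball(radius_mm: float, spacing) -> np.ndarray | None:
    """Boolean ellipsoidal structuring element of the given physical radius."""
    r_vox = np.asarray([radius_mm / s for s in spacing])
    if np.all(r_vox < 1):
        return None
    half = np.ceil(r_vox).astype(int)
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist = sum((g / max(r, 1e-9)) ** 2 for g, r in zip(grids, r_vox))
    return dist <= 1.0


def segment_background(v: Volume3D, p: CtlikeParams | None = None) -> BinaryMask:
    """Separate body (1) from surrounding air (0).

    Threshold (Otsu by default), morphological closing with a
    ``morph_radius`` mm ball, retention of the largest connected
    component, then hole filling — so dark bone interiors enclosed by
    bright soft tissue always end up inside the body mask regardless of
    which side of the threshold they fall on.
    """
    p = p or CtlikeParams()
    vox = v.voxels
    vmin, vmax = float(vox.min()), float(vox.max())
    if vmax <= vmin:
        raise SegmentationError("no foreground/background separation in a constant volume")
    if p.mask_method == "otsu":
        thr = filters.threshold_otsu(vox)
    else:
        thr = vmin + p.mask_threshold * (vmax - vmin)
    fg = vox > thr
    if not fg.any() or fg.all():
        raise SegmentationError("thresholding produced an empty foreground or background")
    ball = _ball(p.morph_radius, v.spacing)
    if ball is not None:
        fg = ndimage.binary_closing(fg, structure=ball)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component found")
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg, v.spacing)


def invert_intensities(v: Volume3D, norm_percentiles=(1.0, 99.0)) -> Volume3D:
    """Percentile-clipped rescale to [0, 1] followed by x -> 1 - x.

    The voxel at the high percentile maps to 0 and the low percentile to
    1, flipping the bone/soft-tissue ordering of the T1-GRE input.
    """
    lo, hi = np.percentile(v.voxels, norm_percentiles)
    if hi <= lo:
        raise NormalizationError(
            f"degenerate intensity window: percentiles {norm_percentiles} both map to {lo:g}"
        )
    x = np.clip((v.voxels - lo) / (hi - lo), 0.0, 1.0)
    return v.with_voxels(1.0 - x)


def _check_unit_range(vox: np.ndarray, op: str) -> None:
    if vox.min() < -1e-9 or vox.max() > 1 + 1e-9:
        raise ParameterError(f"{op} expects intensities in [0, 1]; run invert_intensities first")


def adaptive_equalize(v: Volume3D, p: CtlikeParams | None = None) -> Volume3D:
    """Contrast-limited adaptive histogram equalization on [0, 1] data.

    Applied per axial slice by default (the emulated acquisition is
    transverse), with ``clahe_tile`` tiles per in-plane axis; set
    ``clahe_3d`` for the volumetric variant. Constant inputs pass through
    unchanged.
    """
    p = p or CtlikeParams()
    vox = np.clip(v.voxels, 0.0, 1.0)
    _check_unit_range(v.voxels, "adaptive_equalize")
    if vox.max() <= vox.min():
        return v.with_voxels(vox)
    if p.clahe_3d:
        kernel = tuple(max(s // p.clahe_tile, 1) for s in vox.shape)
        out = exposure.equalize_adapthist(vox, kernel_size=kernel, clip_limit=p.clahe_clip)
    else:
        kernel = tuple(max(s // p.clahe_tile, 1) for s in vox.shape[:2])
        out = np.empty_like(vox)
        for k in range(vox.shape[2]):
            sl = vox[:, :, k]
            if sl.max() <= sl.min():
                out[:, :, k] = sl
            else:
                out[:, :, k] = exposure.equalize_adapthist(
                    sl, kernel_size=kernel, clip_limit=p.clahe_clip
                )
    return v.with_voxels(np.clip(out, 0.0, 1.0))


def power_contrast(v: Volume3D, exponent: float = 15.0) -> Volume3D:
    """Pointwise x -> x**exponent on [0, 1]; fixes 0 and 1, crushes the rest."""
    if exponent <= 0:
        raise ParameterError(f"exponent must be positive, got {exponent}")
    _check_unit_range(v.voxels, "power_contrast")
    return v.with_voxels(np.clip(v.voxels, 0.0, 1.0) ** exponent)


def apply_mask(v: Volume3D, m: BinaryMask) -> Volume3D:
    """Zero the background; foreground voxels pass through unchanged."""
    if m.shape != v.shape:
        raise ShapeError(f"mask shape {m.shape} != volume shape {v.shape}")
    return v.with_voxels(np.where(m.voxels, v.voxels, 0.0))


def ctlike_pipeline(v: Volume3D, p: CtlikeParams | None = None) -> tuple[Volume3D, BinaryMask]:
    """Full conversion chain; returns the CT-like volume and the mask used.

    Deterministic, output in [0, 1], background exactly zero.
    """
    p = p or CtlikeParams()
    mask = segment_background(v, p)
    out = invert_intensities(v, p.norm_percentiles)
    out = adaptive_equalize(out, p)
    out = power_contrast(out, p.power_exponent)
    out = apply_mask(out, mask)
    return out, mask
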