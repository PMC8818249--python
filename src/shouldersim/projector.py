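"""Cone-beam and parallel forward projection (simulated radiographs).

A point X-ray source and a flat detector produce diverging rays; each
detector pixel receives the line integral of the volume intensity along
the ray from the source through the pixel center. The integral is a plain
sum of trilinearly interpolated samples times the step length in mm — no
Beer-Lambert exponentiation — because the CT-like input volume is a
contrast surrogate rather than calibrated attenuation, and a plain
integral directly yields the bone-bright display convention of
conventional radiographs.

World frame is LPS (see :mod:`shouldersim.volume_io`). The beam axis for
the AP view runs anteriorly to posteriorly (+y); other views rotate the
source-detector pair about the superior-inferior axis (+z). On the
detector, columns run along +x rotated with the view (patient left in AP)
and rows run inferiorly, so the top row of the image is superior — the
standard radiograph orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ParameterError
from .volume_io import Radiograph2D, Volume3D


@dataclass
class ProjectionGeometry:
    """Cone-beam source/detector description.

    sid/sdd are the source-to-isocenter and source-to-detector distances in
    mm (magnification = sdd/sid); ``pitch`` is the detector pixel size in
    mm (``None`` = auto: the projected volume footprint fills ~80% of the
    detector); ``view_angle`` rotates the beam about the superior-inferior
    axis, 0 being the AP view; ``step_fraction`` is the ray-marching step
    as a fraction of the smallest voxel size.
    """

    sid: float = 1000.0
    sdd: float = 1150.0
    detector_shape: tuple[int, int] = (512, 512)
    pitch: float | None = None
    view: str = "AP"
    view_angle: float = 0.0
    step_fraction: float = 0.5

    def __post_init__(self):
        if not (0 < self.sid < self.sdd):
            raise GeometryError(f"need 0 < sid < sdd, got sid={self.sid}, sdd={self.sdd}")
        if self.pitch is not None and self.pitch <= 0:
            raise GeometryError(f"pitch must be positive, got {self.pitch}")
        if not (0 < self.step_fraction <= 1):
            raise GeometryError(f"step_fraction must be in (0, 1], got {self.step_fraction}")
        if any(n < 2 for n in self.detector_shape):
            raise GeometryError(f"detector needs >= 2 pixels per axis, got {self.detector_shape}")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sid


@dataclass
class Ray:
    """A world-space ray (origin in mm, unit direction)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise GeometryError("ray direction must be a unit vector")


def make_view(view: str, angle: float | None = None, **overrides) -> ProjectionGeometry:
    """Build a geometry for a named view.

    AP fixes the beam along the anterior-posterior axis (angle 0); Y is the
    oblique scapular view, default 45 degrees about the superior-inferior
    axis; ``custom`` requires an explicit angle in [-180, 180].
    """
    if view == "AP":
        ang = 0.0 if angle is None else float(angle)
        if ang != 0.0:
            raise ParameterError("AP view has a fixed angle of 0 degrees")
    elif view == "Y":
        ang = 45.0 if angle is None else float(angle)
    elif view == "custom":
        if angle is None:
            raise ParameterError("custom view requires an explicit angle")
        ang = float(angle)
    else:
        raise ParameterError(f"unknown view {view!r}")
    if not (-180.0 <= ang <= 180.0):
        raise ParameterError(f"view angle must be in [-180, 180], got {ang}")
    return ProjectionGeometry(view=view, view_angle=ang, **overrides)


def view_axes(view_angle: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam direction and detector (column, row) unit vectors for a rotation
    of ``view_angle`` degrees about the superior-inferior axis."""
    th = math.radians(view_angle)
    d = np.array([-math.sin(th), math.cos(th), 0.0])
    u = np.array([math.cos(th), math.sin(th), 0.0])  # detector columns
    v = np.array([0.0, 0.0, -1.0])  # detector rows: superior at the top
    return d, u, v


def _auto_pitch(v: Volume3D, g: ProjectionGeometry) -> float:
    lo, hi = v.world_bounds()
    extent = float(np.linalg.norm(hi - lo))  # diagonal: covers any view obliquity
    return extent * g.magnification / (0.8 * min(g.detector_shape))


def detector_pixel_positions(v: Volume3D, g: ProjectionGeometry) -> tuple[np.ndarray, np.ndarray, float]:
    """Source position and detector pixel-center world positions.

    Returns ``(source, pixels, pitch)`` with ``pixels`` of shape
    (rows, cols, 3). The isocenter is the volume center.
    """
    d, u, vax = view_axes(g.view_angle)
    c = v.world_center()
    pitch = g.pitch if g.pitch is not None else _auto_pitch(v, g)
    source = c - g.sid * d
    det_c = c + (g.sdd - g.sid) * d
    nr, nc = g.detector_shape
    rows = (np.arange(nr) - (nr - 1) / 2) * pitch
    cols = (np.arange(nc) - (nc - 1) / 2) * pitch
    pix = det_c + cols[None, :, None] * u + rows[:, None, None] * vax
    return source, pix, pitch


def _ray_box_range(origins, dirs, lo, hi):
    """Entry/exit parameters of rays against an axis-aligned box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - origins) / dirs
        t2 = (hi - origins) / dirs
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    zero = np.abs(dirs) < 1e-12
    if np.any(zero):
        inside = (origins >= lo) & (origins <= hi)
        tmin = np.where(zero, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(zero, np.where(inside, np.inf, -np.inf), tmax)
    return tmin.max(axis=-1), tmax.min(axis=-1)


def _march(v: Volume3D, origins: np.ndarray, dirs: np.ndarray, step: float) -> np.ndarray:
    """Line integrals of trilinearly interpolated intensity along rays.

    ``origins``/``dirs`` are (n, 3); each ray's in-box chord is split into
    equal steps no longer than ``step`` and integrated by the midpoint
    rule, so there is no end-of-ray truncation error. Samples outside the
    volume contribute zero.
    """
    lo, hi = v.world_bounds()
    t_in, t_out = _ray_box_range(origins, dirs, lo, hi)
    chord = np.maximum(t_out - t_in, 0.0)
    t_in = np.where(np.isfinite(t_in) & (chord > 0), t_in, 0.0)  # misses: 0-length march
    nsteps = np.maximum(np.ceil(chord / step).astype(np.int64), 1)
    nmax = int(nsteps.max())
    dt = chord / nsteps
    out = np.zeros(len(origins))
    origin = np.asarray(v.origin)
    spacing = np.asarray(v.spacing)
    idx = np.arange(nmax)
    # chunk rays to bound the (rays x samples x 3) scratch arrays
    chunk = max(1, int(4e6 // max(nmax, 1)))
    for a in range(0, len(origins), chunk):
        sl = slice(a, min(a + chunk, len(origins)))
        t = t_in[sl, None] + (idx[None, :] + 0.5) * dt[sl, None]
        valid = idx[None, :] < nsteps[sl, None]
        pos = origins[sl, None, :] + t[..., None] * dirs[sl, None, :]
        coords = ((pos - origin) / spacing).reshape(-1, 3).T
        vals = map_coordinates(v.voxels, coords, order=1, mode="constant", cval=0.0)
        out[sl] = (vals.reshape(t.shape) * valid).sum(axis=1) * dt[sl]
    return out


def forward_project(v: Volume3D, g: ProjectionGeometry) -> Radiograph2D:
    """Cone-beam simulated radiograph of a volume.

    Rays are cast from the point source through each detector pixel center
    and integrated with fixed-step midpoint sampling (step =
    ``step_fraction`` x smallest voxel). Deterministic; rays that miss the
    volume yield zero.
    """
    source, pix, pitch = detector_pixel_positions(v, g)
    nr, nc = pix.shape[:2]
    flat = pix.reshape(-1, 3)
    dirs = flat - source
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lo, hi = v.world_bounds()
    d_axis, u, vax = view_axes(g.view_angle)
    # warn when the volume's shadow falls partly off the detector
    corners = np.array([[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
    rel = corners - source
    depth = rel @ d_axis
    if np.any(depth <= 0):
        raise GeometryError("volume extends behind the X-ray source")
    scale = g.sdd / depth
    proj_u = (rel @ u) * scale
    proj_v = (rel @ vax) * scale
    half_u = (nc - 1) / 2 * pitch
    half_v = (nr - 1) / 2 * pitch
    if np.any(np.abs(proj_u) > half_u + pitch / 2) or np.any(np.abs(proj_v) > half_v + pitch / 2):
        warnings.warn("volume shadow exceeds the detector; returning a truncated projection")
    step = g.step_fraction * min(v.spacing)
    origins = np.broadcast_to(source, dirs.shape)
    pixels = _march(v, origins, dirs, step).reshape(nr, nc)
    label = g.view if g.view != "custom" else f"custom{g.view_angle:g}"
    return Radiograph2D(pixels, pitch=pitch, view=label, magnification=g.magnification)


_AXIS_NAMES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def parallel_project(v: Volume3D, axis_or_angle) -> Radiograph2D:
    """Orthographic line integrals (magnification 1).

    For an axis name/index the integral is an exact sum along that axis
    times its spacing: projecting along y (AP) yields an image with rows
    running superior to inferior and columns along +x; along x, columns run
    along +y; along z (axial), rows run along +y and columns along +x. A
    float argument instead ray-marches parallel rays rotated by that many
    degrees about the superior-inferior axis, on a detector matching the
    AP-view convention.
    """
    if isinstance(axis_or_angle, (int, str)) and axis_or_angle in _AXIS_NAMES:
        ax = _AXIS_NAMES[axis_or_angle]
        sums = v.voxels.sum(axis=ax) * v.spacing[ax]
        if ax == 0:  # remaining axes (y, z) -> rows from z (flipped), cols +y
            img = sums.T[::-1, :]
            inplane = (v.spacing[1], v.spacing[2])
        elif ax == 1:  # remaining (x, z) -> rows from z (flipped), cols +x
            img = sums.T[::-1, :]
            inplane = (v.spacing[0], v.spacing[2])
        else:  # axial: remaining (x, y) -> rows +y, cols +x
            img = sums.T
            inplane = (v.spacing[0], v.spacing[1])
        if abs(inplane[0] - inplane[1]) > 1e-9:
            raise GeometryError(
                f"axis projection needs equal in-plane spacing, got {inplane}"
            )
        return Radiograph2D(img.copy(), pitch=inplane[0], view=f"parallel-{ax}", magnification=1.0)

    angle = float(axis_or_angle)
    d, u, vax = view_axes(angle)
    c = v.world_center()
    lo, hi = v.world_bounds()
    extent = float(np.linalg.norm(hi - lo))
    pitch = min(v.spacing)
    n = int(np.ceil(extent / pitch)) + 2
    rows = (np.arange(n) - (n - 1) / 2) * pitch
    cols = (np.arange(n) - (n - 1) / 2) * pitch
    start = c - extent * d
    origins = (start + cols[None, :, None] * u + rows[:, None, None] * vax).reshape(-1, 3)
    dirs = np.broadcast_to(d, origins.shape)
    step = 0.5 * min(v.spacing)
    pixels = _march(v, origins, dirs, step).reshape(n, n)
    return Radiograph2D(pixels, pitch=pitch, view=f"parallel{angle:g}", magnification=1.0)


def window_output(r: Radiograph2D, mode: str = "minmax", bounds=None) -> Radiograph2D:
    """Linear display windowing of a radiograph onto [0, 1].

    ``minmax`` maps the image min/max (or explicit ``bounds``) to 0/1;
    ``percentile`` clips at the given percentile pair (default (1, 99)).
    A constant image has no window and maps to all zeros with a warning.
    """
    px = r.pixels
    if mode == "minmax":
        lo, hi = bounds if bounds is not None else (float(px.min()), float(px.max()))
    elif mode == "percentile":
        p = bounds if bounds is not None else (1.0, 99.0)
        if not (0 <= p[0] < p[1] <= 100):
            raise ParameterError(f"percentile bounds must satisfy 0 <= lo < hi <= 100, got {p}")
        lo, hi = (float(x) for x in np.percentile(px, p))
    else:
        raise ParameterError(f"unknown windowing mode {mode!r}")
    if hi <= lo:
        warnings.warn("constant radiograph has no display window; returning zeros")
        out = np.zeros_like(px)
    else:
        out = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return Radiograph2D(out, pitch=r.pitch, view=r.view, magnification=r.magnification)
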