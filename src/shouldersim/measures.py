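"""Shoulder morphometry from named landmarks, plus ordinal grading rules.

Two quantitative measurements drive rotator-cuff and osteoarthritis
work-up on shoulder projections:

* the acromiohumeral distance (AHD), the gap in mm between the inferior
  edge of the acromion and the superior surface of the humeral head, read
  on the scapular Y projection; and
* the critical shoulder angle (CSA), the angle between the glenoid rim
  line (superior to inferior rim) and the line from the inferior glenoid
  rim to the inferolateral edge of the acromion, read on a true AP
  projection.

Both are computed from explicitly placed landmarks in mm; the package never
detects landmarks automatically. Alongside these, the module validates the
ordinal codes used by readers: the Samilson-Prieto osteoarthritis grade
(driven by inferior humeral osteophyte size), the Bigliani acromion type
(flat / curved / hooked, a qualitative call that is recorded but never
computed), and 4-point Likert quality scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MeasurementError, ParameterError, ValidationError

AHD_LANDMARKS = ("acromion_inferior", "humeral_head_superior")
CSA_LANDMARKS = ("glenoid_superior", "glenoid_inferior", "acromion_inferolateral")


@dataclass
class LandmarkSet:
    """Named 2D or 3D points in mm, in the world frame of one image."""

    points: dict[str, np.ndarray]
    image_ref: str = ""

    def __post_init__(self):
        pts = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=np.float64)
            if arr.ndim != 1 or arr.size not in (2, 3):
                raise MeasurementError(f"landmark {name!r} must be a 2D or 3D point")
            if not np.all(np.isfinite(arr)):
                raise MeasurementError(f"landmark {name!r} has non-finite coordinates")
            pts[name] = arr
        self.points = pts

    def require(self, names) -> list[np.ndarray]:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MeasurementError(f"missing landmark(s): {', '.join(missing)}")
        return [self.points[n] for n in names]

    @classmethod
    def from_pixels(
        cls,
        pixel_points: dict,
        pitch: float,
        magnification: float = 1.0,
        correct_magnification: bool = False,
        image_ref: str = "",
    ) -> "LandmarkSet":
        """Convert pixel-click coordinates to mm using the detector pitch.

        Cone-beam projections magnify the object plane by sdd/sid; pass
        ``correct_magnification=True`` to report object-plane distances
        instead of detector-plane ones.
        """
        if pitch <= 0:
            raise ParameterError(f"pitch must be positive, got {pitch}")
        scale = pitch / (magnification if correct_magnification else 1.0)
        return cls(
            {n: np.asarray(p, dtype=np.float64) * scale for n, p in pixel_points.items()},
            image_ref=image_ref,
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        raw = json.loads(Path(path).read_text())
        image_ref = raw.pop("image_ref", "")
        units = raw.pop("units", "mm")
        if units != "mm":
            raise MeasurementError(f"landmark file must be in mm, got units={units!r}")
        return cls({k: v for k, v in raw.items()}, image_ref=image_ref)

    def to_json(self, path) -> None:
        out = {n: [float(x) for x in p] for n, p in self.points.items()}
        out["units"] = "mm"
        out["image_ref"] = self.image_ref
        Path(path).write_text(json.dumps(out, indent=2))


def measure_ahd(lm: LandmarkSet) -> float:
    """Acromiohumeral distance: Euclidean mm between the inferior acromion
    edge and the superior humeral head point."""
    a, h = lm.require(AHD_LANDMARKS)
    if a.size != h.size:
        raise MeasurementError("AHD landmarks have mixed dimensionality")
    return float(np.linalg.norm(a - h))


def measure_csa(lm: LandmarkSet) -> float:
    """Critical shoulder angle in degrees.

    The angle at the inferior glenoid rim between the glenoid line
    (inferior -> superior rim) and the line to the inferolateral acromion
    edge; returned in [0, 180).
    """
    gs, gi, ac = lm.require(CSA_LANDMARKS)
    u = gs - gi
    w = ac - gi
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu < 1e-12:
        raise MeasurementError("glenoid_superior and glenoid_inferior coincide")
    if nw < 1e-12:
        raise MeasurementError("acromion_inferolateral coincides with glenoid_inferior")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    return 0.0 if ang >= 180.0 else ang


def grade_samilson(osteophyte_mm: float) -> int:
    """Samilson-Prieto osteoarthritis grade from inferior humeral osteophyte
    size: 0 no osteophyte, I < 3 mm, II 3-6 mm, III >= 7 mm.

    The printed bands leave (6, 7) mm unassigned; sizes there are graded II
    (half-open [3, 7) band, keeping the rule total and monotone) and a
    warning flags the gap.
    """
    mm = float(osteophyte_mm)
    if not np.isfinite(mm) or mm < 0:
        raise ParameterError(f"osteophyte size must be a finite non-negative mm value, got {mm}")
    if mm == 0:
        return 0
    if mm < 3:
        return 1
    if mm < 7:
        if mm > 6:
            warnings.warn(
                f"osteophyte size {mm:g} mm falls in the unassigned 6-7 mm band; graded II"
            )
        return 2
    return 3


def validate_likert(code: int) -> int:
    """Validate a 4-point Likert quality/visibility code (1 best .. 4 worst)."""
    if code not in (1, 2, 3, 4):
        raise ValidationError(f"Likert code must be in 1..4, got {code!r}")
    return int(code)


def validate_bigliani(code: int) -> int:
    """Validate a Bigliani acromion type (1 flat, 2 curved, 3 hooked)."""
    if code not in (1, 2, 3):
        raise ValidationError(f"Bigliani type must be in 1..3, got {code!r}")
    return int(code)


@dataclass
class GradingRecord:
    """One reader's semi-quantitative calls for one shoulder."""

    samilson_grade: int = 0
    bigliani_type: int = 1
    likert_quality: int = 1
    osteophyte_mm: float | None = None

    def __post_init__(self):
        if self.samilson_grade not in (0, 1, 2, 3):
            raise ValidationError(f"Samilson grade must be in 0..3, got {self.samilson_grade!r}")
        validate_bigliani(self.bigliani_type)
        validate_likert(self.likert_quality)
        if self.osteophyte_mm is not None:
            implied = grade_samilson(self.osteophyte_mm)
            if implied != self.samilson_grade:
                raise ValidationError(
                    f"osteophyte size {self.osteophyte_mm:g} mm implies grade {implied}, "
                    f"record says {self.samilson_grade}"
                )
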