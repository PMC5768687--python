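"""Landmark detection and cross-microscope coordinate registration.

An orientation-asymmetric fiducial etched into every slide (50 x 50
um) anchors both instruments to the same physical origin. Each
microscope locates the landmark by normalized 2-D cross-correlation
against its stored template (all four right-angle rotations are
tried; the winner gives the slide orientation) with sub-pixel
refinement by a quadratic fit around the correlation peak.

With the landmark offsets recorded in both instruments, a point
(x1, y1) in source-microscope coordinates maps to target coordinates
via the fixed relation

    x2 = y1 - y_off1 + x_off2
    y2 = x1 - x_off1 + y_off2

i.e. an axis swap between the two stage conventions followed by a
translation — an isometry, so registered cutting contours keep their
shape and area exactly. Rotational misalignment is out of scope: if
the two instruments detect different landmark orientations,
registration refuses rather than silently correcting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import match_template

from .targeting import CuttingContour

__all__ = [
    "LandmarkDetection",
    "MicroscopeFrame",
    "RegisteredPoint",
    "detect_landmark",
    "frame_from_detection",
    "register_point",
    "register_contour",
]

DEFAULT_NCC_THRESHOLD = 0.6


@dataclass(frozen=True)
class LandmarkDetection:
    """Landmark position in the detecting microscope's physical frame."""

    x_um: float
    y_um: float
    rotation_deg: int
    peak: float
    accepted: bool


@dataclass(frozen=True)
class MicroscopeFrame:
    """Origin offsets anchoring one microscope to the etched landmark."""

    microscope_id: str
    x_off_um: float
    y_off_um: float
    rotation_deg: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_off_um) and np.isfinite(self.y_off_um)):
            raise ValueError("frame offsets must be finite")


@dataclass(frozen=True)
class RegisteredPoint:
    x_um: float
    y_um: float
    source_point: tuple[float, float]
    source_frame: str
    target_frame: str


def _subpixel_peak(corr: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic (parabolic) refinement of an integer correlation peak."""
    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2 * v0 + vp
        if abs(denom) < 1e-12:
            return 0.0
        delta = 0.5 * (vm - vp) / denom
        return float(np.clip(delta, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < corr.shape[0] - 1:
        dy = refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx = refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return ix + dx, iy + dy


def detect_landmark(
    image: np.ndarray,
    template: np.ndarray,
    pixel_size_um: float,
    threshold: float = DEFAULT_NCC_THRESHOLD,
    origin_offset_um: tuple[float, float] = (0.0, 0.0),
) -> LandmarkDetection:
    """Locate the fiducial by normalized cross-correlation.

    The template is matched at rotations 0/90/180/270 degrees; the
    rotation with the highest correlation peak wins. The returned
    position is the landmark *center* in physical um. If the best
    peak is below ``threshold`` the detection is returned with
    ``accepted=False`` (landmark not found).
    """
    image = np.asarray(image, dtype=float)
    template = np.asarray(template, dtype=float)
    if template.shape[0] >= image.shape[0] or template.shape[1] >= image.shape[1]:
        raise ValueError("template must be smaller than the image")
    best = None
    for k in range(4):
        rot = np.ascontiguousarray(np.rot90(template, k=-k))
        corr = match_template(image, rot, pad_input=False)
        iy, ix = np.unravel_index(int(np.argmax(corr)), corr.shape)
        peak = float(corr[iy, ix])
        if best is None or peak > best[0]:
            px, py = _subpixel_peak(corr, iy, ix)
            cx = px + rot.shape[1] / 2.0 - 0.5
            cy = py + rot.shape[0] / 2.0 - 0.5
            best = (peak, k * 90, cx, cy)
    peak, rot_deg, cx, cy = best
    ox, oy = origin_offset_um
    return LandmarkDetection(
        x_um=ox + cx * pixel_size_um,
        y_um=oy + cy * pixel_size_um,
        rotation_deg=rot_deg,
        peak=peak,
        accepted=peak >= threshold,
    )


def frame_from_detection(
    microscope_id: str, detection: LandmarkDetection
) -> MicroscopeFrame:
    if not detection.accepted:
        raise ValueError("cannot build a frame from a rejected detection")
    return MicroscopeFrame(
        microscope_id=microscope_id,
        x_off_um=detection.x_um,
        y_off_um=detection.y_um,
        rotation_deg=detection.rotation_deg,
    )


def register_point(
    p: tuple[float, float],
    source: MicroscopeFrame,
    target: MicroscopeFrame,
    swap_axes: bool = True,
) -> RegisteredPoint:
    """Map a source-microscope point into target-microscope coordinates.

    Implements x2 = y1 - y_off1 + x_off2, y2 = x1 - x_off1 + y_off2
    (the stage conventions of the two instruments differ by an axis
    swap). Instruments that share conventions can set
    ``swap_axes=False`` for the plain translation
    x2 = x1 - x_off1 + x_off2, y2 = y1 - y_off1 + y_off2.

    The inverse map is ``register_point(q, target, source)`` with the
    same ``swap_axes``.
    """
    if source.rotation_deg != target.rotation_deg:
        raise ValueError(
            "landmark orientations disagree between microscopes "
            f"({source.rotation_deg} vs {target.rotation_deg} deg); "
            "rotational correction is out of scope — re-mount the slide"
        )
    x1, y1 = p
    if swap_axes:
        x2 = y1 - source.y_off_um + target.x_off_um
        y2 = x1 - source.x_off_um + target.y_off_um
    else:
        x2 = x1 - source.x_off_um + target.x_off_um
        y2 = y1 - source.y_off_um + target.y_off_um
    return RegisteredPoint(
        x_um=x2, y_um=y2, source_point=(x1, y1),
        source_frame=source.microscope_id, target_frame=target.microscope_id,
    )


def register_contour(
    contour: CuttingContour,
    source: MicroscopeFrame,
    target: MicroscopeFrame,
    swap_axes: bool = True,
) -> CuttingContour:
    """Apply the coordinate relation vertex-wise to a cutting contour.

    The map is an isometry (axis swap + translation), so polygon
    simplicity, vertex order and area are preserved exactly.
    """
    verts = np.asarray(contour.vertices_um, dtype=float)
    out = np.empty_like(verts)
    if swap_axes:
        # vectorized form of register_point over all vertices
        if source.rotation_deg != target.rotation_deg:
            register_point((0.0, 0.0), source, target)  # raises
        out[:, 0] = verts[:, 1] - source.y_off_um + target.x_off_um
        out[:, 1] = verts[:, 0] - source.x_off_um + target.y_off_um
    else:
        out[:, 0] = verts[:, 0] - source.x_off_um + target.x_off_um
        out[:, 1] = verts[:, 1] - source.y_off_um + target.y_off_um
    return CuttingContour(
        nucleus_label=contour.nucleus_label,
        slide_id=contour.slide_id,
        vertices_um=out,
        ring_um=contour.ring_um,
        clipped=contour.clipped,
        collides=contour.collides,
        frame_id=target.microscope_id,
    )


def write_manifest(
    path: str | Path,
    detections: dict[str, LandmarkDetection],
    frames: dict[str, MicroscopeFrame],
) -> None:
    """Persist per-slide registration state as a JSON manifest."""
    doc = {
        "detections": {
            k: {"x_um": d.x_um, "y_um": d.y_um, "rotation_deg": d.rotation_deg,
                "peak": d.peak, "accepted": d.accepted}
            for k, d in detections.items()
        },
        "frames": {
            k: {"microscope_id": f.microscope_id, "x_off_um": f.x_off_um,
                "y_off_um": f.y_off_um, "rotation_deg": f.rotation_deg}
            for k, f in frames.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))
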