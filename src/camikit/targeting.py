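"""Laser cutting-contour geometry.

Each selected nucleus receives a cutting contour: a polygon
approximation of a ring offset 3 um outward from the nucleus
boundary. The stand-off keeps the UV laser from ablating nuclear
material while minimising co-captured extracellular matter. Offsetting
is done in physical units (um) so anisotropic pixel calibrations stay
correct, and the offset polygon is simplified to a bounded vertex
count without letting any vertex fall closer to the nucleus than the
ring distance minus a small tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .segmentation import NucleusSegment

__all__ = ["CuttingContour", "make_cutting_contour", "check_collisions"]

DEFAULT_RING_UM = 3.0       # stand-off between nucleus boundary and laser path
OFFSET_TOLERANCE_UM = 0.2   # max inward error allowed by simplification
DEFAULT_MAX_VERTICES = 64


@dataclass
class CuttingContour:
    nucleus_label: int
    slide_id: str
    vertices_um: np.ndarray  # (n, 2) closed ring, source-microscope um
    ring_um: float
    clipped: bool = False
    collides: bool = False
    frame_id: str | None = None  # set once registered to a target frame

    @property
    def vertex_count(self) -> int:
        return len(self.vertices_um) - 1  # closing vertex not counted

    def polygon(self) -> Polygon:
        return Polygon(self.vertices_um)


def _segment_polygon_um(
    segment: NucleusSegment, pixel_size_um: float,
    origin_offset_um: tuple[float, float] = (0.0, 0.0),
) -> Polygon:
    ox, oy = origin_offset_um
    verts = segment.polygon * pixel_size_um + np.array([ox, oy])
    poly = Polygon(verts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def make_cutting_contour(
    segment: NucleusSegment,
    pixel_size_um: float,
    ring_um: float = DEFAULT_RING_UM,
    max_vertices: int = DEFAULT_MAX_VERTICES,
    origin_offset_um: tuple[float, float] = (0.0, 0.0),
    image_bounds_um: tuple[float, float, float, float] | None = None,
    slide_id: str = "slide",
) -> CuttingContour:
    """Offset the nucleus polygon outward by ``ring_um`` and simplify.

    The offset is a true morphological dilation (shapely round-joined
    buffer with fine quadrant resolution), then Douglas-Peucker
    simplification with the largest tolerance that keeps the vertex
    count within ``max_vertices`` and the nucleus-to-contour clearance
    within OFFSET_TOLERANCE_UM of the requested ring. If the contour
    leaves ``image_bounds_um`` (x0, y0, x1, y1) it is flagged clipped
    but still returned — the caller decides whether to exclude it.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if ring_um < 0:
        raise ValueError("ring_um must be >= 0")
    nucleus = _segment_polygon_um(segment, pixel_size_um, origin_offset_um)
    if ring_um == 0:
        ring = nucleus
    else:
        ring = nucleus.buffer(ring_um, quad_segs=32, join_style="round")

    contour = ring
    if contour.exterior is None:
        raise ValueError("degenerate nucleus polygon")
    # simplify under both constraints: vertex budget and clearance
    best = np.asarray(contour.exterior.coords)
    if len(best) - 1 > max_vertices:
        tol = OFFSET_TOLERANCE_UM / 4
        while tol <= 4 * OFFSET_TOLERANCE_UM:
            cand = contour.simplify(tol, preserve_topology=True)
            coords = np.asarray(cand.exterior.coords)
            contains_ok = ring_um == 0 or cand.contains(nucleus)
            clearance_ok = (
                ring_um == 0
                or cand.exterior.distance(nucleus.exterior)
                >= ring_um - OFFSET_TOLERANCE_UM
            )
            if contains_ok and clearance_ok:
                best = coords
                if len(coords) - 1 <= max_vertices:
                    break
            tol *= 1.5
    verts = best
    clipped = False
    if image_bounds_um is not None:
        x0, y0, x1, y1 = image_bounds_um
        xs, ys = verts[:, 0], verts[:, 1]
        clipped = bool(
            (xs < x0).any() or (ys < y0).any() or (xs > x1).any() or (ys > y1).any()
        )
    return CuttingContour(
        nucleus_label=segment.label,
        slide_id=slide_id,
        vertices_um=verts,
        ring_um=ring_um,
        clipped=clipped,
    )


def check_collisions(
    contours: list[CuttingContour],
    segments: list[NucleusSegment],
    pixel_size_um: float,
    origin_offset_um: tuple[float, float] = (0.0, 0.0),
) -> list[CuttingContour]:
    """Flag contours that intersect another nucleus or another contour.

    A cut that crosses a neighbouring nucleus would contaminate the
    capture, and two overlapping cutting paths cannot both be executed;
    both situations set ``collides``. Flagging is symmetric. Contours
    are modified in place and returned.
    """
    polys = [c.polygon() for c in contours]
    seg_polys = {
        s.label: _segment_polygon_um(s, pixel_size_um, origin_offset_um)
        for s in segments
    }
    for idx, c in enumerate(contours):
        p = polys[idx]
        for other_idx, other in enumerate(contours):
            if other_idx != idx and p.intersects(polys[other_idx]):
                c.collides = True
                other.collides = True
        for label, sp in seg_polys.items():
            if label == c.nucleus_label:
                continue
            if p.intersects(sp):
                c.collides = True
    return contours
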