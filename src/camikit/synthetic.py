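"""Ground-truthed synthetic slide generator.

Emulates the imaging conditions of a computer-assisted microscopy
isolation (CAMI) screen: a dark slide carrying one etched, orientation
-asymmetric fiducial landmark (50 x 50 um), a few hundred roughly
elliptical Hoechst-like nuclei (a configurable fraction placed as
touching/overlapping pairs), a marker channel whose intensity and
texture depend on the planted phenotype class ("foci" = punctate spots
inside the nucleus, "homogeneous" = uniform signal, "negative" =
background only), a smooth multiplicative illumination gain field and
additive Gaussian noise.

Every planted quantity is recorded in a :class:`GroundTruth` so each
downstream stage (illumination correction, segmentation, feature
extraction, classification, landmark registration) can be tested
against a known answer without any instrument data.

Coordinate convention (global for the package): pixel (0, 0) is the
center of the top-left pixel; x grows rightward (columns), y grows
downward (rows); physical position [um] = origin_offset + pixel *
pixel_size_um.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MarkerProfile",
    "ClassSpec",
    "SlideSpec",
    "NucleusRecord",
    "GroundTruth",
    "Slide",
    "landmark_template",
    "generate_slide",
    "render_transposed_view",
    "write_slide",
    "read_slide",
]

_PLACEMENT_RETRY_FACTOR = 2000  # attempts per nucleus before "overcrowded"


class OvercrowdedSpecError(ValueError):
    """Raised when nuclei cannot be placed within the retry bound."""


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """One phenotype class: its name, mixture proportion and marker look.

    marker_profile is one of "foci", "homogeneous", "negative".
    """

    name: str
    proportion: float
    marker_profile: str

    def __post_init__(self) -> None:
        if self.marker_profile not in ("foci", "homogeneous", "negative"):
            raise ValueError(f"unknown marker profile {self.marker_profile!r}")


def _default_class_mix() -> tuple[ClassSpec, ...]:
    return (
        ClassSpec("foci", 0.5, "foci"),
        ClassSpec("homogeneous", 0.5, "homogeneous"),
    )


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide.

    Defaults describe the canonical test slide: 1024 x 1024 px at
    0.65 um/px (~666 x 666 um field), 200 nuclei with 20% of them in
    touching pairs, two phenotype classes split 50/50, a smooth
    multiplicative gain field of +-30% relative amplitude and additive
    Gaussian noise.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.65
    n_nuclei: int = 200
    overlap_fraction: float = 0.2
    class_mix: tuple[ClassSpec, ...] = field(default_factory=_default_class_mix)
    illumination_strength: float = 0.3
    noise_sd: float = 8.0
    landmark_position_um: tuple[float, float] = (80.0, 80.0)
    landmark_size_um: float = 50.0  # etched 50 x 50 um fiducial
    landmark_rotation_deg: int = 0
    rng_seed: int = 0
    # imaging model scalars
    background_level: float = 100.0
    nuclear_amplitude: float = 600.0
    marker_amplitude: float = 500.0
    # nucleus geometry (um)
    semi_minor_um: tuple[float, float] = (3.2, 4.6)
    aspect_range: tuple[float, float] = (1.0, 1.5)
    # optional explicit gain polynomial {(i, j): coeff} over (x/W, y/H);
    # None -> default smooth tilted-bowl field scaled by illumination_strength
    gain_poly: dict | None = None
    origin_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.illumination_strength < 0:
            raise ValueError("noise_sd and illumination_strength must be >= 0")
        if self.landmark_size_um <= 0:
            raise ValueError("landmark_size_um must be positive")
        if self.landmark_rotation_deg % 90 != 0:
            raise ValueError("landmark rotation must be a right angle")
        total = sum(c.proportion for c in self.class_mix)
        if self.class_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        lx, ly = self.landmark_position_um
        half = self.landmark_size_um / 2
        w_um = self.width_px * self.pixel_size_um
        h_um = self.height_px * self.pixel_size_um
        if not (half <= lx <= w_um - half and half <= ly <= h_um - half):
            raise ValueError("landmark does not fit inside the image")


@dataclass
class NucleusRecord:
    """Ground truth of one planted nucleus (pixel coordinates)."""

    nucleus_id: int
    cx: float
    cy: float
    semi_major_px: float
    semi_minor_px: float
    orientation_rad: float
    class_name: str
    partner_id: int | None = None  # overlap partner, None for singles


@dataclass
class GroundTruth:
    nuclei: list[NucleusRecord]
    landmark_position_um: tuple[float, float]
    landmark_rotation_deg: int
    gain_field: np.ndarray
    spec: SlideSpec

    def nuclei_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(n) for n in self.nuclei]
        df = pd.DataFrame(
            rows,
            columns=[
                "nucleus_id", "cx", "cy", "semi_major_px", "semi_minor_px",
                "orientation_rad", "class_name", "partner_id",
            ],
        )
        return df

    def nucleus_mask(self, record: NucleusRecord, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the planted ellipse (taper midpoint boundary)."""
        return _ellipse_support(record, shape) >= 1.0


@dataclass
class Slide:
    """One imaged slide: per-channel intensity grids plus calibration."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    origin_offset_um: tuple[float, float]
    slide_id: str = "slide"

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def pixel_to_um(self, x_px: float, y_px: float) -> tuple[float, float]:
        ox, oy = self.origin_offset_um
        return ox + x_px * self.pixel_size_um, oy + y_px * self.pixel_size_um

    def um_to_pixel(self, x_um: float, y_um: float) -> tuple[float, float]:
        ox, oy = self.origin_offset_um
        return (x_um - ox) / self.pixel_size_um, (y_um - oy) / self.pixel_size_um


# ---------------------------------------------------------------------------
# Landmark glyph
# ---------------------------------------------------------------------------

def landmark_template(size_px: int, rotation_deg: int = 0) -> np.ndarray:
    """Render the etched fiducial as a float image in [0, 1].

    The glyph is an asymmetric "L": a full-height vertical bar, a
    shorter and thinner horizontal foot, and a detached square dot in
    the upper-right quadrant. No two right-angle rotations of it are
    alike, so the rotation that maximises normalized cross-correlation
    identifies the slide orientation unambiguously.
    """
    if size_px < 8:
        raise ValueError("template too small to draw the glyph")
    n = size_px
    u = (np.arange(n) + 0.5) / n
    x, y = np.meshgrid(u, u)  # x cols, y rows (y grows downward)
    glyph = np.zeros((n, n), dtype=float)
    glyph[(x < 0.28)] = 1.0                                   # vertical bar
    glyph[(y > 0.82) & (x < 0.72)] = 1.0                      # shorter foot
    glyph[(x > 0.62) & (x < 0.86) & (y > 0.10) & (y < 0.34)] = 1.0  # dot
    k = (rotation_deg // 90) % 4
    return np.rot90(glyph, k=-k)  # negative: clockwise rotation in image coords


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

_EDGE_TAPER = 0.10  # Gaussian boundary taper width, fraction of radius


def _ellipse_support(rec: NucleusRecord, shape: tuple[int, int]) -> np.ndarray:
    """Normalized inverse elliptical radius: 1 at boundary, >1 inside.

    Returned array r_norm satisfies r_norm >= 1 inside the planted
    ellipse; intensity profile and binary ground-truth mask both derive
    from it so they agree by construction.
    """
    h, w = shape
    pad = int(math.ceil(rec.semi_major_px * 1.6)) + 3
    x0, x1 = int(rec.cx) - pad, int(rec.cx) + pad + 1
    y0, y1 = int(rec.cy) - pad, int(rec.cy) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    out = np.zeros(shape, dtype=float)
    if x0c >= x1c or y0c >= y1c:
        return out
    xs = np.arange(x0c, x1c) - rec.cx
    ys = np.arange(y0c, y1c) - rec.cy
    X, Y = np.meshgrid(xs, ys)
    c, s = math.cos(rec.orientation_rad), math.sin(rec.orientation_rad)
    xr = c * X + s * Y
    yr = -s * X + c * Y
    r = np.sqrt((xr / rec.semi_major_px) ** 2 + (yr / rec.semi_minor_px) ** 2)
    with np.errstate(divide="ignore"):
        out[y0c:y1c, x0c:x1c] = np.where(r > 0, 1.0 / np.maximum(r, 1e-9), np.inf)
    return out


def _nucleus_profile(rec: NucleusRecord, shape: tuple[int, int]) -> np.ndarray:
    """Smooth-edged ellipse: 1 inside, Gaussian taper outside the boundary."""
    inv_r = _ellipse_support(rec, shape)
    with np.errstate(divide="ignore"):
        r = np.where(inv_r > 0, 1.0 / np.maximum(inv_r, 1e-9), np.inf)
    excess = np.clip(r - 1.0, 0.0, None)
    prof = np.exp(-(excess ** 2) / (2 * _EDGE_TAPER ** 2))
    prof[inv_r == 0] = 0.0
    return prof


def _default_gain(spec: SlideSpec) -> np.ndarray:
    """Smooth tilted-bowl multiplicative field with relative amplitude s."""
    u = (np.arange(spec.width_px) + 0.5) / spec.width_px
    v = (np.arange(spec.height_px) + 0.5) / spec.height_px
    X, Y = np.meshgrid(u, v)
    s = spec.illumination_strength
    f = 0.55 * (X - 0.5) + 0.30 * (Y - 0.5) - 0.8 * ((X - 0.5) ** 2 + (Y - 0.5) ** 2)
    f = f / max(np.abs(f).max(), 1e-12)
    return 1.0 + s * f


def _poly_gain(spec: SlideSpec) -> np.ndarray:
    u = (np.arange(spec.width_px) + 0.5) / spec.width_px
    v = (np.arange(spec.height_px) + 0.5) / spec.height_px
    X, Y = np.meshgrid(u, v)
    g = np.zeros_like(X)
    for (i, j), c in spec.gain_poly.items():
        g += c * (X ** int(i)) * (Y ** int(j))
    return g


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _sample_geometry(rng: np.random.Generator, spec: SlideSpec) -> tuple[float, float, float]:
    b_um = rng.uniform(*spec.semi_minor_um)
    aspect = rng.uniform(*spec.aspect_range)
    a = (b_um * aspect) / spec.pixel_size_um
    b = b_um / spec.pixel_size_um
    theta = rng.uniform(0, math.pi)
    return a, b, theta


def _landmark_bbox_px(spec: SlideSpec) -> tuple[float, float, float, float]:
    lx = (spec.landmark_position_um[0] - spec.origin_offset_um[0]) / spec.pixel_size_um
    ly = (spec.landmark_position_um[1] - spec.origin_offset_um[1]) / spec.pixel_size_um
    half = spec.landmark_size_um / 2 / spec.pixel_size_um
    return lx - half, lx + half, ly - half, ly + half


def _place_nuclei(rng: np.random.Generator, spec: SlideSpec) -> list[NucleusRecord]:
    n = spec.n_nuclei
    n_pairs = int(round(n * spec.overlap_fraction / 2))
    n_singles = n - 2 * n_pairs

    lx0, lx1, ly0, ly1 = _landmark_bbox_px(spec)
    margin = (spec.semi_minor_um[1] * spec.aspect_range[1]) / spec.pixel_size_um + 3
    placed: list[NucleusRecord] = []
    max_attempts = _PLACEMENT_RETRY_FACTOR * max(n, 1)
    attempts = 0
    sep_factor = 2.4  # min center distance between unrelated nuclei, x mean radius

    def clear_of_landmark(cx: float, cy: float, rad: float) -> bool:
        return not (lx0 - rad < cx < lx1 + rad and ly0 - rad < cy < ly1 + rad)

    def far_from_all(cx: float, cy: float, rad: float, skip: set[int]) -> bool:
        for q in placed:
            if q.nucleus_id in skip:
                continue
            d = math.hypot(cx - q.cx, cy - q.cy)
            if d < sep_factor / 2 * (rad + max(q.semi_major_px, q.semi_minor_px)):
                return False
        return True

    next_id = 0

    def try_place_single() -> NucleusRecord | None:
        nonlocal next_id, attempts
        a, b, theta = _sample_geometry(rng, spec)
        cx = rng.uniform(margin, spec.width_px - margin)
        cy = rng.uniform(margin, spec.height_px - margin)
        attempts += 1
        if clear_of_landmark(cx, cy, a) and far_from_all(cx, cy, a, set()):
            rec = NucleusRecord(next_id, cx, cy, a, b, theta, "")
            next_id += 1
            return rec
        return None

    # overlapping pairs first: center distance in [0.8, 1.2] x (b1 + b2)
    for _ in range(n_pairs):
        while True:
            if attempts > max_attempts:
                raise OvercrowdedSpecError(
                    f"could not place {n} nuclei in {spec.width_px}x{spec.height_px}"
                )
            first = try_place_single()
            if first is None:
                continue
            a2, b2, th2 = _sample_geometry(rng, spec)
            d = rng.uniform(0.8, 1.2) * (first.semi_minor_px + b2)
            ang = rng.uniform(0, 2 * math.pi)
            cx2 = first.cx + d * math.cos(ang)
            cy2 = first.cy + d * math.sin(ang)
            attempts += 1
            inside = margin < cx2 < spec.width_px - margin and margin < cy2 < spec.height_px - margin
            if inside and clear_of_landmark(cx2, cy2, a2) and far_from_all(
                cx2, cy2, a2, {first.nucleus_id}
            ):
                second = NucleusRecord(next_id, cx2, cy2, a2, b2, th2, "")
                next_id += 1
                first.partner_id = second.nucleus_id
                second.partner_id = first.nucleus_id
                placed.append(first)
                placed.append(second)
                break
            next_id -= 1  # roll back the orphaned first nucleus id

    for _ in range(n_singles):
        while True:
            if attempts > max_attempts:
                raise OvercrowdedSpecError(
                    f"could not place {n} nuclei in {spec.width_px}x{spec.height_px}"
                )
            rec = try_place_single()
            if rec is not None:
                placed.append(rec)
                break

    # class assignment: deterministic proportional counts, then shuffle
    labels: list[str] = []
    counts = [int(round(c.proportion * n)) for c in spec.class_mix]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n and counts:
        counts[int(np.argmin(counts))] += 1
    for cspec, k in zip(spec.class_mix, counts):
        labels.extend([cspec.name] * k)
    order = rng.permutation(n)
    for rec, idx in zip(placed, order):
        rec.class_name = labels[idx] if labels else ""
    return placed


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_slide(spec: SlideSpec) -> tuple[Slide, GroundTruth]:
    """Render a slide from its spec; deterministic for a fixed rng_seed.

    Returns the nuclear and marker channels as float arrays
    (counts; quantized only on write) together with the full ground
    truth. image = clean_signal x gain_field + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = (spec.height_px, spec.width_px)
    profiles = {c.name: c.marker_profile for c in spec.class_mix}

    nuclei = _place_nuclei(rng, spec)

    nuclear = np.full(shape, spec.background_level, dtype=float)
    marker = np.full(shape, spec.background_level, dtype=float)

    for rec in nuclei:
        prof = _nucleus_profile(rec, shape)
        amp = spec.nuclear_amplitude * rng.uniform(0.85, 1.15)
        np.maximum(nuclear, spec.background_level + amp * prof, out=nuclear)
        mprofile = profiles.get(rec.class_name, "negative")
        if mprofile == "homogeneous":
            mamp = spec.marker_amplitude * rng.uniform(0.85, 1.15)
            np.maximum(marker, spec.background_level + mamp * prof, out=marker)
        elif mprofile == "foci":
            base = 0.18 * spec.marker_amplitude
            np.maximum(marker, spec.background_level + base * prof, out=marker)
            n_foci = int(rng.integers(5, 11))
            sigma = 1.6
            for _ in range(n_foci):
                rr = math.sqrt(rng.uniform()) * 0.75
                ang = rng.uniform(0, 2 * math.pi)
                c, s = math.cos(rec.orientation_rad), math.sin(rec.orientation_rad)
                dx = rr * math.cos(ang) * rec.semi_major_px
                dy = rr * math.sin(ang) * rec.semi_minor_px
                fx = rec.cx + c * dx - s * dy
                fy = rec.cy + s * dx + c * dy
                famp = spec.marker_amplitude * rng.uniform(0.9, 1.4)
                x0 = max(int(fx) - 6, 0)
                x1 = min(int(fx) + 7, spec.width_px)
                y0 = max(int(fy) - 6, 0)
                y1 = min(int(fy) + 7, spec.height_px)
                if x0 >= x1 or y0 >= y1:
                    continue
                X, Y = np.meshgrid(np.arange(x0, x1) - fx, np.arange(y0, y1) - fy)
                spot = famp * np.exp(-(X ** 2 + Y ** 2) / (2 * sigma ** 2))
                marker[y0:y1, x0:x1] += spot * prof[y0:y1, x0:x1]

    # etched landmark: bright glyph in the nuclear channel; the glyph is
    # rasterised at an integer pixel corner, so the ground truth records
    # the *rendered* center (what is physically on the slide)
    size_px = max(int(round(spec.landmark_size_um / spec.pixel_size_um)), 8)
    glyph = landmark_template(size_px, spec.landmark_rotation_deg)
    lx0, _, ly0, _ = _landmark_bbox_px(spec)
    gx, gy = int(round(lx0)), int(round(ly0))
    amp = spec.nuclear_amplitude * 1.2
    nuclear[gy:gy + size_px, gx:gx + size_px] = np.maximum(
        nuclear[gy:gy + size_px, gx:gx + size_px],
        spec.background_level + amp * glyph,
    )
    ox, oy = spec.origin_offset_um
    rendered_landmark_um = (
        ox + (gx + (size_px - 1) / 2.0) * spec.pixel_size_um,
        oy + (gy + (size_px - 1) / 2.0) * spec.pixel_size_um,
    )

    gain = _poly_gain(spec) if spec.gain_poly is not None else (
        _default_gain(spec) if spec.illumination_strength > 0 else np.ones(shape)
    )

    nuclear = nuclear * gain
    marker = marker * gain
    if spec.noise_sd > 0:
        nuclear = nuclear + rng.normal(0, spec.noise_sd, shape)
        marker = marker + rng.normal(0, spec.noise_sd, shape)
    nuclear = np.clip(nuclear, 0, None)
    marker = np.clip(marker, 0, None)

    slide = Slide(
        channels={"nuclear": nuclear, "marker": marker},
        pixel_size_um=spec.pixel_size_um,
        origin_offset_um=spec.origin_offset_um,
        slide_id=f"synthetic-{spec.rng_seed}",
    )
    gt = GroundTruth(
        nuclei=nuclei,
        landmark_position_um=rendered_landmark_um,
        landmark_rotation_deg=spec.landmark_rotation_deg,
        gain_field=gain,
        spec=spec,
    )
    return slide, gt


def render_transposed_view(
    slide: Slide, gt: GroundTruth, origin_offset_um: tuple[float, float]
) -> tuple[Slide, dict]:
    """Re-render the same physical slide as seen by a second microscope.

    The target instrument views the slide with its x/y axes exchanged
    relative to the source (the coordinate relation between the two
    microscopes swaps axes), so the view is the transposed image with
    an independent stage origin. Returns the new slide plus the
    landmark position and per-nucleus centers in target physical
    coordinates.
    """
    channels = {k: np.ascontiguousarray(v.T) for k, v in slide.channels.items()}
    tgt = Slide(
        channels=channels,
        pixel_size_um=slide.pixel_size_um,
        origin_offset_um=origin_offset_um,
        slide_id=slide.slide_id + "-target",
    )
    # source pixel (px, py) -> target pixel (py, px)
    lx_px, ly_px = slide.um_to_pixel(*gt.landmark_position_um)
    lm_target_um = tgt.pixel_to_um(ly_px, lx_px)
    centers = {
        rec.nucleus_id: tgt.pixel_to_um(rec.cy, rec.cx) for rec in gt.nuclei
    }
    truth = {"landmark_position_um": lm_target_um, "nucleus_centers_um": centers}
    return tgt, truth


# ---------------------------------------------------------------------------
# Disk round trip (16-bit TIFF per channel + CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_slide(slide: Slide, gt: GroundTruth | None, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in slide.channels.items():
        tifffile.imwrite(
            out / f"{name}.tif", np.clip(arr, 0, 65535).astype(np.uint16)
        )
    meta = {
        "slide_id": slide.slide_id,
        "pixel_size_um": slide.pixel_size_um,
        "origin_offset_um": list(slide.origin_offset_um),
        "channels": sorted(slide.channels),
    }
    if gt is not None:
        gt.nuclei_frame().to_csv(out / "ground_truth_nuclei.csv", index=False)
        tifffile.imwrite(out / "true_gain.tif", gt.gain_field.astype(np.float32))
        spec_echo = dataclasses.asdict(gt.spec)
        spec_echo["class_mix"] = [dataclasses.asdict(c) for c in gt.spec.class_mix]
        meta["ground_truth"] = {
            "landmark_position_um": list(gt.landmark_position_um),
            "landmark_rotation_deg": gt.landmark_rotation_deg,
            "spec": spec_echo,
        }
    (out / "slide.json").write_text(json.dumps(meta, indent=2))
    return out


def read_slide(in_dir: str | Path) -> Slide:
    src = Path(in_dir)
    meta = json.loads((src / "slide.json").read_text())
    channels = {
        name: tifffile.imread(src / f"{name}.tif").astype(float)
        for name in meta["channels"]
    }
    return Slide(
        channels=channels,
        pixel_size_um=meta["pixel_size_um"],
        origin_offset_um=tuple(meta["origin_offset_um"]),
        slide_id=meta["slide_id"],
    )
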