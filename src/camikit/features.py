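"""Per-nucleus feature extraction: the 92-measurement profile.

Each segmented nucleus is described by exactly 92 measurements of
intensity, texture and shape, the profile used to train and apply the
phenotype classifiers. The registry is frozen and versioned:

* per channel (nuclear, marker), 14 intensity statistics — mean,
  median, std, MAD, min, max, integrated, four quantiles, IQR, edge
  mean and edge/interior ratio;
* per channel, 26 texture statistics — the 13 classic co-occurrence
  (Haralick) features, each summarised as the mean and range over the
  four GLCM directions at unit offset;
* 12 shape descriptors — area, perimeter, form factor (4*pi*A/P^2),
  eccentricity, solidity, extent, equivalent diameter, major/minor
  axis, orientation, aspect ratio and the coefficient of variation of
  the boundary radius.

2 x (14 + 26) + 12 = 92. The count is asserted at import so a registry
edit cannot silently change the feature space.

Texture is computed on intensities quantized to 32 gray levels inside
the mask (Haralick values depend on the quantization, so it is part of
the frozen registry). Features are meant to be computed on
illumination-corrected images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import graycomatrix
from skimage.measure import regionprops

from .segmentation import NucleusSegment

__all__ = [
    "FEATURE_REGISTRY_VERSION",
    "FEATURE_NAMES",
    "N_FEATURES",
    "FeatureVector",
    "extract_features",
    "features_table",
]

FEATURE_REGISTRY_VERSION = "1.0"
CHANNEL_ORDER = ("nuclear", "marker")
GLCM_LEVELS = 32
GLCM_DISTANCE = 1

_INTENSITY_NAMES = (
    "mean", "median", "std", "mad", "min", "max", "integrated",
    "q10", "q25", "q75", "q90", "iqr", "edge_mean", "edge_interior_ratio",
)
_HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "diff_variance", "diff_entropy", "imc1", "imc2",
)
_SHAPE_NAMES = (
    "area", "perimeter", "form_factor", "eccentricity", "solidity",
    "extent", "equivalent_diameter", "major_axis", "minor_axis",
    "orientation", "aspect_ratio", "radius_cv",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ch}_int_{n}" for ch in CHANNEL_ORDER for n in _INTENSITY_NAMES]
    + [
        f"{ch}_tex_{n}_{agg}"
        for ch in CHANNEL_ORDER
        for n in _HARALICK_NAMES
        for agg in ("mean", "range")
    ]
    + [f"shape_{n}" for n in _SHAPE_NAMES]
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 92, f"feature registry corrupted: {N_FEATURES} != 92"


@dataclass
class FeatureVector:
    """The ordered 92-value profile of one nucleus."""

    label: int
    names: tuple[str, ...]
    values: np.ndarray
    registry_version: str = FEATURE_REGISTRY_VERSION

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names) or len(self.values) != N_FEATURES:
            raise ValueError("feature vector length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite features: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------

def _intensity_stats(crop: np.ndarray, mask: np.ndarray) -> list[float]:
    vals = crop[mask]
    q10, q25, med, q75, q90 = np.quantile(vals, [0.1, 0.25, 0.5, 0.75, 0.9])
    interior = ndi.binary_erosion(mask, iterations=2)
    edge = mask & ~interior
    if not interior.any() or not edge.any():
        interior = mask
        edge = mask
    edge_mean = float(crop[edge].mean())
    interior_mean = float(crop[interior].mean())
    ratio = edge_mean / interior_mean if interior_mean > 0 else 1.0
    return [
        float(vals.mean()), float(med), float(vals.std()),
        float(np.median(np.abs(vals - med))),
        float(vals.min()), float(vals.max()), float(vals.sum()),
        float(q10), float(q25), float(q75), float(q90), float(q75 - q25),
        edge_mean, float(ratio),
    ]


# ---------------------------------------------------------------------------
# Haralick texture from masked GLCM
# ---------------------------------------------------------------------------

def _masked_glcm(crop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric normalized GLCMs (levels x levels x 4 directions).

    Intensities are quantized to GLCM_LEVELS inside the mask; pixels
    outside the mask get level 0, and row/column 0 are removed before
    normalisation so background never contributes pairs.
    """
    vals = crop[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((crop - lo) / (hi - lo) * (GLCM_LEVELS - 1e-9)).astype(int)
        q = np.clip(q, 0, GLCM_LEVELS - 1)
    else:
        q = np.zeros(crop.shape, dtype=int)
    q = np.where(mask, q + 1, 0).astype(np.uint8)
    glcm = graycomatrix(
        q, distances=[GLCM_DISTANCE],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=GLCM_LEVELS + 1, symmetric=True,
    )
    glcm = glcm[1:, 1:, 0, :].astype(float)  # drop background row/col
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    return glcm / sums


def _haralick_13(p: np.ndarray) -> np.ndarray:
    """The 13 classic co-occurrence statistics of one normalized GLCM."""
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx, my = float(px @ i), float(py @ i)
    sx = _sqrt(float(px @ (i - mx) ** 2))
    sy = _sqrt(float(py @ (i - my) ** 2))

    asm = float((p ** 2).sum())
    contrast = float(((I - J) ** 2 * p).sum())
    if sx > 0 and sy > 0:
        correlation = float(((I * J * p).sum() - mx * my) / (sx * sy))
    else:
        correlation = 0.0
    variance = float(((I - mx) ** 2 * p).sum())
    idm = float((p / (1.0 + (I - J) ** 2)).sum())

    k_sum = np.arange(2 * n - 1, dtype=float)  # i + j in [0, 2n-2]
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel(), p.ravel())
    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_ent = _entropy(p_sum)

    k_diff = np.arange(n, dtype=float)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())
    diff_avg = float(k_diff @ p_diff)
    diff_var = float(((k_diff - diff_avg) ** 2) @ p_diff)
    diff_ent = _entropy(p_diff)

    entropy = _entropy(p)
    hx, hy = _entropy(px), _entropy(py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(px[:, None] * py[None, :] > 0,
                           np.log(np.maximum(px[:, None] * py[None, :], 1e-300)), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * log_pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = _sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
    ])


def _sqrt(x: float) -> float:
    return float(np.sqrt(max(x, 0.0)))


def _entropy(p: np.ndarray) -> float:
    q = p[p > 0]
    return float(-(q * np.log(q)).sum())


def _texture_stats(crop: np.ndarray, mask: np.ndarray) -> list[float]:
    glcm = _masked_glcm(crop, mask)
    per_dir = np.stack([_haralick_13(glcm[:, :, d]) for d in range(glcm.shape[2])])
    means = per_dir.mean(axis=0)
    ranges = per_dir.max(axis=0) - per_dir.min(axis=0)
    out = []
    for m, r in zip(means, ranges):
        out.extend([float(m), float(r)])
    return out


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------

def _shape_stats(mask: np.ndarray) -> list[float]:
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter) if props.perimeter > 0 else 1.0
    form_factor = 4.0 * np.pi * area / perimeter ** 2
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    aspect = major / minor if minor > 0 else 1.0
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    boundary = mask & ~ndi.binary_erosion(mask)
    by, bx = np.nonzero(boundary)
    radii = np.hypot(bx - cx, by - cy)
    rmean = radii.mean() if radii.size else 1.0
    radius_cv = float(radii.std() / rmean) if rmean > 0 else 0.0
    return [
        area, perimeter, float(form_factor), float(props.eccentricity),
        float(props.solidity), float(props.extent),
        float(props.equivalent_diameter_area), major, minor,
        float(props.orientation), float(aspect), radius_cv,
    ]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def extract_features(
    channels: dict[str, np.ndarray], segment: NucleusSegment
) -> FeatureVector:
    """Compute the frozen 92-feature profile of one segmented nucleus.

    ``channels`` must provide the registry's channel set (nuclear and
    marker); images are expected to be illumination-corrected.
    """
    missing = [ch for ch in CHANNEL_ORDER if ch not in channels]
    if missing:
        raise ValueError(f"channel(s) {missing} required by feature registry")
    if not segment.mask.any():
        raise ValueError("empty segment mask")
    y0, x0, y1, x1 = segment.bbox
    shape = next(iter(channels.values())).shape
    if y1 > shape[0] or x1 > shape[1] or y0 < 0 or x0 < 0:
        raise ValueError("segment mask outside image bounds")

    values: list[float] = []
    mask = segment.mask
    for ch in CHANNEL_ORDER:
        crop = np.asarray(channels[ch], dtype=float)[y0:y1, x0:x1]
        values.extend(_intensity_stats(crop, mask))
    for ch in CHANNEL_ORDER:
        crop = np.asarray(channels[ch], dtype=float)[y0:y1, x0:x1]
        values.extend(_texture_stats(crop, mask))
    values.extend(_shape_stats(mask))
    return FeatureVector(segment.label, FEATURE_NAMES, np.asarray(values))


def features_table(
    channels: dict[str, np.ndarray], segments: list[NucleusSegment]
) -> pd.DataFrame:
    """Feature matrix for a slide: one row per nucleus, label + 92 columns."""
    rows = []
    for seg in segments:
        fv = extract_features(channels, seg)
        row = {"label": seg.label}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *FEATURE_NAMES])
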