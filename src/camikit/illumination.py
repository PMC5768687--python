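"""Retrospective correction of uneven illumination.

Microscope images of a screen share one smooth multiplicative shading
field (vignetting, lamp inhomogeneity). Given a collection of images
of the same channel, this module estimates that field and removes it
before segmentation and feature extraction.

Model: observed(x, y) = gain(x, y) * clean(x, y) + offset(x, y).
The gain is represented as a low-order 2-D polynomial fitted to a
per-pixel robust quantile of the image stack (background pixels
dominate any sparse fluorescence scene, so the quantile image is the
shading field times the background level) by quasi-Newton (L-BFGS-B)
minimisation of a Huber loss. The offset surface defaults to zero —
a purely multiplicative model matches dark-subtracted fluorescence
data; a constant dark level can be supplied via options.

The fitted gain is normalised to mean 1 so corrected intensities stay
on the input scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.optimize import minimize

__all__ = ["IlluminationModel", "fit_illumination", "apply_correction"]


@dataclass
class IlluminationModel:
    """Per-pixel multiplicative gain and additive offset surfaces."""

    gain: np.ndarray
    offset: np.ndarray
    degree: int
    coefficients: np.ndarray
    residual: float
    iterations: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.gain <= 0):
            raise ValueError("gain surface must be strictly positive")
        if abs(float(self.gain.mean()) - 1.0) > 1e-6:
            raise ValueError("gain surface must have mean 1")

    def save(self, path_stem: str | Path) -> None:
        stem = Path(path_stem)
        tifffile.imwrite(stem.with_suffix(".gain.tif"), self.gain.astype(np.float32))
        tifffile.imwrite(stem.with_suffix(".offset.tif"), self.offset.astype(np.float32))
        stem.with_suffix(".json").write_text(json.dumps({
            "degree": self.degree,
            "coefficients": self.coefficients.tolist(),
            "residual": self.residual,
            "iterations": self.iterations,
        }, indent=2))


def _poly_terms(xn: np.ndarray, yn: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of all monomials x^i y^j with i + j <= degree."""
    cols = [
        (xn ** i) * (yn ** j)
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.stack(cols, axis=-1)


def fit_illumination(
    images: list[np.ndarray],
    degree: int = 2,
    quantile: float = 0.25,
    huber_delta: float = 1.345,
    dark_level: float = 0.0,
    max_samples: int = 20000,
) -> IlluminationModel:
    """Fit the smooth gain surface from a stack of same-shape images.

    Parameters
    ----------
    images : list of 2-D arrays, identical shapes, at least two
        One stage of a screen (same channel, different fields).
    degree : polynomial degree of the gain surface (default 2).
    quantile : per-pixel stack quantile used as the shading probe;
        a low quantile rejects cells that happen to sit on a pixel
        in some of the images.
    huber_delta : Huber loss transition point in robust-sigma units.
    dark_level : constant camera offset subtracted before the fit and
        stored as the model's offset surface.
    """
    if len(images) < 2:
        raise ValueError("need >= 2 images to separate shading from content")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all images must have identical dimensions")
    stack = np.stack([np.asarray(im, dtype=float) for im in images])
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite pixel values in input stack")

    probe = np.quantile(stack - dark_level, quantile, axis=0)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    xn = (xx + 0.5) / w
    yn = (yy + 0.5) / h

    # subsample pixels on a regular grid for the optimizer
    step = max(int(np.sqrt(h * w / max_samples)), 1)
    sl = (slice(step // 2, None, step), slice(step // 2, None, step))
    A = _poly_terms(xn[sl].ravel(), yn[sl].ravel(), degree)
    b = probe[sl].ravel()

    beta0, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid0 = b - A @ beta0
    sigma = float(np.median(np.abs(resid0 - np.median(resid0)))) / 0.6745
    sigma = max(sigma, 1e-6 * max(float(np.abs(b).max()), 1.0), 1e-12)
    delta = huber_delta * sigma

    def huber_obj(beta: np.ndarray) -> tuple[float, np.ndarray]:
        r = A @ beta - b
        absr = np.abs(r)
        quad = absr <= delta
        loss = np.where(quad, 0.5 * r ** 2, delta * (absr - 0.5 * delta))
        dr = np.where(quad, r, delta * np.sign(r))
        return float(loss.sum()), A.T @ dr

    res = minimize(huber_obj, beta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12})
    beta = res.x

    surface = (_poly_terms(xn.ravel(), yn.ravel(), degree) @ beta).reshape(shape)
    floor = 1e-3 * max(float(np.abs(surface).max()), 1e-12)
    surface = np.maximum(surface, floor)
    gain = surface / surface.mean()

    offset = np.full(shape, dark_level, dtype=float)
    return IlluminationModel(
        gain=gain,
        offset=offset,
        degree=degree,
        coefficients=beta,
        residual=float(res.fun),
        iterations=int(res.nit),
        diagnostics={"sigma": sigma, "n_samples": int(b.size),
                     "converged": bool(res.success)},
    )


def apply_correction(image: np.ndarray, model: IlluminationModel) -> np.ndarray:
    """corrected = (image - offset) / gain, clipped at zero.

    The number of pixels clipped to zero is recorded in
    ``model.diagnostics['clipped_px']`` (of the latest call).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != model.gain.shape:
        raise ValueError(
            f"image shape {image.shape} does not match model {model.gain.shape}"
        )
    corrected = (image - model.offset) / model.gain
    clipped = int(np.sum(corrected < 0))
    model.diagnostics["clipped_px"] = clipped
    return np.clip(corrected, 0, None)
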