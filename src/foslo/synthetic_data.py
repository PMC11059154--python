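"""Deterministic synthetic fixtures: knee-phantom images and labeled data.

The phantom is a stylized sagittal-knee-like scene — an elliptical "joint"
region plus a bright diagonal "ligament" band on a dark background; a
"tear" removes a short gap from the band.  It makes no claim of anatomical
realism: it exists to give the denoiser, the contrast enhancer, and the
compact classifier spatial structure to act on without any external data.

The tabular generator draws class-conditional Gaussian features whose
means differ along the first feature by a configurable separation,
emulating an imbalanced two-class screening problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .slo_core import ValidationError

__all__ = ["PhantomSpec", "DatasetSpec", "make_phantom", "tear_gap_mask", "make_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise model of one phantom image.

    ``noise`` is ``None``, ``("gaussian", sd)`` or ``("salt_pepper", rate)``;
    noise is applied after structure rendering and clipped to [0, 255].
    """

    size: int = 64
    background: int = 30
    ellipse_axes: tuple[float, float] = (0.34, 0.26)  # fractions of size
    ellipse_intensity: int = 120
    band_width: float = 5.0
    band_intensity: int = 200
    tear: bool = False
    tear_width: float = 9.0
    noise: Optional[tuple[str, float]] = None
    seed: int = 0


def _grids(size: int):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    return yy - c, xx - c


def _validate_geometry(spec: PhantomSpec) -> None:
    if spec.size < 8:
        raise ValidationError(f"phantom size must be >= 8, got {spec.size}")
    ay, ax = spec.ellipse_axes
    if not (0 < ay <= 0.5 and 0 < ax <= 0.5):
        raise ValidationError("ellipse axes must be fractions in (0, 0.5]")
    if spec.band_width <= 0 or spec.band_width > spec.size:
        raise ValidationError("band width outside the image frame")
    if spec.tear_width <= 0 or spec.tear_width > spec.size:
        raise ValidationError("tear width outside the image frame")


def tear_gap_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the band gap a tear would open (tear flag ignored)."""
    _validate_geometry(spec)
    dy, dx = _grids(spec.size)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    along = (dx + dy) * inv_sqrt2
    across = (dx - dy) * inv_sqrt2
    band = np.abs(across) <= spec.band_width / 2.0
    return band & (np.abs(along) <= spec.tear_width / 2.0)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one deterministic 8-bit phantom from its spec."""
    _validate_geometry(spec)
    size = spec.size
    dy, dx = _grids(size)
    img = np.full((size, size), float(spec.background))

    ay = spec.ellipse_axes[0] * size
    ax = spec.ellipse_axes[1] * size
    ellipse = (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0
    img[ellipse] = spec.ellipse_intensity

    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    across = (dx - dy) * inv_sqrt2
    band = np.abs(across) <= spec.band_width / 2.0
    if spec.tear:
        band = band & ~tear_gap_mask(spec)
    img[band] = spec.band_intensity

    if spec.noise is not None:
        kind, level = spec.noise
        rng = np.random.default_rng(spec.seed)
        if kind == "gaussian":
            img = img + rng.normal(0.0, level, img.shape)
        elif kind == "salt_pepper":
            u = rng.random(img.shape)
            img = np.where(u < level / 2.0, 0.0, img)
            img = np.where((u >= level / 2.0) & (u < level), 255.0, img)
        else:
            raise ValidationError(f"unknown noise model {kind!r}")
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class DatasetSpec:
    """Imbalanced two-class dataset request.

    ``separation`` is the distance between class means along the first
    feature, in units of the noise standard deviation.  ``mode`` is
    ``"tabular"`` (Gaussian feature vectors) or ``"image"`` (phantoms with
    and without a tear, one noise seed per sample).
    """

    n_minority: int = 50
    n_majority: int = 200
    mode: str = "tabular"
    n_features: int = 16
    separation: float = 6.0
    noise: float = 1.0
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


def make_dataset(spec: DatasetSpec):
    """Labeled data with exactly the requested class counts.

    Tabular mode returns a DataFrame with columns ``f0..f{d-1}`` and
    ``label`` (majority 0, minority 1).  Image mode returns
    ``(images, labels)`` with minority samples carrying a torn band.
    """
    if spec.n_minority < 1 or spec.n_majority < 1:
        raise ValidationError("each class needs at least one sample")
    rng = np.random.default_rng(spec.seed)
    labels = np.concatenate(
        [np.zeros(spec.n_majority, dtype=int), np.ones(spec.n_minority, dtype=int)]
    )
    if spec.mode == "tabular":
        n = len(labels)
        x = rng.normal(0.0, spec.noise, size=(n, spec.n_features))
        x[labels == 1, 0] += spec.separation * spec.noise
        table = pd.DataFrame(x, columns=[f"f{i}" for i in range(spec.n_features)])
        table["label"] = labels
        return table
    if spec.mode == "image":
        noise_sd = spec.noise if spec.phantom.noise is None else spec.phantom.noise[1]
        images = []
        for lab in labels:
            p = PhantomSpec(
                size=spec.phantom.size,
                background=spec.phantom.background,
                ellipse_axes=spec.phantom.ellipse_axes,
                ellipse_intensity=spec.phantom.ellipse_intensity,
                band_width=spec.phantom.band_width,
                band_intensity=spec.phantom.band_intensity,
                tear=bool(lab),
                tear_width=spec.phantom.tear_width,
                noise=("gaussian", noise_sd),
                seed=int(rng.integers(2**31 - 1)),
            )
            images.append(make_phantom(p))
        return np.stack(images), labels
    raise ValidationError(f"unknown dataset mode {spec.mode!r}")
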