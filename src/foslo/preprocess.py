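"""Image and tabular preprocessing: fuzzy denoising, BBHE, SMOTE.

Three operators used ahead of MRI-style image classification:

* **Fuzzy-entropy denoising** — every pixel receives a membership to the
  "noisy" class from its robust deviation against the local median; the
  output blends the pixel with its window median, weighted by that
  membership, so crisp noise is replaced while clean structure passes
  through.
* **BBHE** (brightness-preserving bi-histogram equalization) — the
  histogram is split at the mean intensity and each sub-histogram is
  equalized onto its own half of the dynamic range, stretching contrast
  while keeping mean brightness near its original level.
* **SMOTE** — the minority class of a feature table is grown to parity by
  interpolating each synthetic sample between a minority point and one of
  its k nearest minority neighbors.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.neighbors import NearestNeighbors

from .slo_core import ValidationError

__all__ = [
    "AugmentationError",
    "FuzzyMembershipField",
    "fuzzy_entropy",
    "fuzzy_memberships",
    "wang_mendel_denoise",
    "bbhe_enhance",
    "smote_interpolate",
    "smote_augment",
    "load_gray",
    "save_gray",
]

L_LEVELS = 256


class AugmentationError(ValueError):
    """SMOTE cannot proceed (e.g. a singleton minority class)."""


class FuzzyMembershipField:
    """Per-pixel noisy/noise-free memberships and fuzzy entropy.

    ``mu_noise + mu_free == 1`` everywhere; the entropy is zero exactly
    where membership is crisp and peaks at ln 2 where it is maximally
    ambiguous.
    """

    def __init__(self, mu_noise: np.ndarray, local_median: np.ndarray):
        self.mu_noise = mu_noise
        self.mu_free = 1.0 - mu_noise
        self.entropy = fuzzy_entropy(mu_noise)
        self.local_median = local_median


def fuzzy_entropy(mu_noise: np.ndarray) -> np.ndarray:
    """Binary fuzzy entropy ``-mu*ln(mu) - (1-mu)*ln(1-mu)``, 0*ln0 = 0."""
    mu = np.asarray(mu_noise, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mu > 0.0, -mu * np.log(mu), 0.0)
        comp = 1.0 - mu
        terms = terms + np.where(comp > 0.0, -comp * np.log(comp), 0.0)
    return terms


def _check_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("expected a non-empty 2-D grayscale image")
    return arr


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 3, got {window}")


def fuzzy_memberships(img, window: int = 3) -> FuzzyMembershipField:
    """Noisy-class membership per pixel from robust local deviation.

    The deviation ``|x - local_median|`` is scaled by its own image-wide
    median (a robust spread estimate, floored at 1 gray level) and squashed
    through ``d^2 / (d^2 + 1)`` into [0, 1).  Constant regions get
    membership 0; isolated impulses approach 1.
    """
    arr = _check_image(img)
    _check_window(window)
    local_med = median_filter(arr, size=window, mode="reflect")
    deviation = np.abs(arr - local_med)
    spread = max(float(np.median(deviation)), 1.0)
    scaled = deviation / spread
    mu_noise = scaled**2 / (scaled**2 + 1.0)
    return FuzzyMembershipField(mu_noise=mu_noise, local_median=local_med)


def wang_mendel_denoise(img, window: int = 3) -> np.ndarray:
    """Membership-weighted blend of each pixel with its window median.

    ``out = (1 - w)*x + w*median`` with ``w`` the noisy-class membership,
    rounded back to 8-bit.  Identity on constant images; never leaves
    [0, 255].
    """
    arr = _check_image(img)
    field = fuzzy_memberships(arr, window)
    w = field.mu_noise
    blended = (1.0 - w) * arr + w * field.local_median
    return np.clip(np.floor(blended + 0.5), 0, 255).astype(np.uint8)


def bbhe_enhance(img) -> np.ndarray:
    """Bi-histogram equalization split at the mean intensity.

    With split level ``Xm = floor(mean)``, pixels at or below ``Xm`` map
    through the lower sub-histogram CDF onto ``[0, Xm]`` and pixels above
    map through the upper CDF onto ``[Xm+1, 255]``; the two mapped
    sub-images are then united.  Mapped values are rounded half-up.
    """
    arr = _check_image(img)
    levels = np.clip(np.floor(arr + 0.5), 0, L_LEVELS - 1).astype(int)
    split = int(np.floor(levels.mean()))
    counts = np.bincount(levels.ravel(), minlength=L_LEVELS)

    lower_counts = counts[: split + 1]
    upper_counts = counts[split + 1 :]
    mapping = np.arange(L_LEVELS, dtype=float)
    if lower_counts.sum() > 0:
        cdf_lower = np.cumsum(lower_counts) / lower_counts.sum()
        mapping[: split + 1] = 0.0 + (split - 0.0) * cdf_lower
    if upper_counts.sum() > 0:
        cdf_upper = np.cumsum(upper_counts) / upper_counts.sum()
        mapping[split + 1 :] = (split + 1) + (L_LEVELS - 1 - (split + 1)) * cdf_upper
    out = np.floor(mapping[levels] + 0.5)
    return np.clip(out, 0, L_LEVELS - 1).astype(np.uint8)


def smote_interpolate(z_i: np.ndarray, z_j: np.ndarray, gamma: float) -> np.ndarray:
    """One synthetic point ``z_i + gamma * (z_j - z_i)``, gamma in [0, 1]."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    return z_i + gamma * (z_j - z_i)


def smote_augment(
    table: pd.DataFrame,
    label_col: str,
    k: int = 5,
    seed: int = 0,
    return_parents: bool = False,
):
    """Oversample the minority class to exact parity with the majority.

    Each synthetic sample interpolates between a uniformly chosen minority
    point and one of its ``k`` nearest minority neighbors (Euclidean),
    with a fresh ``gamma ~ U(0, 1)``; it is appended with the minority
    label.  ``k`` is clipped to the number of available neighbors.

    With ``return_parents=True`` also returns an ``(n_new, 2, d)`` array of
    the generating endpoint pairs, for auditing interpolation geometry.
    """
    if label_col not in table.columns:
        raise ValidationError(f"label column {label_col!r} not in table")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    counts = table[label_col].value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two classes to balance")
    minority_label = counts.index[-1]
    n_needed = int(counts.iloc[0] - counts.loc[minority_label])
    feature_cols = [c for c in table.columns if c != label_col]
    minority = table.loc[table[label_col] == minority_label, feature_cols]
    features = minority.to_numpy(dtype=float)
    n_min = len(features)
    if n_min < 2:
        raise AugmentationError(
            "minority class has a single sample; no neighbor to interpolate with"
        )
    if n_needed == 0:
        out = table.copy().reset_index(drop=True)
        empty = np.empty((0, 2, len(feature_cols)))
        return (out, empty) if return_parents else out

    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(features)
    _, neighbor_idx = nn.kneighbors(features)  # column 0 is the point itself
    rng = np.random.default_rng(seed)

    new_rows = np.empty((n_needed, len(feature_cols)))
    parents = np.empty((n_needed, 2, len(feature_cols)))
    for s in range(n_needed):
        i = int(rng.integers(n_min))
        j = int(neighbor_idx[i, 1 + rng.integers(k_eff)])
        gamma = rng.random()
        new_rows[s] = smote_interpolate(features[i], features[j], gamma)
        parents[s, 0] = features[i]
        parents[s, 1] = features[j]

    synthetic = pd.DataFrame(new_rows, columns=feature_cols)
    synthetic[label_col] = minority_label
    out = pd.concat([table, synthetic[table.columns]], ignore_index=True)
    return (out, parents) if return_parents else out


def load_gray(path) -> np.ndarray:
    """Read a PNG as 8-bit grayscale (color inputs luminance-converted)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.floor(np.asarray(arr, dtype=float) + 0.5), 0, 255).astype(np.uint8)


def save_gray(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))
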