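"""Paired-condition fluorescence quantification at the neuromuscular junction.

Two protocols from pH-probe (VMAT-pHluorin) experiments share one metric: a
terminal is scanned in standard saline, the solution is exchanged (acidic
saline to quench surface fluorescence, or NH4Cl saline to collapse vesicular
pH gradients and reveal intravesicular probe), and the terminal is scanned
again.  Each Z-stack is maximum-projected, one fixed intensity threshold is
applied to both scans, and the fraction of pixels strictly above threshold is
the signal measure; the reported quantity is the second-scan fraction over the
first-scan fraction.

FM4-64 dye cycling uses intensities instead: the dye signal is summed inside
a binary mask derived from a membrane marker (mCD8::GFP), and the released
fraction is 1 - unloaded/loaded.

Bouton morphology enters as a list of manually measured diameters; the
quantity of interest is the fraction of boutons strictly larger than a cutoff
(4 um by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import EmptyInputError, ValidationError

__all__ = [
    "ImageScan",
    "PairedQuantification",
    "FMQuantification",
    "max_project",
    "area_fraction_above",
    "paired_ratio",
    "masked_intensity",
    "unload_fraction",
    "large_bouton_fraction",
    "suggest_threshold",
]


@dataclass
class ImageScan:
    """A single-channel intensity image (2-D) or Z-stack (3-D)."""

    pixels: np.ndarray
    condition: str | None = None
    pixel_size: float | None = None  # um per pixel, optional

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError("pixels must be a 2-D image or a 3-D stack")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValidationError("intensities must be finite and >= 0")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class PairedQuantification:
    """Fixed-threshold area fractions of two scans and their ratio."""

    threshold: float
    fraction_first: float
    fraction_second: float
    ratio: float  # NaN (with undefined=True) when the first fraction is 0
    undefined: bool = False


@dataclass
class FMQuantification:
    """Mask-restricted FM-dye intensities before and after unloading.

    Both summed and mean intensities within the mask are reported; with a
    fixed mask they give the same ratio, but both conventions exist in
    practice.
    """

    loaded_sum: float
    unloaded_sum: float
    loaded_mean: float
    unloaded_mean: float
    unloaded_over_loaded: float
    released_fraction: float
    undefined: bool = False


def _as_image(img: ImageScan | np.ndarray) -> np.ndarray:
    arr = img.pixels if isinstance(img, ImageScan) else np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D image (project stacks first)")
    return arr


def max_project(stack: ImageScan | np.ndarray) -> ImageScan:
    """Maximum-intensity Z-projection of a stack (a 2-D image passes through)."""
    arr = stack.pixels if isinstance(stack, ImageScan) else np.asarray(stack, dtype=float)
    cond = stack.condition if isinstance(stack, ImageScan) else None
    if arr.ndim == 2:
        return ImageScan(pixels=arr.copy(), condition=cond)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValidationError("stack must be 3-D with at least one plane")
    return ImageScan(pixels=arr.max(axis=0), condition=cond)


def area_fraction_above(image: ImageScan | np.ndarray, threshold: float) -> float:
    """Fraction of pixels with intensity strictly above ``threshold``."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    arr = _as_image(image)
    return float((arr > threshold).sum()) / arr.size


def paired_ratio(
    first: ImageScan | np.ndarray,
    second: ImageScan | np.ndarray,
    threshold: float,
) -> PairedQuantification:
    """Ratio of above-threshold area fractions, second scan over first scan.

    The same fixed threshold is applied to both scans.  A first-scan fraction
    of zero leaves the ratio undefined (NaN, flagged) rather than infinite.
    """
    a, b = _as_image(first), _as_image(second)
    if a.shape != b.shape:
        raise ValidationError(f"scan shapes differ: {a.shape} vs {b.shape}")
    f1 = area_fraction_above(a, threshold)
    f2 = area_fraction_above(b, threshold)
    if f1 == 0:
        return PairedQuantification(threshold, f1, f2, float("nan"), undefined=True)
    return PairedQuantification(threshold, f1, f2, f2 / f1)


def masked_intensity(image: ImageScan | np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Summed and mean intensity over the True pixels of ``mask``."""
    arr = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValidationError("mask shape must match the image")
    n = int(mask.sum())
    if n == 0:
        raise EmptyInputError("mask selects no pixels")
    total = float(arr[mask].sum())
    return total, total / n


def unload_fraction(
    loaded: ImageScan | np.ndarray,
    unloaded: ImageScan | np.ndarray,
    mask: np.ndarray,
) -> FMQuantification:
    """Fraction of loaded FM dye released during unloading, within the mask.

    released = 1 - unloaded/loaded (mask-restricted intensities).  Zero loaded
    intensity leaves the result undefined (NaN, flagged).
    """
    a, b = _as_image(loaded), _as_image(unloaded)
    if a.shape != b.shape:
        raise ValidationError(f"scan shapes differ: {a.shape} vs {b.shape}")
    l_sum, l_mean = masked_intensity(a, mask)
    u_sum, u_mean = masked_intensity(b, mask)
    if l_sum == 0:
        return FMQuantification(
            l_sum, u_sum, l_mean, u_mean, float("nan"), float("nan"), undefined=True
        )
    ratio = u_sum / l_sum
    return FMQuantification(l_sum, u_sum, l_mean, u_mean, ratio, 1.0 - ratio)


def large_bouton_fraction(diameters: Sequence[float], cutoff: float = 4.0) -> float:
    """Fraction of synaptic boutons with diameter strictly greater than
    ``cutoff`` (um); a bouton exactly at the cutoff does not count."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise EmptyInputError("diameter list is empty")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValidationError("diameters must be finite and > 0")
    return float((d > cutoff).sum()) / d.size


def suggest_threshold(image: ImageScan | np.ndarray) -> float:
    """Otsu threshold as a starting suggestion; never applied implicitly.

    The fixed threshold separating synaptic signal from background is an
    acquisition-specific choice and must be supplied explicitly to the
    quantification functions.
    """
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(_as_image(image)))
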