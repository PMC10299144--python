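"""En-face OCTA angiogram processing: binarization, skeletonization, perfusion density.

An en-face angiogram is an 8-bit grayscale image of a retinal capillary
plexus (superficial, SCP, or deep, DCP).  Processing follows the standard
fractal-quantification chain: Otsu binarization into a vessel mask, from
which vascular perfusion density (VPD) is computed; topology-preserving
thinning into a one-pixel-wide skeleton, on which lacunarity is computed
(see :mod:`octadme.lacunarity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize


class DegenerateImageError(ValueError):
    """Raised when an image has a single intensity value and cannot be thresholded."""


@dataclass
class Angiogram:
    """8-bit grayscale en-face angiogram with geometry and identity metadata.

    Parameters
    ----------
    intensities
        2D uint8 array, values in [0, 255].
    plexus
        ``"scp"`` or ``"dcp"``.
    mm_per_pixel
        Physical pixel pitch; a nominal 3x3 mm scan at 256 px/side gives
        about 0.0117 mm/px.
    eye_id, timepoint
        Identifiers; ``timepoint`` is ``"baseline"`` or ``"m12"``.
    """

    intensities: np.ndarray
    plexus: str = "scp"
    mm_per_pixel: float = 3.0 / 256
    eye_id: str = ""
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError(f"angiogram must be 2D, got shape {arr.shape}")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")
        self.intensities = arr.astype(np.uint8)
        if self.plexus not in ("scp", "dcp"):
            raise ValueError(f"plexus must be 'scp' or 'dcp', got {self.plexus!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class VesselMask:
    """Binary vessel mask (True = vessel) plus the threshold that produced it."""

    mask: np.ndarray
    threshold: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class Skeleton:
    """One-pixel-wide vessel centerlines (True = skeleton pixel)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


def _as_intensity_array(image: Angiogram | np.ndarray) -> np.ndarray:
    if isinstance(image, Angiogram):
        return image.intensities
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2D intensity array")
    return arr.astype(np.uint8)


def otsu_threshold(image: Angiogram | np.ndarray) -> int:
    """Otsu threshold of an 8-bit image.

    Returns the smallest ``t`` in [0, 254] maximizing the between-class
    variance of the 256-bin histogram, with classes ``{<= t}`` and
    ``{> t}``.  The smallest-argmax rule makes ties deterministic.

    Raises
    ------
    DegenerateImageError
        If the image holds a single distinct intensity.
    """
    arr = _as_intensity_array(image)
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "constant image: Otsu threshold undefined (needs >= 2 distinct values)"
        )
    n = hist.sum()
    p = hist / n
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]            # weight of class {<= t}, t = 0..254
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * levels)[:-1]
    mu_total = (p * levels).sum()
    # between-class variance; guard empty classes (variance contribution 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = np.where(
            (w0 > 0) & (w1 > 0),
            (mu_total * w0 - cum_mean) ** 2 / (w0 * w1),
            0.0,
        )
    return int(np.argmax(var_between))


def binarize(image: Angiogram | np.ndarray, threshold: int) -> VesselMask:
    """Binarize with foreground = intensity strictly above ``threshold``."""
    if not 0 <= int(threshold) <= 254:
        raise ValueError(f"threshold must be in [0, 254], got {threshold}")
    arr = _as_intensity_array(image)
    return VesselMask(mask=arr > int(threshold), threshold=int(threshold))


def skeletonize(mask: VesselMask | np.ndarray) -> Skeleton:
    """Thin a vessel mask to one-pixel-wide centerlines.

    Topology-preserving (8-connectivity) thinning: the skeleton is a subset
    of the mask, preserves the number of 8-connected components, and is a
    fixed point of re-application.  An empty mask yields an empty skeleton.
    """
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask).astype(bool)
    return Skeleton(mask=_sk_skeletonize(arr))


def vascular_perfusion_density(mask: VesselMask | np.ndarray) -> float:
    """Fraction of image area occupied by vessel signal.

    Computed on the full vessel mask, not the skeleton.  Reported as a
    fraction of image area in [0, 1].
    """
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask).astype(bool)
    if arr.size == 0:
        raise ValueError("cannot compute perfusion density of a zero-size image")
    return float(arr.sum()) / arr.size


def read_angiogram(
    path: str | Path,
    plexus: str = "scp",
    eye_id: str = "",
    timepoint: str = "baseline",
    mm_per_pixel: float = 3.0 / 256,
    luma: bool = False,
) -> Angiogram:
    """Read an 8-bit grayscale PNG/TIFF angiogram.

    RGB input is rejected unless ``luma=True``, in which case the ITU-R
    601 luma conversion is applied.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not luma:
            raise ValueError(
                f"{path}: RGB image; pass luma=True to convert to grayscale"
            )
        arr = np.round(
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        ).astype(np.uint8)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return Angiogram(
        intensities=arr,
        plexus=plexus,
        eye_id=eye_id,
        timepoint=timepoint,
        mm_per_pixel=mm_per_pixel,
    )


def write_angiogram(image: Angiogram, path: str | Path) -> None:
    """Write an angiogram as an 8-bit grayscale PNG/TIFF."""
    iio.imwrite(path, image.intensities)


def angiogram_filename(eye_id: str, plexus: str, timepoint: str) -> str:
    """Canonical ``<eye_id>_<SCP|DCP>_<baseline|m12>.png`` file name."""
    return f"{eye_id}_{plexus.upper()}_{timepoint}.png"
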