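"""Local adaptive binarization and mask-restricted flow density.

Both quantification planes (en face and B-scan) binarize the flow image
with the Phansalkar local threshold and then count foreground pixels
inside a region of interest.  Flow density (FD) is the percentage of
foreground ("white") pixels inside the region after binarization.

The Phansalkar threshold targets low-contrast vascular images.  For each
pixel, with local mean ``m`` and local standard deviation ``s`` computed
over a circular window on the image normalized to [0, 1]::

    t = m * (1 + p * exp(-q * m) + k * ((s / r) - 1))

and a pixel is foreground iff its normalized value strictly exceeds
``t``.  Defaults (k=0.25, r=0.5, p=2, q=10, radius 15 px) follow the
Fiji ``Auto Local Threshold > Phansalkar`` plugin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "PhansalkarParams",
    "phansalkar_threshold",
    "flow_density",
    "local_threshold_comparison",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with a declared intensity range.

    Parameters
    ----------
    data
        2-D array of intensities (any numeric dtype).
    range_max
        Declared maximum of the intensity scale (255 for 8-bit,
        65535 for 16-bit, 1.0 for already-normalized floats).  Used to
        normalize to [0, 1] before thresholding.
    spacing_mm
        Lateral pixel spacing in mm/px, if known.
    """

    data: np.ndarray
    range_max: float = 255.0
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if self.range_max <= 0:
            raise ValueError("range_max must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by the declared range."""
        return np.asarray(self.data, dtype=np.float64) / float(self.range_max)


@dataclass(frozen=True)
class PhansalkarParams:
    """Parameters of the Phansalkar local threshold.

    ``radius`` is the radius of the circular window in pixels; ``k``,
    ``r``, ``p``, ``q`` enter the threshold formula.  ``r`` is the
    expected dynamic range of the local standard deviation on the
    normalized image.
    """

    radius: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


def _disk_footprint(radius: int) -> np.ndarray:
    """Boolean circular footprint: pixels with dy^2 + dx^2 <= radius^2."""
    dy, dx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (dy * dy + dx * dx) <= radius * radius


def _local_mean_std(
    img: np.ndarray, radius: int
) -> tuple[np.ndarray, np.ndarray]:
    # Windowed first and second moments with mirror padding at the edges.
    fp = _disk_footprint(radius)
    w = fp.astype(np.float64) / fp.sum()
    m = ndimage.correlate(img, w, mode="mirror")
    m2 = ndimage.correlate(img * img, w, mode="mirror")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m, s


def phansalkar_threshold(
    image: GrayImage, params: PhansalkarParams | None = None
) -> np.ndarray:
    """Binarize a grayscale image with the Phansalkar local threshold.

    The image is normalized to [0, 1] by its declared intensity range;
    the local mean ``m`` and population standard deviation ``s`` are
    computed over a circular window (mirror padding at the borders), and
    a pixel is foreground iff its normalized value strictly exceeds
    ``t = m * (1 + p*exp(-q*m) + k*((s/r) - 1))``.

    Returns a boolean array of the image's shape (True = foreground).
    """
    if params is None:
        params = PhansalkarParams()
    h, wid = image.shape
    if params.radius > h and params.radius > wid:
        raise ValueError(
            f"window radius {params.radius} exceeds both image dimensions "
            f"{image.shape}"
        )
    img = image.normalized()
    m, s = _local_mean_std(img, params.radius)
    t = m * (
        1.0
        + params.p * np.exp(-params.q * m)
        + params.k * ((s / params.r) - 1.0)
    )
    return img > t


def flow_density(binary: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of foreground pixels of ``binary`` inside ``mask``.

    Both arguments are 2-D boolean arrays of equal shape.  Returns
    ``100 * (# foreground inside mask) / (# pixels inside mask)``,
    a value in [0, 100].

    Raises
    ------
    ValueError
        If the shapes differ or the mask selects no pixels.
    """
    binary = np.asarray(binary, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if binary.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: binary {binary.shape} vs mask {mask.shape}"
        )
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("degenerate ROI: mask selects no pixels")
    return 100.0 * float(np.count_nonzero(binary & mask)) / n_mask


def local_threshold_comparison(
    image: GrayImage, params: PhansalkarParams | None = None
) -> dict[str, np.ndarray]:
    """Optional hook: compare Phansalkar with Niblack/Sauvola masks.

    Returns foreground masks from the three local-threshold families on
    the same normalized image and window size, for side-by-side
    sensitivity checks of the binarization choice.
    """
    from skimage.filters import threshold_niblack, threshold_sauvola

    if params is None:
        params = PhansalkarParams()
    img = image.normalized()
    win = 2 * params.radius + 1
    return {
        "phansalkar": phansalkar_threshold(image, params),
        "niblack": img > threshold_niblack(img, window_size=win, k=params.k),
        "sauvola": img > threshold_sauvola(img, window_size=win, k=params.k),
    }
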