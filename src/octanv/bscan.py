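"""B-scan quantification: flow isolation, FD, and protrusion heights.

The OCTA review software exports B-scans as a grayscale structural
image with the flow signal overlaid in red.  Because the structural
background is achromatic (R = G = B), subtracting the blue channel from
the red channel after color splitting leaves exactly the flow overlay.
The isolated flow image is binarized like the en face angio image, and
flow density is counted inside the manually delineated NV
cross-section, whose lower border is the ILM and upper border the
vitreous.  Protrusion heights are the maximum extent of the NV above
the ILM toward the vitreous — per column, in µm — measured once for the
structural outline and once for the binarized flow.

Image convention: row 0 is at the top of the B-scan (vitreous);
"toward the vitreous" therefore means decreasing row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binarize import GrayImage, PhansalkarParams, flow_density, phansalkar_threshold
from .enface import RoiPolygon, polygon_to_mask
from .exceptions import FormatError, GeometryError

__all__ = ["BScanRGB", "BscanMeasurement", "isolate_flow", "measure_bscan"]


@dataclass(frozen=True)
class BScanRGB:
    """An 8-bit RGB B-scan with flow overlay and its ILM polyline.

    ``data`` has shape (rows, cols, 3).  ``ilm_rows`` gives, per image
    column, the axial row of the ILM.  ``axial_spacing_um`` converts row
    offsets to µm; ``lateral_spacing_mm`` converts columns to mm.
    """

    data: np.ndarray
    axial_spacing_um: float | None = None
    lateral_spacing_mm: float | None = None
    ilm_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(
                f"B-scan must be an RGB image, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            raise FormatError("B-scan overlay images must be 8-bit RGB")
        object.__setattr__(self, "data", arr)
        if self.ilm_rows is not None:
            ilm = np.asarray(self.ilm_rows, dtype=int)
            if len(ilm) != arr.shape[1]:
                raise GeometryError("ILM polyline must cover every column")
            if np.any(ilm < 0) or np.any(ilm >= arr.shape[0]):
                raise GeometryError("ILM polyline outside image bounds")
            object.__setattr__(self, "ilm_rows", ilm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(frozen=True)
class BscanMeasurement:
    """Cross-sectional NV endpoints: area, FD, and heights above ILM."""

    nv_area: float  # mm² when both spacings known, else px²
    fd: float
    height_structure: float  # µm (px when axial spacing absent)
    height_flow: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fd <= 100.0:
            raise ValueError("fd must lie in [0, 100]")
        if self.height_structure < 0 or self.height_flow < 0:
            raise ValueError("heights must be non-negative")


def isolate_flow(bscan: BScanRGB) -> GrayImage:
    """Red-minus-blue channel subtraction, clamped at zero.

    Achromatic structural pixels (R = G = B) vanish exactly; the red
    flow overlay survives.  The green channel never enters.
    """
    rgb = bscan.data.astype(np.int16)
    diff = np.clip(rgb[..., 0] - rgb[..., 2], 0, 255).astype(np.uint8)
    return GrayImage(diff, range_max=255.0)


def measure_bscan(
    bscan: BScanRGB,
    roi: RoiPolygon,
    params: PhansalkarParams | None = None,
) -> BscanMeasurement:
    """Measure one delineated NV cross-section.

    The full isolated-flow image is binarized, then restricted to the
    ROI (symmetric with the en face path).  Heights are the maximum,
    over ROI columns, of (ILM row − topmost row) × axial spacing, taken
    for the ROI mask itself (structure) and for the binarized flow
    inside the ROI; an ROI with no flow yields ``height_flow = 0`` with
    a warning.  The ROI must not extend below the ILM.
    """
    if bscan.ilm_rows is None:
        raise GeometryError("B-scan measurement requires the ILM polyline")
    shape = bscan.shape
    mask = polygon_to_mask(roi, shape)
    if not mask.any():
        raise GeometryError("ROI rasterizes to an empty mask")
    rows = np.arange(shape[0])[:, None]
    below_ilm = rows > bscan.ilm_rows[None, :]
    if np.any(mask & below_ilm):
        raise GeometryError("ROI extends below the ILM polyline")

    flow_img = isolate_flow(bscan)
    binary = phansalkar_threshold(flow_img, params)
    fd = flow_density(binary, mask)

    ax_um = bscan.axial_spacing_um if bscan.axial_spacing_um is not None else 1.0

    def max_height(px_mask: np.ndarray) -> float:
        cols = np.nonzero(px_mask.any(axis=0))[0]
        if len(cols) == 0:
            return 0.0
        top_rows = np.argmax(px_mask[:, cols], axis=0)  # first True per col
        heights = (bscan.ilm_rows[cols] - top_rows) * ax_um
        return float(max(heights.max(), 0.0))

    height_structure = max_height(mask)
    flow_in_roi = binary & mask
    if not flow_in_roi.any():
        warnings.warn("no binarized flow inside the ROI; height_flow = 0")
        height_flow = 0.0
    else:
        height_flow = max_height(flow_in_roi)

    if bscan.axial_spacing_um is not None and bscan.lateral_spacing_mm is not None:
        area = float(mask.sum()) * bscan.lateral_spacing_mm * (
            bscan.axial_spacing_um / 1000.0
        )
    else:
        area = float(mask.sum())
    return BscanMeasurement(
        nv_area=area,
        fd=fd,
        height_structure=height_structure,
        height_flow=height_flow,
    )
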