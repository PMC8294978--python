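"""En face projection and ROI-based NV quantification.

The vitreoretinal-interface (VRI) slab starts at the internal limiting
membrane (ILM) and extends into the vitreous as far as the
neovascularization (NV) reaches.  En face angio and structure images
are maximum intensity projections of the respective channel over that
slab.  The NV is delineated *separately* on the angio and the structure
image; the area of each outline is reported in mm², and flow density is
measured on the binarized **angio** image inside each outline:
FD-angio inside the angio outline, FD-structure inside the structure
outline.  The structure image contributes only its outline, never the
pixels being counted.

Conventions: pixel grid is 0-based with pixel centers at integer
coordinates; the axial slab is half-open (inclusive lower, exclusive
upper index); polygon rasterization uses the even–odd rule on pixel
centers, with centers exactly on an edge counted inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import GrayImage, PhansalkarParams, flow_density, phansalkar_threshold
from .exceptions import DegenerateRoiError, GeometryError
from .synthetic import OctaVolume

__all__ = [
    "EnFacePair",
    "RoiPolygon",
    "EnfaceMeasurement",
    "mip_projection",
    "polygon_to_mask",
    "measure_enface",
]


@dataclass(frozen=True)
class EnFacePair:
    """Registered angio + structure en face images on one pixel grid."""

    angio: GrayImage
    structure: GrayImage

    def __post_init__(self) -> None:
        if self.angio.shape != self.structure.shape:
            raise GeometryError("angio and structure images must share a grid")
        if self.angio.spacing_mm != self.structure.spacing_mm:
            raise GeometryError("angio and structure spacing must match")

    @property
    def spacing_mm(self) -> float | None:
        return self.angio.spacing_mm


@dataclass(frozen=True)
class RoiPolygon:
    """Closed planar polygon delineating one NV in one plane.

    ``vertices`` is an ordered (n, 2) array of (x, y) pixel coordinates;
    the polygon is implicitly closed (last vertex connects to first) and
    must be simple (non-self-intersecting).  ``plane`` tags which image
    the outline was drawn on (``angio`` | ``structure`` | ``bscan``).
    """

    vertices: np.ndarray
    plane: str = "angio"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateRoiError(
                "a polygon ROI needs at least 3 (x, y) vertices"
            )
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class EnfaceMeasurement:
    """Per-visit en face endpoint bundle (areas in mm², FDs in %)."""

    nv_angio_area: float
    nv_structure_area: float
    fd_angio: float
    fd_structure: float

    def __post_init__(self) -> None:
        if self.nv_angio_area < 0 or self.nv_structure_area < 0:
            raise ValueError("areas must be non-negative")
        for fd in (self.fd_angio, self.fd_structure):
            if not 0.0 <= fd <= 100.0:
                raise ValueError("flow densities must lie in [0, 100]")


def mip_projection(
    volume: OctaVolume,
    slab: tuple[np.ndarray | int, np.ndarray | int] | None = None,
) -> EnFacePair:
    """Maximum intensity projection of both channels over an axial slab.

    ``slab`` is ``(lower, upper)`` per-(y, x) axial index bounds,
    inclusive lower and exclusive upper; by default the VRI slab from
    the ILM surface to the top of the volume.  Each en face pixel is the
    maximum of the channel over ``lower <= z < upper`` at that (y, x).
    """
    ny, nx, nz = volume.structure.shape
    if slab is None:
        lo, hi = volume.ilm_z, nz
    else:
        lo, hi = slab
    lo = np.broadcast_to(np.asarray(lo, dtype=int), (ny, nx))
    hi = np.broadcast_to(np.asarray(hi, dtype=int), (ny, nx))
    if np.any(lo < 0) or np.any(hi > nz) or np.any(hi < lo):
        raise GeometryError("slab bounds outside the volume's axial range")
    zs = np.arange(nz)[None, None, :]
    inside = (zs >= lo[..., None]) & (zs < hi[..., None])
    neg = np.float64(-np.inf)
    angio = np.where(inside, volume.flow, neg).max(axis=2)
    structure = np.where(inside, volume.structure, neg).max(axis=2)
    # Empty slab columns (lower == upper) project to zero.
    angio = np.where(np.isfinite(angio), angio, 0.0)
    structure = np.where(np.isfinite(structure), structure, 0.0)
    return EnFacePair(
        angio=GrayImage(angio, range_max=1.0, spacing_mm=volume.lateral_spacing_mm),
        structure=GrayImage(
            structure, range_max=1.0, spacing_mm=volume.lateral_spacing_mm
        ),
    )


def polygon_to_mask(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon ROI onto a pixel grid.

    A pixel belongs to the mask iff its center (integer coordinates)
    lies inside the closed polygon by the even–odd rule; centers exactly
    on an edge are inside (deterministic tie-break).  Returns a boolean
    array of the given (rows, cols) shape.
    """
    h, w = shape
    v = roi.vertices
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    px, py = np.meshgrid(xs, ys)
    inside = np.zeros(shape, dtype=bool)
    on_edge = np.zeros(shape, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # Even–odd crossing of the horizontal ray toward +x.
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < x_at)
        # Pixel centers exactly on the segment.
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (px >= min(x1, x2) - 1e-12)
            & (px <= max(x1, x2) + 1e-12)
            & (py >= min(y1, y2) - 1e-12)
            & (py <= max(y1, y2) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
    return inside | on_edge


def measure_enface(
    pair: EnFacePair,
    roi_angio: RoiPolygon,
    roi_structure: RoiPolygon,
    params: PhansalkarParams | None = None,
) -> EnfaceMeasurement:
    """Measure NV areas and flow densities for one visit.

    Areas are outline-mask pixel counts times the squared pixel spacing.
    The angio image is binarized once over its full extent; FD-angio and
    FD-structure are the foreground percentages of that same binary
    image inside the angio and structure outlines respectively.
    """
    if pair.spacing_mm is None:
        raise ValueError("en face pair needs a pixel spacing to report mm²")
    shape = pair.angio.shape
    mask_a = polygon_to_mask(roi_angio, shape)
    mask_s = polygon_to_mask(roi_structure, shape)
    if not mask_a.any() or not mask_s.any():
        raise DegenerateRoiError("an ROI rasterizes to an empty mask")
    binary = phansalkar_threshold(pair.angio, params)
    px2 = pair.spacing_mm**2
    return EnfaceMeasurement(
        nv_angio_area=float(mask_a.sum()) * px2,
        nv_structure_area=float(mask_s.sum()) * px2,
        fd_angio=flow_density(binary, mask_a),
        fd_structure=flow_density(binary, mask_s),
    )
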