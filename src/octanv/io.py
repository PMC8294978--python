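"""File formats and configuration.

Handles the pipeline's external surface: TIFF images (8/16-bit
grayscale en face, 8-bit RGB B-scan), ROI polygons (ImageJ ``.roi``
polygon records or a JSON dialect), ILM polyline CSVs, measurement
CSVs, YAML configuration, and the packaged per-NV endpoint fixture.

Pixel coordinates are 0-based throughout.  CSV files are
comma-separated UTF-8 with '.' decimal and a mandatory header row.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .binarize import GrayImage, PhansalkarParams
from .bscan import BScanRGB
from .enface import RoiPolygon
from .exceptions import FormatError, ParameterError

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_roi",
    "write_roi",
    "read_ilm_polyline",
    "load_table1",
    "PipelineConfig",
    "ENFACE_CSV_COLUMNS",
    "BSCAN_CSV_COLUMNS",
]

logger = logging.getLogger("octanv")

ENFACE_CSV_COLUMNS = [
    "nv_id", "visit_week", "nv_structure_area_mm2", "nv_angio_area_mm2",
    "fd_structure_pct", "fd_angio_pct",
]
BSCAN_CSV_COLUMNS = [
    "nv_id", "visit_week", "bscan_area", "bscan_fd_pct",
    "height_structure_um", "height_flow_um",
]


def read_tiff(path: str | Path) -> GrayImage | BScanRGB:
    """Read a TIFF export as a grayscale image or an RGB B-scan.

    8- or 16-bit single-channel data becomes a :class:`GrayImage` with
    the bit depth recorded as its intensity range; 8-bit 3-channel data
    becomes a :class:`BScanRGB` (spacings and ILM attached by the
    caller).  Anything else is rejected with the offending layout
    named.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2 and arr.dtype == np.uint8:
        return GrayImage(arr, range_max=255.0)
    if arr.ndim == 2 and arr.dtype == np.uint16:
        return GrayImage(arr, range_max=65535.0)
    if arr.ndim == 3 and arr.shape[2] == 3 and arr.dtype == np.uint8:
        return BScanRGB(arr)
    raise FormatError(
        f"unsupported TIFF layout: shape {arr.shape}, dtype {arr.dtype} "
        f"(expected 8/16-bit grayscale or 8-bit RGB)"
    )


def write_tiff(path: str | Path, array: np.ndarray) -> Path:
    """Write an image array to TIFF unchanged."""
    path = Path(path)
    tifffile.imwrite(str(path), array)
    return path


# --- ImageJ .roi polygon records -------------------------------------
# Big-endian byte layout: "Iout" magic, version short, ROI type byte at
# offset 6, top/left/bottom/right shorts at 8..15, nCoordinates short
# at 16, header of 64 bytes, then n x-coordinates and n y-coordinates
# as shorts relative to (left, top).

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 227
_ROI_TYPE_POLYGON = 0
_ROI_TYPE_NAMES = {
    0: "polygon", 1: "rect", 2: "oval", 3: "line", 4: "freeline",
    5: "polyline", 6: "noRoi", 7: "freehand", 8: "traced", 9: "angle",
    10: "point",
}
_ROI_HEADER_SIZE = 64


def write_roi(path: str | Path, roi: RoiPolygon) -> Path:
    """Write a polygon ROI as an ImageJ ``.roi`` record.

    Vertices are rounded to integer pixel coordinates (the classic
    record has no subpixel resolution)."""
    v = np.round(roi.vertices).astype(int)
    left, top = int(v[:, 0].min()), int(v[:, 1].min())
    right, bottom = int(v[:, 0].max()), int(v[:, 1].max())
    n = len(v)
    header = bytearray(_ROI_HEADER_SIZE)
    header[0:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = _ROI_TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(
        f">{n}h", *(v[:, 0] - left)
    ) + struct.pack(f">{n}h", *(v[:, 1] - top))
    path = Path(path)
    path.write_bytes(bytes(header) + body)
    return path


def _read_imagej_roi(raw: bytes, plane: str) -> RoiPolygon:
    if raw[0:4] != _ROI_MAGIC:
        raise FormatError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = raw[6]
    if roi_type != _ROI_TYPE_POLYGON:
        name = _ROI_TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise FormatError(f"unsupported ROI subtype: {name} (need polygon)")
    top, left, _bottom, _right = struct.unpack_from(">4h", raw, 8)
    (n,) = struct.unpack_from(">h", raw, 16)
    xs = np.array(struct.unpack_from(f">{n}h", raw, _ROI_HEADER_SIZE))
    ys = np.array(
        struct.unpack_from(f">{n}h", raw, _ROI_HEADER_SIZE + 2 * n)
    )
    verts = np.column_stack([xs + left, ys + top]).astype(float)
    return RoiPolygon(vertices=verts, plane=plane)


def _plane_from_name(path: Path) -> str:
    stem = path.stem.lower()
    for tag in ("angio", "structure", "bscan"):
        if stem.endswith(tag):
            return tag
    return "angio"


def read_roi(path: str | Path) -> RoiPolygon:
    """Read a polygon ROI from ``.roi`` (ImageJ) or ``.json``.

    The JSON dialect is ``{"plane": "angio", "vertices": [[x, y], ...]}``.
    For ``.roi`` files the plane tag comes from the filename suffix
    (``*_angio.roi`` etc.; default ``angio``).  Non-polygon ROI
    subtypes are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return RoiPolygon(
            vertices=np.asarray(payload["vertices"], dtype=float),
            plane=payload.get("plane", _plane_from_name(path)),
        )
    return _read_imagej_roi(path.read_bytes(), _plane_from_name(path))


def read_ilm_polyline(path: str | Path, n_columns: int | None = None) -> np.ndarray:
    """Read an ILM polyline CSV (``column_index, axial_row``) into a
    per-column row array, linearly interpolated over missing columns."""
    df = pd.read_csv(path)
    cols = df.iloc[:, 0].to_numpy(float)
    rows = df.iloc[:, 1].to_numpy(float)
    if n_columns is None:
        n_columns = int(cols.max()) + 1
    full = np.interp(np.arange(n_columns), cols, rows)
    return np.round(full).astype(int)


def load_table1() -> pd.DataFrame:
    """The packaged per-NV endpoint fixture (nine NVs).

    Columns carry the printed per-NV endpoint values — signed area
    changes and FD percentages at baseline/posttreatment/last
    follow-up — together with raw area columns derived by normalizing
    every baseline area to 1.0 mm², so relative changes can be
    recomputed from raw values as a self-consistency check.
    """
    with resources.files("octanv.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


_DEFAULT_PATTERNS = {
    "3x3": 3.0 / 256, "6x6": 6.0 / 256, "12x12": 12.0 / 256,
    "9x15": 9.0 / 256,
}


@dataclass
class PipelineConfig:
    """Run-wide configuration: scan-pattern spacings, binarization
    parameters, endpoint window, output directory, seed, log level."""

    pattern_spacing_mm: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PATTERNS)
    )
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    window_weeks: tuple[float, float] = (4.0, 6.0)
    outdir: str = "octanv_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.pattern_spacing_mm.values()):
            raise ParameterError("pattern spacings must be positive")
        lo, hi = self.window_weeks
        if not lo < hi:
            raise ParameterError("window_low must be below window_high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "phansalkar" in payload:
            payload["phansalkar"] = PhansalkarParams(**payload["phansalkar"])
        if "window_weeks" in payload:
            payload["window_weeks"] = tuple(payload["window_weeks"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "pattern_spacing_mm": self.pattern_spacing_mm,
            "phansalkar": {
                "radius": self.phansalkar.radius,
                "k": self.phansalkar.k,
                "r": self.phansalkar.r,
                "p": self.phansalkar.p,
                "q": self.phansalkar.q,
            },
            "window_weeks": list(self.window_weeks),
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Log to stderr, optionally also to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(str(logfile)))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
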