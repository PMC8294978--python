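"""Synthetic OCTA volumes with a ground-truth neovascularization.

Real OCTA exports of treated retinal neovascularization (NV) cannot be
published, so this module generates OCTA-like data with a *known* truth:
a fan-shaped branching vessel tree anchored on the internal limiting
membrane (ILM) and growing into the vitreous, rendered into separate
structure-reflectivity and flow-decorrelation channels.  Anti-VEGF
treatment response is emulated by a perfusion schedule: flow regresses
from the distal branches inward, the structural scaffold persists
("ghost vessels"), and perfusion may recur after a treatment-free
interval — the regression/recurrence pattern reported clinically.

Axial convention: the volume is indexed ``[y, x, z]`` with ``z``
increasing from the retina toward the vitreous; the ILM sits at
``ilm_z`` and the NV occupies ``z >= ilm_z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import GeometryError, ParameterError, ScheduleError

__all__ = [
    "Segment",
    "VesselTree",
    "SynthParams",
    "OctaVolume",
    "SimulatedCase",
    "generate_vessel_tree",
    "apply_treatment_schedule",
    "render_volume",
    "simulate_case",
    "export_case",
    "shoelace_area",
]


@dataclass(frozen=True)
class Segment:
    """One vessel segment: a 3-D capsule (line plus radius) in voxel
    coordinates ``(x, y, z)``.  ``tier`` is the branching generation
    (0 = root trunk)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_px: float
    tier: int


@dataclass(frozen=True)
class VesselTree:
    """A connected branching tree above the ILM plane.

    ``perfused`` holds one flag per segment; the structural scaffold is
    the full segment list regardless of perfusion state.
    """

    segments: tuple[Segment, ...]
    root_anchor: tuple[float, float, float]
    perfused: tuple[bool, ...]
    ilm_z: int

    def __post_init__(self) -> None:
        if len(self.perfused) != len(self.segments):
            raise ParameterError("one perfusion flag per segment required")
        for seg in self.segments:
            if seg.radius_px <= 0:
                raise ParameterError("segment radii must be positive")
            if seg.start[2] < self.ilm_z or seg.end[2] < self.ilm_z:
                raise GeometryError(
                    "segment endpoints must lie at or above the ILM plane"
                )

    @property
    def n_perfused(self) -> int:
        return int(np.sum(self.perfused))


def _default_schedule(recurrence: bool, recurrence_week: int) -> dict[int, float]:
    # Regression under an initial block of monthly injections
    # (weeks 0/4/8), measured at baseline, in-block, posttreatment and
    # late follow-up.  With recurrence, perfusion climbs back after the
    # treatment-free interval.
    sched = {0: 1.0, 4: 0.7, 8: 0.45, 13: 0.3, 17: 0.2}
    if recurrence:
        sched[recurrence_week] = 0.6
        sched[recurrence_week + 9] = 0.85
    else:
        sched[45] = 0.2
    return sched


@dataclass(frozen=True)
class SynthParams:
    """Conditions of one simulated NV case.

    Grid and spacing defaults correspond to a 3 x 3 mm scan pattern
    sampled at 256 x 256 lateral pixels (11.7 um/px) with 128 axial
    voxels at 2 um/px.  ``perfusion_schedule`` maps visit week to the
    fraction of non-root segments still perfused (1 = fully perfused
    baseline, 0 = only the residual truncated root arc).
    """

    nx: int = 256
    ny: int = 256
    nz: int = 128
    lateral_spacing_mm: float = 0.0117
    axial_spacing_um: float = 2.0
    depth: int = 5
    branch_angle_deg: float = 40.0
    noise_level: float = 0.08
    perfusion_schedule: dict[int, float] | None = None
    recurrence: bool = False
    recurrence_week: int = 32
    seed: int = 0
    ilm_z: int = 32

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) <= 0:
            raise ParameterError("grid dimensions must be positive")
        if self.depth < 1:
            raise ParameterError("branching depth must be >= 1")
        if self.lateral_spacing_mm <= 0 or self.axial_spacing_um <= 0:
            raise ParameterError("pixel spacings must be positive")
        if not 0 <= self.ilm_z < self.nz:
            raise ParameterError("ilm_z must lie inside the axial range")
        if self.perfusion_schedule is None:
            object.__setattr__(
                self,
                "perfusion_schedule",
                _default_schedule(self.recurrence, self.recurrence_week),
            )
        for week, frac in self.perfusion_schedule.items():
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(
                    f"perfusion fraction {frac} at week {week} outside [0, 1]"
                )

    @property
    def visit_weeks(self) -> tuple[int, ...]:
        return tuple(sorted(self.perfusion_schedule))


@dataclass(frozen=True)
class OctaVolume:
    """Paired structure/flow volumes with ground-truth voxel masks.

    ``structure`` holds reflectivity and ``flow`` decorrelation, both in
    [0, 1] and indexed ``[y, x, z]``.  ``ilm_z`` gives the per-(y, x)
    axial index of the ILM.  ``truth_structure``/``truth_flow`` are the
    noise-free rasterized vessel masks (scaffold and perfused subset).
    """

    structure: np.ndarray
    flow: np.ndarray
    ilm_z: np.ndarray
    lateral_spacing_mm: float
    axial_spacing_um: float
    truth_structure: np.ndarray | None = None
    truth_flow: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure.shape != self.flow.shape:
            raise ParameterError("structure and flow channels must match")
        nz = self.structure.shape[2]
        if np.any(self.ilm_z < 0) or np.any(self.ilm_z >= nz):
            raise ParameterError("ilm_z indices outside the axial range")


def generate_vessel_tree(params: SynthParams) -> VesselTree:
    """Grow a fan-like branching tree anchored on the ILM.

    A root trunk rises from the anchor a few voxels into the vitreous;
    each tip then splits into two daughters whose directions spread
    laterally within ``branch_angle_deg`` of the parent, with decaying
    length and caliber, producing the dense interlaced fan of an active
    NV.  Deterministic for a fixed seed; total segment count is
    ``2**depth - 1``.
    """
    rng = np.random.default_rng(params.seed)
    margin = 3.0
    anchor = (params.nx / 2.0, params.ny / 2.0, float(params.ilm_z))
    elev = min(6.0, params.nz - params.ilm_z - margin)
    root_len = 0.10 * min(params.nx, params.ny)
    root_dir = np.array([1.0, 0.0, 0.0])
    z_top = params.nz - 1 - margin

    def clamp(pt: np.ndarray) -> tuple[float, float, float]:
        x = float(np.clip(pt[0], margin, params.nx - 1 - margin))
        y = float(np.clip(pt[1], margin, params.ny - 1 - margin))
        z = float(np.clip(pt[2], params.ilm_z, z_top))
        return (x, y, z)

    root_end = clamp(
        np.array(anchor) + root_len * root_dir + np.array([0.0, 0.0, elev])
    )
    segments: list[Segment] = [Segment(anchor, root_end, 2.5, 0)]
    tips: list[tuple[tuple[float, float, float], np.ndarray, float, float]] = [
        (root_end, root_dir, root_len, 2.5)
    ]
    spread = np.deg2rad(params.branch_angle_deg)
    for tier in range(1, params.depth):
        new_tips = []
        for pos, direction, length, radius in tips:
            theta0 = np.arctan2(direction[1], direction[0])
            for sign in (-1.0, 1.0):
                theta = theta0 + sign * spread * rng.uniform(0.4, 1.0)
                dz = rng.uniform(0.0, 0.6)  # drift toward the vitreous
                d = np.array([np.cos(theta), np.sin(theta), dz])
                d /= np.linalg.norm(d)
                clen = length * rng.uniform(0.7, 0.9)
                crad = max(0.8, radius * 0.75)
                end = clamp(np.asarray(pos) + clen * d)
                segments.append(Segment(pos, end, crad, tier))
                new_tips.append((end, d, clen, crad))
        tips = new_tips
    return VesselTree(
        segments=tuple(segments),
        root_anchor=anchor,
        perfused=tuple(True for _ in segments),
        ilm_z=params.ilm_z,
    )


def _perfusion_for_week(params: SynthParams, visit_week: int) -> float:
    if visit_week not in params.perfusion_schedule:
        raise ScheduleError(
            f"week {visit_week} not in schedule {sorted(params.perfusion_schedule)}"
        )
    frac = params.perfusion_schedule[visit_week]
    if params.recurrence and visit_week >= params.recurrence_week:
        # Reperfusion of the persisting scaffold after the
        # treatment-free interval: never below the scheduled floor.
        frac = max(frac, params.perfusion_schedule.get(params.recurrence_week, frac))
    return frac


def apply_treatment_schedule(
    tree: VesselTree, params: SynthParams, visit_week: int
) -> VesselTree:
    """Perfusion state of the tree at one visit.

    The structural scaffold is never deleted; only ``perfused`` flags
    change.  Distal tiers lose perfusion first, so at fraction 0 only
    the root tier — the residual truncated arc seen after regression —
    still carries flow.  Perfused sets at different fractions are nested
    (a prefix in the fixed proximal-to-distal order), so a monotone
    schedule gives monotone perfused-voxel counts.
    """
    frac = _perfusion_for_week(params, visit_week)
    order = sorted(
        range(len(tree.segments)),
        key=lambda i: (tree.segments[i].tier, i),
    )
    n_root = sum(1 for s in tree.segments if s.tier == 0)
    n_rest = len(tree.segments) - n_root
    n_keep = n_root + int(round(frac * n_rest))
    flags = [False] * len(tree.segments)
    for i in order[:n_keep]:
        flags[i] = True
    return replace(tree, perfused=tuple(flags))


def _rasterize_segments(
    segments: list[Segment], shape: tuple[int, int, int]
) -> np.ndarray:
    """Union of capsule voxel sets: voxel centers within ``radius_px``
    of a segment's line, computed per segment on its bounding box."""
    ny, nx, nz = shape
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        a = np.array(seg.start, dtype=float)  # (x, y, z)
        b = np.array(seg.end, dtype=float)
        r = seg.radius_px
        lo = np.floor(np.minimum(a, b) - r).astype(int)
        hi = np.ceil(np.maximum(a, b) + r).astype(int) + 1
        x0, y0, z0 = np.maximum(lo, 0)
        x1 = min(hi[0], nx)
        y1 = min(hi[1], ny)
        z1 = min(hi[2], nz)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        ys, xs, zs = np.meshgrid(
            np.arange(y0, y1), np.arange(x0, x1), np.arange(z0, z1),
            indexing="ij",
        )
        pts = np.stack([xs, ys, zs], axis=-1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros(pts.shape[:-1])
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((pts - closest) ** 2, axis=-1)
        mask[y0:y1, x0:x1, z0:z1] |= d2 <= r * r
    return mask


_VESSEL_REFLECTIVITY = 0.9
_RETINA_REFLECTIVITY = 0.45
_VITREOUS_REFLECTIVITY = 0.03
_FLOW_SIGNAL = 0.9


def render_volume(tree: VesselTree, params: SynthParams) -> OctaVolume:
    """Rasterize a tree into structure and flow channels.

    The structure channel shows the retina below the ILM, dim vitreous
    above it, and *all* segments (the scaffold) at vessel reflectivity;
    the flow channel is nonzero only along perfused segments.  With
    ``noise_level > 0``, multiplicative Rayleigh speckle (unit mean) is
    applied to structure and clipped additive Gaussian noise to flow.
    Ground-truth voxel masks are retained on the returned volume.
    """
    shape = (params.ny, params.nx, params.nz)
    for seg in tree.segments:
        for pt in (seg.start, seg.end):
            if not (
                0 <= pt[0] < params.nx
                and 0 <= pt[1] < params.ny
                and 0 <= pt[2] < params.nz
            ):
                raise GeometryError(f"segment endpoint {pt} outside grid")
    struct_mask = _rasterize_segments(list(tree.segments), shape)
    perf_segs = [s for s, p in zip(tree.segments, tree.perfused) if p]
    flow_mask = _rasterize_segments(perf_segs, shape)

    zs = np.arange(params.nz)[None, None, :]
    structure = np.where(
        zs < params.ilm_z, _RETINA_REFLECTIVITY, _VITREOUS_REFLECTIVITY
    ) * np.ones(shape)
    structure[struct_mask] = _VESSEL_REFLECTIVITY
    flow = np.zeros(shape)
    flow[flow_mask] = _FLOW_SIGNAL

    if params.noise_level > 0:
        rng = np.random.default_rng([params.seed, 1, tree.n_perfused])
        # Rayleigh factor scaled to unit mean; deviation damped by level.
        ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
        structure = structure * (1.0 + params.noise_level * (ray - 1.0))
        flow = flow + rng.normal(0.0, params.noise_level, size=shape)
    structure = np.clip(structure, 0.0, 1.0)
    flow = np.clip(flow, 0.0, 1.0)

    ilm = np.full((params.ny, params.nx), params.ilm_z, dtype=int)
    return OctaVolume(
        structure=structure,
        flow=flow,
        ilm_z=ilm,
        lateral_spacing_mm=params.lateral_spacing_mm,
        axial_spacing_um=params.axial_spacing_um,
        truth_structure=struct_mask,
        truth_flow=flow_mask,
    )


@dataclass(frozen=True)
class SimulatedCase:
    """One NV followed over the visits of the perfusion schedule."""

    params: SynthParams
    weeks: tuple[int, ...]
    trees: tuple[VesselTree, ...]
    volumes: tuple[OctaVolume, ...]
    injection_weeks: tuple[int, ...]


def simulate_case(
    params: SynthParams,
    injection_weeks: tuple[int, ...] = (0, 4, 8),
) -> SimulatedCase:
    """Run the full simulation: one tree, one visit per schedule week."""
    base = generate_vessel_tree(params)
    weeks = params.visit_weeks
    trees = tuple(
        apply_treatment_schedule(base, params, wk) for wk in weeks
    )
    volumes = tuple(render_volume(t, params) for t in trees)
    return SimulatedCase(
        params=params,
        weeks=weeks,
        trees=trees,
        volumes=volumes,
        injection_weeks=tuple(injection_weeks),
    )


def shoelace_area(vertices: np.ndarray) -> float:
    """Area of a closed polygon from its (x, y) vertex list."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _hull_polygon(mask: np.ndarray) -> np.ndarray:
    """Convex-hull outline of a 2-D pixel mask as (x, y) vertices.

    The hull emulates a rater outlining the lesion envelope; hulls of
    nested masks are nested, so regressing flow gives non-increasing
    delineated areas.  Hull vertices are pushed half a pixel outward so
    boundary pixel centers are strictly inside.
    """
    from scipy.spatial import ConvexHull

    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise GeometryError("mask too small to outline")
    pts = np.column_stack([xs, ys]).astype(float)
    # Expand each pixel to its four corners so the hull encloses the
    # full pixel footprint.
    corners = np.concatenate(
        [pts + [dx, dy] for dx in (-0.5, 0.5) for dy in (-0.5, 0.5)]
    )
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def export_case(case: SimulatedCase, outdir: str | Path) -> dict[str, list[Path]]:
    """Write a simulated case as the file set the pipeline consumes.

    Per visit: 16-bit grayscale en face angio and structure TIFFs
    (maximum intensity projection over the slab from the ILM to the top
    of the volume), an 8-bit RGB B-scan through the root anchor with
    the flow overlay in red, ground-truth ROI polygons (JSON dialect)
    for the angio and structure planes plus the B-scan, and an ILM
    polyline CSV.  A ``truth.csv`` records, per visit, the delineated
    areas (polygon shoelace area times pixel spacing squared) and the
    true perfused fraction inside the structure outline; ``meta.json``
    and ``injections.csv`` carry spacings and the treatment schedule.
    """
    import pandas as pd
    import tifffile

    from .enface import mip_projection, polygon_to_mask, RoiPolygon

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = case.params
    files: dict[str, list[Path]] = {
        "angio": [], "structure": [], "bscan": [], "roi": [], "ilm": []
    }
    truth_rows = []
    y_slice = int(round(params.ny / 2.0))
    px_mm = params.lateral_spacing_mm

    for week, tree, vol in zip(case.weeks, case.trees, case.volumes):
        pair = mip_projection(vol)
        stem = outdir / f"visit_{week:03d}"
        p_angio = stem.with_name(stem.name + "_angio.tiff")
        p_struct = stem.with_name(stem.name + "_structure.tiff")
        tifffile.imwrite(
            p_angio, np.round(pair.angio.data * 65535.0).astype(np.uint16)
        )
        tifffile.imwrite(
            p_struct, np.round(pair.structure.data * 65535.0).astype(np.uint16)
        )
        files["angio"].append(p_angio)
        files["structure"].append(p_struct)

        # En face ground-truth outlines from the noise-free masks.
        struct_proj = vol.truth_structure.any(axis=2)
        flow_proj = vol.truth_flow.any(axis=2)
        poly_struct = _hull_polygon(struct_proj)
        poly_angio = _hull_polygon(flow_proj)
        for plane, poly in (("angio", poly_angio), ("structure", poly_struct)):
            p_roi = stem.with_name(stem.name + f"_roi_{plane}.json")
            p_roi.write_text(
                json.dumps(
                    {"plane": plane, "vertices": poly.tolist()}, indent=1
                )
            )
            files["roi"].append(p_roi)

        # B-scan through the root anchor: rows are axial with the
        # vitreous at the top (row 0), columns are x.
        sl_struct = vol.structure[y_slice]          # (nx, nz)
        sl_flow = vol.flow[y_slice]
        gray = np.round(255.0 * sl_struct.T[::-1]).astype(np.uint8)  # (nz, nx)
        flow_img = sl_flow.T[::-1]
        rgb = np.stack([gray, gray, gray], axis=-1)
        rgb[..., 0] = np.clip(
            gray.astype(int) + np.round(255.0 * flow_img).astype(int), 0, 255
        ).astype(np.uint8)
        p_bscan = stem.with_name(stem.name + "_bscan.tiff")
        tifffile.imwrite(p_bscan, rgb)
        files["bscan"].append(p_bscan)

        # ILM polyline in B-scan image coordinates and the cross-section
        # ROI (hull of the scaffold slice, kept above the ILM).
        ilm_rows = params.nz - 1 - vol.ilm_z[y_slice]
        p_ilm = stem.with_name(stem.name + "_ilm.csv")
        pd.DataFrame(
            {"column_index": np.arange(params.nx), "axial_row": ilm_rows}
        ).to_csv(p_ilm, index=False)
        files["ilm"].append(p_ilm)
        sl_mask = vol.truth_structure[y_slice].T[::-1]  # (nz rows, nx cols)
        # The delineation is bounded below by the ILM: drop the part of
        # the root capsule that dips beneath its on-ILM anchor.
        row_idx = np.arange(sl_mask.shape[0])[:, None]
        sl_mask = sl_mask & (row_idx <= ilm_rows[None, :])
        if sl_mask.sum() >= 3:
            poly_bscan = _hull_polygon(sl_mask)
            p_roib = stem.with_name(stem.name + "_roi_bscan.json")
            p_roib.write_text(
                json.dumps(
                    {"plane": "bscan", "vertices": poly_bscan.tolist()},
                    indent=1,
                )
            )
            files["roi"].append(p_roib)

        # Truth: areas from the exported polygons (shoelace), perfused
        # fraction relative to the structure outline's pixel mask.
        shape2d = (params.ny, params.nx)
        m_struct = polygon_to_mask(
            RoiPolygon(vertices=poly_struct, plane="structure"), shape2d
        )
        perfused_px = int(np.count_nonzero(flow_proj & m_struct))
        truth_rows.append(
            {
                "visit_week": week,
                "true_structure_area_mm2": shoelace_area(poly_struct) * px_mm**2,
                "true_angio_area_mm2": shoelace_area(poly_angio) * px_mm**2,
                "true_perfused_fraction": 100.0
                * perfused_px
                / int(np.count_nonzero(m_struct)),
            }
        )

    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(
        {"nv_id": "sim", "injection_week": list(case.injection_weeks)}
    ).to_csv(outdir / "injections.csv", index=False)
    (outdir / "meta.json").write_text(
        json.dumps(
            {
                "nv_id": "sim",
                "lateral_spacing_mm": params.lateral_spacing_mm,
                "axial_spacing_um": params.axial_spacing_um,
                "seed": params.seed,
                "weeks": list(case.weeks),
            },
            indent=1,
        )
    )
    return files
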