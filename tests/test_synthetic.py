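"""Vessel-tree generation, treatment schedules, rendering, export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from octanv.exceptions import GeometryError, ParameterError, ScheduleError
from octanv.synthetic import (
    Segment,
    SynthParams,
    VesselTree,
    apply_treatment_schedule,
    export_case,
    generate_vessel_tree,
    render_volume,
    shoelace_area,
    simulate_case,
)

SMALL = dict(nx=96, ny=96, nz=64, ilm_z=16, noise_level=0.0)


def capsule_voxels(seg: Segment, shape) -> set[tuple[int, int, int]]:
    """Independent exhaustive rasterization of one segment (scalar
    point-to-segment distance over every voxel of the grid)."""
    ny, nx, nz = shape
    ax, ay, az = seg.start
    bx, by, bz = seg.end
    ux, uy, uz = bx - ax, by - ay, bz - az
    denom = ux * ux + uy * uy + uz * uz
    r2 = seg.radius_px**2
    out = set()
    for y in range(ny):
        for x in range(nx):
            for z in range(nz):
                t = 0.0
                if denom > 0:
                    t = ((x - ax) * ux + (y - ay) * uy + (z - az) * uz) / denom
                    t = min(1.0, max(0.0, t))
                dx = x - ax - t * ux
                dy = y - ay - t * uy
                dz = z - az - t * uz
                if dx * dx + dy * dy + dz * dz <= r2:
                    out.add((y, x, z))
    return out


class TestGenerateVesselTree:
    def test_depth_one_gives_single_perfused_root(self):
        tree = generate_vessel_tree(SynthParams(depth=1, **SMALL))
        assert len(tree.segments) == 1
        assert tree.segments[0].tier == 0
        assert tree.perfused == (True,)

    def test_fixed_seed_is_deterministic(self):
        p = SynthParams(depth=4, seed=11, **SMALL)
        t1 = generate_vessel_tree(p)
        t2 = generate_vessel_tree(p)
        assert t1.segments == t2.segments

    def test_segment_count_grows_with_depth(self):
        for depth in (2, 3, 5):
            tree = generate_vessel_tree(SynthParams(depth=depth, **SMALL))
            assert len(tree.segments) >= 2 ** (depth - 1)

    def test_all_endpoints_above_ilm_by_exhaustive_scan(self):
        p = SynthParams(depth=4, branch_angle_deg=40.0, seed=3, **SMALL)
        tree = generate_vessel_tree(p)
        for seg in tree.segments:
            assert seg.start[2] >= p.ilm_z
            assert seg.end[2] >= p.ilm_z

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            SynthParams(depth=0, **SMALL)
        with pytest.raises(ParameterError):
            SynthParams(nx=-5)
        with pytest.raises(ParameterError):
            SynthParams(lateral_spacing_mm=0.0)


class TestTreatmentSchedule:
    @pytest.fixture()
    def tree_and_params(self):
        p = SynthParams(
            depth=4, seed=5,
            perfusion_schedule={0: 1.0, 4: 0.4, 8: 0.9, 12: 0.0},
            **SMALL,
        )
        return generate_vessel_tree(p), p

    def test_fraction_one_perfuses_everything(self, tree_and_params):
        tree, p = tree_and_params
        assert all(apply_treatment_schedule(tree, p, 0).perfused)

    def test_fraction_zero_leaves_only_root_arc(self, tree_and_params):
        tree, p = tree_and_params
        pruned = apply_treatment_schedule(tree, p, 12)
        for seg, perf in zip(pruned.segments, pruned.perfused):
            assert perf == (seg.tier == 0)

    def test_counts_follow_fraction_sequence(self, tree_and_params):
        # 1.0 -> 0.4 -> 0.9: perfused count decreases then increases.
        tree, p = tree_and_params
        counts = [
            apply_treatment_schedule(tree, p, wk).n_perfused
            for wk in (0, 4, 8)
        ]
        assert counts[0] > counts[1] < counts[2]

    def test_structural_scaffold_never_deleted(self, tree_and_params):
        tree, p = tree_and_params
        for wk in (0, 4, 8, 12):
            assert apply_treatment_schedule(tree, p, wk).segments == tree.segments

    def test_unknown_week_rejected(self, tree_and_params):
        tree, p = tree_and_params
        with pytest.raises(ScheduleError):
            apply_treatment_schedule(tree, p, 99)

    def test_monotone_schedule_gives_monotone_counts(self):
        p = SynthParams(
            depth=5, seed=2,
            perfusion_schedule={0: 1.0, 4: 0.7, 8: 0.45, 13: 0.3, 17: 0.2},
            **SMALL,
        )
        tree = generate_vessel_tree(p)
        counts = [
            apply_treatment_schedule(tree, p, wk).n_perfused
            for wk in p.visit_weeks
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recurrence_raises_fraction_after_recurrence_week(self):
        p = SynthParams(
            depth=4, seed=9, recurrence=True, recurrence_week=32,
            perfusion_schedule=None, **SMALL,
        )
        tree = generate_vessel_tree(p)
        n_post = apply_treatment_schedule(tree, p, 17).n_perfused
        n_rec = apply_treatment_schedule(tree, p, 32).n_perfused
        assert n_rec > n_post


class TestRenderVolume:
    def test_flow_exactly_on_perfused_segment_voxels(self):
        p = SynthParams(depth=1, seed=7, nx=48, ny=48, nz=40, ilm_z=10,
                        noise_level=0.0)
        tree = generate_vessel_tree(p)
        vol = render_volume(tree, p)
        got = set(map(tuple, np.argwhere(vol.flow > 0)))
        expected = capsule_voxels(tree.segments[0], vol.flow.shape)
        assert got == expected

    def test_no_perfusion_means_zero_flow(self):
        p = SynthParams(depth=3, seed=7, **SMALL)
        tree = generate_vessel_tree(p)
        dead = VesselTree(
            segments=tree.segments,
            root_anchor=tree.root_anchor,
            perfused=tuple(False for _ in tree.segments),
            ilm_z=tree.ilm_z,
        )
        assert not render_volume(dead, p).flow.any()

    def test_same_seed_identical_arrays(self):
        p = SynthParams(depth=3, seed=13, nx=96, ny=96, nz=64, ilm_z=16,
                        noise_level=0.1)
        tree = generate_vessel_tree(p)
        v1 = render_volume(tree, p)
        v2 = render_volume(tree, p)
        np.testing.assert_array_equal(v1.structure, v2.structure)
        np.testing.assert_array_equal(v1.flow, v2.flow)

    def test_perfused_voxels_subset_of_scaffold(self, regression_case):
        for vol in regression_case.volumes:
            assert not (vol.truth_flow & ~vol.truth_structure).any()

    def test_scaffold_constant_across_visits(self, regression_case):
        first = regression_case.volumes[0].truth_structure
        for vol in regression_case.volumes[1:]:
            np.testing.assert_array_equal(vol.truth_structure, first)

    def test_perfused_count_non_increasing_without_recurrence(
        self, regression_case
    ):
        counts = [v.truth_flow.sum() for v in regression_case.volumes]
        assert counts == sorted(counts, reverse=True)

    def test_out_of_grid_tree_rejected(self):
        p = SynthParams(depth=1, **SMALL)
        seg = Segment((10, 10, 20), (200, 10, 20), 2.0, 0)
        tree = VesselTree((seg,), (10, 10, 20), (True,), ilm_z=16)
        with pytest.raises(GeometryError):
            render_volume(tree, p)


def loop_shoelace(verts) -> float:
    total = 0.0
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        total += x1 * y2 - x2 * y1
    return abs(total) / 2.0


class TestExportCase:
    def test_file_set_complete(self, regression_case, exported_case):
        n = len(regression_case.weeks)
        for pattern, count in [
            ("visit_*_angio.tiff", n),
            ("visit_*_structure.tiff", n),
            ("visit_*_bscan.tiff", n),
            ("visit_*_roi_angio.json", n),
            ("visit_*_roi_structure.json", n),
            ("truth.csv", 1),
            ("injections.csv", 1),
        ]:
            assert len(list(exported_case.glob(pattern))) == count

    def test_tiff_round_trip_equals_projection(
        self, regression_case, exported_case
    ):
        import tifffile

        from octanv.enface import mip_projection

        week = regression_case.weeks[0]
        arr = tifffile.imread(exported_case / f"visit_{week:03d}_angio.tiff")
        pair = mip_projection(regression_case.volumes[0])
        expected = np.round(pair.angio.data * 65535).astype(np.uint16)
        np.testing.assert_array_equal(arr, expected)

    def test_truth_areas_match_shoelace_oracle(self, exported_case):
        import json

        truth = pd.read_csv(exported_case / "truth.csv")
        spacing = json.loads(
            (exported_case / "meta.json").read_text()
        )["lateral_spacing_mm"]
        for _, row in truth.iterrows():
            week = int(row.visit_week)
            for plane, col in (
                ("structure", "true_structure_area_mm2"),
                ("angio", "true_angio_area_mm2"),
            ):
                payload = json.loads(
                    (exported_case / f"visit_{week:03d}_roi_{plane}.json")
                    .read_text()
                )
                oracle = loop_shoelace(payload["vertices"]) * spacing**2
                assert row[col] == pytest.approx(oracle, rel=1e-12)

    def test_export_bit_reproducible(self, tmp_path):
        p = SynthParams(nx=64, ny=64, nz=48, ilm_z=12, depth=3,
                        noise_level=0.05, seed=21,
                        perfusion_schedule={0: 1.0, 13: 0.3})
        d1, d2 = tmp_path / "a", tmp_path / "b"
        export_case(simulate_case(p), d1)
        export_case(simulate_case(p), d2)
        files1 = sorted(f.name for f in d1.iterdir())
        assert files1 == sorted(f.name for f in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_shoelace_matches_loop_on_random_polygons(self, rng):
        for _ in range(5):
            verts = rng.random((6, 2)) * 50
            assert shoelace_area(verts) == pytest.approx(
                loop_shoelace(verts)
            )
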