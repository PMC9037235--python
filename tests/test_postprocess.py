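"""Macro pipeline: channel splitting, hole filling, watershed instance
separation, measurement and filtering — each against brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from pitcount.postprocess import (
    STATUS_EDGE,
    STATUS_INCLUDED,
    STATUS_SIZE,
    STATUS_SOLIDITY,
    ObjectTable,
    PostprocessConfig,
    apply_filters,
    fill_holes,
    measure_cells,
    pixel_solidity,
    run_macro,
    separate_cells,
    split_channels,
)
from pitcount.simulate import sample_scene, scene_truth_stats
from pitcount.types import CELL, PIT, LabelMap

from _oracles import flood_fill_holes, priority_flood_regions, solidity_oracle
from conftest import SMALL_PX, small_scene_config


def _disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestSplitChannels:
    def test_empty_map(self):
        cell, pit = split_channels(LabelMap(np.zeros((16, 16), dtype=np.uint8)))
        assert not cell.any() and not pit.any()

    def test_pit_is_part_of_cell(self):
        codes = np.zeros((32, 32), dtype=np.uint8)
        codes[8:24, 8:24] = CELL
        codes[14:18, 14:18] = PIT
        cell, pit = split_channels(LabelMap(codes))
        assert cell[14:18, 14:18].all()
        assert (cell == (codes > 0)).all()

    def test_matches_per_pixel_scan(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(24, 24)).astype(np.uint8)
        cell, pit = split_channels(LabelMap(codes))
        for r in range(24):
            for c in range(24):
                assert pit[r, c] == (codes[r, c] == 2)
                assert cell[r, c] == (codes[r, c] in (1, 2))


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        mask = _disk_mask((64, 64), (32, 32), 20)
        assert np.array_equal(fill_holes(mask), mask)

    def test_annulus_becomes_disk(self):
        outer = _disk_mask((64, 64), (32, 32), 20)
        inner = _disk_mask((64, 64), (32, 32), 10)
        assert np.array_equal(fill_holes(outer & ~inner), outer)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(10)
        mask = ndimage.binary_dilation(rng.random((48, 48)) > 0.75, iterations=2)
        assert np.array_equal(fill_holes(mask), flood_fill_holes(mask))


class TestSeparateCells:
    def test_single_disk_one_instance(self):
        labels = separate_cells(_disk_mask((64, 64), (32, 32), 20))
        assert labels.max() == 1
        assert (labels > 0).sum() == _disk_mask((64, 64), (32, 32), 20).sum()

    def test_two_tangent_disks_split_matches_oracle(self):
        shape = (96, 128)
        a = _disk_mask(shape, (48, 44), 20)
        b = _disk_mask(shape, (48, 84), 20)
        mask = a | b
        labels = separate_cells(mask)
        ids = sorted(set(labels.ravel()) - {0})
        assert len(ids) == 2
        one_disk = float(a.sum())
        for i in ids:
            assert (labels == i).sum() == pytest.approx(one_disk, rel=0.05)
        oracle = priority_flood_regions(mask, [(48, 44), (48, 84)])
        # identical up to label permutation except possibly ridge ties
        best = max(
            np.mean((labels == ids[0]) == (oracle == k)) for k in (1, 2)
        )
        agreement = max(
            best,
            np.mean((labels[mask] == ids[0]) == (oracle[mask] == 1)),
            np.mean((labels[mask] == ids[0]) == (oracle[mask] == 2)),
        )
        assert agreement >= 0.99

    def test_instances_bounded_by_retained_peaks(self):
        rng = np.random.default_rng(4)
        mask = ndimage.binary_dilation(rng.random((64, 64)) > 0.9, iterations=3)
        cfg = PostprocessConfig()
        dist = ndimage.distance_transform_edt(mask)
        from skimage.morphology import h_maxima

        peaks = h_maxima(dist, cfg.watershed_h, footprint=np.ones((3, 3), bool))
        _, n_peaks = ndimage.label(peaks, structure=np.ones((3, 3)))
        n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
        labels = separate_cells(mask, cfg)
        # every component is seeded even if its peaks were suppressed
        assert labels.max() <= max(n_peaks, n_comp) + n_comp
        assert ((labels > 0) == mask).all()

    def test_partition_conserves_pixels(self, small_scene):
        cell, _ = split_channels(small_scene.truth_label_map)
        labels = separate_cells(fill_holes(cell))
        areas = [(labels == i).sum() for i in range(1, labels.max() + 1)]
        assert sum(areas) == fill_holes(cell).sum()


class TestMeasureCells:
    def test_two_pit_components_counted(self):
        shape = (64, 64)
        labels = _disk_mask(shape, (32, 32), 20).astype(np.int32)
        pit = np.zeros(shape, dtype=bool)
        pit[30, 25:28] = True
        pit[35, 36:39] = True
        cfg = PostprocessConfig(min_pit_area_px=1)
        table = measure_cells(labels, pit, SMALL_PX, cfg)
        assert len(table) == 1
        assert table.records[0].pit_count == 2
        assert table.records[0].pit_area_sum_um2 == pytest.approx(6 * SMALL_PX**2)

    def test_plus_shape_solidity_matches_hull_oracle(self):
        shape = (48, 48)
        mask = np.zeros(shape, dtype=bool)
        mask[16:32, 21:27] = True
        mask[21:27, 16:32] = True
        rows, cols = np.nonzero(mask)
        sol = pixel_solidity(rows, cols)
        assert sol == pytest.approx(solidity_oracle(rows, cols), abs=1e-9)
        assert sol < 0.9

    @pytest.mark.parametrize("fixture", ["disk", "square", "diamond", "ell"])
    def test_solidity_fixtures_match_oracle(self, fixture):
        shape = (40, 40)
        mask = np.zeros(shape, dtype=bool)
        if fixture == "disk":
            mask = _disk_mask(shape, (20, 20), 12)
        elif fixture == "square":
            mask[10:30, 10:30] = True
        elif fixture == "diamond":
            rr, cc = np.mgrid[:40, :40]
            mask = np.abs(rr - 20) + np.abs(cc - 20) <= 10
        else:
            mask[5:35, 5:12] = True
            mask[28:35, 5:35] = True
        rows, cols = np.nonzero(mask)
        sol = pixel_solidity(rows, cols)
        assert sol == pytest.approx(solidity_oracle(rows, cols), abs=1e-9)
        assert sol <= 1.0 + 1e-9

    def test_edge_pixel_flags_touches_edge(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 0:10] = 1
        table = measure_cells(labels, np.zeros((32, 32), bool), SMALL_PX)
        assert table.records[0].touches_edge

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            measure_cells(np.zeros((16, 16), np.int32), np.zeros((16, 17), bool), SMALL_PX)

    def test_min_pit_area_gate(self):
        shape = (64, 64)
        labels = _disk_mask(shape, (32, 32), 20).astype(np.int32)
        pit = np.zeros(shape, dtype=bool)
        pit[30, 25:27] = True  # 2 px, below the default gate of 4
        pit[35:38, 36:39] = True  # 9 px
        table = measure_cells(labels, pit, SMALL_PX, PostprocessConfig())
        assert table.records[0].pit_count == 1


class TestApplyFilters:
    def _record_table(self, **overrides):
        from pitcount.postprocess import CellRecord

        base = dict(
            cell_id=1,
            area_um2=40.0,
            solidity=0.97,
            centroid=(10.0, 10.0),
            touches_edge=False,
            pit_count=0,
            pit_areas_um2=[],
        )
        base.update(overrides)
        return ObjectTable([CellRecord(**base)], "t", "", SMALL_PX)

    def test_wbc_sized_object_excluded_by_size(self):
        table = apply_filters(self._record_table(area_um2=120.0))
        assert table.records[0].status == STATUS_SIZE

    def test_low_solidity_aggregate_excluded(self):
        table = apply_filters(self._record_table(solidity=0.7))
        assert table.records[0].status == STATUS_SOLIDITY

    def test_precedence_size_before_edge_before_solidity(self):
        t = apply_filters(self._record_table(area_um2=5.0, touches_edge=True, solidity=0.5))
        assert t.records[0].status == STATUS_SIZE
        t = apply_filters(self._record_table(touches_edge=True, solidity=0.5))
        assert t.records[0].status == STATUS_EDGE

    def test_empty_table(self):
        out = apply_filters(ObjectTable([], "t", "", SMALL_PX))
        assert len(out) == 0

    def test_records_flagged_never_deleted(self, small_scene):
        table = run_macro(small_scene.truth_label_map, SMALL_PX)
        raw = measure_cells(
            separate_cells(fill_holes(split_channels(small_scene.truth_label_map)[0])),
            split_channels(small_scene.truth_label_map)[1],
            SMALL_PX,
        )
        assert len(table) == len(raw)

    def test_filter_monotonicity(self, small_scene):
        table = run_macro(small_scene.truth_label_map, SMALL_PX)
        n_included = []
        for min_sol in (0.5, 0.8, 0.9, 0.95, 0.99):
            cfg = PostprocessConfig(min_solidity=min_sol)
            n_included.append(len(apply_filters(table, cfg).included()))
        assert n_included == sorted(n_included, reverse=True)
        n_included = []
        for lo, hi in ((5.0, 200.0), (15.0, 100.0), (20.0, 80.0), (25.0, 50.0)):
            cfg = PostprocessConfig(min_cell_area_um2=lo, max_cell_area_um2=hi)
            n_included.append(len(apply_filters(table, cfg).included()))
        assert n_included == sorted(n_included, reverse=True)


class TestTruthPassthrough:
    def test_clean_scene_counts_reproduced_exactly(self):
        cfg = small_scene_config(n_cells=15, pitted_fraction=0.5, seed=33)
        scene = sample_scene(cfg)
        table = run_macro(scene.truth_label_map, cfg.pixel_size_um)
        truth = scene_truth_stats(scene)
        assert len(table.included()) == truth.n_rbc
        assert sorted(r.pit_count for r in table.included()) == sorted(
            scene.per_cell_pit_counts.values()
        )
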