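"""Manual masks, sensor assignment rules, the automatic 10-region scheme."""

import numpy as np
import pytest

from pedobar._geometry import FootprintError, footprint_cells
from pedobar.core import Mask, SensorGrid, Side
from pedobar.masking import (
    AUTOMASK_REGIONS,
    MaskingScheme,
    assign_sensors,
    create_mask_auto,
    create_mask_manual,
    edit_mask,
)
from pedobar.synthetic import FootModel, generate_footprint, generate_multistep, mirror_recording

from conftest import make_recording


def ray_cast_inside(point, verts):
    """Independent even-odd point-in-polygon oracle (boundary-exclusive)."""
    x, y = point
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y) and x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
            inside = not inside
    return inside


class TestManualMasks:
    def test_square_covering_four_centers(self, tiny_rec):
        # centers of tiny_rec sit at multiples of 5 mm
        square = np.array([[2.0, 2.0], [13.0, 2.0], [13.0, 13.0], [2.0, 13.0]])
        create_mask_manual(tiny_rec, [square], ["sq"])
        got = assign_sensors(tiny_rec.masks["sq"], tiny_rec.grid).cells
        oracle = {
            (r, c)
            for r in range(tiny_rec.grid.n_rows)
            for c in range(tiny_rec.grid.n_cols)
            if ray_cast_inside(tiny_rec.grid.centers[r, c], square)
        }
        assert got == oracle == {(1, 1), (1, 2), (2, 1), (2, 2)}

    def test_two_vertex_polygon_rejected(self, tiny_rec):
        with pytest.raises(ValueError):
            create_mask_manual(tiny_rec, [np.array([[0.0, 0.0], [5.0, 5.0]])], ["bad"])

    def test_explicit_sensor_set_is_identity(self, tiny_rec):
        create_mask_manual(tiny_rec, [[(0, 0), (0, 1)]], ["pair"])
        assert assign_sensors(tiny_rec.masks["pair"], tiny_rec.grid).cells == {(0, 0), (0, 1)}

    def test_duplicate_name_rejected(self, tiny_rec):
        create_mask_manual(tiny_rec, [[(0, 0)]], ["m"])
        with pytest.raises(ValueError, match="already exists"):
            create_mask_manual(tiny_rec, [[(0, 1)]], ["m"])


class TestCoverageRules:
    def test_fraction_one_on_cells_own_polygon(self, tiny_rec):
        quad = tiny_rec.grid.polygons[2, 1]
        mask = Mask(name="cell", polygon=quad, coverage_rule="fraction_ge", fraction=1.0)
        assert assign_sensors(mask, tiny_rec.grid).cells == {(2, 1)}

    @pytest.mark.parametrize("fraction,included", [(0.4, True), (0.6, False)])
    def test_half_covered_cell(self, tiny_rec, fraction, included):
        # rectangle covering exactly the left half of cell (1, 1):
        # cell spans x in [2.5, 7.5], so [2.5, 5.0] is covered fraction 0.5
        half = np.array([[2.5, 2.5], [5.0, 2.5], [5.0, 7.5], [2.5, 7.5]])
        mask = Mask(name="half", polygon=half, coverage_rule="fraction_ge", fraction=fraction)
        cells = assign_sensors(mask, tiny_rec.grid).cells
        assert ((1, 1) in cells) is included
        a = assign_sensors(
            Mask(name="h", polygon=half, coverage_rule="fraction_ge", fraction=0.0),
            tiny_rec.grid,
        )
        assert a.fractions[(1, 1)] == pytest.approx(0.5, abs=1e-12)

    def test_center_on_boundary_counts_inside(self, tiny_rec):
        # polygon edge passes exactly through center (1, 1) = (5, 5)
        tri = np.array([[5.0, 0.0], [5.0, 10.0], [15.0, 5.0]])
        mask = Mask(name="tri", polygon=tri, coverage_rule="center_in")
        assert (1, 1) in assign_sensors(mask, tiny_rec.grid).cells

    @pytest.mark.parametrize("shift", [(13.0, -7.0), (0.0, 100.0)])
    def test_assignment_invariant_under_translation(self, tiny_rec, shift):
        square = np.array([[2.0, 2.0], [13.0, 2.0], [13.0, 13.0], [2.0, 13.0]])
        base = assign_sensors(
            Mask(name="sq", polygon=square, coverage_rule="fraction_ge", fraction=0.5),
            tiny_rec.grid,
        )
        g = tiny_rec.grid
        moved = SensorGrid(
            g.centers + shift, g.polygons + shift, g.areas.copy(), g.active.copy()
        )
        shifted = assign_sensors(
            Mask(name="sq", polygon=square + shift, coverage_rule="fraction_ge", fraction=0.5),
            moved,
        )
        assert base.cells == shifted.cells

    def test_fraction_ge_monotone_in_threshold(self, tiny_rec):
        poly = np.array([[1.0, 1.0], [11.0, 3.0], [12.0, 12.0], [2.0, 9.0]])
        previous = None
        for f in np.linspace(0.0, 1.0, 11):
            cells = assign_sensors(
                Mask(name="p", polygon=poly, coverage_rule="fraction_ge", fraction=float(f)),
                tiny_rec.grid,
            ).cells
            if previous is not None:
                assert cells <= previous
            previous = cells


class TestAutomask:
    def test_exactly_ten_named_regions(self, barefoot):
        rec, _ = barefoot
        create_mask_auto(rec, "automask_novel", foot_side="auto")
        assert tuple(rec.masks) == AUTOMASK_REGIONS

    def test_regions_partition_active_footprint(self, barefoot):
        rec, _ = barefoot
        create_mask_auto(rec, "automask_novel", foot_side="auto")
        footprint = {tuple(rc) for rc in np.argwhere(footprint_cells(rec))}
        seen = set()
        for mask in rec.masks.values():
            assert seen.isdisjoint(mask.cells)
            seen |= mask.cells
        assert seen == footprint

    def test_all_zero_recording_raises_no_footprint(self):
        rec = make_recording(np.zeros((5, 8, 8)))
        with pytest.raises(FootprintError, match="no footprint"):
            create_mask_auto(rec, "automask_novel", foot_side="right")

    def test_site_cells_assigned_to_their_region(self, barefoot):
        rec, gt = barefoot
        create_mask_auto(rec, "automask_novel", foot_side="auto")
        for site, cells in gt.site_cells.items():
            region = rec.masks[gt.region_of_site[site]].cells
            assert len(cells & region) / len(cells) >= 0.9

    def test_mirrored_recording_gives_mirrored_masks(self, barefoot):
        rec, _ = barefoot
        create_mask_auto(rec, "automask_novel", foot_side="right")
        mirrored = mirror_recording(rec)
        create_mask_auto(mirrored, "automask_novel", foot_side="left")
        n_cols = rec.grid.n_cols
        for name in AUTOMASK_REGIONS:
            flipped = {(r, n_cols - 1 - c) for r, c in rec.masks[name].cells}
            assert mirrored.masks[name].cells == flipped

    def test_rotated_foot_same_region_sizes(self):
        sizes = {}
        for rot in (0.0, 9.0):
            rec, _ = generate_footprint(FootModel(), rotation_deg=rot, seed=5)
            create_mask_auto(rec, "automask_novel", foot_side="right")
            sizes[rot] = {n: len(m.cells) for n, m in rec.masks.items()}
        for name in AUTOMASK_REGIONS:
            assert sizes[0.0][name] == pytest.approx(sizes[9.0][name], abs=6)

    def test_unknown_scheme_rejected(self, barefoot):
        rec, _ = barefoot
        with pytest.raises(ValueError, match="unknown masking scheme"):
            create_mask_auto(rec, "automask_magic")

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MaskingScheme(longitudinal=(0.5, 0.25, 0.1, 0.1))


class TestPedarSchemes:
    @pytest.mark.parametrize(
        "scheme,n_regions", [("pedar_mask1", 3), ("pedar_mask2", 9), ("pedar_mask3", 10)]
    )
    def test_template_partitions_insole(self, scheme, n_regions):
        rec, _ = generate_multistep(FootModel(), n_steps=1, seed=5)
        create_mask_auto(rec, scheme, foot_side="right")
        assert len(rec.masks) == n_regions
        seen = set()
        for mask in rec.masks.values():
            assert seen.isdisjoint(mask.cells)
            seen |= mask.cells
        assert seen == {tuple(rc) for rc in np.argwhere(rec.grid.active)}


class TestEditMask:
    @pytest.fixture
    def poly_rec(self, tiny_rec):
        square = np.array([[2.0, 2.0], [8.0, 2.0], [8.0, 8.0], [2.0, 8.0]])
        return create_mask_manual(tiny_rec, [square], ["sq"])

    def test_move_and_move_back_restores_assignment(self, poly_rec):
        before = assign_sensors(poly_rec.masks["sq"], poly_rec.grid).cells
        edit_mask(poly_rec, "sq", [((8.0, 8.0), (9.0, 9.0))])
        edit_mask(poly_rec, "sq", [((9.0, 9.0), (8.0, 8.0))])
        assert assign_sensors(poly_rec.masks["sq"], poly_rec.grid).cells == before

    def test_enlarging_gains_exactly_the_new_center(self, poly_rec):
        before = assign_sensors(poly_rec.masks["sq"], poly_rec.grid).cells
        edit_mask(poly_rec, "sq", [((8.0, 8.0), (12.0, 12.0))])
        after = assign_sensors(poly_rec.masks["sq"], poly_rec.grid).cells
        assert after - before == {(2, 2)}
        # oracle: the gained center is inside the new polygon, not the old
        assert ray_cast_inside(poly_rec.grid.centers[2, 2], poly_rec.masks["sq"].polygon)

    def test_sensor_set_mask_rejected(self, tiny_rec):
        create_mask_manual(tiny_rec, [[(0, 0)]], ["cells"])
        with pytest.raises(ValueError, match="not polygon-defined"):
            edit_mask(tiny_rec, "cells", [((0.0, 0.0), (1.0, 1.0))])

    def test_unmatched_vertex_rejected(self, poly_rec):
        with pytest.raises(ValueError, match="within"):
            edit_mask(poly_rec, "sq", [((50.0, 50.0), (0.0, 0.0))])

    def test_missing_mask_rejected(self, poly_rec):
        with pytest.raises(KeyError):
            edit_mask(poly_rec, "nope", [((8.0, 8.0), (9.0, 9.0))])
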