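"""Terrain derivatives, flow routing, and the NULM landform cascade."""

import numpy as np
import pytest

from lcvmap.errors import ConfigurationError, InputError, ParameterError
from lcvmap.grids import Raster
from lcvmap.legends import LANDFORM_CODES, NULM_CODES, NULM_LEGEND
from lcvmap.terrain import (
    NEIGHBOR_OFFSETS,
    NulmThresholds,
    classify_nulm,
    compute_derivatives,
    compute_slope,
    fill_depressions,
    flow_partition,
    local_maxima,
    remap_landform,
    surface_curvature,
    upslope_contributing_area,
)


def d8_accumulation_oracle(dem: Raster) -> np.ndarray:
    """Brute-force D8 specific catchment area by walking every flow path.

    For every cell, follow its single steepest-descent pointer chain to the
    outlet, adding the cell's area to every cell strictly downstream; then
    add each cell's own area and divide by the cell size. Shares only the
    routing directions with the implementation; the accumulation itself is
    independent of the topological-order push.
    """
    flow = flow_partition(dem, method="d8", fill=False)
    rows, cols = dem.shape
    downstream = {}
    for r in range(rows):
        for c in range(cols):
            ks = np.nonzero(flow.fractions[:, r, c])[0]
            if ks.size:
                dr, dc = NEIGHBOR_OFFSETS[int(ks[0])]
                downstream[(r, c)] = (r + dr, c + dc)
    acc = np.full(dem.shape, dem.cell_area)
    for start in np.ndindex(rows, cols):
        cur = start
        while cur in downstream:
            cur = downstream[cur]
            acc[cur] += dem.cell_area
    return acc / dem.cell_size


class TestSlope:
    def test_constant_grid_is_flat(self):
        slope = compute_slope(Raster(np.full((5, 5), 3.0), cell_size=30.0))
        assert np.allclose(slope.values, 0.0)

    @pytest.mark.parametrize("rise,expected", [(1.0, 45.0), (2.0, 63.43494882)])
    def test_inclined_plane_closed_form(self, rise, expected):
        x = np.arange(6, dtype=float) * rise
        dem = Raster(np.tile(x, (6, 1)), cell_size=1.0)
        slope = compute_slope(dem)
        assert np.allclose(slope.values[1:-1, 1:-1], expected)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(InputError):
            compute_slope(Raster(np.ones((2, 5)), cell_size=1.0))


class TestFlowPartition:
    def test_d8_plane_single_steepest_neighbor(self, tilted_plane):
        flow = flow_partition(tilted_plane, method="d8", fill=False)
        inner = flow.fractions[:, 1:-1, 1:-1]
        # z rises with column, so everything goes due west (offset (0,-1))
        k_west = NEIGHBOR_OFFSETS.index((0, -1))
        assert np.allclose(inner[k_west], 1.0)
        assert np.allclose(np.delete(inner, k_west, axis=0), 0.0)

    def test_pit_has_zero_outflow(self):
        z = np.ones((3, 3))
        z[1, 1] = 0.0
        flow = flow_partition(Raster(z, cell_size=1.0), fill=False)
        assert flow.outflow_sum()[1, 1] == 0.0

    def test_mfd_symmetric_ridge_splits_evenly(self):
        z = np.array([[5.0, 5.0, 5.0], [4.0, 5.0, 4.0], [5.0, 5.0, 5.0]])
        flow = flow_partition(Raster(z, cell_size=1.0), method="mfd", fill=False)
        k_w = NEIGHBOR_OFFSETS.index((0, -1))
        k_e = NEIGHBOR_OFFSETS.index((0, 1))
        # equal drops to the two opposite lower neighbors: 0.5 / 0.5
        assert flow.fractions[k_w, 1, 1] == pytest.approx(0.5)
        assert flow.fractions[k_e, 1, 1] == pytest.approx(0.5)
        assert flow.outflow_sum()[1, 1] == pytest.approx(1.0)

    def test_fraction_invariants_on_island(self, island_dem):
        flow = flow_partition(island_dem, method="mfd")
        total = flow.outflow_sum()
        assert np.all(flow.fractions >= 0)
        assert np.all((np.isclose(total, 1.0)) | (total == 0.0))

    def test_unknown_method_rejected(self, tilted_plane):
        with pytest.raises(ParameterError):
            flow_partition(tilted_plane, method="d4")


class TestUpslopeArea:
    def test_no_inflow_cell_is_self_term_only(self):
        x = np.arange(6, dtype=float)
        dem = Raster(np.tile(-x, (6, 1)) * 10, cell_size=30.0)
        flow = flow_partition(dem, method="d8", fill=False)
        upa = upslope_contributing_area(dem, flow)
        # west column receives nothing: AS = A/b = 900/30
        assert np.allclose(upa.values[:, 0], 30.0)

    def test_bowl_border_drains_to_center(self):
        z = np.ones((3, 3))
        z[1, 1] = 0.0
        dem = Raster(z, cell_size=30.0)
        flow = flow_partition(dem, method="d8", fill=False)
        upa = upslope_contributing_area(dem, flow)
        assert upa.values[1, 1] == pytest.approx(9 * 900 / 30)

    def test_strictly_increasing_downstream_on_d8_path(self, cone_dem):
        flow = flow_partition(cone_dem, method="d8")
        upa = upslope_contributing_area(cone_dem, flow).values
        rows, cols = cone_dem.shape
        r, c = rows // 2, cols // 2
        seen = set()
        while (r, c) not in seen:
            seen.add((r, c))
            ks = np.nonzero(flow.fractions[:, r, c])[0]
            if not ks.size:
                break
            dr, dc = NEIGHBOR_OFFSETS[int(ks[0])]
            assert upa[r + dr, c + dc] > upa[r, c]
            r, c = r + dr, c + dc
        assert len(seen) > 3

    @pytest.mark.parametrize("seed", range(5))
    def test_d8_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dem = Raster(rng.uniform(0, 100, size=(6, 6)), cell_size=30.0)
        flow = flow_partition(dem, method="d8", fill=False)
        upa = upslope_contributing_area(dem, flow)
        assert np.allclose(upa.values, d8_accumulation_oracle(dem), atol=1e-9)

    def test_mfd_mass_conservation(self, island_dem):
        # every cell's area must reach an outlet exactly once
        flow = flow_partition(island_dem, method="mfd")
        upa = upslope_contributing_area(island_dem, flow)
        outlets = flow.outflow_sum() == 0.0
        total_out = (upa.values[outlets] * island_dem.cell_size).sum()
        total_area = (~island_dem.nodata_mask).sum() * island_dem.cell_area
        assert total_out == pytest.approx(total_area, rel=1e-6)

    def test_shape_mismatch_rejected(self, island_dem, tilted_plane):
        flow = flow_partition(tilted_plane)
        with pytest.raises(InputError):
            upslope_contributing_area(island_dem, flow)


class TestFillDepressions:
    def test_fill_removes_interior_pits(self):
        rng = np.random.default_rng(3)
        dem = Raster(rng.uniform(0, 50, size=(10, 10)), cell_size=30.0)
        filled = fill_depressions(dem)
        flow = flow_partition(filled, fill=False)
        interior_pits = (flow.outflow_sum()[1:-1, 1:-1] == 0.0).sum()
        assert interior_pits == 0
        assert np.all(filled.values >= dem.values - 1e-12)


class TestCurvature:
    def test_constant_grid_zero(self):
        curv = surface_curvature(Raster(np.full((4, 4), 7.0), cell_size=30.0))
        assert np.allclose(curv.values, 0.0)

    def test_plane_interior_zero(self, tilted_plane):
        curv = surface_curvature(tilted_plane)
        assert np.allclose(curv.values[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_unit_peak_closed_form(self):
        z = np.zeros((3, 3))
        z[1, 1] = 1.0
        curv = surface_curvature(Raster(z, cell_size=1.0))
        assert curv.values[1, 1] == pytest.approx((4 + 4 / np.sqrt(2)) / 8)

    @pytest.mark.parametrize("seed", range(3))
    def test_antisymmetric_under_negation(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(7, 7)) * 10
        plus = surface_curvature(Raster(z, cell_size=30.0)).values
        minus = surface_curvature(Raster(-z, cell_size=30.0)).values
        assert np.allclose(minus, -plus)

    def test_nodata_neighbors_excluded(self):
        z = np.zeros((3, 3))
        z[1, 1] = 1.0
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :] = True  # drop the top row from every mean
        curv = surface_curvature(Raster(z, cell_size=1.0, nodata_mask=mask))
        expected = (2 * 1.0 + 2 / np.sqrt(2) + 1.0) / 5
        assert curv.values[1, 1] == pytest.approx(expected)


class TestNulmCascade:
    def _derivs(self, dem):
        return compute_derivatives(dem)

    def test_steep_cell_is_fall_face(self):
        # z = x at 1 m cells is a 45-degree plane: every interior cell
        # meets the fall-face bound and nothing outranks it at low AS
        x = np.arange(8, dtype=float)
        dem = Raster(np.tile(x, (8, 1)) * 1.0001, cell_size=1.0)
        derivs = self._derivs(dem)
        th = NulmThresholds(channel_upslope_min=1e9, summit_curvature_min=10,
                            shoulder_curvature_min=10, footslope_curvature_max=-10)
        nulm = classify_nulm(derivs, th)
        assert np.all(nulm.values[1:-1, 1:-1] == NULM_CODES["fall face"])

    def test_channel_outranks_curvature(self, island_dem):
        derivs = self._derivs(island_dem)
        th = NulmThresholds().resolve(derivs)
        nulm = classify_nulm(derivs, th)
        over = derivs.upslope_area.values >= th.channel_upslope_min
        assert np.all(nulm.values[over] == NULM_CODES["channel"])

    def test_cone_apex_is_summit(self, cone_dem):
        derivs = self._derivs(cone_dem)
        nulm = classify_nulm(derivs)
        rows, cols = cone_dem.shape
        apex = np.unravel_index(np.argmax(cone_dem.values), cone_dem.shape)
        assert nulm.values[apex] == NULM_CODES["summit"]

    def test_tilted_plane_has_no_summit_or_channel(self, tilted_plane):
        derivs = self._derivs(tilted_plane)
        max_as = derivs.upslope_area.values.max()
        nulm = classify_nulm(derivs, NulmThresholds(channel_upslope_min=max_as + 1))
        assert not np.any(nulm.values == NULM_CODES["summit"])
        assert not np.any(nulm.values == NULM_CODES["channel"])

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            NulmThresholds(fallface_slope_min_deg=95.0)
        with pytest.raises(ParameterError):
            NulmThresholds(channel_upslope_min=-1.0)


class TestRemap:
    def test_standard_merge_table(self):
        codes = np.array([[NULM_CODES["fall face"], NULM_CODES["backslope"]],
                          [NULM_CODES["toeslope"], NULM_CODES["channel"]]])
        nulm = Raster(codes, cell_size=30.0, legend=dict(NULM_LEGEND))
        lf = remap_landform(nulm).classes.values
        assert lf[0, 0] == LANDFORM_CODES["Slope"]
        assert lf[0, 1] == LANDFORM_CODES["Slope"]
        assert lf[1, 0] == LANDFORM_CODES["Flat land"]
        assert lf[1, 1] == LANDFORM_CODES["Channel"]

    def test_footslope_merges_into_slope_by_default(self):
        nulm = Raster(np.full((2, 2), NULM_CODES["footslope"]), cell_size=30.0)
        assert np.all(remap_landform(nulm).classes.values == LANDFORM_CODES["Slope"])

    def test_unmapped_unit_raises_with_name(self):
        nulm = Raster(np.full((2, 2), NULM_CODES["shoulder"]), cell_size=30.0)
        with pytest.raises(ConfigurationError, match="shoulder"):
            remap_landform(nulm, mapping={"channel": "Channel"})

    def test_classification_is_total(self, island_dem):
        landform = remap_landform(classify_nulm(compute_derivatives(island_dem)))
        vals = landform.classes.values[~landform.classes.nodata_mask]
        assert set(np.unique(vals)) <= set(LANDFORM_CODES.values())
        assert np.all(vals > 0)


class TestLocalMaxima:
    def test_matches_strict_scan(self, island_dem):
        strict = local_maxima(island_dem, strict=True)
        from test_synth import strict_local_maxima

        assert np.array_equal(strict, strict_local_maxima(island_dem.values))
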