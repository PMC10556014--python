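"""Regional variables, the FTI/PTI identities, CPEI geometry, DPLI."""

import numpy as np
import pytest

from pedobar.core import Mask, PressureFrameSeries, PressureRecording, SensorGrid, Side
from pedobar.masking import create_mask_auto
from pedobar.metrics import cpei, dpli, mask_analysis, whole_foot_mask
from pedobar.synthetic import mirror_recording

from conftest import make_recording


def value_of(table, region, metric):
    row = table[(table.region == region) & (table.metric == metric)]
    assert len(row) == 1
    return float(row.value.iloc[0])


class TestMaskAnalysis:
    def test_constant_force_fti_closed_form(self):
        # one 4 cm2 cell at 50 kPa -> F = 0.1*50*4 = 20 N, held 0.5 s
        vals = np.full((51, 1, 1), 50.0)
        rec = make_recording(vals, sampling_rate=100.0)
        rec.grid.areas[:] = 4.0
        rec.add_mask(whole_foot_mask(rec))
        table = mask_analysis(rec, ["fti", "pti_melai", "force_max", "contact_time"])
        assert value_of(table, "whole_foot", "force_max") == pytest.approx(20.0)
        assert value_of(table, "whole_foot", "fti") == pytest.approx(10.0, rel=1e-12)
        # PTI (Melai) = FTI / A with A = 4 cm2
        assert value_of(table, "whole_foot", "pti_melai") == pytest.approx(2.5, rel=1e-12)
        assert value_of(table, "whole_foot", "contact_time") == pytest.approx(0.51)

    def test_press_peak_sensor_is_brute_force_max(self):
        vals = np.zeros((3, 1, 3))
        vals[0, 0, 0], vals[1, 0, 1], vals[2, 0, 2] = 120.0, 340.0, 95.0
        rec = make_recording(vals)
        rec.add_mask(whole_foot_mask(rec))
        table = mask_analysis(rec, "press_peak_sensor")
        oracle = max(
            rec.frames.values[t, r, c]
            for t in range(3)
            for r in range(1)
            for c in range(3)
        )
        assert value_of(table, "whole_foot", "press_peak_sensor") == oracle == 340.0

    def test_triangular_ramp_fti_exact_on_knots(self):
        # force 0 -> 10 N -> 0 over 0.2 s: trapezoid exact for linear knots
        vals = np.zeros((21, 1, 1))
        vals[:, 0, 0] = np.concatenate([np.linspace(0, 100, 11), np.linspace(100, 0, 11)[1:]])
        rec = make_recording(vals, sampling_rate=100.0)
        rec.grid.areas[:] = 1.0
        rec.add_mask(whole_foot_mask(rec))
        fti = value_of(mask_analysis(rec, "fti"), "whole_foot", "fti")
        assert fti == pytest.approx(10.0 * 0.2 / 2.0, rel=1e-12)

    def test_pti_times_area_identity(self, barefoot):
        rec, _ = barefoot
        create_mask_auto(rec, foot_side="auto")
        table = mask_analysis(rec, ["fti", "pti_melai", "contact_area_peak"])
        for region in rec.masks:
            pti = value_of(table, region, "pti_melai")
            area = value_of(table, region, "contact_area_peak")
            fti = value_of(table, region, "fti")
            assert pti * area == pytest.approx(fti, rel=1e-12)

    def test_whole_foot_peak_is_max_of_partition_regions(self, barefoot):
        rec, _ = barefoot
        create_mask_auto(rec, foot_side="auto")
        table = mask_analysis(rec, "press_peak_sensor")
        regional_max = table.value.max()
        rec2 = rec.copy()
        rec2.masks = {}
        rec2.add_mask(whole_foot_mask(rec2))
        whole = value_of(mask_analysis(rec2, "press_peak_sensor"), "whole_foot", "press_peak_sensor")
        # equality holds when the regions cover every loaded cell above the
        # footprint threshold; the global max always sits well above it
        assert whole == pytest.approx(regional_max)

    def test_press_peak_mean_is_temporal_mean_of_spatial_peak(self):
        vals = np.zeros((4, 1, 2))
        vals[:, 0, 0] = [10.0, 30.0, 20.0, 0.0]
        vals[:, 0, 1] = [5.0, 40.0, 10.0, 0.0]
        rec = make_recording(vals)
        rec.add_mask(whole_foot_mask(rec))
        got = value_of(mask_analysis(rec, "press_peak_mean"), "whole_foot", "press_peak_mean")
        assert got == pytest.approx(np.mean([10.0, 40.0, 20.0]))

    def test_unknown_variable_and_no_masks_rejected(self, tiny_rec):
        with pytest.raises(ValueError, match="no masks"):
            mask_analysis(tiny_rec)
        tiny_rec.add_mask(whole_foot_mask(tiny_rec))
        with pytest.raises(ValueError, match="unknown variable"):
            mask_analysis(tiny_rec, "pti")

    def test_empty_mask_rejected(self, barefoot):
        rec, _ = barefoot
        rec.add_mask(
            Mask(name="far", polygon=np.array([[500.0, 500.0], [510.0, 500.0], [505.0, 510.0]]))
        )
        with pytest.raises(ValueError, match="zero assigned cells"):
            mask_analysis(rec)


def planted_cpei_recording(lateral_mm: float, rotate_deg: float = 0.0):
    """A footprint rectangle plus a hand-planted COP path.

    Frame 0 loads a 120 x 39 mm rectangle (8 kPa) that defines the
    footprint: foot length L = 119 mm (cell-center extent), forefoot width
    w = 38 mm.  Later frames each load one cell at 5 kPa*10^3 so the COP
    visits chosen cell centers exactly.  The path runs straight up the
    midline (x = 29), bulges laterally by ``lateral_mm`` around the
    anterior trisection boundary (y = 79.33), and its most medial anterior
    point returns to the midline, so the construction line is the midline
    and CPEI = 100 * lateral_mm / 38.
    """
    n_rows, n_cols = 120, 60
    vals = np.zeros((12, n_rows, n_cols))
    vals[0, 0:120, 10:49] = 8.0
    x0 = 29
    path = [
        (10, x0), (25, x0), (40, x0), (55, x0), (65, x0),
        (70, x0 + lateral_mm), (75, x0 + lateral_mm), (85, x0 + lateral_mm),
        (95, x0), (105, x0 + 1),
    ]
    for t, (y, x) in enumerate(path, start=1):
        vals[t, int(y), int(x)] = 5000.0
    grid = SensorGrid.uniform(n_rows, n_cols, 1.0, 1.0)
    if rotate_deg:
        th = np.radians(rotate_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        grid = SensorGrid(
            grid.centers @ R.T, grid.polygons @ R.T, grid.areas, grid.active
        )
    rec = PressureRecording(frames=PressureFrameSeries(vals, 100.0), grid=grid)
    rec.side = Side.RIGHT
    return rec


class TestCPEI:
    def test_on_line_cop_gives_zero(self):
        rec = planted_cpei_recording(lateral_mm=0.0)
        assert cpei(rec).cpei == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [2.0, 4.0, 7.0])
    def test_planted_deviation_gives_100_d_over_w(self, d):
        res = cpei(planted_cpei_recording(lateral_mm=d))
        assert res.forefoot_width == pytest.approx(38.0, rel=1e-9)
        assert res.deviation == pytest.approx(d, rel=1e-9)
        assert res.cpei == pytest.approx(100.0 * d / 38.0, rel=1e-6)

    def test_invariant_under_rigid_rotation(self):
        flat = cpei(planted_cpei_recording(4.0)).cpei
        rotated = cpei(planted_cpei_recording(4.0, rotate_deg=30.0)).cpei
        assert rotated == pytest.approx(flat, rel=1e-6)

    def test_mirror_preserves_magnitude_and_sign(self):
        rec = planted_cpei_recording(4.0)
        res = cpei(rec)
        mirrored = cpei(mirror_recording(rec))
        assert mirrored.side is Side.LEFT
        assert mirrored.cpei == pytest.approx(res.cpei, rel=1e-9)

    def test_lateral_bulge_positive_on_default_foot(self, barefoot):
        rec, _ = barefoot
        res = cpei(rec, force_threshold=10.0)
        assert res.forefoot_width > 0
        assert res.side is Side.RIGHT

    def test_chord_variant_runs(self):
        rec = planted_cpei_recording(4.0)
        assert np.isfinite(cpei(rec, method="chord").cpei)


def dpli_grid_oracle(y: np.ndarray) -> float:
    """Independent brute-force Gaussian fit over a dense parameter grid."""
    t = np.arange(len(y), dtype=float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 1e-12 * len(y) * y.max() ** 2:
        return 0.0
    a_grid = y.max() * np.linspace(0.7, 1.3, 31)
    mu_grid = np.argmax(y) + np.linspace(-4.0, 4.0, 41)
    half = np.flatnonzero(y >= y.max() / 2.0)
    s0 = max((half[-1] - half[0]) / 2.0, 0.5) / np.sqrt(2 * np.log(2))
    s_grid = s0 * np.geomspace(0.4, 2.5, 41)
    best = np.inf
    for mu in mu_grid:
        e = np.exp(-((t - mu) ** 2)[None, :] / (2.0 * s_grid[:, None] ** 2))  # (S, T)
        for a in a_grid:
            res = ((y[None, :] - a * e) ** 2).sum(axis=1).min()
            best = min(best, res)
    return float(np.clip(best / ss_tot, 0.0, 1.0))


class TestDPLI:
    def test_exact_gaussian_gives_zero(self):
        t = np.arange(80.0)
        y = 250.0 * np.exp(-((t - 35.0) ** 2) / (2 * 9.0**2))
        assert dpli(y) < 1e-6

    def test_flat_series_matches_grid_oracle(self):
        y = np.full(40, 7.5)
        assert dpli(y) == pytest.approx(dpli_grid_oracle(y), abs=1e-9) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_curves_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(61.0)
        y = 200.0 * np.exp(-((t - 30.0) ** 2) / (2 * 8.0**2))
        y = np.clip(y + rng.normal(0.0, 10.0, y.shape), 0.0, None)
        got = dpli(y)
        oracle = dpli_grid_oracle(y)
        assert got <= oracle + 1e-3  # least squares at least as good as grid
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_noise_increases_dpli_in_expectation(self):
        t = np.arange(61.0)
        base = 200.0 * np.exp(-((t - 30.0) ** 2) / (2 * 8.0**2))
        means = []
        for sd in (2.0, 10.0, 40.0):
            vals = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                vals.append(dpli(np.clip(base + rng.normal(0, sd, base.shape), 0, None)))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_result_always_in_unit_interval(self, barefoot):
        from pedobar.preprocess import whole_pressure_curve

        rec, _ = barefoot
        value = dpli(whole_pressure_curve(rec, "peak_pressure").values)
        assert 0.0 <= value <= 1.0

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dpli(np.zeros(10))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dpli(np.ones(4))
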