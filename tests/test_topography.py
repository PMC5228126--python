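"""Topographic-map construction, contours, fovea location and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

import foveate as fv
from foveate.synthetic import density_at
from foveate.topography import TopographicMap

from conftest import exact_moment_sample


def _frames_from_densities(sites, densities, frame_side=50.0):
    """Exact (noiseless) counting frames whose count/area equals density."""
    area = (frame_side / 1000.0) ** 2
    counts = np.asarray(densities) * area
    return fv.CountingFrameSet(
        sites=np.asarray(sites), frame_side=frame_side, counts=counts
    )


class TestBuildMap:
    def test_constant_density_gives_constant_field(self):
        outline = fv.circle_outline(5.0)
        rng = np.random.default_rng(0)
        sites = rng.uniform(-3, 3, size=(30, 2))
        frames = _frames_from_densities(sites, np.full(30, 1234.0))
        field = fv.build_topographic_map(frames, outline, grid_step=0.25)
        vals = field.grid[np.isfinite(field.grid)]
        assert np.allclose(vals, 1234.0)

    def test_site_density_arithmetic(self):
        frames = fv.CountingFrameSet(
            sites=[[0.0, 0.0]] * 4, frame_side=50.0, counts=[10, 10, 10, 10]
        )
        assert np.allclose(frames.densities, 4000.0)

    def test_reconstruction_of_known_field(self):
        # noiseless lattice sampling reconstructs the planted surface
        spec = fv.RetinaSpec(radius=6.0, fovea_xy=(-0.2, 0.1))
        field = fv.generate_density_field(spec, grid_step=0.1)
        frames = fv.sample_counting_frames(
            field, n_sites=400, seed=1, layout="lattice"
        )
        truth = density_at(spec, frames.sites[:, 0], frames.sites[:, 1])
        exact = _frames_from_densities(frames.sites, truth)
        rec = fv.build_topographic_map(exact, field.outline, grid_step=0.1)
        rng = np.random.default_rng(2)
        pts = rng.uniform(-6, 6, size=(2000, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 4.8]  # away from the margin
        est = rec.value_at(pts[:, 0], pts[:, 1])
        tru = density_at(spec, pts[:, 0], pts[:, 1])
        mare = np.nanmean(np.abs(est - tru) / tru)
        assert mare < 0.05

    def test_reconstruction_recovers_planted_fovea(self):
        # fovea planted on a sampled site: peak recovered within a grid step
        spec = fv.RetinaSpec(radius=6.0, fovea_xy=(-0.25, 0.0))
        field = fv.generate_density_field(spec, grid_step=0.1)
        frames = fv.sample_counting_frames(
            field, n_sites=350, seed=4, layout="lattice"
        )
        sites = np.vstack([frames.sites, spec.fovea_mm])
        truth = density_at(spec, sites[:, 0], sites[:, 1])
        rec = fv.build_topographic_map(
            _frames_from_densities(sites, truth), field.outline, grid_step=0.1
        )
        found = fv.locate_fovea(rec)
        assert np.hypot(found[0] - spec.fovea_mm[0], found[1] - spec.fovea_mm[1]) <= 0.1 + 1e-9

    def test_all_zero_counts_warns_flat_field(self):
        outline = fv.circle_outline(3.0)
        sites = np.array([[0, 0], [1, 0], [0, 1], [-1, -1]], dtype=float)
        frames = fv.CountingFrameSet(sites=sites, frame_side=50.0, counts=[0] * 4)
        with pytest.warns(UserWarning, match="zero"):
            field = fv.build_topographic_map(frames, outline, grid_step=0.2)
        assert np.nanmax(field.grid) == 0.0

    def test_collinear_sites_rejected(self):
        outline = fv.circle_outline(3.0)
        sites = np.column_stack([np.linspace(-1, 1, 6), np.zeros(6)])
        frames = _frames_from_densities(sites, np.full(6, 100.0))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            fv.build_topographic_map(frames, outline, grid_step=0.2)

    def test_estimator_interface(self):
        outline = fv.circle_outline(4.0)
        rng = np.random.default_rng(1)
        sites = rng.uniform(-2.5, 2.5, size=(40, 2))
        frames = _frames_from_densities(sites, 1000 + 100 * sites[:, 0])
        tm = TopographicMap(grid_step=0.2).fit(frames, outline)
        assert tm.get_params()["grid_step"] == 0.2
        # exact at the sites for the default linear method
        pred = tm.predict(sites)
        assert np.allclose(pred, frames.densities, rtol=1e-6)


class TestContours:
    def test_symmetric_contour_centroid_near_fovea(self, linear_field):
        contours = fv.isodensity_contours(linear_field, [2000.0])[2000.0]
        assert len(contours) >= 1
        ring = max(contours, key=len)
        cx, cy = ring[:, 0].mean(), ring[:, 1].mean()
        assert np.hypot(cx, cy) <= linear_field.step

    def test_flat_field_levels(self):
        spec = fv.RetinaSpec(base_density=800.0, peak_density=800.0)
        field = fv.generate_density_field(spec, grid_step=0.2)
        below = fv.isodensity_contours(field, [100.0])[100.0]
        above = fv.isodensity_contours(field, [900.0])[900.0]
        assert above == []
        assert len(below) == 1  # the whole outline
        assert np.allclose(below[0], np.asarray(field.outline.exterior.coords))

    def test_contour_nesting_by_enclosed_area(self, linear_field):
        def enclosed_area(level):
            rings = fv.isodensity_contours(linear_field, [level])[level]
            ring = max(rings, key=len)
            x, y = ring[:, 0], ring[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

        assert enclosed_area(3200.0) < enclosed_area(1200.0)

    def test_levels_must_increase(self, linear_field):
        with pytest.raises(ValueError, match="increasing"):
            fv.isodensity_contours(linear_field, [2000.0, 1000.0])


class TestLocateFovea:
    def test_peak_on_grid_node_exact(self):
        spec = fv.RetinaSpec(radius=6.0, fovea_xy=(-0.15, 0.05))
        field = fv.generate_density_field(spec, grid_step=0.1)
        assert fv.locate_fovea(field) == pytest.approx(spec.fovea_mm)

    def test_plateau_tie_broken_at_midpoint(self):
        outline = fv.circle_outline(2.0)
        grid = np.full((21, 21), 10.0)
        grid[10, 9] = grid[10, 10] = 50.0
        xx, yy = np.meshgrid(np.linspace(-2, 2, 21), np.linspace(-2, 2, 21))
        grid[np.hypot(xx, yy) > 2.0] = np.nan
        field = fv.DensityField(
            grid=grid, origin=(-2.0, -2.0), step=0.2, outline=outline
        )
        x, y = fv.locate_fovea(field)
        assert y == pytest.approx(0.0)
        assert x == pytest.approx(-0.1)  # midpoint of the two max cells

    def test_flat_field_rejected(self):
        spec = fv.RetinaSpec(base_density=100.0, peak_density=100.0)
        field = fv.generate_density_field(spec, grid_step=0.2)
        with pytest.raises(ValueError, match="no unique fovea"):
            fv.locate_fovea(field)


class TestNormalizePosition:
    def test_centroid_maps_to_origin(self):
        outline = fv.circle_outline(5.0, center=(2.0, -1.0))
        pos = fv.normalize_fovea_position((2.0, -1.0), outline)
        assert pos.x == pytest.approx(0.0, abs=1e-9)
        assert pos.y == pytest.approx(0.0, abs=1e-9)

    def test_known_offsets_divide_by_radius(self):
        # 0.725 mm temporal, 0.285 mm dorsal on a 5 mm-radius retina
        outline = fv.circle_outline(5.0, n_vertices=4096)
        pos = fv.normalize_fovea_position((-0.725, 0.285), outline)
        assert pos.x == pytest.approx(-0.145, abs=1e-3)
        assert pos.y == pytest.approx(0.057, abs=1e-3)

    def test_left_right_mirroring_comparable(self):
        outline = fv.circle_outline(5.0)
        right = fv.normalize_fovea_position((-0.7, 0.3), outline, "right")
        left = fv.normalize_fovea_position((0.7, 0.3), outline, "left")
        assert left.x == pytest.approx(right.x)
        assert left.y == pytest.approx(right.y)

    def test_fovea_outside_outline_rejected(self):
        outline = fv.circle_outline(2.0)
        with pytest.raises(ValueError, match="outside"):
            fv.normalize_fovea_position((3.0, 0.0), outline)

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        base = np.array(
            [[2, 0], [1.5, 1.5], [0, 2], [-1.6, 1.2], [-2, 0], [-1.2, -1.7],
             [0, -2], [1.4, -1.4]], dtype=float
        )
        f = (0.5, -0.3)
        a = fv.normalize_fovea_position(f, Polygon(base))
        b = fv.normalize_fovea_position(
            (f[0] * k, f[1] * k), Polygon(base * k)
        )
        assert a.x == pytest.approx(b.x, abs=1e-12)
        assert a.y == pytest.approx(b.y, abs=1e-12)


class TestPositionSummary:
    def test_identical_positions_collapse_ci(self):
        pos = [fv.FoveaPosition(0.1, 0.2, species=f"s{i}") for i in range(5)]
        out = fv.mean_position_with_ci(pos)
        assert out["x"].se == 0.0
        assert out["x"].ci_low == out["x"].ci_high == pytest.approx(0.1)

    def test_duplicate_species_rejected(self):
        pos = [fv.FoveaPosition(0.1, 0.2, species="a"),
               fv.FoveaPosition(0.0, 0.1, species="a")]
        with pytest.raises(ValueError, match="duplicate"):
            fv.mean_position_with_ci(pos)

    def test_ci_coverage_is_nominal(self):
        # 95% t-interval covers the true mean in ~95% of i.i.d. draws
        rng = np.random.default_rng(7)
        n, reps, hits = 12, 1000, 0
        for _ in range(reps):
            xs = rng.normal(0.3, 0.1, n)
            ys = rng.normal(-0.1, 0.2, n)
            pos = [fv.FoveaPosition(x, y) for x, y in zip(xs, ys)]
            s = fv.mean_position_with_ci(pos)["x"]
            hits += s.ci_low <= 0.3 <= s.ci_high
        assert abs(hits / reps - 0.95) < 0.02

    def test_summary_from_reported_moments(self):
        xs = exact_moment_sample(-0.145, 0.013, 29)
        ys = exact_moment_sample(0.057, 0.017, 29)
        pos = [fv.FoveaPosition(x, y, species=f"s{i}")
               for i, (x, y) in enumerate(zip(xs, ys))]
        out = fv.mean_position_with_ci(pos, alpha=0.05)
        assert out["x"].mean == pytest.approx(-0.145)
        assert out["x"].se == pytest.approx(0.013)
        assert out["y"].ci_low < out["y"].mean < out["y"].ci_high
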