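"""Distances to glands, KDE density fields and aggregate detection."""

import numpy as np
import pytest

from conftest import make_cell, star_polygon

from neurotme.core import Polygon2D
from neurotme.errors import (
    DegenerateInputError,
    DomainError,
    MissingAnnotationError,
)
from neurotme.spatial import (
    count_lymphoid_aggregates,
    detect_aggregates,
    distance_to_glands,
    estimate_density,
    fascicle_aggregate_distances,
    la_dichotomize,
    render_heatmap,
)


def brute_force_distance(xy, polys, step=0.05):
    """Oracle: densely sample each gland boundary and take the minimum
    point-to-sample distance (0 for points covered by a gland)."""
    import shapely
    samples = []
    for p in polys:
        ring = p.to_shapely().exterior
        n = max(int(np.ceil(ring.length / step)), 4)
        ts = np.linspace(0, ring.length, n, endpoint=False)
        pts = [ring.interpolate(t) for t in ts]
        samples.append(np.array([[q.x, q.y] for q in pts]))
    samples = np.vstack(samples)
    out = np.full(len(xy), np.inf)
    for i, (x, y) in enumerate(xy):
        if any(shapely.contains_xy(p.to_shapely().buffer(1e-12), x, y)
               for p in polys):
            out[i] = 0.0
        else:
            out[i] = np.sqrt(((samples - (x, y)) ** 2).sum(1)).min()
    return out


def kde_double_sum(xy, bbox, h, grid_size=100):
    """Oracle: direct (grid point x data point) evaluation of the Gaussian
    kernel formula, without the separable factorization."""
    xmin, ymin, xmax, ymax = bbox
    xe = np.linspace(xmin, xmax, grid_size + 1)
    ye = np.linspace(ymin, ymax, grid_size + 1)
    gx = 0.5 * (xe[:-1] + xe[1:])
    gy = 0.5 * (ye[:-1] + ye[1:])
    gxx, gyy = np.meshgrid(gx, gy)
    g = np.column_stack([gxx.ravel(), gyy.ravel()])
    z = ((g[:, None, :] - xy[None, :, :]) / h) ** 2
    vals = np.exp(-0.5 * z.sum(-1)).sum(1) / (len(xy) * 2 * np.pi * h[0] * h[1])
    return vals.reshape(grid_size, grid_size)


def thomas_points(rng, centers, n_per=150, sd=50.0, bbox=(0, 0, 5000, 5000)):
    pts = []
    for c in centers:
        p = rng.normal(c, sd, (rng.poisson(n_per), 2))
        keep = (p[:, 0] >= bbox[0]) & (p[:, 0] <= bbox[2]) \
            & (p[:, 1] >= bbox[1]) & (p[:, 1] <= bbox[3])
        pts.append(p[keep])
    return np.vstack(pts) if pts else np.empty((0, 2))


class TestDistanceToGlands:
    def test_cell_inside_gland_is_zero(self):
        gland = Polygon2D.rectangle(0, 0, 100, 100)
        res = distance_to_glands([make_cell("c", 50, 50)], [gland])
        assert res.distances_um[0] == 0.0

    def test_axis_aligned_distance(self):
        gland = Polygon2D(((0, -50), (100, -50), (100, 50), (0, 50)))
        res = distance_to_glands(np.array([[200.0, 0.0]]), [gland])
        assert res.distances_um[0] == pytest.approx(100.0)

    def test_empty_gland_list_raises(self):
        with pytest.raises(MissingAnnotationError):
            distance_to_glands([make_cell("c", 0, 0)], [])

    def test_matches_boundary_sampling_oracle(self):
        rng = np.random.default_rng(5)
        glands = [
            star_polygon(rng, n_vertices=10,
                         center=rng.uniform(500, 4500, 2), radius=300.0)
            for _ in range(5)
        ]
        xy = rng.uniform(0, 5000, (500, 2))
        res = distance_to_glands(xy, glands)
        oracle = brute_force_distance(xy, glands)
        np.testing.assert_allclose(res.distances_um, oracle, atol=0.1)

    def test_summary_consistency(self):
        rng = np.random.default_rng(6)
        gland = Polygon2D.rectangle(2000, 2000, 2500, 2500)
        xy = rng.uniform(0, 5000, (200, 2))
        res = distance_to_glands(xy, [gland], bin_width_um=50.0)
        assert res.mean_um == pytest.approx(res.distances_um.mean())
        assert res.hist_counts.sum() == 200
        assert np.all(res.distances_um >= 0)


class TestEstimateDensity:
    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_density(np.array([[1.0, 1.0]]), (0, 0, 10, 10))
        with pytest.raises(DegenerateInputError):
            # zero variance in y
            estimate_density(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
                             (0, 0, 10, 10))

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("bandwidth", [None, 75.0, (40.0, 120.0)])
    def test_matches_double_sum_oracle(self, seed, bandwidth):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 2000, (80, 2))
        field = estimate_density(xy, (0, 0, 2000, 2000), bandwidth_um=bandwidth)
        oracle = kde_double_sum(xy, (0, 0, 2000, 2000),
                                np.array(field.bandwidth_um))
        np.testing.assert_allclose(field.grid_values, oracle, atol=1e-8)

    def test_scott_bandwidth_value(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(500, 100, (200, 2))
        field = estimate_density(xy, (0, 0, 1000, 1000))
        expected = xy.std(axis=0, ddof=1) * 200 ** (-1 / 6)
        np.testing.assert_allclose(field.bandwidth_um, expected)

    def test_two_cluster_peaks_near_planted_centers(self):
        rng = np.random.default_rng(2)
        centers = np.array([[1500.0, 2000.0], [3500.0, 2000.0]])
        xy = np.vstack([rng.normal(c, 30.0, (100, 2)) for c in centers])
        bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
        field = estimate_density(xy, bbox)
        gx, gy = field.x_centers, field.y_centers
        for c in centers:
            # best grid cell within each cluster's half of the box
            half = field.grid_values[:, np.abs(gx - c[0]) < 1000]
            gxh = gx[np.abs(gx - c[0]) < 1000]
            iy, ix = np.unravel_index(np.argmax(half), half.shape)
            assert np.hypot(gxh[ix] - c[0], gy[iy] - c[1]) < 100.0

    def test_mass_bounded_and_monotone_in_margin(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(0, 200, (150, 2))
        masses = []
        for margin in (200.0, 600.0, 2000.0):
            field = estimate_density(xy, (-margin, -margin, margin, margin))
            masses.append(field.total_mass())
        assert all(0 < m <= 1 + 1e-6 for m in masses)
        assert masses[0] < masses[1] < masses[2]


class TestDetectAggregates:
    def test_no_cells_gives_zero(self):
        aggs, field = count_lymphoid_aggregates([], (0, 0, 1000, 1000))
        assert aggs.la_count == 0
        assert field is None

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(4)
        centers = [(1000, 1000), (1000, 4000), (4000, 2500)]
        xy = np.vstack([thomas_points(rng, centers),
                        rng.uniform(0, 5000, (30, 2))])  # sparse background
        aggs, _ = count_lymphoid_aggregates(xy, (0, 0, 5000, 5000))
        assert aggs.la_count == 3
        found = np.array([[a.centroid.x_um, a.centroid.y_um]
                          for a in aggs.aggregates])
        for c in centers:
            assert np.sqrt(((found - c) ** 2).sum(1)).min() < 100.0

    def test_close_clusters_merge(self):
        rng = np.random.default_rng(5)
        sd = 50.0
        centers = [(2500, 2500), (2500 + sd, 2500)]  # 1 x sd apart
        xy = thomas_points(rng, centers, sd=sd)
        aggs, _ = count_lymphoid_aggregates(xy, (0, 0, 5000, 5000))
        assert aggs.la_count == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        centers = [(1000, 1000), (2500, 3500), (4000, 1500)]
        xy = np.vstack([thomas_points(rng, centers),
                        rng.uniform(0, 5000, (50, 2))])
        field = estimate_density(xy, (0, 0, 5000, 5000), bandwidth_um=75.0)
        counts = [
            detect_aggregates(field, xy, rel_threshold=t).la_count
            for t in (0.05, 0.15, 0.25, 0.5, 0.75, 0.95)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_min_member_cells_filters_small_components(self):
        rng = np.random.default_rng(7)
        xy = np.vstack([thomas_points(rng, [(2500, 2500)], n_per=150),
                        thomas_points(rng, [(1000, 1000)], n_per=60)])
        field = estimate_density(xy, (0, 0, 5000, 5000), bandwidth_um=75.0)
        assert detect_aggregates(field, xy, min_member_cells=20).la_count == 2
        assert detect_aggregates(field, xy, min_member_cells=100).la_count == 1

    def test_member_counts_and_params_recorded(self):
        rng = np.random.default_rng(8)
        xy = thomas_points(rng, [(2500, 2500)])
        aggs, _ = count_lymphoid_aggregates(xy, (0, 0, 5000, 5000))
        assert aggs.la_count == 1
        assert aggs.aggregates[0].member_cell_count >= 100
        assert aggs.params["rel_threshold"] == 0.25

    def test_invalid_connectivity(self):
        rng = np.random.default_rng(9)
        xy = thomas_points(rng, [(2500, 2500)])
        field = estimate_density(xy, (0, 0, 5000, 5000), bandwidth_um=75.0)
        with pytest.raises(DomainError):
            detect_aggregates(field, xy, connectivity=6)


class TestLaDichotomize:
    @pytest.mark.parametrize("count,expected", [(0, "lt5"), (4, "lt5"),
                                                (5, "ge5"), (12, "ge5")])
    def test_cutpoint(self, count, expected):
        assert la_dichotomize(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            la_dichotomize(-1)


class TestFascicleAggregateDistances:
    def test_descriptive_distances(self):
        rng = np.random.default_rng(10)
        xy = thomas_points(rng, [(1000, 1000)])
        aggs, _ = count_lymphoid_aggregates(xy, (0, 0, 5000, 5000))
        from conftest import make_fascicle
        d = fascicle_aggregate_distances(
            [make_fascicle("f0", 1000, 1100), make_fascicle("f1", 4000, 4000)],
            aggs,
        )
        assert d[0] < 150 and d[1] > 3000


class TestRenderHeatmap:
    def test_writes_png_deterministically(self, tmp_path):
        rng = np.random.default_rng(11)
        xy = thomas_points(rng, [(2500, 2500), (1000, 4000)])
        field = estimate_density(xy, (0, 0, 5000, 5000), bandwidth_um=75.0)
        glands = [Polygon2D.rectangle(3000, 3000, 4000, 4000)]
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_heatmap(field, glands, p1)
        render_heatmap(field, glands, p2)
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()
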