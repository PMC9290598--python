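"""Canopy height model extraction against brute-force oracles."""

import numpy as np
import pytest

from canopymass import (
    ChmConfig, CanopyHeightGrid, EmptyPlotError, PlotRecord, PointCloud,
    build_terrain, clip_to_plot, compute_plot_metrics, height_above_ground,
    idw_fill, rasterize_max, summarize_grid,
)


# ------------------------------------------------------------ clipping

def ray_cast_inside(poly_xy, px, py):
    """Point-in-polygon by ray casting, with boundary special-casing."""
    n = len(poly_xy)
    on_edge = False
    inside = False
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        # boundary check: point on the segment
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                on_edge = True
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    return inside or on_edge


def test_interior_point_retained(unit_plot):
    cloud = PointCloud([[0.5, 0.5, 100.3]])
    assert len(clip_to_plot(cloud, unit_plot)) == 1


def test_boundary_point_retained(unit_plot):
    cloud = PointCloud([[0.0, 0.5, 100.3], [1.0, 1.0, 100.3]])
    assert len(clip_to_plot(cloud, unit_plot)) == 2


def test_noise_points_removed(unit_plot):
    cloud = PointCloud([[0.5, 0.5, 100.3], [0.6, 0.6, 105.0]],
                       noise=[False, True])
    clipped = clip_to_plot(cloud, unit_plot)
    assert len(clipped) == 1
    assert clipped.z[0] == pytest.approx(100.3)


def test_empty_plot_signal(unit_plot):
    cloud = PointCloud([[5.0, 5.0, 100.0]])
    with pytest.raises(EmptyPlotError):
        clip_to_plot(cloud, unit_plot)


def test_clipping_matches_ray_casting_oracle(rng):
    corners = [(0, 0, 0), (2, 0.2, 0), (1.8, 1.9, 0), (0.1, 1.5, 0)]
    plot = PlotRecord(plot_id="q", corners=corners, biomass=1.0)
    pts = np.column_stack([
        rng.uniform(-0.5, 2.5, 10_000), rng.uniform(-0.5, 2.5, 10_000),
        np.zeros(10_000),
    ])
    cloud = PointCloud(pts)
    clipped = clip_to_plot(cloud, plot)
    got = {(round(x, 9), round(y, 9)) for x, y in clipped.xyz[:, :2]}
    poly_xy = [(x, y) for x, y, _ in corners]
    expect = {
        (round(x, 9), round(y, 9))
        for x, y in pts[:, :2]
        if ray_cast_inside(poly_xy, x, y)
    }
    assert got == expect


# ------------------------------------------------------------ heights

def test_flat_terrain_subtraction(unit_plot):
    terrain = build_terrain(unit_plot.corners)
    cloud = PointCloud([[0.5, 0.5, 100.30]])
    h = height_above_ground(cloud, terrain)
    assert h[0] == pytest.approx(0.30, abs=1e-12)


def test_negative_heights_clamped_to_zero(unit_plot):
    terrain = build_terrain(unit_plot.corners)
    cloud = PointCloud([[0.5, 0.5, 99.8]])
    assert height_above_ground(cloud, terrain, clamp=True)[0] == 0.0
    assert height_above_ground(cloud, terrain, clamp=False)[0] == \
        pytest.approx(-0.2)


def test_sloped_plane_heights_match_closed_form(rng):
    def plane(x, y):
        return 50.0 + 0.2 * x - 0.1 * y

    corners = [(x, y, plane(x, y)) for x, y in
               [(0, 0), (4, 0), (4, 4), (0, 4)]]
    terrain = build_terrain(corners)
    xy = rng.uniform(0.1, 3.9, (100, 2))
    z = plane(xy[:, 0], xy[:, 1]) + rng.uniform(0, 2, 100)
    cloud = PointCloud(np.column_stack([xy, z]))
    h = height_above_ground(cloud, terrain)
    np.testing.assert_allclose(h, z - plane(xy[:, 0], xy[:, 1]), atol=1e-9)


# ------------------------------------------------------------ rasterize

def test_single_point_single_cell(default_chm):
    grid = rasterize_max([[0.005, 0.005]], [0.42], (0, 0, 1, 1),
                         default_chm)
    assert grid.shape == (100, 100)
    assert (~grid.empty).sum() == 1
    assert grid.values[0, 0] == pytest.approx(0.42)


def test_max_rule(default_chm):
    grid = rasterize_max([[0.005, 0.005], [0.006, 0.004]], [0.2, 0.5],
                         (0, 0, 1, 1), default_chm)
    assert grid.values[0, 0] == pytest.approx(0.5)


def test_upper_boundary_point_not_lost(default_chm):
    grid = rasterize_max([[1.0, 1.0]], [0.3], (0, 0, 1, 1), default_chm)
    assert grid.values[99, 99] == pytest.approx(0.3)


def test_rasterize_matches_brute_force_binning(rng, default_chm):
    xy = rng.uniform(0, 0.3, (1000, 2))
    h = rng.uniform(0, 2, 1000)
    grid = rasterize_max(xy, h, (0, 0, 0.3, 0.3), default_chm)
    res = default_chm.resolution
    nx, ny = grid.shape
    for i in range(nx):
        for j in range(ny):
            sel = (
                (xy[:, 0] >= i * res)
                & (xy[:, 0] < (i + 1) * res if i < nx - 1
                   else xy[:, 0] <= nx * res)
                & (xy[:, 1] >= j * res)
                & (xy[:, 1] < (j + 1) * res if j < ny - 1
                   else xy[:, 1] <= ny * res)
            )
            if sel.any():
                assert grid.values[i, j] == pytest.approx(h[sel].max())
            else:
                assert grid.empty[i, j]


# ------------------------------------------------------------ IDW fill

def brute_force_idw(values, empty, window, power):
    nx, ny = values.shape
    radius = window // 2
    out = values.copy()
    out_empty = empty.copy()
    for i in range(nx):
        for j in range(ny):
            if not empty[i, j]:
                continue
            num = den = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny and not empty[ii, jj]:
                        w = float(np.hypot(di, dj)) ** (-power)
                        num += w * values[ii, jj]
                        den += w
            if den > 0:
                out[i, j] = num / den
                out_empty[i, j] = False
    return out, out_empty


def random_grid(rng, nx=20, ny=20, empty_frac=0.4):
    values = rng.uniform(0, 2, (nx, ny))
    empty = rng.uniform(size=(nx, ny)) < empty_frac
    values[empty] = np.nan
    return CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)


def test_fully_populated_grid_unchanged(rng, default_chm):
    grid = random_grid(rng, empty_frac=0.0)
    filled = idw_fill(grid, default_chm)
    np.testing.assert_array_equal(filled.values, grid.values)
    assert not filled.empty.any()


def test_single_source_weight_cancels(default_chm):
    values = np.full((7, 7), np.nan)
    empty = np.ones((7, 7), dtype=bool)
    values[0, 0] = 0.77
    empty[0, 0] = False
    grid = CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)
    filled = idw_fill(grid, default_chm)
    assert filled.values[3, 3] == pytest.approx(0.77)


def test_idw_matches_brute_force_oracle(rng, default_chm):
    grid = random_grid(rng)
    filled = idw_fill(grid, default_chm)
    expect_vals, expect_empty = brute_force_idw(
        grid.values, grid.empty, default_chm.idw_window,
        default_chm.idw_power
    )
    np.testing.assert_array_equal(filled.empty, expect_empty)
    ok = ~filled.empty
    np.testing.assert_allclose(filled.values[ok], expect_vals[ok],
                               atol=1e-12)


def test_isolated_cells_remain_empty(default_chm):
    values = np.full((20, 20), np.nan)
    empty = np.ones((20, 20), dtype=bool)
    values[0, 0] = 1.0
    empty[0, 0] = False
    grid = CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)
    filled = idw_fill(grid, default_chm)
    # beyond the 7x7 window of (0,0) nothing can be filled
    assert filled.empty[10, 10]
    assert not filled.empty[2, 3]


def test_fill_never_alters_populated_cells_and_is_bounded(rng, default_chm):
    grid = random_grid(rng)
    filled = idw_fill(grid, default_chm)
    src = ~grid.empty
    np.testing.assert_array_equal(filled.values[src], grid.values[src])
    lo, hi = np.nanmin(grid.values), np.nanmax(grid.values)
    new = ~filled.empty & grid.empty
    assert (filled.values[new] >= lo - 1e-12).all()
    assert (filled.values[new] <= hi + 1e-12).all()


def test_no_cascading_fill(default_chm):
    # one source at a corner; a cell 4 cells away is outside its window and
    # must remain empty even though a cell 3 away will be filled
    values = np.full((10, 1), np.nan)
    empty = np.ones((10, 1), dtype=bool)
    values[0, 0] = 1.0
    empty[0, 0] = False
    grid = CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)
    filled = idw_fill(grid, default_chm)
    assert not filled.empty[3, 0]
    assert filled.empty[4, 0]


# ------------------------------------------------------------ summarize

def two_cell_grid():
    values = np.array([[0.1, 0.3, np.nan]])
    empty = np.array([[False, False, True]])
    return CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)


def test_mean_over_nonempty_cells():
    m = summarize_grid(two_cell_grid(), ChmConfig(), plot_id="p")
    assert m.mean_height == pytest.approx(0.2)
    assert m.max_height == pytest.approx(0.3)
    assert m.filled_fraction == pytest.approx(2 / 3)


def test_mean_zero_fill_policy():
    cfg = ChmConfig(mean_over="all_cells_empty_as_zero")
    m = summarize_grid(two_cell_grid(), cfg, plot_id="p")
    assert m.mean_height == pytest.approx(0.4 / 3)


def test_constant_field_both_policies_when_full():
    values = np.full((5, 5), 0.5)
    empty = np.zeros((5, 5), dtype=bool)
    grid = CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)
    for policy in ("nonempty_cells", "all_cells_empty_as_zero"):
        m = summarize_grid(grid, ChmConfig(mean_over=policy), plot_id="p")
        assert m.mean_height == pytest.approx(0.5)
        assert m.max_height == pytest.approx(0.5)


def test_all_empty_raises():
    values = np.full((2, 2), np.nan)
    empty = np.ones((2, 2), dtype=bool)
    grid = CanopyHeightGrid(origin=(0, 0), resolution=0.01, values=values,
                            empty=empty)
    with pytest.raises(EmptyPlotError):
        summarize_grid(grid, ChmConfig(), plot_id="p")


# ------------------------------------------------------------ composition

def dense_uniform_cloud(height, rng, n=40_000):
    xy = rng.uniform(0, 1, (n, 2))
    return PointCloud(np.column_stack([xy, 100.0 + height * np.ones(n)]))


def test_uniform_canopy_recovered_exactly(unit_plot, rng, default_chm):
    cloud = dense_uniform_cloud(0.4, rng)
    terrain = build_terrain(unit_plot.corners)
    m = compute_plot_metrics(cloud, unit_plot, terrain, default_chm)
    assert m.mean_height == pytest.approx(0.4, abs=1e-6)
    assert m.max_height == pytest.approx(0.4, abs=1e-6)


def test_downward_jitter_lowers_mean(unit_plot, rng, default_chm):
    n = 40_000
    xy = rng.uniform(0, 1, (n, 2))
    z = 100.0 + 0.4 * np.ones(n)
    half = rng.uniform(size=n) < 0.5
    z[half] -= rng.uniform(0, 0.2, half.sum())
    cloud = PointCloud(np.column_stack([xy, z]))
    terrain = build_terrain(unit_plot.corners)
    m = compute_plot_metrics(cloud, unit_plot, terrain, default_chm)
    assert m.mean_height < 0.4


def test_metrics_translation_invariant(unit_plot, rng, default_chm):
    cloud = dense_uniform_cloud(0.4, rng, n=5000)
    terrain = build_terrain(unit_plot.corners)
    m0 = compute_plot_metrics(cloud, unit_plot, terrain, default_chm)
    dx, dy, dz = 1234.5, -987.25, 55.125
    shifted_cloud = PointCloud(cloud.xyz + [dx, dy, dz])
    shifted_plot = PlotRecord(
        plot_id="p1", corners=unit_plot.corners + [dx, dy, dz],
        biomass=unit_plot.biomass,
    )
    shifted_terrain = build_terrain(shifted_plot.corners)
    m1 = compute_plot_metrics(shifted_cloud, shifted_plot, shifted_terrain,
                              default_chm)
    assert m1.mean_height == pytest.approx(m0.mean_height, abs=1e-9)
    assert m1.max_height == pytest.approx(m0.max_height, abs=1e-9)


def test_resolution_refinement_converges(rng):
    """Mean height approaches the true surface mean as cells shrink."""
    from canopymass import SceneParams, generate_canopy_field

    params = SceneParams(seed=3, roughness=0.25, canopy_length_scale=0.3)
    field = generate_canopy_field(params, 1.0, 0.5,
                                  np.random.default_rng(3))
    n = 400
    c = (np.arange(n) + 0.5) / n
    xx, yy = np.meshgrid(c, c, indexing="ij")
    true_mean = field(xx.ravel(), yy.ravel()).mean()
    xy = rng.uniform(0, 1, (200_000, 2))
    h = field(xy[:, 0], xy[:, 1])
    errors = []
    for res in (0.04, 0.02, 0.01):
        cfg = ChmConfig(resolution=res)
        grid = idw_fill(rasterize_max(xy, h, (0, 0, 1, 1), cfg), cfg)
        m = summarize_grid(grid, cfg, plot_id="x")
        errors.append(abs(m.mean_height - true_mean))
    assert errors[2] < errors[0]
    assert errors[2] < 0.01
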