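"""Gridded landscapes: optimum interpolation, dispersal kernel, geometry
and plain-text raster I/O."""

import numpy as np
import pytest

from evorange.fixtures import FixtureSpec, make_landscape, make_scenario
from evorange.landscape import ClimateScenario, EnvScaler, Landscape, \
    disperse_seeds, grid_area, read_ascii_grid, theta_at, theta_field, \
    write_ascii_grid


@pytest.fixture(scope="module")
def land():
    return make_landscape(FixtureSpec(grid_shape=(12, 12), seed=3))


@pytest.fixture(scope="module")
def scen(land):
    return make_scenario(FixtureSpec(grid_shape=(12, 12), seed=3), land,
                         "moderate")


def test_theta_constant_after_2090(land, scen):
    np.testing.assert_array_equal(theta_field(land, scen, 2150),
                                  theta_field(land, scen, 2090))
    np.testing.assert_array_equal(theta_field(land, scen, 2000),
                                  theta_field(land, scen, 2010))


def test_theta_linear_interpolation_midpoint(land, scen):
    mid = theta_field(land, scen, 2045)
    mean = 0.5 * (theta_field(land, scen, 2040) + theta_field(land, scen, 2050))
    np.testing.assert_allclose(mid, mean, rtol=1e-12)


def test_theta_carbonate_static(land, scen):
    for year in (2010, 2047, 2090, 2120):
        np.testing.assert_array_equal(theta_field(land, scen, year)[..., 2],
                                      land.carbonate)


def test_theta_year_out_of_range(land, scen):
    with pytest.raises(ValueError):
        theta_at(land, scen, (0, 0), 1999)
    with pytest.raises(ValueError):
        theta_at(land, scen, (0, 0), 2151)


def test_grid_area_examples():
    flat = np.zeros((32, 32))
    assert grid_area(Landscape(flat, flat, flat, 250.0)) == pytest.approx(64.0)
    one = np.zeros((1, 1))
    assert grid_area(Landscape(one, one, one, 1000.0)) == pytest.approx(1.0)
    assert grid_area(Landscape(flat, flat, flat, 500.0)) \
        == pytest.approx(4 * 64.0)


def test_dispersal_stay_probability_zero_movement(rng):
    r = np.arange(100) % 10
    c = np.arange(100) // 10
    rows, cols, lost = disperse_seeds(r, c, (10, 10), 250.0, 0.0, 300.0, rng)
    np.testing.assert_array_equal(rows, r)
    np.testing.assert_array_equal(cols, c)
    assert not lost.any()


def test_dispersal_conservation(rng):
    """Staying + moved-within-grid + lost-off-grid equals produced."""
    n = 20000
    r = rng.integers(0, 16, n)
    c = rng.integers(0, 16, n)
    rows, cols, lost = disperse_seeds(r, c, (16, 16), 250.0, 0.5, 400.0, rng)
    stayed = int(((rows == r) & (cols == c) & ~lost).sum())
    moved = int((~lost).sum()) - stayed
    assert stayed + moved + int(lost.sum()) == n
    assert lost.sum() > 0 and moved > 0


def test_dispersal_kernel_mean_distance(rng):
    """Realized dispersal distances of moved seeds match the kernel mean
    (sampling oracle; large grid so nothing is lost)."""
    n = 100000
    mid = 200
    r = np.full(n, mid)
    c = np.full(n, mid)
    mean_d = 2000.0
    cell = 250.0
    rows, cols, lost = disperse_seeds(r, c, (401, 401), cell, 1.0, mean_d, rng)
    assert lost.sum() == 0
    d = np.hypot(rows - mid, cols - mid) * cell
    # cell-centre rounding keeps the mean within a cell of the kernel mean
    assert d.mean() == pytest.approx(mean_d, abs=cell / 2)


def test_corner_cell_offgrid_fraction_matches_integration(rng):
    """Off-grid loss from a corner cell equals the numeric integral of
    the exponential kernel over the grid interior."""
    R = C = 12
    cell = 250.0
    mean_d = 600.0
    n = 200000
    rows, cols, lost = disperse_seeds(np.zeros(n, int), np.zeros(n, int),
                                      (R, C), cell, 1.0, mean_d, rng)
    sim_frac = lost.mean()
    # numeric polar integration of the displacement distribution
    d = np.linspace(1e-3, 12 * mean_d, 4000)
    th = np.linspace(0, 2 * np.pi, 1441, endpoint=False)
    dd, tt = np.meshgrid(d, th, indexing="ij")
    drow = np.rint(dd * np.sin(tt) / cell)
    dcol = np.rint(dd * np.cos(tt) / cell)
    inside = (drow >= 0) & (drow < R) & (dcol >= 0) & (dcol < C)
    pdf = np.exp(-d / mean_d) / mean_d
    p_inside = np.trapezoid(pdf * inside.mean(axis=1), d)
    assert sim_frac == pytest.approx(1.0 - p_inside, abs=0.01)


def test_ascii_grid_roundtrip(tmp_path, rng):
    grid = rng.normal(size=(7, 5))
    path = tmp_path / "layer.asc"
    write_ascii_grid(path, grid, cellsize=250.0, xllcorner=10.0, yllcorner=20.0)
    back, header = read_ascii_grid(path)
    np.testing.assert_allclose(back, grid, rtol=1e-9)
    assert header["ncols"] == 5 and header["nrows"] == 7
    assert header["cellsize"] == 250.0


def test_env_scaler_roundtrip(land, scen):
    scaler = EnvScaler.fit(land, scen)
    field = theta_field(land, scen, 2050)
    z = scaler.transform(field)
    np.testing.assert_allclose(scaler.inverse(z), field, rtol=1e-10)
    z0 = scaler.transform(theta_field(land, scen, 2010)).reshape(-1, 3)
    np.testing.assert_allclose(z0.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z0.std(axis=0), 1.0, rtol=1e-9)
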