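"""Raster interpolation contracts, including the brute-force plane-solve
oracle the point-location + barycentric implementation must agree with."""

import numpy as np
import pandas as pd
import pytest

from geopharm import env_raster as er
from geopharm.errors import DegenerateGeometryError, InvalidInputError


def points_df(rows):
    return pd.DataFrame(rows, columns=["lat", "lon", "value"])


# ---------------------------------------------------------------- brute-force
# oracle: exhaustive point-in-triangle test + plane equation solve

def oracle_interpolate(pts: pd.DataFrame, tri: er.Triangulation, lat, lon):
    q = np.array([lon, lat])
    for verts in tri.simplices:
        p = tri.xy[verts]
        # solve the plane z = a*lon + b*lat + c through the three vertices
        A = np.column_stack([p, np.ones(3)])
        sign = np.sign(np.linalg.det(A))
        inside = True
        for i in range(3):
            e1, e2 = p[(i + 1) % 3] - p[i], q - p[i]
            if sign * (e1[0] * e2[1] - e1[1] * e2[0]) < -1e-12:
                inside = False
                break
        if inside:
            coef = np.linalg.solve(A, tri.values[verts])
            return coef[0] * lon + coef[1] * lat + coef[2]
    return None


class TestGrid:
    def test_one_degree_grid_has_global_cell_count(self):
        grid = er.build_grid(1.0)
        assert grid.n_cells == 64800
        assert grid.shape == (180, 360)
        assert grid.lat_centers[0] == -89.5 and grid.lat_centers[-1] == 89.5
        assert np.all(np.diff(grid.lat_centers) > 0)

    def test_coarse_grid_arithmetic(self):
        assert er.build_grid(90.0).n_cells == 8

    @pytest.mark.parametrize("bad", [7.0, 0.0, -1.0])
    def test_non_divisor_resolution_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            er.build_grid(bad)


class TestTriangulate:
    def test_minimal_triangle(self):
        tri = er.triangulate(points_df([(0, 0, 1.0), (0, 2, 2.0), (2, 0, 3.0)]))
        assert tri.n_triangles == 1
        assert set(tri.hull) == {0, 1, 2}

    def test_square_satisfies_empty_circumcircle(self):
        pts = points_df([(0, 0, 0), (0, 1, 1), (1, 0, 2), (1, 1, 3)])
        tri = er.triangulate(pts)
        assert tri.n_triangles == 2
        # brute-force circumcircle check over all (triangle, point) pairs
        for verts in tri.simplices:
            p = tri.xy[verts]
            d = np.column_stack([p, (p**2).sum(axis=1), np.ones(3)])
            for j in range(len(tri.xy)):
                if j in verts:
                    continue
                q = tri.xy[j]
                mat = np.vstack([d, [q[0], q[1], (q**2).sum(), 1.0]])
                # orientation-normalised in-circle determinant <= 0 outside
                orient = np.linalg.det(np.column_stack([p[1] - p[0], p[2] - p[0]]))
                incircle = np.linalg.det(mat) * np.sign(orient)
                assert incircle <= 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            er.triangulate(points_df([(0, 0, 1), (1, 1, 2), (2, 2, 3)]))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            er.triangulate(points_df([(0, 0, 1), (1, 0, 2)]))


class TestInterpolate:
    def test_exact_at_vertices(self):
        pts = points_df([(0, 0, 5.0), (0, 3, 7.0), (3, 0, 9.0), (2, 2, 4.0)])
        tri = er.triangulate(pts)
        for _, row in pts.iterrows():
            got = er.interpolate_linear(pts, tri, (row.lat, row.lon))
            assert got == pytest.approx(row.value, abs=1e-12)

    def test_plane_through_three_points(self):
        # vertices (lat, lon, val) = (0,0,0), (0,2,2), (2,0,4): z = lon + 2*lat
        pts = points_df([(0, 0, 0.0), (0, 2, 2.0), (2, 0, 4.0)])
        tri = er.triangulate(pts)
        assert er.interpolate_linear(pts, tri, (0.5, 0.5)) == pytest.approx(1.5)

    def test_outside_hull_returns_marker(self):
        pts = points_df([(0, 0, 0.0), (0, 2, 2.0), (2, 0, 4.0)])
        tri = er.triangulate(pts)
        assert np.isnan(er.interpolate_linear(pts, tri, (50.0, 50.0)))

    def test_oracle_equivalence_on_random_networks(self):
        """Implementation agrees with exhaustive triangle location + plane
        solve on 100 random instances (tol 1e-9, off triangle boundaries)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 12)
            pts = points_df(np.column_stack([
                rng.uniform(-30, 30, n), rng.uniform(-60, 60, n),
                rng.uniform(0, 10, n)]))
            tri = er.triangulate(pts)
            for _ in range(5):
                lat, lon = rng.uniform(-35, 35), rng.uniform(-65, 65)
                expected = oracle_interpolate(pts, tri, lat, lon)
                got = er.interpolate_linear(pts, tri, (lat, lon))
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_value_within_triangle_vertex_bounds(self):
        rng = np.random.default_rng(1)
        pts = points_df(np.column_stack([
            rng.uniform(-20, 20, 15), rng.uniform(-20, 20, 15),
            rng.uniform(0, 100, 15)]))
        tri = er.triangulate(pts)
        for _ in range(50):
            lat, lon = rng.uniform(-20, 20, 2)
            idx, w = er._locate(tri, np.array([[lon, lat]]))
            if idx[0] < 0:
                continue
            vals = tri.values[tri.simplices[idx[0]]]
            got = er.interpolate_linear(pts, tri, (lat, lon))
            assert vals.min() - 1e-9 <= got <= vals.max() + 1e-9


class TestNearest:
    def test_single_point_dominates(self):
        pts = points_df([(10, 10, 3.5)])
        assert er.fill_nearest(pts, (-80, 100)) == 3.5

    def test_tie_broken_by_lowest_index(self):
        pts = points_df([(0, -1, 1.0), (0, 1, 2.0)])
        assert er.fill_nearest(pts, (5, 0)) == 1.0

    def test_exact_at_point_location(self):
        pts = points_df([(3, 4, 9.0), (0, 0, 1.0)])
        assert er.fill_nearest(pts, (3, 4)) == 9.0

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidInputError):
            er.fill_nearest(points_df([]), (0, 0))


class TestBuildRaster:
    def test_constant_field_reproduced_everywhere(self):
        rng = np.random.default_rng(0)
        rows = np.column_stack([rng.uniform(-80, 80, 40),
                                rng.uniform(-170, 170, 40),
                                np.full(40, 6.25)])
        pts = points_df(rows)
        raster = er.build_raster(pts, pts, resolution=10.0)
        np.testing.assert_allclose(raster.uv_annual, 6.25, atol=1e-9)
        np.testing.assert_allclose(raster.pm25_ug_m3, 6.25, atol=1e-9)

    def test_affine_field_exact_inside_hull(self):
        # linear interpolation reproduces z = a*lat + b*lon + c exactly
        rng = np.random.default_rng(3)
        lat = np.concatenate([[-89.9, -89.9, 89.9, 89.9], rng.uniform(-85, 85, 60)])
        lon = np.concatenate([[-179.9, 179.9, -179.9, 179.9],
                              rng.uniform(-175, 175, 60)])
        a, b, c = 0.3, -0.1, 20.0
        pts = points_df(np.column_stack([lat, lon, a * lat + b * lon + c]))
        raster = er.build_raster(pts, pts, resolution=15.0)
        lon_g, lat_g = np.meshgrid(raster.grid.lon_centers, raster.grid.lat_centers)
        expected = a * lat_g + b * lon_g + c
        inside = ~raster.uv_nearest
        assert inside.sum() > 0
        np.testing.assert_allclose(raster.uv_annual[inside], expected[inside],
                                   atol=1e-9)

    def test_fill_flag_marks_exactly_outside_hull_cells(self):
        rng = np.random.default_rng(5)
        pts = points_df(np.column_stack([
            rng.uniform(-40, 40, 25), rng.uniform(-90, 90, 25),
            rng.uniform(0, 5, 25)]))
        raster = er.build_raster(pts, pts, resolution=30.0)
        tri = er.triangulate(pts)
        lon_g, lat_g = np.meshgrid(raster.grid.lon_centers, raster.grid.lat_centers)
        q = np.column_stack([lon_g.ravel(), lat_g.ravel()])
        idx, _ = er._locate(tri, q)
        np.testing.assert_array_equal(raster.uv_nearest.ravel(), idx < 0)

    def test_csv_schema_and_row_count(self, tmp_path):
        rng = np.random.default_rng(6)
        pts = points_df(np.column_stack([
            rng.uniform(-80, 80, 10), rng.uniform(-170, 170, 10),
            rng.uniform(0, 5, 10)]))
        path = tmp_path / "raster.csv"
        raster = er.build_raster(pts, pts, resolution=30.0, out_csv=path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["lat", "lon", "UV_Annual", "PM25_ug_m3"]
        assert len(df) == raster.grid.n_cells
        assert np.isfinite(df.to_numpy()).all()
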