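import json

import numpy as np
import pytest
import shapely

from pivpressure.flow_data import (
    BodyKinematics,
    BoundaryConditionSpec,
    PressureFieldSeries,
    ScalingSet,
    VelocityFieldSeries,
    mask_body_interior,
    nondimensionalize,
    read_kinematics,
    read_pressure_series,
    read_velocity_series,
    redimensionalize,
    write_kinematics,
    write_pressure_series,
    write_velocity_series,
)


class TestScalingSet:
    def test_rejects_nonpositive_scales(self):
        with pytest.raises(ValueError):
            ScalingSet(L_char=0.0)
        with pytest.raises(ValueError):
            ScalingSet(Re=-1.0)

    def test_consistency_check_against_nu(self):
        # zebrafish-style case: L = 22 mm, T = 0.15 s, Re = 918
        L, T = 0.022, 0.15
        U = L / T
        nu = L * U / 918.0
        s = ScalingSet(L_char=L, T_char=T, U_char=U, rho=1000.0, nu=nu, Re=918.0)
        assert s.time_coefficient == pytest.approx(1.0)
        with pytest.raises(ValueError, match="inconsistent"):
            ScalingSet(L_char=L, T_char=T, U_char=U, nu=nu, Re=500.0)

    def test_tailbeat_convention_matches_L2f_over_nu(self):
        # Re_L = L^2 f / nu with U = L f is the same number as L U / nu
        L, f = 1.0, 1.0
        nu = L**2 * f / 5000.0
        s = ScalingSet(L_char=L, T_char=1 / f, U_char=L * f, nu=nu, Re=5000.0)
        assert s.Re == pytest.approx(L**2 * f / nu)

    def test_nondimensionalization_roundtrip_is_identity(self, small_series):
        s = ScalingSet(L_char=0.022, T_char=0.15, U_char=0.022 / 0.15)
        back = redimensionalize(nondimensionalize(small_series, s), s)
        np.testing.assert_allclose(back.u, small_series.u, atol=1e-12)
        np.testing.assert_allclose(back.x_coords, small_series.x_coords, atol=1e-12)
        np.testing.assert_allclose(back.times, small_series.times, atol=1e-12)

    def test_body_length_maps_to_unity(self):
        # a body spanning 22 mm becomes one body length after scaling
        s = ScalingSet(L_char=0.022, T_char=0.15, U_char=1.0)
        x = np.linspace(0.0, 0.022, 5)
        ser = VelocityFieldSeries(x, x, np.array([0.0, 0.15]),
                                  u=np.zeros((5, 5, 2)), v=np.zeros((5, 5, 2)))
        nd = nondimensionalize(ser, s)
        assert nd.x_coords[-1] - nd.x_coords[0] == pytest.approx(1.0)
        assert nd.times[-1] == pytest.approx(1.0)

    def test_identity_scaling_is_noop(self, small_series):
        nd = nondimensionalize(small_series, ScalingSet())
        np.testing.assert_array_equal(nd.u, small_series.u)


class TestSeriesValidation:
    def test_nonuniform_grid_rejected(self):
        x = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            VelocityFieldSeries(x, x, np.array([0.0, 1.0]),
                                u=np.zeros((4, 4, 2)), v=np.zeros((4, 4, 2)))

    def test_decreasing_times_rejected(self):
        x = np.linspace(0, 1, 4)
        with pytest.raises(ValueError, match="not increasing"):
            VelocityFieldSeries(x, x, np.array([0.0, 2.0, 1.0]),
                                u=np.zeros((4, 4, 3)), v=np.zeros((4, 4, 3)))

    def test_nan_in_valid_region_rejected(self):
        x = np.linspace(0, 1, 4)
        u = np.zeros((4, 4, 2))
        u[1, 1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            VelocityFieldSeries(x, x, np.array([0.0, 1.0]), u=u, v=np.zeros_like(u))

    def test_nan_under_mask_accepted(self):
        x = np.linspace(0, 1, 4)
        u = np.zeros((4, 4, 2))
        u[1, 1, 0] = np.nan
        mask = np.ones((4, 4, 2), bool)
        mask[1, 1, 0] = False
        s = VelocityFieldSeries(x, x, np.array([0.0, 1.0]), u=u, v=np.zeros((4, 4, 2)),
                                valid_mask=mask)
        assert not s.valid_mask[1, 1, 0]

    def test_unknown_gauge_rejected(self):
        x = np.linspace(0, 1, 4)
        with pytest.raises(ValueError, match="gauge"):
            PressureFieldSeries(x, x, np.array([0.0, 1.0]),
                                p=np.zeros((4, 4, 2)), gauge="whatever")


class TestIO:
    def test_hdf5_roundtrip_bit_exact(self, small_series, tmp_path):
        path = tmp_path / "vel.h5"
        write_velocity_series(small_series, path)
        back = read_velocity_series(path)
        np.testing.assert_array_equal(back.u, small_series.u)
        np.testing.assert_array_equal(back.v, small_series.v)
        np.testing.assert_array_equal(back.x_coords, small_series.x_coords)
        np.testing.assert_array_equal(back.valid_mask, small_series.valid_mask)

    def test_csv_roundtrip_to_printed_precision(self, small_series, tmp_path):
        d = tmp_path / "vel_csv"
        write_velocity_series(small_series, d)
        back = read_velocity_series(d)
        assert np.max(np.abs(back.u - small_series.u)) < 1e-8
        assert back.shape == small_series.shape

    def test_pressure_roundtrip_keeps_gauge(self, tmp_path):
        x = np.linspace(0, 1, 4)
        p = PressureFieldSeries(x, x, np.array([0.0, 1.0]),
                                p=np.ones((4, 4, 2)), gauge="zero_at_boundary")
        path = tmp_path / "p.h5"
        write_pressure_series(p, path)
        assert read_pressure_series(path).gauge == "zero_at_boundary"

    def test_missing_time_step_file_rejected(self, small_series, tmp_path):
        d = tmp_path / "vel_csv"
        write_velocity_series(small_series, d)
        (d / "u_0001.csv").unlink()
        with pytest.raises(ValueError, match="missing time step"):
            read_velocity_series(d)

    def test_shuffled_times_rejected(self, small_series, tmp_path):
        d = tmp_path / "vel_csv"
        write_velocity_series(small_series, d)
        meta = json.loads((d / "meta.json").read_text())
        meta["t"] = meta["t"][::-1]
        (d / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="not increasing"):
            read_velocity_series(d)

    def test_empty_series_rejected(self, tmp_path):
        x = np.linspace(0, 1, 4)
        s = VelocityFieldSeries(x, x, np.array([0.0, 1.0]),
                                u=np.zeros((4, 4, 2)), v=np.zeros((4, 4, 2)))
        s.times = np.array([])  # sabotage after validation
        with pytest.raises(ValueError, match="empty"):
            write_velocity_series(s, tmp_path / "x.h5")

    def test_dimensional_input_requires_scaling(self, small_series, tmp_path):
        path = tmp_path / "vel.h5"
        write_velocity_series(small_series, path)
        with pytest.raises(ValueError, match="ScalingSet"):
            read_velocity_series(path, metadata={"units": "dimensional"})

    def test_kinematics_roundtrip(self, swimmer_kinematics, tmp_path):
        for target in (tmp_path / "kin.h5", tmp_path / "kin_csv"):
            write_kinematics(swimmer_kinematics, target)
            back = read_kinematics(target)
            np.testing.assert_allclose(back.contour, swimmer_kinematics.contour,
                                       atol=1e-8)
            np.testing.assert_allclose(back.surface_velocity,
                                       swimmer_kinematics.surface_velocity, atol=1e-8)


class TestBodyKinematics:
    def test_normals_unit_and_outward(self, swimmer_kinematics):
        for it in (0, 5):
            n = swimmer_kinematics.normals(it)
            np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)
            poly = swimmer_kinematics.polygon(it)
            probe = swimmer_kinematics.contour[it] + 1e-4 * n
            assert not shapely.contains_xy(poly, probe[:, 0], probe[:, 1]).any()

    def test_normal_velocity_is_projection(self, swimmer_kinematics):
        it = 3
        n = swimmer_kinematics.normals(it)
        un = swimmer_kinematics.normal_velocity(it)
        manual = (swimmer_kinematics.surface_velocity[it] * n).sum(axis=1)
        np.testing.assert_allclose(un, manual, atol=1e-12)

    def test_explicit_closing_point_dropped(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        kin = BodyKinematics(times=np.array([0.0]), contour=sq[None],
                             surface_velocity=np.zeros_like(sq)[None])
        assert kin.n_points == 4

    def test_degenerate_contour_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            BodyKinematics(times=np.array([0.0]), contour=line[None],
                           surface_velocity=np.zeros_like(line)[None])


class TestMasking:
    @staticmethod
    def _ray_cast_inside(px, py, poly):
        """Brute-force point-in-polygon (ray casting), boundary counts inside."""
        n = len(poly)
        inside = False
        for i in range(n):
            x1, y1 = poly[i]
            x2, y2 = poly[(i + 1) % n]
            # on-segment test
            cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
            if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                    and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
            if (y1 > py) != (y2 > py):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                if px < xint:
                    inside = not inside
        return inside

    def test_mask_matches_ray_casting_oracle(self, swimmer_kinematics):
        kin = swimmer_kinematics
        # grid offset avoids nodes landing exactly on contour vertices, where
        # the oracle's on-segment tolerance and exact geometry could disagree
        x = np.linspace(-0.1, 1.1, 25) + 0.0037
        y = np.linspace(-0.3, 0.3, 13) + 0.0041
        t = kin.times[:3]
        ser = VelocityFieldSeries(x, y, t, u=np.zeros((13, 25, 3)),
                                  v=np.zeros((13, 25, 3)))
        masked = mask_body_interior(ser, kin)
        for it in range(3):
            poly = kin.contour[it]
            expected = np.array([
                [self._ray_cast_inside(xi, yi, poly) for xi in x] for yi in y
            ])
            np.testing.assert_array_equal(~masked.valid_mask[:, :, it], expected)
        assert (~masked.valid_mask).sum() > 0

    def test_masking_idempotent(self, swimmer_kinematics):
        kin = swimmer_kinematics
        x = np.linspace(-0.1, 1.1, 20)
        ser = VelocityFieldSeries(x, np.linspace(-0.3, 0.3, 10), kin.times[:2],
                                  u=np.zeros((10, 20, 2)), v=np.zeros((10, 20, 2)))
        once = mask_body_interior(ser, kin)
        twice = mask_body_interior(once, kin)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)

    def test_centroid_masked_far_node_not(self, swimmer_kinematics):
        kin = swimmer_kinematics
        x = np.array([0.5, 5.0, 9.5])  # centroid-ish, far, far
        ser = VelocityFieldSeries(x, np.array([-4.5, 0.0, 4.5]), kin.times[:2],
                                  u=np.zeros((3, 3, 2)), v=np.zeros((3, 3, 2)))
        masked = mask_body_interior(ser, kin)
        assert not masked.valid_mask[1, 0, 0]   # (y=0, x=0.5) inside body
        assert masked.valid_mask[1, 1, 0]       # x=5 far outside


class TestBoundaryConditionSpec:
    def test_inlet_requires_values(self):
        with pytest.raises(ValueError, match="inlet"):
            BoundaryConditionSpec(left="inlet_velocity")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown boundary kind"):
            BoundaryConditionSpec(top="free_slip")

    def test_edges_query(self):
        bc = BoundaryConditionSpec(top="zero_pressure", bottom="zero_pressure",
                                   left="inlet_velocity", inlet_u=1.0, inlet_v=0.0)
        assert set(bc.edges("zero_pressure")) == {"top", "bottom"}
        assert bc.edges("inlet_velocity") == ["left"]
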