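import numpy as np
import pytest

from pivpressure.flow_data import (
    BodyKinematics,
    BoundaryConditionSpec,
    ScalingSet,
    VelocityFieldSeries,
)
from pivpressure.network import Network, NetworkConfig, forward_values
from pivpressure.pinn_reconstruction import (
    LossWeights,
    PinnDivergenceError,
    PinnPressure,
    TrainingConfig,
    boundary_losses,
    data_loss,
    ns_residuals,
    total_loss,
)

TINY_NET = NetworkConfig(n_hidden_layers=2, neurons_per_layer=8,
                         parameter_init_seed=1)
TINY_TRAIN = TrainingConfig(minibatch_size=256, epochs=5, learning_rate=2e-3,
                            sampling_seed=2)


@pytest.fixture(scope="module")
def rnd_net():
    return Network(NetworkConfig(n_hidden_layers=2, neurons_per_layer=10,
                                 parameter_init_seed=4))


class _ForcedOutputNet(Network):
    """Network whose forward is overridden to a fixed analytic map (tests)."""


def _constant_output_net(u0, v0, p0):
    net = Network(NetworkConfig(n_hidden_layers=1, neurons_per_layer=2,
                                parameter_init_seed=0))
    for p in net.params:
        p.value[:] = 0.0
    W, b, g, hidden = net._layers[-1]
    b.value[:] = [u0, v0, p0]
    return net


class TestLossWeights:
    def test_defaults(self):
        w = LossWeights()
        assert (w.lambda_data, w.lambda_ic, w.lambda_bc, w.lambda_eq) == \
            (100.0, 0.0, 100.0, 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_bc=-1.0)


class TestDataLoss:
    def test_exact_fit_gives_zero(self):
        net = _constant_output_net(0.3, -0.2, 0.0)
        batch = np.array([[0.1, 0.2, 0.0, 0.3, -0.2],
                          [0.5, 0.5, 0.1, 0.3, -0.2]])
        assert data_loss(net, batch).value == pytest.approx(0.0, abs=1e-30)

    def test_uniform_offset_gives_delta_squared(self):
        delta = 0.37
        net = _constant_output_net(delta, 0.0, 0.0)
        batch = np.zeros((20, 5))  # measured u = v = 0
        assert data_loss(net, batch).value == pytest.approx(delta**2, rel=1e-12)

    def test_matches_bruteforce_loop(self, rnd_net):
        rng = np.random.default_rng(8)
        batch = rng.normal(size=(40, 5))
        pred = forward_values(rnd_net, batch[:, :3]).value
        expected = np.mean((pred[:, 0] - batch[:, 3]) ** 2) + \
            np.mean((pred[:, 1] - batch[:, 4]) ** 2)
        assert data_loss(rnd_net, batch).value == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self, rnd_net):
        with pytest.raises(ValueError):
            data_loss(rnd_net, np.zeros((0, 5)))


class TestNSResiduals:
    def test_constant_output_gives_zero_residuals(self):
        net = _constant_output_net(1.2, -0.5, 3.0)
        pts = np.random.default_rng(0).normal(size=(15, 3))
        res, loss = ns_residuals(net, pts, Re=100.0)
        assert np.abs(res["x_momentum"]).max() < 1e-14
        assert np.abs(res["y_momentum"]).max() < 1e-14
        assert loss.value == pytest.approx(0.0, abs=1e-28)

    def test_continuity_included_only_on_request(self, rnd_net):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        res1, _ = ns_residuals(rnd_net, pts, Re=10.0, enforce_continuity=False)
        res2, _ = ns_residuals(rnd_net, pts, Re=10.0, enforce_continuity=True)
        assert "continuity" not in res1
        assert "continuity" in res2

    def test_nonpositive_reynolds_rejected(self, rnd_net):
        with pytest.raises(ValueError):
            ns_residuals(rnd_net, np.zeros((3, 3)), Re=0.0)

    def test_residual_derivatives_match_network_finite_differences(self, rnd_net):
        """Assemble the x-momentum residual from FD of the network itself."""
        pts = np.random.default_rng(2).normal(size=(12, 3))
        res, _ = ns_residuals(rnd_net, pts, Re=50.0)
        h = 1e-4

        def f(p):
            return forward_values(rnd_net, p).value

        base = f(pts)
        parts = {}
        for i, nm in ((0, "x"), (1, "y"), (2, "t")):
            pp, pm = pts.copy(), pts.copy()
            pp[:, i] += h
            pm[:, i] -= h
            parts[f"d{nm}"] = (f(pp) - f(pm)) / (2 * h)
            parts[f"d{nm}{nm}"] = (f(pp) - 2 * base + f(pm)) / h**2
        u, v = base[:, 0], base[:, 1]
        fd_resid = (parts["dt"][:, 0] + u * parts["dx"][:, 0]
                    + v * parts["dy"][:, 0] + parts["dx"][:, 2]
                    - (parts["dxx"][:, 0] + parts["dyy"][:, 0]) / 50.0)
        np.testing.assert_allclose(res["x_momentum"], fd_resid, atol=1e-5)


class TestBoundaryLosses:
    def test_still_body_zero_velocity_net_gives_zero(self):
        net = _constant_output_net(0.0, 0.0, 5.0)
        body = np.zeros((10, 6))
        body[:, 3] = 1.0  # normals +x; u_n = 0
        terms = boundary_losses(net, body_batch=body)
        assert terms["body"].value == pytest.approx(0.0, abs=1e-30)

    def test_zero_pressure_edge_constant_p_gives_c_squared(self):
        c = -0.8
        net = _constant_output_net(0.0, 0.0, c)
        pts = np.random.default_rng(3).normal(size=(7, 3))
        terms = boundary_losses(net, zero_pressure_batch=pts)
        assert terms["zero_pressure"].value == pytest.approx(c**2, rel=1e-12)

    def test_body_term_matches_bruteforce(self, rnd_net):
        rng = np.random.default_rng(5)
        body = rng.normal(size=(25, 6))
        n = body[:, 3:5]
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        body[:, 3:5] = n
        pred = forward_values(rnd_net, body[:, :3]).value
        expected = np.mean((pred[:, 0] * n[:, 0] + pred[:, 1] * n[:, 1]
                            - body[:, 5]) ** 2)
        terms = boundary_losses(rnd_net, body_batch=body)
        assert terms["body"].value == pytest.approx(expected, rel=1e-12)

    def test_inlet_term(self, rnd_net):
        rng = np.random.default_rng(6)
        inlet = rng.normal(size=(9, 5))
        pred = forward_values(rnd_net, inlet[:, :3]).value
        expected = np.mean((pred[:, 0] - inlet[:, 3]) ** 2) + \
            np.mean((pred[:, 1] - inlet[:, 4]) ** 2)
        terms = boundary_losses(rnd_net, inlet_batch=inlet)
        assert terms["inlet"].value == pytest.approx(expected, rel=1e-12)


class TestTotalLoss:
    def _batches(self, rng):
        return {
            "data": rng.normal(size=(20, 5)),
            "collocation": rng.normal(size=(15, 3)),
            "body": rng.normal(size=(8, 6)),
            "zero_pressure": rng.normal(size=(6, 3)),
        }

    def test_all_zero_weights_give_zero(self, rnd_net):
        batches = self._batches(np.random.default_rng(7))
        total, _ = total_loss(rnd_net, batches, LossWeights(0, 0, 0, 0), Re=10.0)
        assert total.value == 0.0

    def test_weighted_combination(self, rnd_net):
        batches = self._batches(np.random.default_rng(9))
        a = data_loss(rnd_net, batches["data"]).value
        b = (boundary_losses(rnd_net, body_batch=batches["body"],
                             zero_pressure_batch=batches["zero_pressure"]))
        bsum = sum(t.value for t in b.values())
        _, c = ns_residuals(rnd_net, batches["collocation"], Re=10.0)
        total, breakdown = total_loss(rnd_net, batches, LossWeights(), Re=10.0)
        assert total.value == pytest.approx(100 * a + 100 * bsum + c.value, rel=1e-12)

    def test_breakdown_is_consistent(self, rnd_net):
        batches = self._batches(np.random.default_rng(10))
        w = LossWeights()
        total, br = total_loss(rnd_net, batches, w, Re=10.0)
        recomputed = (w.lambda_data * br["data"]
                      + w.lambda_bc * (br["bc_body"] + br["bc_zero_pressure"])
                      + w.lambda_eq * br["equation"])
        assert br["total"] == pytest.approx(recomputed, abs=1e-12)
        assert br["total"] == pytest.approx(total.value, abs=1e-12)

    def test_gauge_freedom_without_pressure_terms(self, rnd_net):
        """Adding a constant to the pressure output changes no active loss
        when no pressure boundary term is used."""
        rng = np.random.default_rng(11)
        batches = {"data": rng.normal(size=(20, 5)),
                   "collocation": rng.normal(size=(15, 3)),
                   "body": rng.normal(size=(8, 6))}
        w = LossWeights()
        t1, _ = total_loss(rnd_net, batches, w, Re=10.0)
        W, b, g, _ = rnd_net._layers[-1]
        b.value[2] += 123.4  # shift p output only
        t2, _ = total_loss(rnd_net, batches, w, Re=10.0)
        b.value[2] -= 123.4
        assert t2.value == pytest.approx(t1.value, rel=1e-12)


def _tiny_dataset():
    x = np.linspace(0.0, 1.0, 8)
    t = np.linspace(0.0, 0.2, 3)
    X, Y = np.meshgrid(x, x)
    u = np.stack([np.sin(2 * np.pi * X) * np.exp(-ti) for ti in t], axis=2)
    v = np.stack([np.cos(2 * np.pi * Y) * np.exp(-ti) for ti in t], axis=2)
    return VelocityFieldSeries(x, x, t, u=u, v=v)


class TestTraining:
    def test_same_seeds_identical_histories(self):
        ser = _tiny_dataset()
        s = ScalingSet(Re=100.0)
        h1 = PinnPressure(ser, s, network=TINY_NET, training=TINY_TRAIN).fit().history
        h2 = PinnPressure(ser, s, network=TINY_NET, training=TINY_TRAIN).fit().history
        assert [e["total"] for e in h1] == [e["total"] for e in h2]

    def test_pure_regression_loss_decreases(self):
        ser = _tiny_dataset()
        s = ScalingSet(Re=100.0)
        w = LossWeights(lambda_data=1.0, lambda_bc=0.0, lambda_eq=0.0)
        net = NetworkConfig(n_hidden_layers=2, neurons_per_layer=16,
                            parameter_init_seed=1)
        tr = TrainingConfig(minibatch_size=4096, epochs=400, learning_rate=1e-2,
                            sampling_seed=0)
        res = PinnPressure(ser, s, network=net, weights=w, training=tr).fit()
        losses = np.array([e["data"] for e in res.history])
        # overall downward trend on a noiseless dataset
        assert losses[-1] < 0.2 * losses[0]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # inf/nan arithmetic expected
    def test_divergence_aborts_with_diagnostic(self):
        ser = _tiny_dataset()
        tr = TrainingConfig(minibatch_size=256, epochs=50,
                            learning_rate=float("inf"), sampling_seed=0)
        with pytest.raises(PinnDivergenceError, match="non-finite"):
            PinnPressure(ser, ScalingSet(Re=100.0), network=TINY_NET,
                         training=tr).fit()

    def test_body_bc_without_kinematics_rejected(self):
        ser = _tiny_dataset()
        bc = BoundaryConditionSpec(body=True)
        with pytest.raises(ValueError, match="kinematics"):
            PinnPressure(ser, ScalingSet(Re=100.0), bc_spec=bc, network=TINY_NET)

    def test_checkpoint_resume_matches_uninterrupted(self, tmp_path):
        ser = _tiny_dataset()
        s = ScalingSet(Re=100.0)
        tr = TrainingConfig(minibatch_size=256, epochs=6, learning_rate=2e-3,
                            sampling_seed=3)
        full = PinnPressure(ser, s, network=TINY_NET, training=tr).fit()
        ckpt = tmp_path / "ck.npz"
        PinnPressure(ser, s, network=TINY_NET, training=tr).fit(
            checkpoint_path=ckpt, checkpoint_every=3)
        resumed = PinnPressure(ser, s, network=TINY_NET, training=tr).fit(
            resume_from=ckpt)
        assert resumed.history[-1]["total"] == pytest.approx(
            full.history[-1]["total"], abs=1e-10)
        X = np.random.default_rng(0).normal(size=(5, 3))
        np.testing.assert_allclose(resumed.model(X), full.model(X), atol=1e-12)


@pytest.fixture(scope="module")
def trained():
    ser = _tiny_dataset()
    return PinnPressure(ser, ScalingSet(Re=100.0), network=TINY_NET,
                        training=TINY_TRAIN).fit()


class TestResults:

    def test_predict_is_pure_function(self, trained):
        v1, p1 = trained.predict_field()
        v2, p2 = trained.predict_field()
        np.testing.assert_array_equal(v1.u, v2.u)
        np.testing.assert_array_equal(p1.p, p2.p)

    def test_fine_grid_restriction_matches_coarse(self, trained):
        ser = trained.spec.series
        xf = np.linspace(ser.x_coords[0], ser.x_coords[-1],
                         2 * ser.x_coords.size - 1)
        vf, pf = trained.predict_field(x_coords=xf, y_coords=xf)
        vc, pc = trained.predict_field()
        np.testing.assert_allclose(vf.u[::2, ::2], vc.u, atol=1e-14)
        # pressures carry a per-time gauge constant tied to each grid's mean
        a = pf.p[::2, ::2] - pf.p[::2, ::2].mean(axis=(0, 1), keepdims=True)
        b = pc.p - pc.p.mean(axis=(0, 1), keepdims=True)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_mean_gauge_when_no_pressure_bc(self, trained):
        _, pres = trained.predict_field()
        assert pres.gauge == "zero_mean"
        assert np.abs(pres.p.mean(axis=(0, 1))).max() < 1e-12

    def test_summary_mentions_architecture(self, trained):
        s = trained.summary()
        assert "2 x 8" in s
        assert "loss" in s

    def test_surface_pressure_exact_contour_evaluation(self, trained,
                                                       swimmer_kinematics):
        kin = swimmer_kinematics
        p, dist = trained.surface_pressure(0.0, kinematics=kin)
        assert p.shape == (kin.n_points,)
        np.testing.assert_array_equal(dist, np.zeros(kin.n_points))
        # evaluating the model at the same points gives the same pressures
        pts = kin.contour[0]
        direct = trained.model(np.column_stack([pts, np.zeros(len(pts))]))[:, 2]
        np.testing.assert_array_equal(p, direct)

    def test_surface_pressure_requires_known_time(self, trained,
                                                  swimmer_kinematics):
        with pytest.raises(ValueError, match="undefined"):
            trained.surface_pressure(17.3, kinematics=swimmer_kinematics)

    def test_untrained_model_rejected(self):
        ser = _tiny_dataset()
        model = PinnPressure(ser, ScalingSet(Re=100.0), network=TINY_NET,
                             training=TINY_TRAIN)
        from pivpressure.pinn_reconstruction import PinnModel, PinnPressureResults
        from pivpressure.network import Network
        res = PinnPressureResults(model, PinnModel(Network(TINY_NET), TINY_NET,
                                                   ScalingSet(Re=100.0)), [])
        with pytest.raises(ValueError, match="not trained"):
            res.predict_field()

    def test_masked_nodes_flagged_in_prediction(self, swimmer_kinematics):
        kin = swimmer_kinematics
        x = np.linspace(-0.1, 1.1, 13)
        y = np.linspace(-0.3, 0.3, 7)
        t = kin.times[:3]
        from pivpressure.flow_data import mask_body_interior
        ser = VelocityFieldSeries(x, y, t, u=np.ones((7, 13, 3)),
                                  v=np.zeros((7, 13, 3)))
        ser = mask_body_interior(ser, kin)
        res = PinnPressure(ser, ScalingSet(Re=100.0), kinematics=kin,
                           network=TINY_NET, training=TINY_TRAIN).fit()
        _, pres = res.predict_field()
        np.testing.assert_array_equal(pres.valid_mask, ser.valid_mask)
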