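"""Physics-informed pressure reconstruction (the core method).

A fully connected network maps (x, y, t) to (u, v, p).  Training minimizes

    L = lambda_data * L_data + lambda_ic * L_ic + lambda_bc * L_bc + lambda_eq * L_eq

where ``L_data`` is the mean-square mismatch with the measured velocities,
``L_eq`` the mean-square residual of the non-dimensional 2D momentum
equations (computed with exact derivatives of the network — the continuity
residual is optional, since a 2D slice of a 3D flow is not divergence-free),
and ``L_bc`` collects the boundary terms: non-penetration on the moving body
(u . n = u_n), zero pressure and/or inlet velocity on selected external
edges.  An initial-condition term is supported but disabled by default.
Default weights: lambda_data = lambda_bc = 100, lambda_ic = 0, lambda_eq = 1.

Because only pressure *gradients* are constrained when no pressure boundary
term is active, the network pressure carries a free additive constant per
time instant; predictions are therefore returned with a declared gauge and
all comparisons in that configuration must be gauge-removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .flow_data import (
    BodyKinematics,
    BoundaryConditionSpec,
    PressureFieldSeries,
    ScalingSet,
    VelocityFieldSeries,
    mask_body_interior,
)
from .network import Network, NetworkConfig, forward_values, forward_with_derivatives

__all__ = [
    "LossWeights",
    "TrainingConfig",
    "PinnModel",
    "PinnPressure",
    "PinnPressureResults",
    "PinnDivergenceError",
    "data_loss",
    "ns_residuals",
    "boundary_losses",
    "total_loss",
    "DESK_NETWORK",
    "DESK_TRAINING",
]


class PinnDivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


@dataclass(frozen=True)
class LossWeights:
    lambda_data: float = 100.0
    lambda_ic: float = 0.0
    lambda_bc: float = 100.0
    lambda_eq: float = 1.0

    def __post_init__(self):
        for name in ("lambda_data", "lambda_ic", "lambda_bc", "lambda_eq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TrainingConfig:
    """Optimizer settings.  Full-scale defaults: mini-batch 10,000, 1500 epochs.

    An epoch is one full pass over the data-loss points; collocation and
    boundary points are sampled in independent random subsets (each capped at
    ``minibatch_size``) at every iteration, without replacement within their
    own shuffled cycles.
    """

    minibatch_size: int = 10_000
    epochs: int = 1500
    learning_rate: float = 1e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 500  # epochs
    sampling_seed: int = 0
    enforce_continuity: bool = False
    collocation_batch_size: int | None = None  # default: minibatch_size
    # optional deterministic quasi-Newton refinement after the ADAM phase,
    # on fixed batches (standard practice for physics-informed training:
    # ADAM escapes poor basins, L-BFGS then converges tightly)
    lbfgs_steps: int = 0
    lbfgs_collocation_cap: int = 2048
    lbfgs_data_cap: int | None = None  # default: all data points
    lbfgs_history_size: int = 50
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.minibatch_size < 1 or self.epochs < 0:
            raise ValueError("minibatch_size >= 1 and epochs >= 0 required")


# desk-scale presets: small enough for CPU runs, same loss structure.
# 1200 ADAM steps (240 epochs x 5 iterations) + up to 500 L-BFGS steps.
DESK_NETWORK = NetworkConfig(n_hidden_layers=4, neurons_per_layer=64, activation="tanh")
DESK_TRAINING = TrainingConfig(minibatch_size=2048, collocation_batch_size=1024,
                               epochs=240, learning_rate=2e-3,
                               lr_decay=0.5, lr_decay_every=100,
                               lbfgs_steps=500)


# ------------------------------------------------------------ loss functions
def data_loss(net: Network, batch: np.ndarray) -> Tensor:
    """Mean-square velocity mismatch: mean (u-u_d)^2 + mean (v-v_d)^2.

    ``batch`` columns: x, y, t, u, v (valid measured nodes only).
    """
    if batch.shape[0] == 0:
        raise ValueError("empty data batch")
    out = forward_values(net, batch[:, :3])
    du = out.col(0) - batch[:, 3]
    dv = out.col(1) - batch[:, 4]
    return du.square().mean() + dv.square().mean()


def ns_residuals(net: Network, points: np.ndarray, Re: float,
                 enforce_continuity: bool = False, time_coeff: float = 1.0):
    """Momentum-equation residuals at collocation ``points`` (N, 3).

    Returns ``(residuals, loss)`` where ``residuals`` is a dict of per-point
    numpy arrays (``x_momentum``, ``y_momentum`` and optionally
    ``continuity``) and ``loss`` is the taped mean-square Tensor.
    All derivatives are exact network derivatives.
    """
    if Re <= 0:
        raise ValueError("Re must be positive")
    ch = forward_with_derivatives(net, points)
    u, v = ch["val"].col(0), ch["val"].col(1)
    ux, vx, px = ch["dx"].col(0), ch["dx"].col(1), ch["dx"].col(2)
    uy, vy, py = ch["dy"].col(0), ch["dy"].col(1), ch["dy"].col(2)
    ut, vt = ch["dt"].col(0), ch["dt"].col(1)
    uxx, vxx = ch["dxx"].col(0), ch["dxx"].col(1)
    uyy, vyy = ch["dyy"].col(0), ch["dyy"].col(1)

    inv_re = 1.0 / Re
    e1 = time_coeff * ut + u * ux + v * uy + px - inv_re * (uxx + uyy)
    e2 = time_coeff * vt + u * vx + v * vy + py - inv_re * (vxx + vyy)
    loss = e1.square().mean() + e2.square().mean()
    residuals = {"x_momentum": e1.value, "y_momentum": e2.value}
    if enforce_continuity:
        e3 = ux + vy
        loss = loss + e3.square().mean()
        residuals["continuity"] = e3.value
    return residuals, loss


def boundary_losses(net: Network, body_batch: np.ndarray | None = None,
                    zero_pressure_batch: np.ndarray | None = None,
                    inlet_batch: np.ndarray | None = None) -> dict:
    """Boundary loss terms; inactive terms are absent from the returned dict.

    * ``body_batch`` (N, 6): x, y, t, n_x, n_y, u_n — non-penetration,
      mean (u n_x + v n_y - u_n)^2 over sampled surface points;
    * ``zero_pressure_batch`` (N, 3): mean p^2 on sampled edge points;
    * ``inlet_batch`` (N, 5): x, y, t, u_in, v_in — mean (u-u_in)^2+(v-v_in)^2.
    """
    terms = {}
    if body_batch is not None and body_batch.shape[0] > 0:
        out = forward_values(net, body_batch[:, :3])
        un_pred = out.col(0) * body_batch[:, 3] + out.col(1) * body_batch[:, 4]
        terms["body"] = (un_pred - body_batch[:, 5]).square().mean()
    if zero_pressure_batch is not None and zero_pressure_batch.shape[0] > 0:
        out = forward_values(net, zero_pressure_batch[:, :3])
        terms["zero_pressure"] = out.col(2).square().mean()
    if inlet_batch is not None and inlet_batch.shape[0] > 0:
        out = forward_values(net, inlet_batch[:, :3])
        terms["inlet"] = ((out.col(0) - inlet_batch[:, 3]).square().mean()
                          + (out.col(1) - inlet_batch[:, 4]).square().mean())
    return terms


def total_loss(net: Network, batches: dict, weights: LossWeights, Re: float,
               enforce_continuity: bool = False, time_coeff: float = 1.0):
    """Weighted composite loss; returns (Tensor total, dict breakdown of floats).

    ``batches`` keys: ``data`` (N,5), ``collocation`` (N,3), optional
    ``body`` (N,6), ``zero_pressure`` (N,3), ``inlet`` (N,5), ``ic`` (N,5).
    """
    breakdown = {}
    total = Tensor(0.0)
    if weights.lambda_data > 0 and "data" in batches:
        ld = data_loss(net, batches["data"])
        breakdown["data"] = float(ld.value)
        total = total + weights.lambda_data * ld
    if weights.lambda_ic > 0 and batches.get("ic") is not None:
        lic = data_loss(net, batches["ic"])
        breakdown["ic"] = float(lic.value)
        total = total + weights.lambda_ic * lic
    bc_terms = boundary_losses(
        net,
        body_batch=batches.get("body"),
        zero_pressure_batch=batches.get("zero_pressure"),
        inlet_batch=batches.get("inlet"),
    )
    if weights.lambda_bc > 0 and bc_terms:
        lbc = Tensor(0.0)
        for name, term in bc_terms.items():
            breakdown[f"bc_{name}"] = float(term.value)
            lbc = lbc + term
        total = total + weights.lambda_bc * lbc
    if weights.lambda_eq > 0 and "collocation" in batches:
        _, leq = ns_residuals(net, batches["collocation"], Re,
                              enforce_continuity, time_coeff)
        breakdown["equation"] = float(leq.value)
        total = total + weights.lambda_eq * leq
    breakdown["total"] = float(total.value)
    return total, breakdown


# --------------------------------------------------------------------- model
@dataclass
class PinnModel:
    """Trained (or untrained) network plus the scaling it operates under."""

    network: Network
    config: NetworkConfig
    scaling: ScalingSet
    trained: bool = False

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate (u, v, p) at arbitrary (x, y, t) points, shape (N, 3)."""
        return forward_values(self.network, np.atleast_2d(points)).value


class _CyclicSampler:
    """Shuffled without-replacement batches, reshuffling each full cycle."""

    def __init__(self, data: np.ndarray, batch: int, rng: np.random.Generator):
        self.data = data
        self.batch = min(batch, len(data)) if len(data) else 0
        self.rng = rng
        self._order = rng.permutation(len(data))
        self._pos = 0

    def next(self) -> np.ndarray:
        if len(self.data) == 0:
            return self.data
        if self._pos + self.batch > len(self.data):
            self._order = self.rng.permutation(len(self.data))
            self._pos = 0
        sel = self._order[self._pos:self._pos + self.batch]
        self._pos += self.batch
        return self.data[sel]


class PinnPressure:
    """Pressure-reconstruction model: fit a coordinate network to a velocity
    series (plus body kinematics and external boundary conditions).

    Parameters
    ----------
    series : non-dimensional velocity measurements (masked inside the body).
    scaling : the non-dimensionalization contract; supplies Re and the
        unsteady-term coefficient L/(U T).
    kinematics : body contour motion for the non-penetration term (optional).
    bc_spec : external-edge boundary conditions (optional).
    residual_points : (N, 3) collocation points for the momentum residuals;
        defaults to the measurement grid itself.  Per standard practice the
        residuals should be evaluated on the *finest* grid available even
        when the measurements are coarser.
    """

    def __init__(self, series: VelocityFieldSeries, scaling: ScalingSet,
                 kinematics: BodyKinematics | None = None,
                 bc_spec: BoundaryConditionSpec | None = None,
                 network: NetworkConfig | None = None,
                 weights: LossWeights | None = None,
                 training: TrainingConfig | None = None,
                 residual_points: np.ndarray | None = None):
        self.series = series
        self.scaling = scaling
        self.kinematics = kinematics
        self.bc_spec = bc_spec
        self.weights = weights or LossWeights()
        self.training = training or TrainingConfig()
        if self.bc_spec is not None and self.bc_spec.body and kinematics is None:
            raise ValueError("body boundary term requested without kinematics")

        cfg = network or NetworkConfig()
        cfg = _fit_input_normalization(cfg, series)
        self.network_config = cfg

        self._batches = self._assemble(residual_points)

    # ------------------------------------------------------------- assembly
    def _assemble(self, residual_points):
        s = self.series
        batches = {"data": s.sample_points()}
        if residual_points is None:
            X, Y = s.meshgrid()
            pts = []
            for it, t in enumerate(s.times):
                m = s.valid_mask[:, :, it]
                pts.append(np.column_stack([X[m], Y[m], np.full(m.sum(), t)]))
            residual_points = np.concatenate(pts, axis=0)
        batches["collocation"] = np.asarray(residual_points, dtype=float)

        if self.kinematics is not None and (self.bc_spec is None or self.bc_spec.body):
            rows = []
            for it, t in enumerate(self.kinematics.times):
                if t < s.times[0] - 1e-12 or t > s.times[-1] + 1e-12:
                    continue
                n = self.kinematics.normals(it)
                un = self.kinematics.normal_velocity(it)
                pts = self.kinematics.contour[it]
                rows.append(np.column_stack([
                    pts, np.full(len(pts), t), n, un,
                ]))
            if rows:
                batches["body"] = np.concatenate(rows, axis=0)

        if self.bc_spec is not None:
            zp, inlet = [], []
            edges = {
                "left": (s.x_coords[:1], s.y_coords),
                "right": (s.x_coords[-1:], s.y_coords),
                "bottom": (s.x_coords, s.y_coords[:1]),
                "top": (s.x_coords, s.y_coords[-1:]),
            }
            for edge, (ex, ey) in edges.items():
                kind = getattr(self.bc_spec, edge)
                if kind == "none":
                    continue
                EX, EY = np.meshgrid(ex, ey)
                for t in s.times:
                    pts = np.column_stack([EX.ravel(), EY.ravel(),
                                           np.full(EX.size, t)])
                    if kind == "zero_pressure":
                        zp.append(pts)
                    else:
                        inlet.append(np.column_stack([
                            pts,
                            np.full(EX.size, self.bc_spec.inlet_u),
                            np.full(EX.size, self.bc_spec.inlet_v),
                        ]))
            if zp:
                batches["zero_pressure"] = np.concatenate(zp, axis=0)
            if inlet:
                batches["inlet"] = np.concatenate(inlet, axis=0)
        return batches

    # ------------------------------------------------------------------ fit
    def fit(self, checkpoint_path=None, checkpoint_every: int | None = None,
            resume_from=None, callback=None) -> "PinnPressureResults":
        """Train with ADAM; fully reproducible under the two seeds.

        ``checkpoint_every`` (epochs) writes resumable state to
        ``checkpoint_path``; ``resume_from`` continues a previous run
        bit-identically.
        """
        cfg = self.training
        net = Network(self.network_config)
        model = PinnModel(net, self.network_config, self.scaling)

        rng = np.random.default_rng(cfg.sampling_seed)
        m_state = [np.zeros_like(p.value) for p in net.params]
        v_state = [np.zeros_like(p.value) for p in net.params]
        step = 0
        epoch0 = 0
        history: list[dict] = []

        colloc_cap = cfg.collocation_batch_size or cfg.minibatch_size
        samplers = {
            k: _CyclicSampler(v, colloc_cap if k == "collocation" else cfg.minibatch_size, rng)
            for k, v in self._batches.items()
        }

        if resume_from is not None:
            ckpt = _load_checkpoint(resume_from)
            net.set_state(ckpt["params"])
            m_state, v_state = ckpt["adam_m"], ckpt["adam_v"]
            step = ckpt["step"]
            epoch0 = ckpt["epoch"]
            history = ckpt["history"]
            rng.bit_generator.state = ckpt["rng_state"]
            for name, sampler in samplers.items():
                st = ckpt["samplers"][name]
                sampler._order = st["order"]
                sampler._pos = st["pos"]

        n_data = len(self._batches["data"])
        iters_per_epoch = max(1, int(np.ceil(n_data / samplers["data"].batch)))
        time_coeff = self.scaling.time_coefficient
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps

        for epoch in range(epoch0, cfg.epochs):
            lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
            epoch_terms: dict[str, float] = {}
            for _ in range(iters_per_epoch):
                batch = {k: s.next() for k, s in samplers.items()}
                net.zero_grad()
                loss, breakdown = total_loss(net, batch, self.weights,
                                             self.scaling.Re,
                                             cfg.enforce_continuity, time_coeff)
                if not np.isfinite(loss.value):
                    raise PinnDivergenceError(
                        f"non-finite loss at epoch {epoch}: {breakdown}")
                loss.backward()
                step += 1
                for i, p in enumerate(net.params):
                    g = p.grad if p.grad is not None else np.zeros_like(p.value)
                    m_state[i] = b1 * m_state[i] + (1 - b1) * g
                    v_state[i] = b2 * v_state[i] + (1 - b2) * g * g
                    mhat = m_state[i] / (1 - b1**step)
                    vhat = v_state[i] / (1 - b2**step)
                    p.value -= lr * mhat / (np.sqrt(vhat) + eps)
                for k, val in breakdown.items():
                    epoch_terms[k] = epoch_terms.get(k, 0.0) + val / iters_per_epoch
            epoch_terms["epoch"] = epoch
            epoch_terms["lr"] = lr
            history.append(epoch_terms)
            if callback is not None:
                callback(epoch, epoch_terms)
            if (checkpoint_path is not None and checkpoint_every
                    and (epoch + 1) % checkpoint_every == 0):
                _save_checkpoint(checkpoint_path, net, m_state, v_state, step,
                                 epoch + 1, history, rng, samplers)

        if cfg.lbfgs_steps > 0:
            self._lbfgs_refine(net, cfg, rng, history, time_coeff)

        model.trained = True
        return PinnPressureResults(self, model, history)

    def _lbfgs_refine(self, net, cfg, rng, history, time_coeff):
        """Quasi-Newton refinement on fixed (seed-drawn) full-ish batches."""
        from scipy.optimize import minimize

        batches = {}
        for name, arr in self._batches.items():
            if name == "collocation":
                cap = cfg.lbfgs_collocation_cap
            elif name == "data":
                cap = cfg.lbfgs_data_cap or len(arr)
            else:
                cap = cfg.minibatch_size
            if cap < len(arr):
                batches[name] = arr[rng.choice(len(arr), cap, replace=False)]
            else:
                batches[name] = arr

        shapes = [p.value.shape for p in net.params]
        sizes = [p.value.size for p in net.params]

        def unpack(theta):
            off = 0
            for p, shp, sz in zip(net.params, shapes, sizes):
                p.value = theta[off:off + sz].reshape(shp)
                off += sz

        def fun_grad(theta):
            unpack(theta)
            net.zero_grad()
            loss, _ = total_loss(net, batches, self.weights, self.scaling.Re,
                                 cfg.enforce_continuity, time_coeff)
            if not np.isfinite(loss.value):
                raise PinnDivergenceError("non-finite loss in refinement phase")
            loss.backward()
            g = np.concatenate([
                (p.grad if p.grad is not None else np.zeros_like(p.value)).ravel()
                for p in net.params
            ])
            return float(loss.value), g

        theta0 = np.concatenate([p.value.ravel() for p in net.params])
        out = minimize(fun_grad, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.lbfgs_steps,
                                "maxcor": cfg.lbfgs_history_size})
        unpack(out.x)
        _, breakdown = total_loss(net, batches, self.weights, self.scaling.Re,
                                  cfg.enforce_continuity, time_coeff)
        breakdown["epoch"] = (history[-1]["epoch"] + 1) if history else 0
        breakdown["phase"] = "lbfgs"
        breakdown["lbfgs_iterations"] = out.nit
        history.append(breakdown)


def _fit_input_normalization(cfg: NetworkConfig, series: VelocityFieldSeries) -> NetworkConfig:
    if cfg.input_center != (0.0, 0.0, 0.0) or cfg.input_halfwidth != (1.0, 1.0, 1.0):
        return cfg  # user-specified
    lo = np.array([series.x_coords[0], series.y_coords[0], series.times[0]])
    hi = np.array([series.x_coords[-1], series.y_coords[-1], series.times[-1]])
    center = 0.5 * (lo + hi)
    half = np.maximum(0.5 * (hi - lo), 1e-12)
    return replace(cfg, input_center=tuple(center), input_halfwidth=tuple(half))


# --------------------------------------------------------------- checkpoints
def _save_checkpoint(path, net, m_state, v_state, step, epoch, history, rng, samplers):
    path = Path(path)
    arrays = {}
    for i, p in enumerate(net.params):
        arrays[f"param_{i}"] = p.value
        arrays[f"adam_m_{i}"] = m_state[i]
        arrays[f"adam_v_{i}"] = v_state[i]
    for name, s in samplers.items():
        arrays[f"sampler_order_{name}"] = s._order
    meta = {
        "n_params": len(net.params),
        "step": step,
        "epoch": epoch,
        "history": history,
        "rng_state": rng.bit_generator.state,
        "sampler_pos": {name: s._pos for name, s in samplers.items()},
    }
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, default=int))


def _load_checkpoint(path):
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    meta = json.loads(Path(str(path) + ".json").read_text())
    n = meta["n_params"]
    samplers = {}
    for key in data.files:
        if key.startswith("sampler_order_"):
            name = key[len("sampler_order_"):]
            samplers[name] = {"order": data[key],
                              "pos": meta["sampler_pos"][name]}
    return {
        "params": [data[f"param_{i}"] for i in range(n)],
        "adam_m": [data[f"adam_m_{i}"] for i in range(n)],
        "adam_v": [data[f"adam_v_{i}"] for i in range(n)],
        "step": meta["step"],
        "epoch": meta["epoch"],
        "history": meta["history"],
        "rng_state": meta["rng_state"],
        "samplers": samplers,
    }


# ------------------------------------------------------------------- results
class PinnPressureResults:
    """Trained reconstruction: dense field evaluation, surface pressure,
    loss history and a text summary."""

    def __init__(self, model_spec: PinnPressure, model: PinnModel, history: list[dict]):
        self.spec = model_spec
        self.model = model
        self.history = history

    # loss curves as column arrays
    def loss_history(self) -> dict:
        keys = sorted({k for h in self.history for k in h})
        return {k: np.array([h.get(k, np.nan) for h in self.history]) for k in keys}

    def predict_field(self, x_coords=None, y_coords=None, times=None):
        """Dense (u, v, p) evaluation on any grid (may exceed the training
        resolution).  Body-interior nodes are masked when kinematics with
        matching times are available.  Pressure gauge: ``zero_at_boundary``
        if a zero-pressure edge was trained, else per-time zero mean."""
        if not self.model.trained:
            raise ValueError("model is not trained")
        s = self.spec.series
        x = s.x_coords if x_coords is None else np.asarray(x_coords, dtype=float)
        y = s.y_coords if y_coords is None else np.asarray(y_coords, dtype=float)
        t = s.times if times is None else np.asarray(times, dtype=float)
        X, Y = np.meshgrid(x, y)
        u = np.empty((y.size, x.size, t.size))
        v = np.empty_like(u)
        p = np.empty_like(u)
        for it, ti in enumerate(t):
            pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, ti)])
            out = self.model(pts)
            u[:, :, it] = out[:, 0].reshape(X.shape)
            v[:, :, it] = out[:, 1].reshape(X.shape)
            p[:, :, it] = out[:, 2].reshape(X.shape)
        vel = VelocityFieldSeries(x, y, t, u=u, v=v)
        if self.spec.kinematics is not None:
            try:
                vel = mask_body_interior(vel, self.spec.kinematics)
            except ValueError:
                pass  # prediction times outside the kinematics record
        zero_p_trained = (self.spec.bc_spec is not None
                          and self.spec.bc_spec.edges("zero_pressure"))
        if zero_p_trained:
            gauge = "zero_at_boundary"
        else:
            gauge = "zero_mean"
            for it in range(t.size):
                m = vel.valid_mask[:, :, it]
                p[:, :, it] -= p[:, :, it][m].mean()
        pres = PressureFieldSeries(x, y, t, p=p, valid_mask=vel.valid_mask.copy(),
                                   gauge=gauge)
        return vel, pres

    def surface_pressure(self, time: float, kinematics: BodyKinematics | None = None):
        """Pressure evaluated *exactly* on the body contour at ``time``.

        Returns (p, extrapolation_distance) — the distance is identically
        zero, by construction: no grid-to-surface extrapolation is involved.
        """
        if not self.model.trained:
            raise ValueError("model is not trained")
        kin = kinematics or self.spec.kinematics
        if kin is None:
            raise ValueError("surface pressure requires body kinematics")
        it = kin.time_index(time)
        pts = kin.contour[it]
        out = self.model(np.column_stack([pts, np.full(len(pts), kin.times[it])]))
        return out[:, 2], np.zeros(len(pts))

    def summary(self) -> str:
        cfg = self.model.config
        last = self.history[-1] if self.history else {}
        lines = [
            "Physics-informed pressure reconstruction",
            "=" * 44,
            f"network: {cfg.n_hidden_layers} x {cfg.neurons_per_layer} "
            f"({cfg.activation}), gamma gains: {cfg.use_gamma}",
            f"epochs run: {len(self.history)}",
            f"Re: {self.model.scaling.Re:g}",
        ]
        for k in ("total", "data", "equation", "bc_body", "bc_zero_pressure", "bc_inlet"):
            if k in last:
                lines.append(f"final {k} loss: {last[k]:.3e}")
        return "\n".join(lines)
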