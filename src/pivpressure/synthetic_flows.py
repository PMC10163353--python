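"""Analytic ground-truth flows and measurement-degradation operators.

Real validation data for pressure reconstruction (a DNS mid-plane slice, or
PIV around a live fish) are large and not redistributable, so every component
here is exercised against *analytic* unsteady flows whose pressure is known
in closed form:

* the decaying Taylor-Green vortex — an exact Navier-Stokes solution on
  [0, 2pi]^2, the standard benchmark for pressure solvers;
* an unsteady potential-flow "swimmer": point doublets riding on a
  carangiform midline in a free stream.  Potential velocity fields are
  harmonic, so they satisfy the full Navier-Stokes momentum equations with
  pressure given exactly by the unsteady Bernoulli relation — which makes the
  surrogate an exact oracle for surface-pressure reconstruction around a
  moving, deforming body.

Degradation operators emulate what a PIV experiment does to the truth:
spatio-temporal subsampling and additive white measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow_data import (
    BodyKinematics,
    PressureFieldSeries,
    VelocityFieldSeries,
    mask_body_interior,
)

__all__ = [
    "CarangiformParams",
    "DegradationSpec",
    "taylor_green_truth",
    "carangiform_kinematics",
    "potential_swimmer_truth",
    "downsample",
    "add_noise",
    "DoubletLayout",
]


def _default_halfwidth(xhat: np.ndarray) -> np.ndarray:
    """Smooth body half-width vanishing at nose and tail (max 0.0875 L,
    comparable to a fusiform fish body)."""
    return 0.35 * xhat * (1.0 - xhat)


@dataclass
class CarangiformParams:
    """Carangiform undulation: Delta y / L = A(x) sin(k x - 2 pi f t + phi),
    with amplitude envelope A(x) = a0 + a1 (x/L) + a2 (x/L)^2.

    Defaults are the mackerel-style envelope (a0=0.02, a1=-0.08, a2=0.16)
    with wave number k = 2 pi / L and unit tail-beat period.
    """

    a0: float = 0.02
    a1: float = -0.08
    a2: float = 0.16
    k: float = 2.0 * np.pi
    f: float = 1.0
    phi: float = 0.0
    L: float = 1.0
    halfwidth: callable = _default_halfwidth

    @property
    def T_period(self) -> float:
        return 1.0 / self.f

    def amplitude(self, x: np.ndarray) -> np.ndarray:
        xh = np.asarray(x, dtype=float) / self.L
        return self.a0 + self.a1 * xh + self.a2 * xh**2

    def lateral_displacement(self, x, t):
        """Delta y(x, t) (in units of L)."""
        x = np.asarray(x, dtype=float)
        return self.L * self.amplitude(x) * np.sin(
            self.k * x - 2.0 * np.pi * self.f * np.asarray(t) + self.phi
        )

    def lateral_velocity(self, x, t):
        """d(Delta y)/dt, the material lateral velocity of the midline."""
        x = np.asarray(x, dtype=float)
        # d/dt sin(kx - 2 pi f t + phi) = -2 pi f cos(...)
        return (
            -2.0 * np.pi * self.f * self.L * self.amplitude(x)
            * np.cos(self.k * x - 2.0 * np.pi * self.f * np.asarray(t) + self.phi)
        )


@dataclass
class DegradationSpec:
    """How to coarsen/corrupt a truth series to emulate a PIV measurement."""

    spatial_step: float | None = None   # target grid spacing, units of L
    temporal_step: float | None = None  # target time step, units of T
    noise_level: float = 0.0            # fraction of the reference velocity
    seed: int = 0
    reference_velocity: float | None = None  # default: max speed of the clean series

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


# ------------------------------------------------------------- Taylor-Green
def taylor_green_truth(x_coords, y_coords, times, Re: float):
    """Decaying Taylor-Green vortex on a grid within [0, 2 pi]^2.

    u = -cos x sin y F(t),  v = sin x cos y F(t),  F = exp(-2 t / Re)
    p = -(1/4) (cos 2x + cos 2y) F^2, returned with zero spatial mean
    per time step (the gauge constant is free in time).
    """
    if Re <= 0:
        raise ValueError("Re must be positive")
    x = np.asarray(x_coords, dtype=float)
    y = np.asarray(y_coords, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.min() < -1e-12 or x.max() > 2 * np.pi + 1e-12 or \
       y.min() < -1e-12 or y.max() > 2 * np.pi + 1e-12:
        raise ValueError("Taylor-Green domain must lie within [0, 2 pi]^2")
    X, Y = np.meshgrid(x, y)
    F = np.exp(-2.0 * t / Re)
    u = -np.cos(X)[:, :, None] * np.sin(Y)[:, :, None] * F[None, None, :]
    v = np.sin(X)[:, :, None] * np.cos(Y)[:, :, None] * F[None, None, :]
    p = -0.25 * (np.cos(2 * X) + np.cos(2 * Y))[:, :, None] * (F**2)[None, None, :]
    p -= p.mean(axis=(0, 1), keepdims=True)
    vel = VelocityFieldSeries(x, y, t, u=u, v=v)
    pres = PressureFieldSeries(x, y, t, p=p, gauge="zero_mean")
    return vel, pres


def taylor_green_pressure_gradient(x_coords, y_coords, times, Re: float):
    """Analytic (dp/dx, dp/dy) of the Taylor-Green solution (test oracle)."""
    x = np.asarray(x_coords, dtype=float)
    y = np.asarray(y_coords, dtype=float)
    t = np.asarray(times, dtype=float)
    X, Y = np.meshgrid(x, y)
    F2 = np.exp(-4.0 * t / Re)
    px = 0.5 * np.sin(2 * X)[:, :, None] * F2[None, None, :]
    py = 0.5 * np.sin(2 * Y)[:, :, None] * F2[None, None, :]
    return px, py


# --------------------------------------------------------------- kinematics
def carangiform_kinematics(params: CarangiformParams, n_surface_points: int,
                           times) -> BodyKinematics:
    """Closed body contour (midline +/- half-width) undulating laterally.

    The contour is sampled at ``n_surface_points`` axial stations per side,
    sharing single nose and tail points.  Surface material points move only
    laterally, with the analytic velocity d(Delta y)/dt.
    """
    if n_surface_points < 8:
        raise ValueError("n_surface_points must be >= 8")
    times = np.asarray(times, dtype=float)
    xh = np.linspace(0.0, 1.0, n_surface_points)
    x = xh * params.L
    w = params.halfwidth(xh) * params.L
    nt = times.size

    # stations: nose (j=0), upper side j=1..n-2, tail (j=n-1), lower side reversed
    idx_upper = np.arange(1, n_surface_points - 1)
    idx_lower = idx_upper[::-1]
    station = np.concatenate([[0], idx_upper, [n_surface_points - 1], idx_lower])
    sgn = np.concatenate([[0.0], np.ones(idx_upper.size), [0.0], -np.ones(idx_lower.size)])

    contour = np.empty((nt, station.size, 2))
    surf_vel = np.empty_like(contour)
    for it, t in enumerate(times):
        dy = params.lateral_displacement(x, t)
        vy = params.lateral_velocity(x, t)
        contour[it, :, 0] = x[station]
        contour[it, :, 1] = dy[station] + sgn * w[station]
        surf_vel[it, :, 0] = 0.0
        surf_vel[it, :, 1] = vy[station]
    return BodyKinematics(
        times=times, contour=contour, surface_velocity=surf_vel,
        side=np.where(sgn > 0, 1, np.where(sgn < 0, -1, 0)),
        arclength_x=xh[station],
    )


# ------------------------------------------------------ potential-flow truth
@dataclass
class DoubletLayout:
    """Point doublets carried by the midline; strength scales with local width.

    Doublets are confined to the mid-body (``margin`` from either end) where
    the body is thick: a doublet close beneath a thin nose/tail surface
    produces near-singular surface pressure that no method could recover
    from exterior velocity data.
    """

    n_doublets: int = 4
    strength: float = 0.3  # velocity scale of each doublet at one half-width
    free_stream: float = 1.0
    margin: float = 0.25

    def positions(self, L: float) -> np.ndarray:
        frac = self.margin + (1.0 - 2.0 * self.margin) * \
            (np.arange(self.n_doublets) + 0.5) / self.n_doublets
        return frac * L


def potential_swimmer_truth(params: CarangiformParams, x_coords, y_coords, times,
                            n_surface_points: int = 64,
                            layout: DoubletLayout | None = None):
    """Unsteady potential flow around a carangiform swimmer surrogate.

    Point doublets (x-oriented, complex potential mu / (z - z_j(t))) ride on
    the undulating midline inside the body; the free stream is uniform.  The
    velocity field is harmonic, hence an exact Navier-Stokes solution, and

        p = 0.5 U_inf^2 - d(phi)/dt - 0.5 |u|^2

    (unsteady Bernoulli anchored so p -> 0 far from the body).  Grid nodes
    inside the body are masked; a doublet whose neighborhood is not fully
    masked raises.

    The returned kinematics carry *flow-consistent* surface velocities: the
    contour is a sensing surface embedded in the exact flow (the doublet
    superposition is not constructed to make the drawn contour a stream
    surface), so its normal-velocity data are sampled from the flow itself —
    the role silhouette-derived u_n plays for experimental data.

    Returns (VelocityFieldSeries, PressureFieldSeries, BodyKinematics).
    """
    layout = layout or DoubletLayout()
    x = np.asarray(x_coords, dtype=float)
    y = np.asarray(y_coords, dtype=float)
    t = np.asarray(times, dtype=float)
    kin = carangiform_kinematics(params, n_surface_points, t)

    xj = layout.positions(params.L)
    wj = params.halfwidth(xj / params.L) * params.L
    mu = layout.strength * wj**2  # doublet velocity ~ mu / r^2 = strength at r = w

    X, Y = np.meshgrid(x, y)
    Z = X + 1j * Y
    nt = t.size
    u = np.empty((y.size, x.size, nt))
    v = np.empty_like(u)
    p = np.empty_like(u)
    for it, ti in enumerate(t):
        uu, vv, pp = _potential_fields(Z, ti, params, xj, mu, layout.free_stream)
        u[:, :, it], v[:, :, it], p[:, :, it] = uu, vv, pp

    # surface velocities from the exact flow at the contour points
    for it, ti in enumerate(t):
        pts = kin.contour[it]
        Zs = (pts[:, 0] + 1j * pts[:, 1]).reshape(-1, 1)
        us, vs, _ = _potential_fields(Zs, ti, params, xj, mu, layout.free_stream)
        kin.surface_velocity[it, :, 0] = us.ravel()
        kin.surface_velocity[it, :, 1] = vs.ravel()

    vel = VelocityFieldSeries(x, y, t, u=u, v=v)
    vel = mask_body_interior(vel, kin)
    pres = PressureFieldSeries(x, y, t, p=p, valid_mask=vel.valid_mask.copy(),
                               gauge="zero_at_boundary")

    # no doublet may sit near an unmasked node (its field is singular there)
    for it, ti in enumerate(t):
        zj = xj + 1j * params.lateral_displacement(xj, ti)
        _check_doublet_clearance(Z, vel.valid_mask[:, :, it], zj, wj)
    return vel, pres, kin


def _check_doublet_clearance(Z, valid, zj, wj) -> None:
    """Raise if any flow singularity sits near an unmasked evaluation node."""
    if not valid.any():
        return
    zv = Z[valid]
    dmin = np.min(np.abs(zv[None, :] - zj[:, None]), axis=1)
    if np.any(dmin < 0.5 * wj):
        raise ValueError("doublet too close to an unmasked grid node")


def _potential_fields(Z, t, params, xj, mu, U_inf):
    """Velocity and Bernoulli pressure of the doublet superposition at time t."""
    dyj = params.lateral_displacement(xj, t)
    vyj = params.lateral_velocity(xj, t)
    zj = xj + 1j * dyj
    zdot = 1j * vyj
    dz = Z[:, :, None] - zj[None, None, :]
    w_conj = U_inf - np.sum(mu / dz**2, axis=2)       # u - i v
    u = w_conj.real
    v = -w_conj.imag
    # phi_t = Re(dF/dt), dF_j/dt = mu_j zdot_j / (z - z_j)^2
    phi_t = np.sum((mu * zdot) / dz**2, axis=2).real
    p = 0.5 * U_inf**2 - phi_t - 0.5 * (u**2 + v**2)
    return u, v, p


def potential_swimmer_surface_pressure(params: CarangiformParams,
                                       kin: BodyKinematics, it: int,
                                       layout: DoubletLayout | None = None) -> np.ndarray:
    """Exact Bernoulli pressure evaluated on the body contour at time index it."""
    layout = layout or DoubletLayout()
    xj = layout.positions(params.L)
    wj = params.halfwidth(xj / params.L) * params.L
    mu = layout.strength * wj**2
    pts = kin.contour[it]
    Z = (pts[:, 0] + 1j * pts[:, 1]).reshape(-1, 1)
    _, _, p = _potential_fields(Z, kin.times[it], params, xj, mu, layout.free_stream)
    return p.ravel()


# ---------------------------------------------------------------- degradation
def downsample(series: VelocityFieldSeries, spec: DegradationSpec) -> VelocityFieldSeries:
    """Pure spatio-temporal subsampling (no smoothing); mask carried along."""
    sx = _stride(spec.spatial_step, series.dx, "spatial_step")
    sy = _stride(spec.spatial_step, series.dy, "spatial_step")
    st = _stride(spec.temporal_step, series.dt, "temporal_step")
    return VelocityFieldSeries(
        series.x_coords[::sx], series.y_coords[::sy], series.times[::st],
        u=series.u[::sy, ::sx, ::st],
        v=series.v[::sy, ::sx, ::st],
        valid_mask=series.valid_mask[::sy, ::sx, ::st],
    )


def _stride(step: float | None, source: float, name: str) -> int:
    if step is None:
        return 1
    ratio = step / source
    s = int(round(ratio))
    if s < 1 or abs(ratio - s) > 1e-6 * max(1, s):
        raise ValueError(f"{name}={step} is not an integer multiple of the source step {source}")
    return s


def add_noise(series: VelocityFieldSeries, spec: DegradationSpec) -> VelocityFieldSeries:
    """Additive zero-mean Gaussian noise on u and v at valid nodes only.

    Standard deviation = ``noise_level`` x reference velocity, where the
    reference defaults to the maximum speed over the clean series.
    Reproducible under ``spec.seed``.
    """
    out = series.copy()
    if spec.noise_level == 0:
        return out
    ref = spec.reference_velocity
    if ref is None:
        speed = np.hypot(series.u, series.v)
        ref = float(np.max(speed[series.valid_mask]))
    sigma = spec.noise_level * ref
    rng = np.random.default_rng(spec.seed)
    m = series.valid_mask
    noise_u = rng.normal(0.0, sigma, size=series.u.shape)
    noise_v = rng.normal(0.0, sigma, size=series.v.shape)
    out.u = series.u + np.where(m, noise_u, 0.0)
    out.v = series.v + np.where(m, noise_v, 0.0)
    return out
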