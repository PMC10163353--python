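"""Classical pressure-reconstruction baselines.

Two methods the field has long used to obtain pressure from PIV velocity
fields, both built on the momentum-equation pressure gradient

    grad p = -(du/dt + (u . grad) u) + (1/Re) laplacian(u)      (non-dim)

* a pressure-Poisson solve:  laplacian(p) = div(grad p), discretized with the
  five-point stencil on the uniform grid, Neumann or Dirichlet edges;
* multi-directional (omnidirectional) integration: straight-ray line
  integrals of the gradient from the external boundary to every node,
  aggregated by the median, with rays terminated at the body contour —
  the surface pressure is then *extrapolated* from the nearest valid node.

Boundary reference for the integration: by default the boundary pressure is
itself obtained by integrating the gradient around the perimeter from a
single zero-pressure reference corner (gauge ``zero_at_boundary``).  The
strict convention of pinning p = 0 on all external boundaries is available
via ``zero_boundary=True``; it is only consistent when the true boundary
pressure is uniform, and is kept for comparisons against tools that use it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates

from .flow_data import BodyKinematics, PressureFieldSeries, VelocityFieldSeries

__all__ = [
    "PoissonOptions",
    "IntegrationOptions",
    "pressure_gradient_field",
    "integrate_multidirectional",
    "solve_poisson",
    "nearest_point_surface_pressure",
    "PoissonPressure",
    "MultipathIntegrationPressure",
]


@dataclass
class PoissonOptions:
    boundary: str = "neumann_from_momentum"  # "dirichlet_zero" | "neumann_from_momentum"
    viscous_terms: bool = True
    time_derivative_scheme: str = "central"  # central interior; one-sided 2nd-order ends

    def __post_init__(self):
        if self.boundary not in ("dirichlet_zero", "neumann_from_momentum"):
            raise ValueError(f"unknown boundary treatment {self.boundary!r}")


@dataclass
class IntegrationOptions:
    n_ray_directions: int = 8
    aggregator: str = "median"  # "median" | "mean"
    stop_at_body: bool = True
    zero_boundary: bool = False  # strict zero-pressure at all external boundaries
    time_derivative_scheme: str = "central"

    def __post_init__(self):
        if self.n_ray_directions < 2:
            raise ValueError("n_ray_directions must be >= 2")
        if self.aggregator not in ("median", "mean"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


# --------------------------------------------------------------- time deriv
def _time_derivative(a: np.ndarray, dt: float) -> np.ndarray:
    """Second-order central differences; one-sided second-order at the ends."""
    nt = a.shape[2]
    if nt < 2:
        raise ValueError("need at least 2 time steps")
    out = np.empty_like(a)
    if nt == 2:
        out[:, :, 0] = out[:, :, 1] = (a[:, :, 1] - a[:, :, 0]) / dt
        return out
    out[:, :, 1:-1] = (a[:, :, 2:] - a[:, :, :-2]) / (2 * dt)
    out[:, :, 0] = (-3 * a[:, :, 0] + 4 * a[:, :, 1] - a[:, :, 2]) / (2 * dt)
    out[:, :, -1] = (3 * a[:, :, -1] - 4 * a[:, :, -2] + a[:, :, -3]) / (2 * dt)
    return out


def pressure_gradient_field(series: VelocityFieldSeries, Re: float,
                            viscous_terms: bool = True):
    """Momentum-derived (dp/dx, dp/dy) per time step on the grid.

    Second-order central differences in space; nodes whose stencil touches a
    masked node are flagged invalid in the returned ``grad_valid`` mask.

    Returns (px, py, grad_valid), each of grid x time shape.
    """
    if Re <= 0:
        raise ValueError("Re must be positive")
    if series.times.size < 2:
        raise ValueError("need at least 2 time steps for the material derivative")
    dx, dy, dt = series.dx, series.dy, series.dt
    u, v = series.u, series.v

    def ddx(a):
        return np.gradient(a, dx, axis=1)

    def ddy(a):
        return np.gradient(a, dy, axis=0)

    ut = _time_derivative(u, dt)
    vt = _time_derivative(v, dt)
    ux, uy = ddx(u), ddy(u)
    vx, vy = ddx(v), ddy(v)
    px = -(ut + u * ux + v * uy)
    py = -(vt + u * vx + v * vy)
    if viscous_terms:
        px += (ddx(ux) + ddy(uy)) / Re
        py += (ddx(vx) + ddy(vy)) / Re

    # gradient undefined where any stencil neighbor (5-point, in space or time) is masked
    m = series.valid_mask
    grad_valid = m.copy()
    grad_valid[1:, :, :] &= m[:-1, :, :]
    grad_valid[:-1, :, :] &= m[1:, :, :]
    grad_valid[:, 1:, :] &= m[:, :-1, :]
    grad_valid[:, :-1, :] &= m[:, 1:, :]
    px = np.where(grad_valid, px, np.nan)
    py = np.where(grad_valid, py, np.nan)
    return px, py, grad_valid


# -------------------------------------------------------------- integration
def integrate_multidirectional(series_or_grad, Re: float | None = None,
                               options: IntegrationOptions | None = None,
                               gradient=None) -> PressureFieldSeries:
    """Multi-directional straight-ray integration of the pressure gradient.

    For every node, the gradient is line-integrated (trapezoid rule on
    bilinear-interpolated samples) along ``n_ray_directions`` straight rays
    from the external boundary; ray values are aggregated by the median.
    Rays crossing invalid (body) regions are discarded when ``stop_at_body``.
    """
    options = options or IntegrationOptions()
    series = series_or_grad
    if gradient is None:
        px, py, gvalid = pressure_gradient_field(series, Re)
    else:
        px, py, gvalid = gradient
    x, y, t = series.x_coords, series.y_coords, series.times
    ny, nx, nt = px.shape
    dx, dy = series.dx, series.dy

    p = np.empty((ny, nx, nt))
    for it in range(nt):
        p[:, :, it] = _integrate_one(
            px[:, :, it], py[:, :, it], gvalid[:, :, it],
            series.valid_mask[:, :, it], dx, dy, options,
        )
    return PressureFieldSeries(x, y, t, p=p, valid_mask=series.valid_mask.copy(),
                               gauge="zero_at_boundary")


def _boundary_pressure(px, py, dx, dy):
    """Integrate the gradient around the perimeter from corner (0, 0) with p=0."""
    ny, nx = px.shape
    p = np.full((ny, nx), np.nan)
    p[0, 0] = 0.0
    # bottom edge (y index 0), left->right, trapezoid in px
    p[0, 1:] = np.cumsum(0.5 * (px[0, :-1] + px[0, 1:]) * dx)
    # left edge bottom->top
    p[1:, 0] = np.cumsum(0.5 * (py[:-1, 0] + py[1:, 0]) * dy)
    # top edge left->right from top-left corner
    p[-1, 1:] = p[-1, 0] + np.cumsum(0.5 * (px[-1, :-1] + px[-1, 1:]) * dx)
    # right edge bottom->top from bottom-right corner
    p[1:, -1] = p[0, -1] + np.cumsum(0.5 * (py[:-1, -1] + py[1:, -1]) * dy)
    return p


def _integrate_one(px, py, gvalid, valid, dx, dy, options: IntegrationOptions):
    ny, nx = px.shape
    h = min(dx, dy)
    pxf = np.nan_to_num(px)
    pyf = np.nan_to_num(py)
    if options.zero_boundary:
        pb = np.zeros((ny, nx))
    else:
        pb = _boundary_pressure(pxf, pyf, dx, dy)

    # node coordinates in index space
    J, I = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    nodes_i = I.ravel()
    nodes_j = J.ravel()
    n_nodes = nodes_i.size
    angles = 2 * np.pi * np.arange(options.n_ray_directions) / options.n_ray_directions
    ray_vals = np.full((options.n_ray_directions, n_nodes), np.nan)

    body = ~valid  # rays may not cross the body interior
    x_max, y_max = (nx - 1) * dx, (ny - 1) * dy

    for a_idx, ang in enumerate(angles):
        cx, sy = np.cos(ang), np.sin(ang)
        # distance from each node backwards along -direction to the boundary
        xs = nodes_j * dx
        ys = nodes_i * dy
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = np.where(cx > 1e-12, xs / cx,
                          np.where(cx < -1e-12, (xs - x_max) / cx, np.inf))
            ty = np.where(sy > 1e-12, ys / sy,
                          np.where(sy < -1e-12, (ys - y_max) / sy, np.inf))
        dist = np.minimum(tx, ty)  # >= 0
        n_steps = int(np.ceil(np.nanmax(dist[np.isfinite(dist)]) / h)) + 1
        svals = np.linspace(0.0, 1.0, n_steps + 1)  # normalized arclength per node
        # sample positions along the ray from boundary point (s=0) to node (s=dist)
        s = svals[None, :] * dist[:, None]
        px_pts = xs[:, None] - (dist[:, None] - s) * cx
        py_pts = ys[:, None] - (dist[:, None] - s) * sy
        ci = py_pts / dy  # row index coordinate
        cj = px_pts / dx
        gproj = (
            map_coordinates(pxf, [ci.ravel(), cj.ravel()], order=1, mode="nearest") * cx
            + map_coordinates(pyf, [ci.ravel(), cj.ravel()], order=1, mode="nearest") * sy
        ).reshape(ci.shape)
        # trapezoid along the ray
        ds = np.diff(s, axis=1)
        integral = np.sum(0.5 * (gproj[:, :-1] + gproj[:, 1:]) * ds, axis=1)
        # boundary starting value (linear interpolation along the perimeter)
        bi = np.clip(ci[:, 0], 0, ny - 1)
        bj = np.clip(cj[:, 0], 0, nx - 1)
        p_start = _perimeter_value(pb, bi, bj)
        vals = p_start + integral
        if options.stop_at_body and body.any():
            # discard rays that pass through the body interior: those paths
            # are terminated before reaching the fluid-body interface
            hit = map_coordinates(body.astype(float), [ci.ravel(), cj.ravel()],
                                  order=0, mode="nearest").reshape(ci.shape)
            crosses = hit[:, :-1].max(axis=1) > 0
            vals = np.where(crosses, np.nan, vals)
        ray_vals[a_idx] = vals

    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # body-interior nodes legitimately have no valid ray (all-NaN)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if options.aggregator == "median":
            agg = np.nanmedian(ray_vals, axis=0)
        else:
            agg = np.nanmean(ray_vals, axis=0)
    n_valid_rays = np.sum(np.isfinite(ray_vals), axis=0)
    enclosed = (n_valid_rays == 0) & valid.ravel()
    if np.any(enclosed):
        raise ValueError("node enclosed by the body mask: no valid integration ray")
    return agg.reshape(ny, nx)


def _perimeter_value(pb, ci, cj):
    """Linear interpolation of perimeter pressure at boundary hit points."""
    ny, nx = pb.shape
    out = np.full(ci.shape, np.nan)
    out = np.where(ci < 0.5, _lin(pb[0, :], cj), out)
    out = np.where((ci > ny - 1.5) & np.isnan(out), _lin(pb[-1, :], cj), out)
    out = np.where((cj < 0.5) & np.isnan(out), _lin(pb[:, 0], ci), out)
    out = np.where((cj > nx - 1.5) & np.isnan(out), _lin(pb[:, -1], ci), out)
    # numerical residue (hits between edge bands): snap to nearest perimeter node
    if np.any(np.isnan(out)):
        ii = np.clip(np.round(ci).astype(int), 0, ny - 1)
        jj = np.clip(np.round(cj).astype(int), 0, nx - 1)
        on_perim = (ii == 0) | (ii == ny - 1) | (jj == 0) | (jj == nx - 1)
        snap = pb[np.where(on_perim, ii, 0), np.where(on_perim, jj, 0)]
        out = np.where(np.isnan(out), snap, out)
    return out


def _lin(edge_vals, coord):
    i0 = np.clip(np.floor(coord).astype(int), 0, edge_vals.size - 2)
    w = np.clip(coord - i0, 0.0, 1.0)
    return (1 - w) * edge_vals[i0] + w * edge_vals[i0 + 1]


# ------------------------------------------------------------------- Poisson
def solve_poisson(series: VelocityFieldSeries, Re: float,
                  options: PoissonOptions | None = None) -> PressureFieldSeries:
    """Five-point pressure-Poisson solve: laplacian(p) = div(momentum gradient).

    Masked (body-interior) nodes are excluded from the system; fluid nodes
    adjacent to the body receive the momentum-derived normal-gradient
    (Neumann) closure.  With all-Neumann edges the gauge is pinned by
    projecting to a zero-mean solution.
    """
    options = options or PoissonOptions()
    px, py, gvalid = pressure_gradient_field(series, Re, options.viscous_terms)
    x, y, t = series.x_coords, series.y_coords, series.times
    p = np.empty(series.shape)
    for it in range(t.size):
        p[:, :, it] = _poisson_one(
            np.nan_to_num(px[:, :, it]), np.nan_to_num(py[:, :, it]),
            series.valid_mask[:, :, it], series.dx, series.dy, options,
        )
    gauge = "zero_at_boundary" if options.boundary == "dirichlet_zero" else "zero_mean"
    return PressureFieldSeries(x, y, t, p=p, valid_mask=series.valid_mask.copy(),
                               gauge=gauge)


def _poisson_one(px, py, valid, dx, dy, options: PoissonOptions):
    ny, nx = px.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    fluid = valid
    # divergence of the gradient field (source term), central differences
    src = np.gradient(px, dx, axis=1) + np.gradient(py, dy, axis=0)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    dirichlet = options.boundary == "dirichlet_zero"

    inv_dx2, inv_dy2 = 1.0 / dx**2, 1.0 / dy**2
    for i in range(ny):
        for j in range(nx):
            k = idx[i, j]
            if not fluid[i, j]:
                rows.append(k); cols.append(k); vals.append(1.0)
                rhs[k] = 0.0
                continue
            if dirichlet and (i in (0, ny - 1) or j in (0, nx - 1)):
                rows.append(k); cols.append(k); vals.append(1.0)
                rhs[k] = 0.0
                continue
            diag = 0.0
            b = src[i, j]
            for (ii, jj, oi, oj, inv_h2, gcomp, sign) in (
                (i, j - 1, i, j + 1, inv_dx2, px, -1.0),
                (i, j + 1, i, j - 1, inv_dx2, px, +1.0),
                (i - 1, j, i + 1, j, inv_dy2, py, -1.0),
                (i + 1, j, i - 1, j, inv_dy2, py, +1.0),
            ):
                h = dx if gcomp is px else dy
                if 0 <= ii < ny and 0 <= jj < nx and fluid[ii, jj]:
                    rows.append(k); cols.append(idx[ii, jj]); vals.append(inv_h2)
                    diag -= inv_h2
                elif 0 <= oi < ny and 0 <= oj < nx and fluid[oi, oj]:
                    # second-order Neumann: mirror ghost across the node,
                    # ghost = opposite + sign*2*h*g — doubles the opposite
                    # neighbor's weight and moves the gradient to the RHS
                    g = gcomp[i, j]
                    rows.append(k); cols.append(idx[oi, oj]); vals.append(inv_h2)
                    diag -= inv_h2
                    b -= sign * 2.0 * g / h
                else:
                    # isolated strip: first-order ghost = p_k + sign*h*g
                    g = gcomp[i, j]
                    diag -= inv_h2
                    rows.append(k); cols.append(k); vals.append(inv_h2)
                    b -= sign * g / h
            rows.append(k); cols.append(k); vals.append(diag)
            rhs[k] = b

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if dirichlet:
        sol = spla.spsolve(A, rhs)
    else:
        # all-Neumann: singular up to a constant; pin one fluid node then re-gauge
        pin = int(idx[fluid][0])
        A = A.tolil()
        A.rows[pin] = [pin]
        A.data[pin] = [1.0]
        rhs[pin] = 0.0
        sol = spla.spsolve(A.tocsr(), rhs)
    P = sol.reshape(ny, nx)
    if not dirichlet:
        P = P - P[fluid].mean()
    P = np.where(fluid, P, np.nan)
    return np.nan_to_num(P)


# ---------------------------------------------------- surface extrapolation
def nearest_point_surface_pressure(pressure: PressureFieldSeries,
                                   kinematics: BodyKinematics, it: int | None = None):
    """Surface pressure by nearest-valid-grid-node extrapolation.

    For each contour point, the pressure of the nearest valid grid node (ties
    broken by lowest flat index, row-major).  Returns (p_surface, distance)
    arrays of shape (nt, n_pts) — or (n_pts,) when ``it`` is given.  The
    reported distance is the extrapolation length from surface to node.
    """
    X, Y = pressure.meshgrid()
    t_indices = range(pressure.times.size) if it is None else [it]
    ps, ds = [], []
    for i in t_indices:
        ik = kinematics.time_index(pressure.times[i])
        valid = pressure.valid_mask[:, :, i]
        if not valid.any():
            raise ValueError("no valid pressure node in the domain")
        gx, gy = X[valid], Y[valid]
        gp = pressure.p[:, :, i][valid]
        pts = kinematics.contour[ik]
        d2 = (pts[:, 0:1] - gx[None, :]) ** 2 + (pts[:, 1:2] - gy[None, :]) ** 2
        nearest = np.argmin(d2, axis=1)  # argmin returns the lowest index on ties
        ps.append(gp[nearest])
        ds.append(np.sqrt(d2[np.arange(pts.shape[0]), nearest]))
    if it is not None:
        return ps[0], ds[0]
    return np.asarray(ps), np.asarray(ds)


# ------------------------------------------------------- model-style facades
@dataclass
class _BaselineResults:
    """Reconstruction output: the pressure field plus surface extraction."""

    pressure: PressureFieldSeries
    kinematics: BodyKinematics | None = None

    def surface_pressure(self, it: int):
        if self.kinematics is None:
            raise ValueError("no kinematics attached")
        return nearest_point_surface_pressure(self.pressure, self.kinematics, it)


class PoissonPressure:
    """Pressure-Poisson reconstruction model over a velocity series."""

    def __init__(self, series: VelocityFieldSeries, Re: float,
                 kinematics: BodyKinematics | None = None,
                 options: PoissonOptions | None = None):
        self.series = series
        self.Re = Re
        self.kinematics = kinematics
        self.options = options or PoissonOptions()

    def fit(self) -> _BaselineResults:
        return _BaselineResults(solve_poisson(self.series, self.Re, self.options),
                                self.kinematics)


class MultipathIntegrationPressure:
    """Omnidirectional pressure-gradient-integration reconstruction model."""

    def __init__(self, series: VelocityFieldSeries, Re: float,
                 kinematics: BodyKinematics | None = None,
                 options: IntegrationOptions | None = None):
        self.series = series
        self.Re = Re
        self.kinematics = kinematics
        self.options = options or IntegrationOptions()

    def fit(self) -> _BaselineResults:
        return _BaselineResults(
            integrate_multidirectional(self.series, self.Re, self.options),
            self.kinematics,
        )
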