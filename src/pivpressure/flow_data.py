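"""Domain types and I/O for gridded velocity/pressure series and body kinematics.

Conventions
-----------
* Node-centered uniform grids; coordinates stored explicitly; all internal
  computation in non-dimensional units (x/L, t/T, u/U).
* Fields are arrays of shape ``(ny, nx, nt)`` (C-order rows = y).
* ``valid_mask`` is False exactly where vectors were removed (grid nodes
  inside — or on — the body contour at that time step).
* Text format: one CSV per time step per component (``u_0000.csv`` ...)
  plus a JSON metadata descriptor.  Binary container: HDF5 with datasets
  ``/x /y /t /u /v /mask`` (``/p`` for pressure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import shapely

__all__ = [
    "ScalingSet",
    "VelocityFieldSeries",
    "PressureFieldSeries",
    "BodyKinematics",
    "BoundaryConditionSpec",
    "read_velocity_series",
    "write_velocity_series",
    "read_pressure_series",
    "write_pressure_series",
    "read_kinematics",
    "write_kinematics",
    "nondimensionalize",
    "redimensionalize",
    "mask_body_interior",
]

_GRID_RTOL = 1e-9


# --------------------------------------------------------------------- scaling
@dataclass(frozen=True)
class ScalingSet:
    """Characteristic scales defining the non-dimensionalization contract.

    Parameters
    ----------
    L_char : characteristic length (e.g. body length), in meters or 1.
    T_char : characteristic time (e.g. tail-beat period or turning time).
    U_char : characteristic velocity.
    rho : fluid density.
    nu : kinematic viscosity; may be None if only ``Re`` is known.
    Re : Reynolds number.  With the tail-beat convention U = L*f = L/T this
        equals L^2 f / nu; generally it is validated against L*U/nu when nu
        is provided.
    """

    L_char: float = 1.0
    T_char: float = 1.0
    U_char: float = 1.0
    rho: float = 1.0
    nu: float | None = None
    Re: float = 1.0

    def __post_init__(self):
        for name in ("L_char", "T_char", "U_char", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Re <= 0:
            raise ValueError("Re must be positive")
        if self.nu is not None:
            re_check = self.L_char * self.U_char / self.nu
            if not np.isclose(re_check, self.Re, rtol=1e-6):
                raise ValueError(
                    f"inconsistent scaling: L*U/nu = {re_check:g} but Re = {self.Re:g}"
                )

    @property
    def time_coefficient(self) -> float:
        """Factor L/(U*T) on the unsteady term of the non-dimensional momentum
        equations; 1 when T_char is the convective time L/U."""
        return self.L_char / (self.U_char * self.T_char)

    @property
    def dynamic_pressure(self) -> float:
        return 0.5 * self.rho * self.U_char**2

    def to_dict(self) -> dict:
        return {
            "L_char": self.L_char,
            "T_char": self.T_char,
            "U_char": self.U_char,
            "rho": self.rho,
            "nu": self.nu,
            "Re": self.Re,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSet":
        return cls(**d)


def _check_axis(a: np.ndarray, name: str) -> None:
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"{name} must be 1-D with >= 2 entries")
    d = np.diff(a)
    if np.any(d <= 0):
        raise ValueError(f"{name} not increasing")
    span = abs(a[-1] - a[0])
    if np.max(np.abs(d - d[0])) > _GRID_RTOL * max(span, abs(d[0])):
        raise ValueError(f"{name} not uniformly spaced")


# ---------------------------------------------------------------- field series
@dataclass
class _GriddedSeries:
    x_coords: np.ndarray
    y_coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        _check_axis(self.x_coords, "x_coords")
        _check_axis(self.y_coords, "y_coords")
        _check_axis(self.times, "times")

    @property
    def shape(self):
        return (self.y_coords.size, self.x_coords.size, self.times.size)

    @property
    def dx(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    @property
    def dy(self) -> float:
        return float(self.y_coords[1] - self.y_coords[0])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def meshgrid(self):
        return np.meshgrid(self.x_coords, self.y_coords)  # (ny, nx) each


@dataclass
class VelocityFieldSeries(_GriddedSeries):
    """Gridded (u, v) samples over time with a validity mask."""

    u: np.ndarray = None
    v: np.ndarray = None
    valid_mask: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        for name, a in (("u", self.u), ("v", self.v), ("valid_mask", self.valid_mask)):
            if a.shape != self.shape:
                raise ValueError(f"{name} shape {a.shape} != grid shape {self.shape}")
        for name, a in (("u", self.u), ("v", self.v)):
            if not np.all(np.isfinite(a[self.valid_mask])):
                raise ValueError(f"non-finite {name} in valid region")

    def copy(self) -> "VelocityFieldSeries":
        return VelocityFieldSeries(
            self.x_coords.copy(), self.y_coords.copy(), self.times.copy(),
            u=self.u.copy(), v=self.v.copy(), valid_mask=self.valid_mask.copy(),
        )

    def sample_points(self):
        """Flatten valid nodes into training samples (x, y, t, u, v), shape (N, 5)."""
        X, Y = self.meshgrid()
        rows = []
        for it, t in enumerate(self.times):
            m = self.valid_mask[:, :, it]
            rows.append(np.column_stack([
                X[m], Y[m], np.full(m.sum(), t), self.u[:, :, it][m], self.v[:, :, it][m],
            ]))
        return np.concatenate(rows, axis=0)


@dataclass
class PressureFieldSeries(_GriddedSeries):
    """Gridded pressure over time, with a declared additive gauge."""

    p: np.ndarray = None
    valid_mask: np.ndarray = None
    gauge: str = "zero_mean"  # "zero_at_boundary" | "zero_mean"

    def __post_init__(self):
        super().__post_init__()
        self.p = np.asarray(self.p, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.p.shape != self.shape:
            raise ValueError(f"p shape {self.p.shape} != grid shape {self.shape}")
        if self.gauge not in ("zero_at_boundary", "zero_mean"):
            raise ValueError(f"unknown gauge {self.gauge!r}")

    def copy(self) -> "PressureFieldSeries":
        return PressureFieldSeries(
            self.x_coords.copy(), self.y_coords.copy(), self.times.copy(),
            p=self.p.copy(), valid_mask=self.valid_mask.copy(), gauge=self.gauge,
        )


# -------------------------------------------------------------- body geometry
@dataclass
class BodyKinematics:
    """Time series of a closed 2D body contour with surface motion.

    ``contour`` has shape (nt, n_pts, 2) — ordered, not repeating the first
    point; closure is implicit.  ``surface_velocity`` has the same shape;
    ``side`` optionally labels points +1 (left/upper) or -1 (right/lower).
    Normals are recomputed from the polyline and oriented outward (the
    contour is stored counter-clockwise, i.e. positive signed area).
    """

    times: np.ndarray
    contour: np.ndarray
    surface_velocity: np.ndarray
    side: np.ndarray | None = None
    arclength_x: np.ndarray | None = None  # x/L station per point (plotting axis)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.contour = np.asarray(self.contour, dtype=float)
        self.surface_velocity = np.asarray(self.surface_velocity, dtype=float)
        if self.contour.ndim != 3 or self.contour.shape[2] != 2:
            raise ValueError("contour must have shape (nt, n_pts, 2)")
        if self.contour.shape != self.surface_velocity.shape:
            raise ValueError("surface_velocity shape must match contour")
        if self.contour.shape[0] != self.times.size:
            raise ValueError("contour time dimension must match times")
        if self.contour.shape[1] < 3:
            raise ValueError("contour needs at least 3 points")
        # drop an explicitly repeated closing point
        if np.allclose(self.contour[:, 0, :], self.contour[:, -1, :]):
            self.contour = self.contour[:, :-1, :]
            self.surface_velocity = self.surface_velocity[:, :-1, :]
            if self.side is not None:
                self.side = np.asarray(self.side)[:-1]
            if self.arclength_x is not None:
                self.arclength_x = np.asarray(self.arclength_x)[:-1]
        # enforce counter-clockwise orientation (positive signed area)
        area = _signed_area(self.contour[0])
        if abs(area) < 1e-14:
            raise ValueError("degenerate (zero-area) contour")
        if area < 0:
            self.contour = self.contour[:, ::-1, :]
            self.surface_velocity = self.surface_velocity[:, ::-1, :]
            if self.side is not None:
                self.side = np.asarray(self.side)[::-1]
            if self.arclength_x is not None:
                self.arclength_x = np.asarray(self.arclength_x)[::-1]

    @property
    def n_points(self) -> int:
        return self.contour.shape[1]

    def normals(self, it: int) -> np.ndarray:
        """Outward unit normals per contour point (edge-averaged)."""
        pts = self.contour[it]
        nxt = np.roll(pts, -1, axis=0)
        prv = np.roll(pts, 1, axis=0)
        tangent = nxt - prv
        # rotate tangent -90 deg: outward for a CCW contour
        n = np.column_stack([tangent[:, 1], -tangent[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError("duplicate contour points produce zero normals")
        return n / norm

    def normal_velocity(self, it: int) -> np.ndarray:
        """u_n = surface velocity projected on the outward normal."""
        return np.einsum("ij,ij->i", self.surface_velocity[it], self.normals(it))

    def time_index(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, atol=1e-9 * max(1.0, abs(t))):
            raise ValueError(f"contour undefined at requested time {t}")
        return i

    def polygon(self, it: int) -> shapely.Polygon:
        return shapely.Polygon(self.contour[it])


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ------------------------------------------------------------------------- BC
_EDGES = ("left", "right", "top", "bottom")
_BC_KINDS = ("none", "zero_pressure", "inlet_velocity")


@dataclass(frozen=True)
class BoundaryConditionSpec:
    """External-edge boundary conditions plus the body non-penetration switch."""

    left: str = "none"
    right: str = "none"
    top: str = "none"
    bottom: str = "none"
    inlet_u: float | None = None
    inlet_v: float | None = None
    body: bool = True

    def __post_init__(self):
        kinds = {e: getattr(self, e) for e in _EDGES}
        for e, k in kinds.items():
            if k not in _BC_KINDS:
                raise ValueError(f"unknown boundary kind {k!r} on edge {e!r}")
        has_inlet = any(k == "inlet_velocity" for k in kinds.values())
        if has_inlet and (self.inlet_u is None or self.inlet_v is None):
            raise ValueError("inlet_velocity edges require inlet_u and inlet_v")
        if not has_inlet and (self.inlet_u is not None or self.inlet_v is not None):
            raise ValueError("inlet values given but no inlet_velocity edge")

    def edges(self, kind: str):
        return [e for e in _EDGES if getattr(self, e) == kind]

    def to_dict(self) -> dict:
        return {
            **{e: getattr(self, e) for e in _EDGES},
            "inlet_u": self.inlet_u,
            "inlet_v": self.inlet_v,
            "body": self.body,
        }


# ------------------------------------------------------------------------ I/O
def write_velocity_series(series: VelocityFieldSeries, path) -> None:
    """Write a series as per-timestep CSVs + metadata, or one HDF5 container.

    A path ending in ``.h5``/``.hdf5`` selects the binary container
    (bit-exact round trip); a directory selects CSV at 9 significant digits.
    """
    _write_gridded(path, series, {"u": series.u, "v": series.v}, extra_meta={})


def write_pressure_series(series: PressureFieldSeries, path) -> None:
    _write_gridded(path, series, {"p": series.p}, extra_meta={"gauge": series.gauge})


def _write_gridded(path, series, fields: dict, extra_meta: dict) -> None:
    if series.times.size == 0:
        raise ValueError("empty series")
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=series.x_coords)
            f.create_dataset("y", data=series.y_coords)
            f.create_dataset("t", data=series.times)
            for k, a in fields.items():
                f.create_dataset(k, data=a)
            f.create_dataset("mask", data=series.valid_mask.astype(np.uint8))
            for k, v in extra_meta.items():
                f.attrs[k] = v
        return
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "x": series.x_coords.tolist(),
        "y": series.y_coords.tolist(),
        "t": series.times.tolist(),
        "fields": sorted(fields),
        **extra_meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for it in range(series.times.size):
        for k, a in fields.items():
            np.savetxt(path / f"{k}_{it:04d}.csv", a[:, :, it], delimiter=",", fmt="%.9g")
        np.savetxt(
            path / f"mask_{it:04d}.csv",
            series.valid_mask[:, :, it].astype(int), delimiter=",", fmt="%d",
        )


def read_velocity_series(path, metadata: dict | None = None,
                         scaling: ScalingSet | None = None) -> VelocityFieldSeries:
    """Read a velocity series (CSV directory or HDF5 container).

    If ``metadata`` declares ``units: dimensional``, a ``scaling`` must be
    supplied and the series is non-dimensionalized on read.
    """
    x, y, t, fields, mask, _ = _read_gridded(path, ("u", "v"))
    s = VelocityFieldSeries(x, y, t, u=fields["u"], v=fields["v"], valid_mask=mask)
    if metadata and metadata.get("units") == "dimensional":
        if scaling is None:
            raise ValueError("dimensional input requires an explicit ScalingSet")
        s = nondimensionalize(s, scaling)
    return s


def read_pressure_series(path) -> PressureFieldSeries:
    x, y, t, fields, mask, meta = _read_gridded(path, ("p",))
    return PressureFieldSeries(x, y, t, p=fields["p"], valid_mask=mask,
                               gauge=meta.get("gauge", "zero_mean"))


def _read_gridded(path, names):
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            x, y, t = f["x"][:], f["y"][:], f["t"][:]
            fields = {k: f[k][:] for k in names}
            mask = f["mask"][:].astype(bool)
            meta = dict(f.attrs)
        return x, y, t, fields, mask, meta
    meta = json.loads((path / "meta.json").read_text())
    x = np.asarray(meta["x"], dtype=float)
    y = np.asarray(meta["y"], dtype=float)
    t = np.asarray(meta["t"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times not increasing")
    nt = t.size
    fields = {}
    for k in names:
        stack = []
        for it in range(nt):
            fp = path / f"{k}_{it:04d}.csv"
            if not fp.exists():
                raise ValueError(f"missing time step file {fp.name}")
            stack.append(np.loadtxt(fp, delimiter=",", ndmin=2))
        fields[k] = np.stack(stack, axis=2)
    mstack = []
    for it in range(nt):
        fp = path / f"mask_{it:04d}.csv"
        mstack.append(np.loadtxt(fp, delimiter=",", ndmin=2).astype(bool)
                      if fp.exists() else np.ones_like(stack[0], dtype=bool))
    mask = np.stack(mstack, axis=2)
    return x, y, t, fields, mask, meta


def write_kinematics(kin: BodyKinematics, path) -> None:
    """Body-contour series: HDF5 container (.h5) or per-timestep CSV of
    ``x, y, u_surf, v_surf`` columns plus a JSON descriptor."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=kin.times)
            f.create_dataset("contour", data=kin.contour)
            f.create_dataset("surface_velocity", data=kin.surface_velocity)
            if kin.side is not None:
                f.create_dataset("side", data=np.asarray(kin.side))
            if kin.arclength_x is not None:
                f.create_dataset("arclength_x", data=np.asarray(kin.arclength_x))
        return
    path.mkdir(parents=True, exist_ok=True)
    meta = {"t": kin.times.tolist()}
    if kin.side is not None:
        meta["side"] = np.asarray(kin.side).tolist()
    if kin.arclength_x is not None:
        meta["arclength_x"] = np.asarray(kin.arclength_x).tolist()
    (path / "kinematics_meta.json").write_text(json.dumps(meta, indent=1))
    for it in range(kin.times.size):
        np.savetxt(path / f"contour_{it:04d}.csv",
                   np.hstack([kin.contour[it], kin.surface_velocity[it]]),
                   delimiter=",", fmt="%.9g", header="x,y,u_surf,v_surf")


def read_kinematics(path) -> BodyKinematics:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return BodyKinematics(
                times=f["t"][:], contour=f["contour"][:],
                surface_velocity=f["surface_velocity"][:],
                side=f["side"][:] if "side" in f else None,
                arclength_x=f["arclength_x"][:] if "arclength_x" in f else None,
            )
    meta = json.loads((path / "kinematics_meta.json").read_text())
    t = np.asarray(meta["t"], dtype=float)
    contour, surf = [], []
    for it in range(t.size):
        a = np.loadtxt(path / f"contour_{it:04d}.csv", delimiter=",", ndmin=2)
        contour.append(a[:, :2])
        surf.append(a[:, 2:4])
    return BodyKinematics(
        times=t, contour=np.stack(contour), surface_velocity=np.stack(surf),
        side=np.asarray(meta["side"]) if "side" in meta else None,
        arclength_x=np.asarray(meta["arclength_x"]) if "arclength_x" in meta else None,
    )


# -------------------------------------------------------------------- scaling
def nondimensionalize(series: VelocityFieldSeries, scaling: ScalingSet) -> VelocityFieldSeries:
    """Apply x/L, y/L, t/T, u/U, v/U."""
    return VelocityFieldSeries(
        series.x_coords / scaling.L_char,
        series.y_coords / scaling.L_char,
        series.times / scaling.T_char,
        u=series.u / scaling.U_char,
        v=series.v / scaling.U_char,
        valid_mask=series.valid_mask.copy(),
    )


def redimensionalize(series: VelocityFieldSeries, scaling: ScalingSet) -> VelocityFieldSeries:
    return VelocityFieldSeries(
        series.x_coords * scaling.L_char,
        series.y_coords * scaling.L_char,
        series.times * scaling.T_char,
        u=series.u * scaling.U_char,
        v=series.v * scaling.U_char,
        valid_mask=series.valid_mask.copy(),
    )


# -------------------------------------------------------------------- masking
def mask_body_interior(series: VelocityFieldSeries,
                       kinematics: BodyKinematics) -> VelocityFieldSeries:
    """Mark grid nodes inside (or on) the body contour invalid at each time.

    On-contour nodes count as interior: vectors there are boundary-layer
    corrupted in real PIV.  Idempotent and time-local.
    """
    out = series.copy()
    X, Y = series.meshgrid()
    for it, t in enumerate(series.times):
        ik = kinematics.time_index(t)
        poly = kinematics.polygon(ik)
        if not poly.is_valid:
            raise ValueError(f"invalid/self-intersecting contour at t={t}")
        inside = shapely.intersects_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
        out.valid_mask[:, :, it] &= ~inside
    return out
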