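"""Steady low-Reynolds flow in the chip: analytic duct results and a
depth-averaged planform solver.

The channel is shallow (50 um deep, 200 um wide, Re ~ 1e-2 at the working
flow rates), so the full 3D Stokes problem is reduced to a 2D depth-averaged
Stokes-Brinkman system on the planform:

    (6/5) div( eta grad(u) ) - (12 eta / h^2) u - grad(p) = 0,   div(u) = 0

where ``u`` is the depth-averaged in-plane velocity.  Both coefficients
follow from a Galerkin (parabolic-profile-weighted) projection of the 3D
Stokes equations over the depth: the drag ``12 eta / h^2`` is the exact
closure for a locally parabolic depth profile, and the 6/5 factor on the
in-plane viscous term is the profile-weighted momentum correction, which
reproduces the sidewall boundary layers of the true duct flow to ~1%.
Boundary conditions: no-slip on all walls, prescribed flow rate at the inlet
(fully developed Brinkman profile), zero pressure at the outlet.  For Carreau
fluids the local viscosity is updated from a characteristic shear rate by
under-relaxed Picard iteration.

Discretization: marker-and-cell (staggered) finite differences on the
rasterized planform grid, with mirror ghosts for tangential no-slip, solved
directly (sparse LU).  Mass is conserved cell-wise to solver precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve

from .geometry import Defect, PlanformGrid, _Arc
from .rheology import FluidModel, viscosity

__all__ = [
    "VelocityProfile",
    "FlowField",
    "slit_wall_shear",
    "rect_duct_velocity",
    "rect_duct_profile",
    "slit_depth_profile",
    "shear_from_profile",
    "solve_planform",
    "spanwise_profile",
    "constriction_speedup",
    "bend_speed_asymmetry",
]

UL_PER_MIN = 1e-9 / 60.0  # m^3/s per uL/min


@dataclass
class VelocityProfile:
    """Binned 1-D velocity profile across a channel dimension.

    ``coord_um`` are bin centers between the walls at ``span_um[0]`` and
    ``span_um[1]``; ``speed_mm_s`` holds the mean speed per bin (NaN where a
    bin is empty) and ``counts`` the number of samples per bin (0 for
    analytic profiles).
    """

    coord_um: np.ndarray
    speed_mm_s: np.ndarray
    counts: np.ndarray
    span_um: tuple[float, float]
    axis: str = "spanwise"


# --------------------------------------------------------------------------- #
# analytic results
# --------------------------------------------------------------------------- #

def slit_wall_shear(Q_ul_min: float, w_um: float, h_um: float, eta: float) -> float:
    """Wall shear stress tau = 6 eta Q / (w h^2) of plane-slit flow, in Pa.

    This is the thin-gap estimate tau ~ eta * dv/dy at the top/bottom walls
    of a wide rectangular duct (aspect w/h >= ~2; a warning is issued below
    that).  ``Q`` in uL/min, ``w`` and ``h`` in um, ``eta`` in Pa s.
    """
    if Q_ul_min < 0 or w_um <= 0 or h_um <= 0 or eta <= 0:
        raise ValueError("Q must be >= 0 and w, h, eta positive")
    if w_um / h_um < 2.0:
        warnings.warn("slit formula is inaccurate for aspect ratio w/h < 2",
                      stacklevel=2)
    Q = Q_ul_min * UL_PER_MIN
    w = w_um * 1e-6
    h = h_um * 1e-6
    return 6.0 * eta * Q / (w * h * h)


def rect_duct_velocity(y_um, z_um, Q_ul_min: float, w_um: float, h_um: float,
                       n_terms: int = 51) -> np.ndarray:
    """Axial velocity (mm/s) of Newtonian flow in a rectangular duct.

    Fourier-series solution of ``eta lap(u) = dp/dx`` on the cross-section,
    normalized so that the flow rate equals ``Q``.  ``y`` is spanwise in
    [-w/2, w/2], ``z`` depthwise in [-h/2, h/2] (um, broadcastable arrays).
    """
    if Q_ul_min < 0 or w_um <= 0 or h_um <= 0:
        raise ValueError("Q must be >= 0 and w, h positive")
    a = h_um / 2.0
    b = w_um / 2.0
    y = np.asarray(y_um, dtype=float)
    z = np.asarray(z_um, dtype=float)
    ns = np.arange(1, 2 * n_terms, 2)

    def cosh_ratio(num, den):
        # cosh(num)/cosh(den) for 0 <= num <= den, overflow-safe
        return np.exp(num - den) * (1.0 + np.exp(-2.0 * num)) \
            / (1.0 + np.exp(-2.0 * den))

    def shape(yv, zv):
        out = np.zeros(np.broadcast(yv, zv).shape)
        for n in ns:
            k = n * np.pi / (2.0 * a)
            out += ((-1) ** ((n - 1) // 2) / n**3
                    * (1.0 - cosh_ratio(k * np.abs(yv), k * b))
                    * np.cos(k * zv))
        return out

    u = shape(y, z)
    # normalize by the exact series integral over the cross-section
    q_shape = 0.0
    for n in ns:
        k = n * np.pi / (2.0 * a)
        q_shape += (1.0 / n**3
                    * (2 * b - 2.0 * np.tanh(k * b) / k)
                    * (4.0 * a / (n * np.pi)))
    q_shape *= 1e-12  # um^2 -> m^2
    Q = Q_ul_min * UL_PER_MIN
    return u * Q / q_shape * 1e3  # m/s -> mm/s


def rect_duct_profile(Q_ul_min: float, w_um: float, h_um: float,
                      n_bins: int = 40, depth_averaged: bool = False,
                      n_terms: int = 51) -> VelocityProfile:
    """Spanwise velocity profile of the rectangular-duct series solution.

    By default the profile is evaluated at mid-height (the focal plane of
    the tracer measurements); with ``depth_averaged=True`` it is the mean
    over the channel depth (the quantity the planform solver computes).
    """
    yc = (np.arange(n_bins) + 0.5) / n_bins * w_um - w_um / 2.0
    if depth_averaged:
        zs = np.linspace(-h_um / 2.0, h_um / 2.0, 65)
        u = np.trapezoid(
            rect_duct_velocity(yc[:, None], zs[None, :], Q_ul_min, w_um, h_um,
                               n_terms), zs, axis=1) / h_um
    else:
        u = rect_duct_velocity(yc, 0.0, Q_ul_min, w_um, h_um, n_terms)
    return VelocityProfile(coord_um=yc + w_um / 2.0, speed_mm_s=u,
                           counts=np.zeros(n_bins, dtype=int),
                           span_um=(0.0, w_um))


def slit_depth_profile(Q_ul_min: float, w_um: float, h_um: float,
                       n_bins: int = 25) -> VelocityProfile:
    """Parabolic depth profile v(z) = 6Q/(w h^3) z (h - z) of slit flow.

    Bins span the channel depth; useful as the exact reference for
    wall-shear estimation from a measured profile.
    """
    z = (np.arange(n_bins) + 0.5) / n_bins * h_um
    Q = Q_ul_min * UL_PER_MIN
    w = w_um * 1e-6
    h = h_um * 1e-6
    zm = z * 1e-6
    v = 6.0 * Q / (w * h**3) * zm * (h - zm) * 1e3  # mm/s
    return VelocityProfile(coord_um=z, speed_mm_s=v,
                           counts=np.zeros(n_bins, dtype=int),
                           span_um=(0.0, h_um), axis="depthwise")


def shear_from_profile(profile: VelocityProfile, fluid: FluidModel) -> float:
    """Wall shear stress (Pa) from a velocity profile: tau = eta * dv/dy.

    The wall velocity gradient is obtained from a quadratic fit through the
    three bins nearest each wall (exact for a parabolic profile), evaluated
    at the wall, and averaged over the two walls.  For Carreau fluids the
    viscosity is evaluated at the measured wall shear rate.
    """
    ok = np.isfinite(profile.speed_mm_s)
    coord = profile.coord_um[ok]
    speed = profile.speed_mm_s[ok]
    if coord.size < 3:
        raise ValueError("profile too sparse near wall: need >= 3 bins")
    taus = []
    for wall in profile.span_um:
        order = np.argsort(np.abs(coord - wall))[:3]
        c = np.polyfit(coord[order], speed[order], 2)
        grad = abs(2.0 * c[0] * wall + c[1])  # (mm/s)/um
        gdot = grad * 1e3                      # 1/s
        eta = viscosity(fluid, gdot)
        taus.append(eta * gdot)
    return float(np.mean(taus))


# --------------------------------------------------------------------------- #
# planform solver
# --------------------------------------------------------------------------- #

@dataclass
class FlowField:
    """Depth-averaged velocity/pressure/viscosity fields on a planform grid.

    Velocities are stored in SI (m/s) at cell centers; face-normal
    velocities are kept for exact flux accounting.  User-facing speeds are
    mm/s.
    """

    grid: PlanformGrid
    fluid: FluidModel
    Q_ul_min: float
    vx: np.ndarray            # m/s, cell-centered
    vy: np.ndarray
    pressure: np.ndarray      # Pa
    shear_rate: np.ndarray    # 1/s characteristic
    viscosity: np.ndarray     # Pa s
    u_faces: np.ndarray       # m/s, shape (ny, nx+1)
    v_faces: np.ndarray       # m/s, shape (ny+1, nx)
    picard_iterations: int = 0
    picard_residual: float = 0.0
    _interp: object = field(default=None, repr=False, compare=False)

    @property
    def speed_mm_s(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy) * 1e3

    def velocity_at(self, points_um: np.ndarray) -> np.ndarray:
        """Bilinear velocity (m/s) at planform points (N, 2) in um."""
        if self._interp is None:
            x, y = self.grid.cell_centers()
            vals = np.dstack([self.vx, self.vy])
            self._interp = RegularGridInterpolator(
                (y, x), vals, bounds_error=False, fill_value=0.0)
        pts = np.atleast_2d(points_um)
        return self._interp(np.column_stack([pts[:, 1], pts[:, 0]]))

    def flux_at_station(self, s_mm: float) -> float:
        """Volumetric flux (uL/min) through the cross-section at path
        position ``s_mm`` of a straight, axis-aligned limb."""
        g = self.grid
        p, t = g.geometry.point_at(s_mm)
        if abs(t[0]) < 0.99:
            raise ValueError("flux stations only supported on x-aligned limbs")
        px = g.pixel_size_um
        ic = int(round((p[0] - g.origin_um[0]) / px))
        ic = np.clip(ic, 0, g.mask.shape[1] - 1)
        _, ys = g.cell_centers()
        rows = np.abs(ys - p[1]) <= g.geometry.width_um / 2.0
        u = self.u_faces[rows, ic]
        h = g.geometry.height_um * 1e-6
        flux = np.sign(t[0]) * np.sum(u) * (px * 1e-6) * h
        return float(flux / UL_PER_MIN)

    def to_csv(self, path) -> None:
        """Export the fluid cells as CSV (x_um, y_um, vx_mm_s, vy_mm_s,
        pressure_Pa, viscosity_Pa_s)."""
        import pandas as pd

        g = self.grid
        x, y = g.cell_centers()
        jj, ii = np.nonzero(g.mask)
        pd.DataFrame({
            "x_um": x[ii], "y_um": y[jj],
            "vx_mm_s": self.vx[jj, ii] * 1e3,
            "vy_mm_s": self.vy[jj, ii] * 1e3,
            "pressure_Pa": self.pressure[jj, ii],
            "viscosity_Pa_s": self.viscosity[jj, ii],
        }).to_csv(path, index=False)

    def magnitude_to_tiff(self, path) -> None:
        """Export the speed magnitude (mm/s) as float32 TIFF."""
        import tifffile

        tifffile.imwrite(path, self.speed_mm_s.astype(np.float32))


#: profile-weighted (Galerkin) correction on the in-plane viscous term
_DEPTH_VISC_FACTOR = 6.0 / 5.0


def _brinkman_inlet_profile(ys: np.ndarray, yc: float, half_w_um: float,
                            h_um: float) -> np.ndarray:
    """Fully developed depth-averaged spanwise shape, unnormalized."""
    k = np.sqrt(12.0 / _DEPTH_VISC_FACTOR) / h_um  # 1/um
    u = 1.0 - np.cosh(k * (ys - yc)) / np.cosh(k * half_w_um)
    return np.clip(u, 0.0, None)


def _assemble_and_solve(grid: PlanformGrid, eta_cells: np.ndarray,
                        Q_ul_min: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Stokes-Brinkman solve at frozen viscosity field.

    Returns face velocities u (ny, nx+1), v (ny+1, nx) in m/s and cell
    pressures (Pa).
    """
    mask = grid.mask
    ny, nx = mask.shape
    dx = grid.pixel_size_um * 1e-6
    h = grid.geometry.height_um * 1e-6
    Q = Q_ul_min * UL_PER_MIN

    if grid.inlet_side not in ("W", "E") or grid.outlet_side not in ("W", "E"):
        raise ValueError("solver supports W/E inlet and outlet mouths only")

    inlet_col = 0 if grid.inlet_side == "W" else nx - 1
    outlet_col = 0 if grid.outlet_side == "W" else nx - 1

    # --- classify u faces: 0 wall, 1 unknown, 2 dirichlet (inlet), 3 outlet
    u_type = np.zeros((ny, nx + 1), dtype=np.int8)
    u_val = np.zeros((ny, nx + 1))
    fl = mask
    u_type[:, 1:nx][fl[:, :-1] & fl[:, 1:]] = 1

    # inlet Dirichlet profile on the mouth boundary faces
    _, ys = grid.cell_centers()
    jin = np.nonzero(grid.inlet_mask[:, inlet_col])[0]
    yc = 0.5 * (ys[jin].min() + ys[jin].max())
    prof = _brinkman_inlet_profile(ys[jin], yc, grid.geometry.width_um / 2.0,
                                   grid.geometry.height_um)
    scale = Q / (np.sum(prof) * dx * h)
    sign_in = 1.0 if grid.inlet_side == "W" else -1.0
    iface = inlet_col if grid.inlet_side == "W" else nx
    u_type[jin, iface] = 2
    u_val[jin, iface] = sign_in * prof * scale

    jout = np.nonzero(grid.outlet_mask[:, outlet_col])[0]
    oface = outlet_col if grid.outlet_side == "W" else nx
    u_type[jout, oface] = 3

    # --- v faces: unknown where both vertical neighbours are fluid
    v_type = np.zeros((ny + 1, nx), dtype=np.int8)
    v_type[1:ny, :][fl[:-1, :] & fl[1:, :]] = 1

    # unknown numbering
    u_idx = -np.ones((ny, nx + 1), dtype=np.int64)
    un = np.argwhere((u_type == 1) | (u_type == 3))
    u_idx[un[:, 0], un[:, 1]] = np.arange(len(un))
    nu = len(un)
    v_idx = -np.ones((ny + 1, nx), dtype=np.int64)
    vn = np.argwhere(v_type == 1)
    v_idx[vn[:, 0], vn[:, 1]] = nu + np.arange(len(vn))
    nv = len(vn)
    p_idx = -np.ones((ny, nx), dtype=np.int64)
    pn = np.argwhere(mask)
    p_idx[pn[:, 0], pn[:, 1]] = nu + nv + np.arange(len(pn))
    npp = len(pn)
    ntot = nu + nv + npp

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    eta = eta_cells
    inv_dx2 = _DEPTH_VISC_FACTOR / dx**2

    def eta_cell(j, i):
        if 0 <= j < ny and 0 <= i < nx and mask[j, i]:
            return eta[j, i]
        return np.nan

    def corner_eta(j, i):
        # average viscosity of fluid cells around the corner (j-1/2 rows)
        cands = [eta_cell(j, i - 1), eta_cell(j, i),
                 eta_cell(j - 1, i - 1), eta_cell(j - 1, i)]
        cands = [c for c in cands if np.isfinite(c)]
        return float(np.mean(cands)) if cands else 0.0

    # ---- u momentum ------------------------------------------------------
    for j, i in un:
        r = u_idx[j, i]
        outlet = u_type[j, i] == 3
        eW = eta_cell(j, i - 1)
        eE = eta_cell(j, i)
        if not np.isfinite(eW):
            eW = eE
        if not np.isfinite(eE):
            eE = eW
        diag = 0.0

        # x-diffusion
        for nb_i, e in ((i - 1, eW), (i + 1, eE)):
            if nb_i < 0 or nb_i > nx:
                continue  # zero-gradient ghost outside a mouth edge
            t = u_type[j, nb_i]
            coef = e * inv_dx2
            if t in (1, 3):
                add(r, u_idx[j, nb_i], coef)
                diag -= coef
            elif t == 2:
                rhs[r] -= coef * u_val[j, nb_i]
                diag -= coef
            else:
                # wall plane coincides with that face: u = 0 there
                diag -= coef

        # y-diffusion with mirror ghosts at tangential walls
        for nb_j in (j - 1, j + 1):
            eN = corner_eta(max(j, nb_j), i)
            coef = eN * inv_dx2
            if 0 <= nb_j < ny and u_type[nb_j, i] in (1, 3):
                add(r, u_idx[nb_j, i], coef)
                diag -= coef
            elif 0 <= nb_j < ny and u_type[nb_j, i] == 2:
                rhs[r] -= coef * u_val[nb_j, i]
                diag -= coef
            else:
                # wall halfway: ghost = -u  => contributes -2 coef
                diag -= 2.0 * coef

        # Brinkman drag
        diag -= 12.0 * 0.5 * (eW + eE) / h**2

        # pressure gradient; at the outlet the face pressure is pinned to 0,
        # giving a half-cell one-sided gradient
        if outlet:
            if grid.outlet_side == "E":
                add(r, p_idx[j, i - 1], 2.0 / dx)   # -(0 - p_W)/(dx/2)
            else:
                add(r, p_idx[j, i], -2.0 / dx)      # -(p_E - 0)/(dx/2)
        else:
            add(r, p_idx[j, i], -1.0 / dx)
            add(r, p_idx[j, i - 1], 1.0 / dx)

        add(r, u_idx[j, i], diag)

    # ---- v momentum ------------------------------------------------------
    for j, i in vn:
        r = v_idx[j, i]
        eS = eta_cell(j - 1, i)
        eN = eta_cell(j, i)
        if not np.isfinite(eS):
            eS = eN
        if not np.isfinite(eN):
            eN = eS
        diag = 0.0

        # y-diffusion (cell viscosities)
        for nb_j, e in ((j - 1, eS), (j + 1, eN)):
            coef = e * inv_dx2
            if 0 <= nb_j <= ny and v_type[nb_j, i] == 1:
                add(r, v_idx[nb_j, i], coef)
                diag -= coef
            else:
                diag -= coef  # wall face: v = 0 exactly at that plane

        # x-diffusion with mirror ghosts / zero-gradient at domain edge
        for nb_i in (i - 1, i + 1):
            eC = corner_eta(j, max(i, nb_i))
            coef = eC * inv_dx2
            if 0 <= nb_i < nx and v_type[j, nb_i] == 1:
                add(r, v_idx[j, nb_i], coef)
                diag -= coef
            elif nb_i < 0 or nb_i >= nx:
                continue  # domain edge at a mouth column: zero-gradient
            else:
                # solid neighbour: wall halfway -> mirror ghost
                diag -= 2.0 * coef

        diag -= 12.0 * 0.5 * (eS + eN) / h**2

        add(r, p_idx[j, i], -1.0 / dx)
        add(r, p_idx[j - 1, i], 1.0 / dx)
        add(r, v_idx[j, i], diag)

    # ---- continuity ------------------------------------------------------
    for j, i in pn:
        r = p_idx[j, i]
        for fi, sgn in ((i + 1, 1.0), (i, -1.0)):
            t = u_type[j, fi]
            if t in (1, 3):
                add(r, u_idx[j, fi], sgn / dx)
            elif t == 2:
                rhs[r] -= sgn / dx * u_val[j, fi]
        for fj, sgn in ((j + 1, 1.0), (j, -1.0)):
            if v_type[fj, i] == 1:
                add(r, v_idx[fj, i], sgn / dx)

    A = sparse.coo_matrix((vals, (rows, cols)), shape=(ntot, ntot)).tocsc()
    sol = spsolve(A, rhs)

    u = np.array(u_val)
    u[un[:, 0], un[:, 1]] = sol[:nu]
    v = np.zeros((ny + 1, nx))
    v[vn[:, 0], vn[:, 1]] = sol[nu:nu + nv]
    p = np.zeros((ny, nx))
    p[pn[:, 0], pn[:, 1]] = sol[nu + nv:]
    return u, v, p


def _characteristic_shear(grid: PlanformGrid, vx: np.ndarray, vy: np.ndarray
                          ) -> np.ndarray:
    """Characteristic shear rate combining in-plane strain and the dominant
    depthwise contribution sqrt(12) |v| / h of the parabolic depth profile."""
    dx = grid.pixel_size_um * 1e-6
    h = grid.geometry.height_um * 1e-6
    dudy, dudx = np.gradient(vx, dx)
    dvdy, dvdx = np.gradient(vy, dx)
    plane = np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + (dudy + dvdx) ** 2)
    depth = np.sqrt(12.0) * np.hypot(vx, vy) / h
    return np.sqrt(plane**2 + depth**2)


def solve_planform(grid: PlanformGrid, fluid: FluidModel, Q_ul_min: float,
                   *, picard_tol: float = 1e-6, picard_max_iter: int = 200,
                   picard_relax: float = 0.5) -> FlowField:
    """Solve steady depth-averaged flow at flow rate ``Q`` (uL/min).

    Newtonian fluids need a single linear solve; Carreau fluids iterate the
    viscosity field (under-relaxed Picard) until the largest relative
    viscosity update falls below ``picard_tol``.
    """
    if Q_ul_min <= 0:
        raise ValueError("flow rate must be positive")
    mask = grid.mask
    h = grid.geometry.height_um * 1e-6
    w = grid.geometry.width_um * 1e-6
    vbar = Q_ul_min * UL_PER_MIN / (w * h)
    gdot0 = np.sqrt(12.0) * vbar / h

    eta_cells = np.where(mask, viscosity(fluid, np.full(mask.shape, gdot0)), 0.0)
    iters = 0
    resid = 0.0
    while True:
        u, v, p = _assemble_and_solve(grid, eta_cells, Q_ul_min)
        vx = 0.5 * (u[:, :-1] + u[:, 1:]) * mask
        vy = 0.5 * (v[:-1, :] + v[1:, :]) * mask
        if fluid.law == "newtonian":
            gdot = _characteristic_shear(grid, vx, vy)
            break
        gdot = _characteristic_shear(grid, vx, vy)
        eta_new = np.where(mask, viscosity(fluid, gdot), 0.0)
        delta = np.abs(eta_new - eta_cells)[mask]
        resid = float(np.max(delta / np.maximum(eta_cells[mask], 1e-30)))
        eta_cells = eta_cells + picard_relax * (eta_new - eta_cells)
        iters += 1
        if resid < picard_tol:
            u, v, p = _assemble_and_solve(grid, eta_cells, Q_ul_min)
            vx = 0.5 * (u[:, :-1] + u[:, 1:]) * mask
            vy = 0.5 * (v[:-1, :] + v[1:, :]) * mask
            gdot = _characteristic_shear(grid, vx, vy)
            break
        if iters >= picard_max_iter:
            raise RuntimeError(
                f"Picard iteration did not converge: residual {resid:.2e} "
                f"after {iters} iterations")

    return FlowField(
        grid=grid, fluid=fluid, Q_ul_min=Q_ul_min,
        vx=vx, vy=vy, pressure=p * mask,
        shear_rate=gdot * mask,
        viscosity=eta_cells if fluid.law != "newtonian"
        else np.where(mask, fluid.eta, 0.0),
        u_faces=u, v_faces=v,
        picard_iterations=iters, picard_residual=resid,
    )


# --------------------------------------------------------------------------- #
# field diagnostics
# --------------------------------------------------------------------------- #

def spanwise_profile(flow: FlowField, s_mm: float, window_mm: float = 0.2,
                     n_bins: int = 40) -> VelocityProfile:
    """Spanwise profile of depth-averaged speed around path position ``s``."""
    g = flow.grid
    w = g.geometry.width_um
    s_um = s_mm * 1e3
    sel = g.mask & (np.abs(g.s_map_um - s_um) <= window_mm * 1e3 / 2.0)
    d = g.d_map_um[sel]
    spd = flow.speed_mm_s[sel]
    edges = np.linspace(-w / 2.0, w / 2.0, n_bins + 1)
    which = np.digitize(d, edges) - 1
    speed = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = which == b
        counts[b] = m.sum()
        if counts[b]:
            speed[b] = spd[m].mean()
    return VelocityProfile(coord_um=0.5 * (edges[:-1] + edges[1:]) + w / 2.0,
                           speed_mm_s=speed, counts=counts, span_um=(0.0, w))


def _section_mean_speed(flow: FlowField, s_mm: float, half_len_um: float) -> float:
    g = flow.grid
    sel = g.mask & (np.abs(g.s_map_um - s_mm * 1e3) <= half_len_um) \
        & (np.abs(g.d_map_um) <= g.geometry.width_um / 2.0)
    if not sel.any():
        raise ValueError(f"no fluid cells around path position {s_mm} mm")
    return float(flow.speed_mm_s[sel].mean())


def constriction_speedup(flow: FlowField, defect: Defect,
                         reference_offset_mm: float | None = None) -> float:
    """Ratio of mean speed inside a clot constriction to an open reference
    section of the same length upstream.

    By mass conservation the ratio approaches ``1 / (1 - spanwise_extent)``
    for a clot blocking ``spanwise_extent`` of the width.
    """
    if defect not in flow.grid.geometry.defects:
        raise ValueError("defect is not part of the solved geometry")
    if defect.kind != "clot":
        raise ValueError("constriction speed-up is defined for clot defects")
    half = defect.axial_extent_um / 2.0
    if reference_offset_mm is None:
        reference_offset_mm = max(3.0 * defect.axial_extent_um * 1e-3, 0.4)
    s_ref = defect.path_position_mm - reference_offset_mm
    if s_ref <= 0:
        s_ref = defect.path_position_mm + reference_offset_mm
    return (_section_mean_speed(flow, defect.path_position_mm, half)
            / _section_mean_speed(flow, s_ref, half))


def bend_speed_asymmetry(flow: FlowField, bend_index: int = 0) -> tuple[float, float]:
    """Mean speeds (mm/s) on the inner and outer half of a serpentine bend.

    Returns ``(inner, outer)``; low-Re channel bends carry faster flow on
    the inner (shorter) side.
    """
    g = flow.grid
    geom = g.geometry
    s0 = -geom.lead_um
    k = -1
    for part in geom.centerline():
        if isinstance(part, _Arc):
            k += 1
            if k == bend_index:
                s1 = s0 + part.length
                turn = np.sign(part.a1 - part.a0)  # +1: center on the left
                sel = g.mask & (g.s_map_um >= s0) & (g.s_map_um <= s1)
                inner = sel & (turn * g.d_map_um > 0)
                outer = sel & (turn * g.d_map_um < 0)
                if not inner.any() or not outer.any():
                    raise ValueError("bend region not resolved on this grid")
                return (float(flow.speed_mm_s[inner].mean()),
                        float(flow.speed_mm_s[outer].mean()))
        s0 += part.length
    raise ValueError(f"geometry has no bend with index {bend_index}")
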