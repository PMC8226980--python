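"""Synthetic raw data: stochastic tracer/RBC trajectories and rendered frames.

Stands in for the chip's microscopy acquisitions.  Tracer beads (0.75 um
latex spheres) are advected through a solved :class:`~vesselchip.flow.FlowField`
at the acquisition interval (default 2 ms/frame).  Crowding by red blood
cells is modelled as a Poisson collision process: at each frame step the
number of collisions k is Poisson(rate * dt) and, if k > 0, the step
direction is deflected by a zero-mean Gaussian angle of standard deviation
``sigma_phi * sqrt(k)``.  The collision rate scales linearly with hematocrit.

Rendered frames are 16-bit grayscale: beads as Gaussian spots, an optional
advected band-limited speckle texture standing in for label-free RBC
contrast (the texture PIV locks onto), plus additive Gaussian noise.
Everything is deterministic given the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .flow import FlowField, solve_planform
from .geometry import ChannelGeometry, Defect, add_defect, build_serpentine, rasterize
from .rheology import get_fluid
from .tracking import Trajectory

__all__ = [
    "ScatterModel",
    "Optics",
    "SceneSpec",
    "Scene",
    "advect_particles",
    "render_frames",
    "make_scene",
]


@dataclass(frozen=True)
class ScatterModel:
    """Bead-RBC collision model.

    ``collision_rate`` is events/s, by default proportional to hematocrit
    (50 s^-1 per Hct %, i.e. 2250 s^-1 at the adult default Hct = 45%, so a
    2 ms frame sees several collisions).  ``sigma_phi_deg`` is the standard
    deviation of the per-collision deflection angle; the per-step deflection
    compounds as sqrt(k) over k collisions.  ``wall_interaction`` selects
    elastic reflection or absorption at walls.
    """

    hematocrit_pct: float = 45.0
    collision_rate: float | None = None      # events/s; None -> 50 * Hct
    sigma_phi_deg: float = 0.0
    wall_interaction: Literal["reflect", "absorb"] = "reflect"

    def __post_init__(self) -> None:
        if self.hematocrit_pct < 0 or self.sigma_phi_deg < 0:
            raise ValueError("hematocrit and sigma_phi must be >= 0")
        if self.rate < 0:
            raise ValueError("collision_rate must be >= 0")

    @property
    def rate(self) -> float:
        if self.collision_rate is not None:
            return self.collision_rate
        return 50.0 * self.hematocrit_pct

    def expected_step_angle_deg(self, dt_ms: float) -> float:
        """Expected per-step mean absolute deflection angle (degrees)."""
        lam = self.rate * dt_ms * 1e-3
        k = np.arange(0, max(int(lam + 10 * np.sqrt(lam + 1)), 20))
        pmf = np.exp(-lam + k * np.log(np.maximum(lam, 1e-300)) -
                     [float(np.sum(np.log(np.arange(1, kk + 1)))) for kk in k])
        return float(self.sigma_phi_deg * np.sqrt(2.0 / np.pi)
                     * np.sum(pmf * np.sqrt(k)))

    @classmethod
    def calibrated(cls, mean_abs_angle_deg: float, dt_ms: float = 2.0,
                   hematocrit_pct: float = 45.0,
                   wall_interaction: str = "reflect") -> "ScatterModel":
        """Choose ``sigma_phi`` so the per-step mean |deflection| at frame
        interval ``dt_ms`` equals ``mean_abs_angle_deg`` (e.g. the 1.2 deg
        scattering scale measured for beads in whole blood)."""
        base = cls(hematocrit_pct=hematocrit_pct, sigma_phi_deg=1.0,
                   wall_interaction=wall_interaction)
        per_unit = base.expected_step_angle_deg(dt_ms)
        if per_unit <= 0:
            raise ValueError("collision rate too low to calibrate scattering")
        return replace(base, sigma_phi_deg=mean_abs_angle_deg / per_unit)


@dataclass(frozen=True)
class Optics:
    """Rendering parameters (image-plane units are pixels of size
    ``pixel_size_um``)."""

    pixel_size_um: float = 1.0
    spot_sigma_px: float = 1.5
    bead_intensity: float = 12000.0
    speckle_contrast: float = 4000.0     # 0 disables the RBC texture
    speckle_corr_um: float = 6.0         # ~RBC diameter
    background: float = 800.0
    noise_sd: float = 50.0

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.spot_sigma_px) <= 0:
            raise ValueError("optics lengths must be positive")
        if min(self.bead_intensity, self.speckle_contrast, self.background,
               self.noise_sd) < 0:
            raise ValueError("optics intensities must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of a synthetic acquisition."""

    preset: str = "baseline"
    fluid_name: str = "blood"
    Q_ul_min: float = 0.5
    n_particles: int = 60
    dt_ms: float = 2.0
    n_frames: int = 25
    optics: Optics = field(default_factory=Optics)
    scatter: ScatterModel = field(default_factory=ScatterModel)
    seed: int = 0
    seed_margin_um: float = 20.0   # keep initial beads off the walls
    central_fraction: float = 1.0  # restrict seeding to central lane

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_frames < 1 or self.n_particles < 1:
            raise ValueError("need at least one frame and one particle")


@dataclass
class Scene:
    """A generated scene: geometry, flow, trajectories and frames."""

    spec: SceneSpec
    geometry: ChannelGeometry
    flow: FlowField
    trajectories: list[Trajectory]
    frames: np.ndarray | None = None   # (n_frames, ny, nx) uint16
    crop_um: tuple[float, float, float, float] | None = None

    def manifest(self) -> dict:
        sp = self.spec
        return {
            "preset": sp.preset, "fluid": sp.fluid_name, "Q_ul_min": sp.Q_ul_min,
            "n_particles": sp.n_particles, "dt_ms": sp.dt_ms,
            "n_frames": sp.n_frames, "seed": sp.seed,
            "hematocrit_pct": sp.scatter.hematocrit_pct,
            "collision_rate_per_s": sp.scatter.rate,
            "sigma_phi_deg": sp.scatter.sigma_phi_deg,
            "pixel_size_um": sp.optics.pixel_size_um,
            "total_path_length_mm": self.geometry.total_path_length_mm,
        }


# --------------------------------------------------------------------------- #
# particle advection
# --------------------------------------------------------------------------- #

def _seed_positions(flow: FlowField, spec: SceneSpec, rng: np.random.Generator
                    ) -> np.ndarray:
    g = flow.grid
    margin = spec.seed_margin_um
    ok = g.mask & (g.wall_distance_um > margin)
    if spec.central_fraction < 1.0:
        half = spec.central_fraction * g.geometry.width_um / 2.0
        ok &= np.abs(g.d_map_um) <= half
    # avoid seeding particles that exit immediately
    smax = np.nanmax(np.where(g.mask, g.s_map_um, np.nan))
    ok &= g.s_map_um < smax - 5.0 * margin
    jj, ii = np.nonzero(ok)
    if jj.size == 0:
        raise ValueError("no admissible seeding cells (margin too large?)")
    pick = rng.integers(0, jj.size, size=spec.n_particles)
    px = g.pixel_size_um
    x = g.origin_um[0] + (ii[pick] + rng.random(spec.n_particles)) * px
    y = g.origin_um[1] + (jj[pick] + rng.random(spec.n_particles)) * px
    return np.column_stack([x, y])


def _in_fluid(flow: FlowField, pts: np.ndarray) -> np.ndarray:
    g = flow.grid
    px = g.pixel_size_um
    i = np.floor((pts[:, 0] - g.origin_um[0]) / px).astype(int)
    j = np.floor((pts[:, 1] - g.origin_um[1]) / px).astype(int)
    ny, nx = g.mask.shape
    inside = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
    out = np.zeros(len(pts), dtype=bool)
    out[inside] = g.mask[j[inside], i[inside]]
    return out


def advect_particles(flow: FlowField, spec: SceneSpec) -> list[Trajectory]:
    """Advect beads through ``flow`` for ``n_frames`` steps of ``dt_ms``.

    Each step moves a particle along the local depth-averaged velocity
    (midpoint rule with substeps), then rotates the net step by the
    collision deflection.  Steps that would leave the lumen are reflected
    (specularly, via retrying the unrotated step) or absorbed depending on
    the scatter model.  Particles reaching the outlet end of the path are
    terminated.  Fully deterministic given ``spec.seed``.
    """
    g = flow.grid
    rng = np.random.default_rng(spec.seed)
    pos = _seed_positions(flow, spec, rng)
    bad = ~_in_fluid(flow, pos)
    if bad.any():
        raise ValueError("particle seeded in a solid cell")
    n = spec.n_particles
    alive = np.ones(n, dtype=bool)
    dt = spec.dt_ms * 1e-3
    nsub = 4
    smax = np.nanmax(np.where(g.mask, g.s_map_um, np.nan))

    traj_x = [[pos[k, 0]] for k in range(n)]
    traj_y = [[pos[k, 1]] for k in range(n)]
    t0_frame = np.zeros(n, dtype=int)

    for _ in range(spec.n_frames - 1):
        if not alive.any():
            break
        cur = pos[alive]
        # midpoint advection with substeps; velocities m/s -> um
        new = cur.copy()
        for _s in range(nsub):
            v1 = flow.velocity_at(new)
            mid = new + 0.5 * v1 * (dt / nsub) * 1e6
            v2 = flow.velocity_at(mid)
            new = new + v2 * (dt / nsub) * 1e6
        step = new - cur

        # collision deflection: rotate the net step
        k = rng.poisson(spec.scatter.rate * dt, size=len(cur))
        theta = np.where(
            k > 0,
            rng.normal(0.0, 1.0, size=len(cur))
            * np.deg2rad(spec.scatter.sigma_phi_deg) * np.sqrt(np.maximum(k, 1)),
            0.0,
        )
        ct, st = np.cos(theta), np.sin(theta)
        rot = np.column_stack([ct * step[:, 0] - st * step[:, 1],
                               st * step[:, 0] + ct * step[:, 1]])
        cand = cur + rot

        # wall handling
        okc = _in_fluid(flow, cand)
        if not okc.all():
            if spec.scatter.wall_interaction == "absorb":
                pass  # terminated below
            else:
                # fall back to the unrotated step; if that also exits, stay
                cand[~okc] = np.where(
                    _in_fluid(flow, new[~okc])[:, None], new[~okc], cur[~okc])
                okc = _in_fluid(flow, cand)

        idx_alive = np.nonzero(alive)[0]
        for m, ka in enumerate(idx_alive):
            if not okc[m]:
                alive[ka] = False
                continue
            traj_x[ka].append(cand[m, 0])
            traj_y[ka].append(cand[m, 1])
        pos[idx_alive] = cand

        # terminate particles at the outlet end of the path
        s_here = _chart_lookup(g, pos[alive], "s")
        done = s_here > smax - 2.0 * g.pixel_size_um
        if done.any():
            alive[np.nonzero(alive)[0][done]] = False

    out = []
    for k in range(n):
        xs = np.asarray(traj_x[k])
        ys = np.asarray(traj_y[k])
        t = (t0_frame[k] + np.arange(len(xs))) * spec.dt_ms
        out.append(Trajectory(particle_id=k, t_ms=t, x_um=xs, y_um=ys))
    return out


def _chart_lookup(grid, pts: np.ndarray, which: str) -> np.ndarray:
    px = grid.pixel_size_um
    i = np.clip(np.floor((pts[:, 0] - grid.origin_um[0]) / px).astype(int),
                0, grid.mask.shape[1] - 1)
    j = np.clip(np.floor((pts[:, 1] - grid.origin_um[1]) / px).astype(int),
                0, grid.mask.shape[0] - 1)
    m = grid.s_map_um if which == "s" else grid.d_map_um
    return m[j, i]


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

def _speckle_texture(shape: tuple[int, int], corr_px: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Band-limited unit-variance speckle (filtered white noise)."""
    white = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(white, corr_px, mode="wrap")
    tex -= tex.mean()
    sd = tex.std()
    return tex / (sd if sd > 0 else 1.0)


def render_frames(trajectories: list[Trajectory], flow: FlowField,
                  spec: SceneSpec,
                  crop_um: tuple[float, float, float, float] | None = None
                  ) -> np.ndarray:
    """Render a 16-bit frame stack from trajectories and the flow field.

    ``crop_um = (x0, y0, x1, y1)`` restricts the image to a region of the
    planform (defaults to the full grid).  Beads are Gaussian spots at the
    trajectory positions; if ``speckle_contrast > 0`` an RBC-like speckle
    texture is advected with the flow (semi-Lagrangian backtrace along the
    frozen field) to provide label-free PIV contrast.  Byte-identical
    across reruns with the same inputs.
    """
    g = flow.grid
    opt = spec.optics
    if crop_um is None:
        x0, y0 = g.origin_um
        x1 = x0 + g.mask.shape[1] * g.pixel_size_um
        y1 = y0 + g.mask.shape[0] * g.pixel_size_um
    else:
        x0, y0, x1, y1 = crop_um
    psz = opt.pixel_size_um
    nx = int(round((x1 - x0) / psz))
    ny = int(round((y1 - y0) / psz))
    if nx < 4 or ny < 4:
        raise ValueError("crop region too small to render")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    xs = x0 + (np.arange(nx) + 0.5) * psz
    ys = y0 + (np.arange(ny) + 0.5) * psz
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    fluid = _in_fluid(flow, pts).reshape(ny, nx)

    frames = np.zeros((spec.n_frames, ny, nx), dtype=np.float64)
    frames += opt.background

    if opt.speckle_contrast > 0:
        tex0 = _speckle_texture((ny, nx), opt.speckle_corr_um / psz, rng)
        dt = spec.dt_ms * 1e-3
        coords = pts.copy()
        for f in range(spec.n_frames):
            if f > 0:
                # backtrace one frame interval (2 midpoint substeps)
                for _ in range(2):
                    v1 = flow.velocity_at(coords)
                    mid = coords - 0.5 * v1 * (dt / 2) * 1e6
                    v2 = flow.velocity_at(mid)
                    coords = coords - v2 * (dt / 2) * 1e6
            ii = (coords[:, 0] - x0) / psz - 0.5
            jj = (coords[:, 1] - y0) / psz - 0.5
            samp = ndimage.map_coordinates(
                tex0, np.vstack([jj, ii]), order=1, mode="grid-wrap")
            frames[f] += opt.speckle_contrast * samp.reshape(ny, nx) * fluid

    # beads
    rad = max(int(np.ceil(4 * opt.spot_sigma_px)), 2)
    for tr in trajectories:
        f0 = int(round(tr.t_ms[0] / spec.dt_ms))
        for k in range(len(tr.t_ms)):
            f = f0 + k
            if f >= spec.n_frames:
                break
            cx = (tr.x_um[k] - x0) / psz - 0.5
            cy = (tr.y_um[k] - y0) / psz - 0.5
            i0, j0 = int(round(cx)), int(round(cy))
            if not (-rad <= i0 < nx + rad and -rad <= j0 < ny + rad):
                continue
            ia, ib = max(i0 - rad, 0), min(i0 + rad + 1, nx)
            ja, jb = max(j0 - rad, 0), min(j0 + rad + 1, ny)
            if ia >= ib or ja >= jb:
                continue
            gx = np.arange(ia, ib) - cx
            gy = np.arange(ja, jb) - cy
            spot = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2)
                          / (2 * opt.spot_sigma_px ** 2))
            frames[f, ja:jb, ia:ib] += opt.bead_intensity * spot

    if opt.noise_sd > 0:
        frames += rng.normal(0.0, opt.noise_sd, size=frames.shape)
    return np.clip(frames, 0, 65535).astype(np.uint16)


# --------------------------------------------------------------------------- #
# scene presets
# --------------------------------------------------------------------------- #

#: desk-scale study geometries: short serpentines/limbs that preserve the
#: 200 x 50 um cross-section and defect scales of the full chip, plus the
#: rendered field of view (x0, y0, x1, y1 in um)
_PRESET_BUILDERS = {}


def _baseline_geometry() -> tuple[ChannelGeometry, float, tuple]:
    geom = build_serpentine(segment_length_mm=0.8, n_segments=2,
                            bend_radius_mm=0.3)
    return geom, 5.0, (100.0, -110.0, 700.0, 110.0)


def _thrombus_geometry() -> tuple[ChannelGeometry, float, tuple]:
    geom = build_serpentine(segment_length_mm=2.0, n_segments=1)
    geom = add_defect(geom, Defect(kind="clot", path_position_mm=1.4,
                                   spanwise_extent=0.5, axial_extent_um=200.0,
                                   wall_side="left"))
    return geom, 5.0, (600.0, -110.0, 1800.0, 110.0)


def _hemorrhage_geometry() -> tuple[ChannelGeometry, float, tuple]:
    geom = build_serpentine(segment_length_mm=0.6, n_segments=2,
                            bend_radius_mm=0.25)
    geom = add_defect(geom, Defect(kind="wall_gap", path_position_mm=0.3,
                                   gap_length_um=20.0, wall_side="left"))
    return geom, 4.0, (100.0, -110.0, 500.0, 610.0)


_PRESET_BUILDERS.update({
    "baseline": _baseline_geometry,
    "thrombus": _thrombus_geometry,
    "hemorrhage": _hemorrhage_geometry,
})


def make_scene(preset: str = "baseline", *, render: bool = True,
               flow: FlowField | None = None, **overrides) -> Scene:
    """Build a preset scene end to end: geometry -> flow -> trajectories
    -> (optionally) rendered frames.

    ``overrides`` replace :class:`SceneSpec` fields.  A pre-solved ``flow``
    for the same preset may be supplied to skip the solver stage.
    """
    if preset not in _PRESET_BUILDERS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(_PRESET_BUILDERS)}")
    spec = SceneSpec(preset=preset, **overrides)
    geom, pixel, crop = _PRESET_BUILDERS[preset]()
    if flow is None:
        grid = rasterize(geom, pixel)
        flow = solve_planform(grid, get_fluid(spec.fluid_name), spec.Q_ul_min)
    else:
        geom = flow.grid.geometry
    trajs = advect_particles(flow, spec)
    frames = render_frames(trajs, flow, spec, crop_um=crop) if render else None
    return Scene(spec=spec, geometry=geom, flow=flow,
                 trajectories=trajs, frames=frames, crop_um=crop)
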