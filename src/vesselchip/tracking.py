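"""Spot detection, trajectory linking, and trajectory statistics.

The statistics mirror the bead-tracking analysis of the chip experiments:

* mean speed  <v> = sum_i v_i / (n - 1)  over the n - 1 instantaneous
  speeds v_i = delta_i / dt of an n-point track, where
  delta_i = sqrt(dx_i^2 + dy_i^2) is the step length;
* per-step scattering angle  phi_i = asin(|lateral_i| / delta_i), the
  angular deviation of each step from the local flow direction, with the
  lateral displacement measured perpendicular to the channel centerline;
* wall-interaction length  L = half_width / tan(mean phi), the expected
  streamwise distance for a bead starting on the centerline to reach a
  wall by angular scattering.

Positions are micrometres, times milliseconds, speeds mm/s (um/ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

from .flow import VelocityProfile
from .geometry import PlanformGrid

__all__ = [
    "Trajectory",
    "ScatterSummary",
    "detect_spots",
    "link",
    "mean_speed",
    "scattering_angles",
    "interaction_length",
    "velocity_profile",
    "tracks_to_csv",
    "tracks_from_csv",
]


@dataclass
class Trajectory:
    """Time-stamped particle positions with derived step metrics."""

    particle_id: int
    t_ms: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not len(self.t_ms) == len(self.x_um) == len(self.y_um):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_ms) > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def steps_um(self) -> np.ndarray:
        """Per-step displacement vectors, shape (n-1, 2)."""
        return np.column_stack([np.diff(self.x_um), np.diff(self.y_um)])

    @property
    def step_lengths_um(self) -> np.ndarray:
        """delta_i = sqrt(dx_i^2 + dy_i^2)."""
        s = self.steps_um
        return np.hypot(s[:, 0], s[:, 1])

    @property
    def speeds_mm_s(self) -> np.ndarray:
        """Instantaneous speeds v_i = delta_i / dt (um/ms = mm/s)."""
        return self.step_lengths_um / np.diff(self.t_ms)


@dataclass
class ScatterSummary:
    """Mean +/- sd of per-step scattering angles at one flow condition."""

    mean_deg: float
    sd_deg: float
    n_steps: int
    n_excluded: int = 0
    Q_ul_min: float | None = None
    interaction_length_mm: float | None = None


# --------------------------------------------------------------------------- #
# detection and linking
# --------------------------------------------------------------------------- #

def detect_spots(frame: np.ndarray, threshold: float,
                 min_separation_px: int = 5) -> np.ndarray:
    """Subpixel centroids of bright spots in a grayscale frame.

    Local maxima above ``threshold`` separated by at least
    ``min_separation_px`` are refined by an intensity-weighted centroid on
    the background-subtracted neighbourhood.  Peaks closer than the
    separation are merged into the brighter one.  Returns an (N, 2) array
    of (x, y) pixel positions sorted by (y, x).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single grayscale frame")
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        if (np.asarray(frame) == np.iinfo(np.asarray(frame).dtype).max).any():
            warnings.warn("frame contains saturated pixels; centroids may be "
                          "biased", stacklevel=2)
    peaks = peak_local_max(img, min_distance=min_separation_px,
                           threshold_abs=threshold, exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 2))
    rad = max(min_separation_px // 2, 2)
    bg = np.median(img)
    out = []
    for j0, i0 in peaks:
        ja, jb = max(j0 - rad, 0), min(j0 + rad + 1, img.shape[0])
        ia, ib = max(i0 - rad, 0), min(i0 + rad + 1, img.shape[1])
        patch = np.clip(img[ja:jb, ia:ib] - bg, 0, None)
        tot = patch.sum()
        if tot <= 0:
            out.append((float(i0), float(j0)))
            continue
        jj, ii = np.mgrid[ja:jb, ia:ib]
        out.append((float((patch * ii).sum() / tot),
                    float((patch * jj).sum() / tot)))
    out = np.array(out)
    order = np.lexsort((out[:, 0], out[:, 1]))
    return out[order]


def link(detections: list[np.ndarray], max_disp_px: float,
         dt_ms: float = 2.0, pixel_size_um: float = 1.0,
         origin_um: tuple[float, float] = (0.0, 0.0),
         min_length: int = 3) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    ``detections[f]`` is the (N_f, 2) array of (x, y) pixel positions of
    frame ``f``.  A detection links to the next frame if the two are
    mutual nearest neighbours within ``max_disp_px``; ambiguities are
    resolved by distance, then by index order (deterministic).  Tracks
    shorter than ``min_length`` points are discarded.  Output positions
    are converted to micrometres via ``pixel_size_um`` and ``origin_um``.
    """
    if len(detections) < 2:
        raise ValueError("need detections for at least two frames")
    next_id = 0
    cur_tracks: dict[int, int] = {}   # detection index in frame f -> track key
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    for k, (x, y) in enumerate(np.atleast_2d(detections[0])):
        tracks[next_id] = [(0, float(x), float(y))]
        cur_tracks[k] = next_id
        next_id += 1

    for f in range(len(detections) - 1):
        a = np.atleast_2d(detections[f]) if len(detections[f]) else np.empty((0, 2))
        b = np.atleast_2d(detections[f + 1]) if len(detections[f + 1]) else np.empty((0, 2))
        new_cur: dict[int, int] = {}
        if len(a) and len(b):
            d = cdist(a, b)
            fwd = np.argmin(d, axis=1)
            bwd = np.argmin(d, axis=0)
            pairs = [(d[i, fwd[i]], i, fwd[i]) for i in range(len(a))
                     if bwd[fwd[i]] == i and d[i, fwd[i]] <= max_disp_px]
            pairs.sort()
            used_b: set[int] = set()
            for _, i, jb in pairs:
                if jb in used_b or i not in cur_tracks:
                    continue
                used_b.add(jb)
                key = cur_tracks[i]
                tracks[key].append((f + 1, float(b[jb, 0]), float(b[jb, 1])))
                new_cur[jb] = key
        # unmatched detections in frame f+1 start new tracks
        for jb, (x, y) in enumerate(np.atleast_2d(b) if len(b) else []):
            if jb not in new_cur:
                tracks[next_id] = [(f + 1, float(x), float(y))]
                new_cur[jb] = next_id
                next_id += 1
        cur_tracks = new_cur

    out = []
    for key in sorted(tracks):
        pts = tracks[key]
        if len(pts) < min_length:
            continue
        fr = np.array([p[0] for p in pts], dtype=float)
        xs = np.array([p[1] for p in pts]) * pixel_size_um + origin_um[0]
        ys = np.array([p[2] for p in pts]) * pixel_size_um + origin_um[1]
        out.append(Trajectory(particle_id=len(out), t_ms=fr * dt_ms,
                              x_um=xs, y_um=ys))
    return out


# --------------------------------------------------------------------------- #
# trajectory statistics
# --------------------------------------------------------------------------- #

def mean_speed(traj: Trajectory) -> float:
    """Track-average speed <v> = (sum of instantaneous speeds) / (n - 1),
    in mm/s.  Invariant to rigid translation and rotation of the track."""
    if len(traj) < 2:
        raise ValueError("mean speed needs at least two track points")
    return float(np.mean(traj.speeds_mm_s))


def _local_frames(traj: Trajectory, flow_axis) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (axial, lateral) displacement components."""
    steps = traj.steps_um
    if isinstance(flow_axis, PlanformGrid):
        # project each step onto the local centerline tangent at its midpoint
        mids = np.column_stack([0.5 * (traj.x_um[:-1] + traj.x_um[1:]),
                                0.5 * (traj.y_um[:-1] + traj.y_um[1:])])
        chart = flow_axis.chart_at(mids)
        t = chart[:, 1:]
        t = np.where(np.isfinite(t), t, [1.0, 0.0])
        n = np.column_stack([-t[:, 1], t[:, 0]])
        return np.einsum("ij,ij->i", steps, t), np.einsum("ij,ij->i", steps, n)
    axis = np.array([1.0, 0.0]) if flow_axis in ("x", None) else \
        np.asarray(flow_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    normal = np.array([-axis[1], axis[0]])
    return steps @ axis, steps @ normal


def scattering_angles(trajectories, flow_axis="x",
                      Q_ul_min: float | None = None
                      ) -> tuple[np.ndarray, ScatterSummary]:
    """Per-step scattering angles phi_i = asin(|lateral| / delta) and their
    summary over all steps of all tracks.

    ``flow_axis`` defines "lateral": a direction vector / ``"x"`` for a
    straight field of view, or a :class:`PlanformGrid` to use the local
    centerline tangent (so serpentine bends do not inflate the angles).
    Zero-length steps are excluded and counted in ``n_excluded``.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    phis = []
    excluded = 0
    for tr in trajectories:
        if len(tr) < 2:
            continue
        delta = tr.step_lengths_um
        _, lat = _local_frames(tr, flow_axis)
        ok = delta > 0
        excluded += int((~ok).sum())
        ratio = np.clip(np.abs(lat[ok]) / delta[ok], 0.0, 1.0)
        phis.append(np.degrees(np.arcsin(ratio)))
    phi = np.concatenate(phis) if phis else np.empty(0)
    if phi.size == 0:
        raise ValueError("no usable steps for scattering analysis")
    return phi, ScatterSummary(
        mean_deg=float(phi.mean()), sd_deg=float(phi.std(ddof=1)) if phi.size > 1 else 0.0,
        n_steps=int(phi.size), n_excluded=excluded, Q_ul_min=Q_ul_min)


def interaction_length(summary: "ScatterSummary | float",
                       half_width_um: float = 100.0) -> float:
    """Wall-interaction length L = half_width / tan(mean phi), in mm.

    The streamwise distance over which a bead on the centerline, deviating
    from the flow direction by the mean scattering angle, reaches a wall.
    A zero angle returns ``inf`` (no scattering, no wall interaction).
    """
    phi = summary.mean_deg if isinstance(summary, ScatterSummary) else float(summary)
    if phi < 0 or phi > 90:
        raise ValueError("mean angle must lie in [0, 90] degrees")
    if phi == 0:
        warnings.warn("zero scattering angle: interaction length is infinite",
                      stacklevel=2)
        return float("inf")
    L = half_width_um * 1e-3 / np.tan(np.radians(phi))
    if isinstance(summary, ScatterSummary):
        summary.interaction_length_mm = L
    return L


def velocity_profile(trajectories, grid: PlanformGrid,
                     n_bins: int = 20) -> VelocityProfile:
    """Spanwise binned mean speed of tracked particles across the width.

    Steps are assigned to bins by the lateral (centerline-normal) position
    of their midpoint; empty bins are NaN, not zero.
    """
    w = grid.geometry.width_um
    edges = np.linspace(-w / 2.0, w / 2.0, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    px = grid.pixel_size_um
    for tr in trajectories:
        if len(tr) < 2:
            continue
        mids = np.column_stack([0.5 * (tr.x_um[:-1] + tr.x_um[1:]),
                                0.5 * (tr.y_um[:-1] + tr.y_um[1:])])
        d = grid.chart_at(mids)[:, 0]
        v = tr.speeds_mm_s
        ok = np.isfinite(d) & (np.abs(d) <= w / 2.0)
        which = np.digitize(d[ok], edges) - 1
        for b, vv in zip(which, v[ok]):
            if 0 <= b < n_bins:
                sums[b] += vv
                counts[b] += 1
    speed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return VelocityProfile(coord_um=0.5 * (edges[:-1] + edges[1:]) + w / 2.0,
                           speed_mm_s=speed, counts=counts, span_um=(0.0, w))


# --------------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------------- #

def tracks_to_csv(trajectories: list[Trajectory], path) -> None:
    """Write tracks as CSV with columns particle_id, frame, t_ms, x_um, y_um."""
    rows = []
    for tr in trajectories:
        dt = np.median(np.diff(tr.t_ms)) if len(tr) > 1 else 1.0
        for k in range(len(tr)):
            rows.append((tr.particle_id, int(round(tr.t_ms[k] / dt)),
                         tr.t_ms[k], tr.x_um[k], tr.y_um[k]))
    pd.DataFrame(rows, columns=["particle_id", "frame", "t_ms", "x_um", "y_um"]
                 ).to_csv(path, index=False)


def tracks_from_csv(path) -> list[Trajectory]:
    """Read tracks written by :func:`tracks_to_csv`."""
    df = pd.read_csv(path)
    out = []
    for pid, sub in df.groupby("particle_id"):
        sub = sub.sort_values("t_ms")
        out.append(Trajectory(particle_id=int(pid),
                              t_ms=sub["t_ms"].to_numpy(),
                              x_um=sub["x_um"].to_numpy(),
                              y_um=sub["y_um"].to_numpy()))
    return out
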