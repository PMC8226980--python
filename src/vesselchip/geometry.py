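"""Serpentine microchannel geometry: planform construction, defects, rasterization.

The channel emulates the tortuous morphology of tumor-derived microvasculature:
parallel straight limbs of rectangular cross-section (default 200 um wide,
50 um deep) joined by 180-degree circular bends, for a total centerline path of
roughly 200 mm.  Two kinds of lumen defects can be inserted:

* ``clot`` -- a sharp-edged, wall-attached occlusion blocking a fraction of the
  channel width, the reduced lumen left by a mural red-cell aggregate;
* ``wall_gap`` -- a short aperture (default scale ~20 um) through the wall
  separating two adjacent limbs, the "leaky vessel" defect that drives
  bleeding into the neighbouring limb.

All planform coordinates are micrometres, origin at the inlet mouth.  Grids
are cell-centered with 0-based ``[row=y, col=x]`` indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Defect",
    "ChannelGeometry",
    "PlanformGrid",
    "build_serpentine",
    "add_defect",
    "rasterize",
]


# --------------------------------------------------------------------------- #
# centerline primitives
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class _Straight:
    p0: tuple[float, float]   # um
    p1: tuple[float, float]   # um

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def sample(self, ds: float) -> np.ndarray:
        n = max(int(np.ceil(self.length / ds)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)
        return np.column_stack([
            self.p0[0] + t * (self.p1[0] - self.p0[0]),
            self.p0[1] + t * (self.p1[1] - self.p0[1]),
        ])


@dataclass(frozen=True)
class _Arc:
    center: tuple[float, float]  # um
    radius: float                # um
    a0: float                    # start angle, rad
    a1: float                    # end angle, rad (signed sweep a1 - a0)

    @property
    def length(self) -> float:
        return abs(self.a1 - self.a0) * self.radius

    def sample(self, ds: float) -> np.ndarray:
        n = max(int(np.ceil(self.length / ds)) + 1, 3)
        a = np.linspace(self.a0, self.a1, n)
        return np.column_stack([
            self.center[0] + self.radius * np.cos(a),
            self.center[1] + self.radius * np.sin(a),
        ])


# --------------------------------------------------------------------------- #
# public types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Defect:
    """A lumen defect anchored at a position along the centerline.

    Parameters
    ----------
    kind:
        ``"clot"`` (wall-attached occlusion) or ``"wall_gap"`` (aperture
        through the wall between adjacent limbs).
    path_position_mm:
        Distance along the centerline from the inlet, in mm.
    spanwise_extent:
        Clot only: fraction of the channel width blocked, in (0, 1).
    gap_length_um:
        Wall gap only: length of the aperture along the wall, um.
    wall_side:
        Which wall the defect sits on, looking downstream: ``"left"`` (+90
        degrees from the tangent) or ``"right"``.
    axial_extent_um:
        Clot only: streamwise length of the occlusion, um.
    """

    kind: Literal["clot", "wall_gap"]
    path_position_mm: float
    spanwise_extent: float = 0.5
    gap_length_um: float = 20.0
    wall_side: Literal["left", "right"] = "left"
    axial_extent_um: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("clot", "wall_gap"):
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.kind == "clot" and not 0.0 < self.spanwise_extent < 1.0:
            raise ValueError("clot spanwise_extent must lie in (0, 1)")
        if self.kind == "wall_gap" and self.gap_length_um <= 0:
            raise ValueError("gap_length_um must be positive")
        if self.axial_extent_um <= 0:
            raise ValueError("axial_extent_um must be positive")
        if self.wall_side not in ("left", "right"):
            raise ValueError("wall_side must be 'left' or 'right'")

    @property
    def axial_span_mm(self) -> tuple[float, float]:
        half = 0.5 * (self.axial_extent_um if self.kind == "clot"
                      else self.gap_length_um) * 1e-3
        return (self.path_position_mm - half, self.path_position_mm + half)


@dataclass(frozen=True)
class ChannelGeometry:
    """Serpentine channel planform plus cross-section dimensions."""

    width_um: float = 200.0
    height_um: float = 50.0
    segment_length_mm: float = 9.0
    n_segments: int = 20
    bend_radius_mm: float = 0.3
    defects: tuple[Defect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("channel width and height must be positive")
        if self.segment_length_mm <= 0:
            raise ValueError("segment_length_mm must be positive")
        if self.n_segments < 1:
            raise ValueError("need at least one straight segment")
        if self.n_segments > 1 and 2.0 * self.bend_radius_mm * 1e3 <= self.width_um:
            raise ValueError("bend radius too small: adjacent limbs would overlap")

    # -- derived ------------------------------------------------------------
    @property
    def total_path_length_mm(self) -> float:
        n_bends = self.n_segments - 1
        return (self.n_segments * self.segment_length_mm
                + n_bends * np.pi * self.bend_radius_mm)

    @property
    def lead_um(self) -> float:
        """Length of straight inlet/outlet leads outside the nominal path.

        For three or more limbs the 180-degree bends overhang the limb ends
        on both sides, so the mouths are extended past the bends to reach
        the domain edge.  Leads carry negative path positions (inlet) or
        positions beyond ``total_path_length_mm`` (outlet) and do not count
        toward the nominal path length.
        """
        if self.n_segments < 3:
            return 0.0
        return self.bend_radius_mm * 1e3 + 2.0 * self.width_um

    def centerline(self) -> list[_Straight | _Arc]:
        """Boustrophedon centerline: limbs along +/-x, stacked in +y.

        Includes the inlet/outlet leads (see :attr:`lead_um`); path position
        0 is the start of the first nominal limb.
        """
        L = self.segment_length_mm * 1e3          # um
        r = self.bend_radius_mm * 1e3
        lead = self.lead_um
        parts: list[_Straight | _Arc] = []
        if lead > 0:
            parts.append(_Straight((-lead, 0.0), (0.0, 0.0)))
        y = 0.0
        for k in range(self.n_segments):
            if k % 2 == 0:   # heading +x
                parts.append(_Straight((0.0, y), (L, y)))
                if k + 1 < self.n_segments:
                    # left turn around (L, y + r): angle -90 deg -> +90 deg
                    parts.append(_Arc((L, y + r), r, -np.pi / 2, np.pi / 2))
            else:            # heading -x
                parts.append(_Straight((L, y), (0.0, y)))
                if k + 1 < self.n_segments:
                    parts.append(_Arc((0.0, y + r), r, 3 * np.pi / 2, np.pi / 2))
            y += 2.0 * r
        if lead > 0:
            y_end = 2.0 * r * (self.n_segments - 1)
            if self.n_segments % 2 == 0:   # last limb heads -x, mouth at west
                parts.append(_Straight((0.0, y_end), (-lead, y_end)))
            else:                          # mouth at east
                parts.append(_Straight((L, y_end), (L + lead, y_end)))
        return parts

    def sample_centerline(self, ds_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Densely sampled centerline.

        Returns ``(points (N,2) um, s (N,) um, tangent (N,2) unit)``.
        """
        pts, ss = [], []
        s0 = -self.lead_um
        for part in self.centerline():
            p = part.sample(ds_um)
            seg = np.hypot(*np.diff(p, axis=0).T)
            s = s0 + np.concatenate([[0.0], np.cumsum(seg)])
            pts.append(p)
            ss.append(s)
            s0 = s[-1]
        points = np.vstack(pts)
        s_arr = np.concatenate(ss)
        tang = np.gradient(points, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = tang / np.where(norm == 0, 1.0, norm)
        return points, s_arr, tang

    def point_at(self, s_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Centerline point and unit tangent at path position ``s_mm``."""
        target = s_mm * 1e3
        s0 = -self.lead_um
        parts = self.centerline()
        for k, part in enumerate(parts):
            if target <= s0 + part.length or k == len(parts) - 1:
                local = np.clip(target - s0, 0.0, part.length)
                if isinstance(part, _Straight):
                    d = np.array(part.p1) - np.array(part.p0)
                    t = d / np.linalg.norm(d)
                    return np.array(part.p0) + t * local, t
                sweep = np.sign(part.a1 - part.a0)
                a = part.a0 + sweep * local / part.radius
                p = np.array([part.center[0] + part.radius * np.cos(a),
                              part.center[1] + part.radius * np.sin(a)])
                t = sweep * np.array([-np.sin(a), np.cos(a)])
                return p, t
            s0 += part.length
        raise ValueError("path position outside channel")  # pragma: no cover


@dataclass
class PlanformGrid:
    """Rasterized planform: occupancy, wall distance and centerline charts.

    Attributes
    ----------
    pixel_size_um: cell edge, um.
    mask: boolean fluid occupancy, shape (ny, nx).
    wall_distance_um: Euclidean distance to the nearest solid cell, um.
    tx_map, ty_map: unit tangent of the nearest centerline point (local
        flow direction chart used by the trajectory statistics).
    s_map_um, d_map_um: path position and signed lateral offset of each cell
        center relative to the channel centerline (d > 0 on the left wall
        side looking downstream).  Defined on all cells, NaN far from path.
    inlet_mask, outlet_mask: boolean flags of mouth cells on the domain edge.
    inlet_side, outlet_side: which domain edge ('W', 'E', 'N', 'S').
    origin_um: physical coordinate of the (0, 0) cell corner.
    """

    geometry: ChannelGeometry
    pixel_size_um: float
    mask: np.ndarray
    wall_distance_um: np.ndarray
    s_map_um: np.ndarray
    d_map_um: np.ndarray
    tx_map: np.ndarray
    ty_map: np.ndarray
    inlet_mask: np.ndarray
    outlet_mask: np.ndarray
    inlet_side: str
    outlet_side: str
    origin_um: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical x and y coordinates (um) of cell centers, 1-D each."""
        ny, nx = self.mask.shape
        x = self.origin_um[0] + (np.arange(nx) + 0.5) * self.pixel_size_um
        y = self.origin_um[1] + (np.arange(ny) + 0.5) * self.pixel_size_um
        return x, y

    def chart_at(self, points_um: np.ndarray) -> np.ndarray:
        """Bilinear (d, tx, ty) chart at planform points (N, 2) um.

        Returns an (N, 3) array of signed lateral offset and unit tangent
        components, NaN outside the charted region.
        """
        from scipy.interpolate import RegularGridInterpolator

        x, y = self.cell_centers()
        vals = np.dstack([self.d_map_um, self.tx_map, self.ty_map])
        interp = RegularGridInterpolator((y, x), vals, bounds_error=False,
                                         fill_value=np.nan)
        pts = np.atleast_2d(points_um)
        out = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
        norm = np.hypot(out[:, 1], out[:, 2])
        out[:, 1:] /= np.where(norm > 0, norm, 1.0)[:, None]
        return out

    def to_tiff(self, path) -> None:
        """Export occupancy as uint8 TIFF (0 = solid, 255 = fluid)."""
        import tifffile

        tifffile.imwrite(path, np.where(self.mask, 255, 0).astype(np.uint8))


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def build_serpentine(
    width_um: float = 200.0,
    height_um: float = 50.0,
    segment_length_mm: float = 9.0,
    n_segments: int = 20,
    bend_radius_mm: float = 0.3,
) -> ChannelGeometry:
    """Construct a defect-free serpentine channel.

    Defaults give a 200 x 50 um cross-section and a total centerline path of
    20 * 9 mm + 19 * pi * 0.3 mm = 197.9 mm, i.e. the ~200 mm channel of the
    physical chip.
    """
    return ChannelGeometry(
        width_um=width_um,
        height_um=height_um,
        segment_length_mm=segment_length_mm,
        n_segments=n_segments,
        bend_radius_mm=bend_radius_mm,
    )


def add_defect(geometry: ChannelGeometry, defect: Defect) -> ChannelGeometry:
    """Return a new geometry with ``defect`` recorded.

    Rejects defects outside the channel and axially overlapping defects.
    """
    if not 0.0 < defect.path_position_mm < geometry.total_path_length_mm:
        raise ValueError(
            f"defect at {defect.path_position_mm} mm lies outside the "
            f"{geometry.total_path_length_mm:.1f} mm channel"
        )
    lo, hi = defect.axial_span_mm
    for other in geometry.defects:
        olo, ohi = other.axial_span_mm
        if lo < ohi and olo < hi:
            raise ValueError("defects overlap along the channel path")
    return replace(geometry, defects=geometry.defects + (defect,))


def _bounding_box(points: np.ndarray, half_w: float, pad: float,
                  mouth_sides: set[str]) -> tuple[float, float, float, float]:
    x0 = points[:, 0].min() - half_w - (0.0 if "W" in mouth_sides else pad)
    x1 = points[:, 0].max() + half_w + (0.0 if "E" in mouth_sides else pad)
    y0 = points[:, 1].min() - half_w - (0.0 if "S" in mouth_sides else pad)
    y1 = points[:, 1].max() + half_w + (0.0 if "N" in mouth_sides else pad)
    if "W" in mouth_sides:
        x0 = points[:, 0].min()
    if "E" in mouth_sides:
        x1 = points[:, 0].max()
    if "S" in mouth_sides:
        y0 = points[:, 1].min()
    if "N" in mouth_sides:
        y1 = points[:, 1].max()
    return x0, x1, y0, y1


def _mouth_side(tangent: np.ndarray, outward: bool) -> str:
    """Domain edge faced by a path endpoint; tangent must be axis-aligned."""
    t = tangent if outward else -tangent
    if abs(t[0]) >= abs(t[1]):
        return "E" if t[0] > 0 else "W"
    return "N" if t[1] > 0 else "S"


def rasterize(geometry: ChannelGeometry, pixel_size_um: float = 5.0) -> PlanformGrid:
    """Rasterize the planform onto a uniform cell-centered grid.

    The domain is the tight bounding box of the wetted planform, padded by a
    ring of solid cells except where the inlet/outlet mouths meet the box
    edge.  Clots carve solid material into the lumen; wall gaps carve fluid
    through the wall between adjacent limbs.
    """
    w = geometry.width_um
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if pixel_size_um > w / 10.0:
        raise ValueError("pixel_size_um too coarse: need >= 10 cells across width")
    for d in geometry.defects:
        open_w = (w * (1.0 - d.spanwise_extent) if d.kind == "clot"
                  else d.gap_length_um)
        if pixel_size_um > open_w / 4.0:
            raise ValueError("pixel_size_um too coarse to resolve defect")

    half_w = w / 2.0
    ds = pixel_size_um / 4.0
    points, s_arr, tangents = geometry.sample_centerline(ds)

    in_side = _mouth_side(tangents[0], outward=False)
    out_side = _mouth_side(tangents[-1], outward=True)
    pad = 2.0 * pixel_size_um
    x0, x1, y0, y1 = _bounding_box(points, half_w, pad, {in_side, out_side})

    nx = int(np.ceil((x1 - x0) / pixel_size_um))
    ny = int(np.ceil((y1 - y0) / pixel_size_um))
    xs = x0 + (np.arange(nx) + 0.5) * pixel_size_um
    ys = y0 + (np.arange(ny) + 0.5) * pixel_size_um
    X, Y = np.meshgrid(xs, ys)

    tree = cKDTree(points)
    dist, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]), workers=-1)
    dist = dist.reshape(ny, nx)
    idx = idx.reshape(ny, nx)
    mask = dist <= half_w

    # centerline charts: path position s and signed lateral offset d
    s_map = s_arr[idx]
    near = points[idx]
    tang = tangents[idx]
    rel = np.dstack([X - near[..., 0], Y - near[..., 1]])
    # left of tangent (cross product z-component) is positive d
    d_map = tang[..., 0] * rel[..., 1] - tang[..., 1] * rel[..., 0]
    far = dist > 4.0 * half_w
    s_map = np.where(far, np.nan, s_map)
    d_map = np.where(far, np.nan, d_map)

    # defects
    for dft in geometry.defects:
        lo_um, hi_um = (v * 1e3 for v in dft.axial_span_mm)
        in_axial = (s_map >= lo_um) & (s_map <= hi_um)
        if dft.kind == "clot":
            # occlusion attached to one wall, blocking spanwise_extent * w
            if dft.wall_side == "left":
                blocked = d_map >= half_w - dft.spanwise_extent * w
            else:
                blocked = d_map <= -half_w + dft.spanwise_extent * w
            mask &= ~(in_axial & blocked & (dist <= half_w))
        else:  # wall_gap: world-space rectangle through the wall to the
            # adjacent limb centerline (charts are ambiguous between limbs)
            p0, t = geometry.point_at(dft.path_position_mm)
            sign = 1.0 if dft.wall_side == "left" else -1.0
            n = sign * np.array([-t[1], t[0]])
            rx, ry = X - p0[0], Y - p0[1]
            along = rx * t[0] + ry * t[1]
            across = rx * n[0] + ry * n[1]
            reach = 2.0 * geometry.bend_radius_mm * 1e3
            mask |= (np.abs(along) <= dft.gap_length_um / 2.0) & \
                    (across > 0) & (across <= reach)

    # enforce a solid ring except at mouth edges
    ring = np.zeros_like(mask)
    if in_side != "W" and out_side != "W":
        ring[:, 0] = True
    if in_side != "E" and out_side != "E":
        ring[:, -1] = True
    if in_side != "S" and out_side != "S":
        ring[0, :] = True
    if in_side != "N" and out_side != "N":
        ring[-1, :] = True
    mask &= ~ring

    # connectivity: all fluid reachable from the inlet mouth
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, nlab + 1))
        keep = int(np.argmax(sizes)) + 1
        if (mask & (lab != keep)).sum() > 0.01 * mask.sum():
            raise ValueError("fluid domain is disconnected")
        mask &= lab == keep

    wall_dist = ndimage.distance_transform_edt(mask) * pixel_size_um

    def _mouth_mask(endpoint: np.ndarray, side: str) -> np.ndarray:
        m = np.zeros_like(mask)
        if side in ("W", "E"):
            col = 0 if side == "W" else nx - 1
            rows = np.abs(ys - endpoint[1]) <= half_w
            m[rows, col] = mask[rows, col]
        else:
            row = 0 if side == "S" else ny - 1
            cols = np.abs(xs - endpoint[0]) <= half_w
            m[row, cols] = mask[row, cols]
        return m

    inlet_mask = _mouth_mask(points[0], in_side)
    outlet_mask = _mouth_mask(points[-1], out_side)
    if inlet_mask.sum() == 0 or outlet_mask.sum() == 0:
        raise ValueError("failed to locate inlet/outlet mouths on the domain edge")

    return PlanformGrid(
        geometry=geometry,
        pixel_size_um=pixel_size_um,
        mask=mask,
        wall_distance_um=wall_dist,
        s_map_um=s_map,
        d_map_um=d_map,
        tx_map=tang[..., 0],
        ty_map=tang[..., 1],
        inlet_mask=inlet_mask,
        outlet_mask=outlet_mask,
        inlet_side=in_side,
        outlet_side=out_side,
        origin_um=(x0, y0),
    )
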