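"""Aortic morphometry from 3D binary lumen masks.

Given a segmented lumen volume this module extracts a smoothed, resampled
centerline, partitions it into the four conventional aortic segments
(S1 ascending, S2 arch, S3 suprarenal descending, S4 infrarenal abdominal),
measures per-segment centerline length and maximal mean cross-sectional
diameter from radial spikes, and fits a circle to the ascending-aorta
centerline to obtain the curvature radius (a smaller radius corresponds to a
more acutely angled ascending aorta).

Coordinates are world millimeters.  A voxel at integer index ``i`` has its
center at ``origin_mm + i * spacing_mm`` (the NIfTI convention used by the
I/O layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import euler_number

from .errors import DegenerateGeometryError, TopologyError

logger = logging.getLogger(__name__)

SEGMENT_LABELS = ("S1", "S2", "S3", "S4")

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LumenMask:
    """Binary lumen volume with world geometry.

    ``voxels`` is a 3D boolean array; ``spacing_mm`` the per-axis voxel size;
    ``origin_mm`` the world coordinate of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("voxel spacing must be strictly positive")

    def world_from_index(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def index_from_world(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin_mm) / self.spacing_mm


@dataclass
class Centerline:
    """Ordered centerline from the proximal (valve) end to the distal end."""

    points_mm: np.ndarray
    arc_length_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise ValueError("centerline points must be (N, 3)")
        if self.arc_length_mm is None:
            self.arc_length_mm = _cumulative_arc_length(self.points_mm)
        else:
            self.arc_length_mm = np.asarray(self.arc_length_mm, dtype=float)
        if np.any(np.diff(self.arc_length_mm) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points_mm, self.arc_length_mm, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        scalar = np.ndim(s) == 0
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s_arr, self.arc_length_mm, self.points_mm[:, k]) for k in range(3)]
        )
        return out[0] if scalar else out

    def restrict(self, s_lo: float, s_hi: float) -> "Centerline":
        """Sub-centerline between two arc-length positions (endpoints interpolated)."""
        if not (0.0 <= s_lo < s_hi <= self.length_mm + 1e-9):
            raise ValueError("restriction bounds outside the centerline extent")
        inside = (self.arc_length_mm > s_lo) & (self.arc_length_mm < s_hi)
        pts = [self.point_at(np.array([s_lo]))[0]]
        pts.extend(self.points_mm[inside])
        pts.append(self.point_at(np.array([s_hi]))[0])
        return Centerline(np.asarray(pts))


@dataclass
class SegmentPartition:
    """Three arc-length boundaries splitting a centerline into S1..S4."""

    boundaries_mm: tuple[float, float, float]
    total_length_mm: float

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries_mm)
        if not (0.0 < b[0] < b[1] < b[2] < self.total_length_mm):
            raise ValueError(
                "segment boundaries must be strictly increasing and interior: "
                f"{b} on total length {self.total_length_mm:.2f}"
            )
        self.boundaries_mm = b

    def extent(self, segment: str) -> tuple[float, float]:
        edges = (0.0, *self.boundaries_mm, self.total_length_mm)
        i = SEGMENT_LABELS.index(segment)
        return edges[i], edges[i + 1]

    def label_of(self, s: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.boundaries_mm), np.atleast_1d(s), side="right")
        return np.asarray(SEGMENT_LABELS)[idx]


@dataclass
class CrossSectionProfile:
    """Radial-spike diameters at one centerline station."""

    station_arc_length_mm: float
    plane_normal: np.ndarray
    spike_lengths_mm: np.ndarray

    @property
    def mean_diameter_mm(self) -> float:
        return float(np.mean(self.spike_lengths_mm))


@dataclass
class SegmentMorphometry:
    segment_id: str
    length_mm: float
    max_mean_diameter_mm: float
    station_of_max_mm: float


@dataclass
class CurvatureFit:
    circle_center_mm: np.ndarray
    radius_mm: float
    rms_residual_mm: float
    plane_normal: np.ndarray


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    s = _cumulative_arc_length(points)
    total = s[-1]
    n = max(int(np.ceil(total / step_mm)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])


def _smooth_polyline(points: np.ndarray, window_mm: float, step_mm: float) -> np.ndarray:
    """Quadratic Savitzky-Golay smoothing over ~window_mm on an even polyline.

    A plain moving average systematically flattens curved sections (and worst
    of all at the ends, where the window shrinks asymmetrically), which biases
    a downstream circle fit toward larger radii; an order-2 polynomial filter
    preserves circular arcs to second order.
    """
    half = max(int(round(window_mm / (2.0 * step_mm))), 1)
    window = 2 * half + 1
    if len(points) <= window:
        return points.copy()
    return savgol_filter(points, window_length=window, polyorder=2, axis=0, mode="interp")


def _interp_mask(mask: LumenMask, pts_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the binary mask at world points."""
    idx = mask.index_from_world(pts_mm)
    return ndimage.map_coordinates(
        mask.voxels.astype(np.float32), idx.T, order=1, mode="constant", cval=0.0
    )


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

_OFFSETS_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) > (0, 0, 0)
    ]
)


def _validate_topology(mask: LumenMask) -> None:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    _, n_comp = ndimage.label(mask.voxels, structure=structure)
    if n_comp == 0:
        raise TopologyError("mask is empty")
    if n_comp > 1:
        raise TopologyError(f"mask has {n_comp} 6-connected components; expected exactly 1")
    # a solid tube has Euler number 1; a loop (handle) drops it to 0 or below
    eu = euler_number(mask.voxels, connectivity=3)
    if eu != 1:
        raise TopologyError(
            f"mask Euler number is {eu}, expected 1; the lumen appears to contain "
            "a loop/handle or cavity and is not tube-like"
        )


def _voxel_graph(mask: LumenMask, dt_mm: np.ndarray, ridge_power: float = 4.0):
    """Sparse 26-connectivity graph over foreground voxels.

    Edge cost = euclidean step / mean(distance-to-wall)^ridge_power, so shortest
    paths run along the medial ridge instead of cutting corners.
    """
    fg = mask.voxels
    node_id = -np.ones(fg.shape, dtype=np.int64)
    coords = np.argwhere(fg)
    node_id[tuple(coords.T)] = np.arange(len(coords))
    dt_fg = dt_mm[tuple(coords.T)]
    shape = np.array(fg.shape)

    rows, cols, ws = [], [], []
    for off in _OFFSETS_26:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = np.nonzero(ok)[0]
        nb_ids = node_id[tuple(nb[ok].T)]
        valid = nb_ids >= 0
        src = src[valid]
        dst = nb_ids[valid]
        step = np.linalg.norm(off * mask.spacing_mm)
        davg = 0.5 * (dt_fg[src] + dt_fg[dst])
        w = step / np.maximum(davg, 0.25 * float(mask.spacing_mm.min())) ** ridge_power
        rows.append(src)
        cols.append(dst)
        ws.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    ws = np.concatenate(ws)
    n = len(coords)
    g = coo_matrix((ws, (rows, cols)), shape=(n, n)).tocsr()
    return g, coords, node_id


def _auto_endpoints(graph, coords: np.ndarray, dt_fg: np.ndarray) -> tuple[int, int]:
    """Two-pass farthest-point search for the tube's two openings."""
    seed = int(np.argmax(dt_fg))
    d0 = dijkstra(graph, directed=False, indices=seed, unweighted=True)
    d0[~np.isfinite(d0)] = -1
    e1 = int(np.argmax(d0))
    d1 = dijkstra(graph, directed=False, indices=e1, unweighted=True)
    d1[~np.isfinite(d1)] = -1
    e2 = int(np.argmax(d1))
    return e1, e2


def _recenter(mask: LumenMask, points: np.ndarray, grid_step_mm: float = 0.5) -> np.ndarray:
    """Move each point to the centroid of the lumen cross-section through it.

    The cross-section is sampled in the plane perpendicular to the local
    tangent, on a disk bounded by the local distance-to-wall (so the sampling
    cannot leak into another limb of a strongly curved vessel).
    """
    dt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing_mm)
    s = _cumulative_arc_length(points)
    tang = np.gradient(points, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    idx = np.clip(mask.index_from_world(points), 0, np.array(mask.voxels.shape) - 1)
    dt_here = ndimage.map_coordinates(dt, idx.T, order=1, mode="nearest")

    out = points.copy()
    for i, (p, t, d) in enumerate(zip(points, tang, dt_here)):
        rad = max(2.2 * float(d), 3.0 * float(mask.spacing_mm.max()))
        u, v = _plane_basis(t)
        r = np.arange(-rad, rad + grid_step_mm, grid_step_mm)
        uu, vv = np.meshgrid(r, r, indexing="ij")
        disk = uu**2 + vv**2 <= rad**2
        pts = p + uu[disk, None] * u + vv[disk, None] * v
        vals = _interp_mask(mask, pts)
        inside = vals > 0.5
        if inside.sum() < 4:
            continue
        out[i] = pts[inside].mean(axis=0)
    return out


def _extend_to_openings(
    mask: LumenMask,
    points: np.ndarray,
    step_mm: float = 0.25,
    max_extension_mm: float = 8.0,
    fit_mm: float = 15.0,
) -> np.ndarray:
    """Re-grow each end until it leaves the lumen, by quadratic extrapolation.

    Each coordinate is fitted as a quadratic in arc length over the last
    ~fit_mm of the curve, which continues the local bend (a straight tangent
    ray would flatten curved ends and bias a downstream circle fit).  The
    extension is capped: the curve ends were trimmed only a few millimeters
    from the opening, so a long walk means the extrapolation is sliding along
    inside the lumen instead of exiting through the cap.
    """
    out = [points]
    max_steps = int(np.ceil(max_extension_mm / step_mm))
    s = _cumulative_arc_length(points)
    for end in (0, -1):
        sel = s <= s[0] + fit_mm if end == 0 else s >= s[-1] - fit_mm
        if sel.sum() < 3:
            continue
        s_end = s[0] if end == 0 else s[-1]
        coef = np.polynomial.polynomial.polyfit(s[sel] - s_end, points[sel], deg=2)
        direction = -1.0 if end == 0 else 1.0
        ext = []
        for k in range(1, max_steps + 1):
            q = np.polynomial.polynomial.polyval(direction * k * step_mm, coef)
            if _interp_mask(mask, q[None])[0] <= 0.5:
                break
            ext.append(q)
        if ext:
            ext_arr = np.asarray(ext)
            if end == 0:
                out.insert(0, ext_arr[::-1])
            else:
                out.append(ext_arr)
    return np.vstack(out)


def _trim_ends(points: np.ndarray, trim_mm: float) -> np.ndarray:
    """Drop points within trim_mm of either end (recentering is unreliable there)."""
    s = _cumulative_arc_length(points)
    keep = (s >= trim_mm) & (s <= s[-1] - trim_mm)
    if keep.sum() < max(8, len(points) // 4):
        return points
    return points[keep]


def extract_centerline(
    mask: LumenMask,
    endpoints_mm: Sequence[np.ndarray] | None = None,
    smoothing_window_mm: float = 12.0,
    resample_step_mm: float = 1.0,
    n_recenter: int = 2,
) -> Centerline:
    """Extract a smoothed 1-mm-resampled centerline from a tubular lumen mask.

    The rough path is a distance-transform-weighted shortest path between the
    two endpoints (auto-detected as the graph-farthest voxel pair when not
    given), which is then smoothed, iteratively re-centered onto cross-section
    centroids, and extended to the lumen openings.

    Parameters
    ----------
    endpoints_mm
        Optional pair of world points marking the proximal (first) and distal
        ends.  When omitted, endpoints are found automatically and the
        ordering is arbitrary but deterministic.
    """
    _validate_topology(mask)
    dt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing_mm)
    graph, coords, node_id = _voxel_graph(mask, dt)
    dt_fg = dt[tuple(coords.T)]

    if endpoints_mm is not None:
        if len(endpoints_mm) != 2:
            raise ValueError("endpoints_mm must contain exactly two points")
        ends = []
        for p in endpoints_mm:
            d2 = np.sum((coords * mask.spacing_mm + mask.origin_mm - np.asarray(p)) ** 2, axis=1)
            ends.append(int(np.argmin(d2)))
        e1, e2 = ends
    else:
        e1, e2 = _auto_endpoints(graph, coords, dt_fg)

    dists, pred = dijkstra(
        graph, directed=False, indices=e1, return_predecessors=True
    )
    if not np.isfinite(dists[e2]):
        raise TopologyError("endpoints are not connected within the mask")
    path = [e2]
    while path[-1] != e1:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    pts = coords[path] * mask.spacing_mm + mask.origin_mm

    # elongation sanity check: a blob yields a path barely longer than its radius
    # a ball's diameter path is ~2x its inscribed radius; a tube is longer
    path_len = _cumulative_arc_length(pts)[-1]
    if path_len < 2.5 * float(dt_fg.max()):
        raise TopologyError(
            "mask is not elongated (centerline shorter than 3x the inscribed radius); "
            "expected a tube-like structure"
        )

    anchors = None
    if endpoints_mm is not None:
        anchors = (np.asarray(endpoints_mm[0], float), np.asarray(endpoints_mm[1], float))

    def _pin(arr: np.ndarray) -> np.ndarray:
        if anchors is not None:
            arr[0], arr[-1] = anchors
        return arr

    pts = _resample_polyline(pts, resample_step_mm)
    pts = _pin(_smooth_polyline(pts, smoothing_window_mm, resample_step_mm))
    for _ in range(n_recenter):
        pts = _pin(_recenter(mask, pts))
        pts = _pin(_smooth_polyline(pts, smoothing_window_mm, resample_step_mm))
        pts = _pin(_resample_polyline(pts, resample_step_mm))

    if anchors is None:
        # auto-detected ends: within ~one tube radius of an opening the
        # recentering disk protrudes past the cap and the centroid drifts, so
        # drop that zone and re-grow each end by extrapolating the (accurate)
        # interior curve until it exits the lumen
        s_now = _cumulative_arc_length(pts)
        probe = pts[
            [int(np.searchsorted(s_now, 15.0)), int(np.searchsorted(s_now, s_now[-1] - 15.0))]
        ]
        dt_ends = ndimage.map_coordinates(
            dt,
            np.clip(mask.index_from_world(probe), 0, np.array(mask.voxels.shape) - 1).T,
            order=1,
            mode="nearest",
        )
        trim_mm = max(3.0, float(dt_ends.max()) + 2.0 * float(mask.spacing_mm.max()))
        pts = _trim_ends(pts, trim_mm=trim_mm)
        pts = _extend_to_openings(mask, pts, max_extension_mm=trim_mm + 5.0)
    pts = _pin(_resample_polyline(pts, resample_step_mm))
    return Centerline(pts)


# ---------------------------------------------------------------------------
# segment partition
# ---------------------------------------------------------------------------


def partition_segments(
    centerline: Centerline,
    landmarks: Sequence[float] | Sequence[dict],
    *,
    as_fractions: bool = False,
) -> SegmentPartition:
    """Partition a centerline into S1..S4 at three explicit landmarks.

    Landmarks emulate the manual segment cuts of the original analysis and may
    be given as arc-length positions (mm), arc-length fractions of the total
    length (``as_fractions=True``), or cut planes (dicts with ``point`` and
    ``normal``) whose first centerline crossing defines the boundary.
    """
    if len(landmarks) != 3:
        raise ValueError("exactly three landmarks are required for four segments")
    total = centerline.length_mm
    cuts = []
    for lm in landmarks:
        if isinstance(lm, dict):
            cuts.append(_plane_crossing(centerline, lm["point"], lm["normal"]))
        else:
            s = float(lm) * total if as_fractions else float(lm)
            cuts.append(s)
    for s in cuts:
        if not (0.0 < s < total):
            raise ValueError(f"landmark at arc length {s:.2f} mm outside centerline (0, {total:.2f})")
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError(f"landmarks must be ordered along the centerline, got {cuts}")
    return SegmentPartition(tuple(cuts), total)


def _plane_crossing(centerline: Centerline, point, normal) -> float:
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    g = (centerline.points_mm - point) @ normal
    sign_change = np.nonzero(np.diff(np.signbit(g)))[0]
    if len(sign_change) == 0:
        raise ValueError("cut plane does not intersect the centerline")
    i = int(sign_change[0])
    f = g[i] / (g[i] - g[i + 1])
    s = centerline.arc_length_mm
    return float(s[i] + f * (s[i + 1] - s[i]))


# ---------------------------------------------------------------------------
# cross sections and diameters
# ---------------------------------------------------------------------------


def build_cross_sections(
    mask: LumenMask,
    centerline: Centerline,
    step_mm: float = 1.0,
    n_spikes: int = 90,
    ray_step_mm: float = 0.2,
    max_radius_mm: float = 50.0,
) -> list[CrossSectionProfile]:
    """Radial-spike cross-sections perpendicular to the centerline at every station.

    At each arc-length station a cross-section plane is spanned perpendicular
    to the local tangent and ``n_spikes`` full chords through the centerline
    point are measured at equally spaced angles.  Each chord end is located by
    bidirectional ray-casting with sub-voxel linear interpolation of the
    0.5-isocontour crossing.  Stations whose centerline point falls outside
    the lumen are excluded with a warning.
    """
    total = centerline.length_mm
    stations = np.arange(0.0, total + 1e-9, step_mm)
    stations = stations[stations <= total]
    pts = centerline.point_at(stations)
    tang = centerline.tangents()
    tang = np.column_stack(
        [np.interp(stations, centerline.arc_length_mm, tang[:, k]) for k in range(3)]
    )
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    angles = np.arange(n_spikes) * (np.pi / n_spikes)  # full chords: half-turn suffices
    n_ray = int(np.ceil(max_radius_mm / ray_step_mm))
    radii = (np.arange(n_ray) + 1) * ray_step_mm

    vol = mask.voxels.astype(np.float32)
    profiles: list[CrossSectionProfile] = []
    n_excluded = 0
    for s, p, t in zip(stations, pts, tang):
        if _interp_mask(mask, p[None])[0] <= 0.5:
            n_excluded += 1
            continue
        u, v = _plane_basis(t)
        dirs = np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * v  # (n_spikes, 3)
        # both directions of every chord in one batch: (2*n_spikes, n_ray, 3)
        alldirs = np.vstack([dirs, -dirs])
        sample_pts = p + alldirs[:, None, :] * radii[None, :, None]
        idx = mask.index_from_world(sample_pts.reshape(-1, 3))
        vals = ndimage.map_coordinates(vol, idx.T, order=1, mode="constant", cval=0.0)
        vals = vals.reshape(2 * n_spikes, n_ray)
        half = _first_crossing(vals, radii, ray_step_mm)
        spikes = half[:n_spikes] + half[n_spikes:]
        profiles.append(
            CrossSectionProfile(
                station_arc_length_mm=float(s),
                plane_normal=t,
                spike_lengths_mm=spikes,
            )
        )
    if n_excluded:
        logger.warning("%d stations excluded: centerline point outside the lumen", n_excluded)
    return profiles


def _first_crossing(vals: np.ndarray, radii: np.ndarray, step: float) -> np.ndarray:
    """Sub-voxel radius of the first 0.5-crossing along each ray."""
    below = vals < 0.5
    first = np.argmax(below, axis=1)
    never = ~below.any(axis=1)
    first[never] = vals.shape[1] - 1
    rows = np.arange(vals.shape[0])
    v_out = vals[rows, first]
    prev = np.clip(first - 1, 0, None)
    v_in = np.where(first > 0, vals[rows, prev], 1.0)
    r_in = np.where(first > 0, radii[prev], 0.0)
    frac = np.where(v_in > v_out, (v_in - 0.5) / np.maximum(v_in - v_out, 1e-12), 0.0)
    r = r_in + frac * step
    r[never] = radii[-1]
    return r


def segment_morphometry(
    profiles: Sequence[CrossSectionProfile], partition: SegmentPartition
) -> list[SegmentMorphometry]:
    """Per-segment centerline length and largest mean radial-spike diameter."""
    stations = np.array([p.station_arc_length_mm for p in profiles])
    if len(stations) == 0:
        raise ValueError("no cross-section profiles provided")
    if stations.max() < partition.boundaries_mm[-1]:
        raise ValueError("profiles do not cover all segments (last boundary beyond coverage)")
    out = []
    for seg in SEGMENT_LABELS:
        lo, hi = partition.extent(seg)
        in_seg = [p for p in profiles if lo - 1e-9 <= p.station_arc_length_mm <= hi + 1e-9]
        if not in_seg:
            raise ValueError(f"segment {seg} contains no cross-section stations")
        means = np.array([p.mean_diameter_mm for p in in_seg])
        k = int(np.argmax(means))
        out.append(
            SegmentMorphometry(
                segment_id=seg,
                length_mm=hi - lo,
                max_mean_diameter_mm=float(means[k]),
                station_of_max_mm=in_seg[k].station_arc_length_mm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# curvature radius
# ---------------------------------------------------------------------------


def fit_curvature_radius(centerline_segment: Centerline) -> CurvatureFit:
    """Circle fit through a centerline segment: the ascending-aorta curvature radius.

    A total-least-squares plane is fitted first (minimizing perpendicular
    distances), the points are projected into it, a circle is fitted
    algebraically (Kåsa) and refined by geometric least squares.  Near-straight
    segments, for which the radius diverges, are rejected: if the algebraic
    radius exceeds 10x the segment's chord length the fit is reported as
    degenerate rather than returning an arbitrarily large radius.
    """
    pts = centerline_segment.points_mm
    if len(pts) < 5:
        raise DegenerateGeometryError("need at least 5 centerline points for a circle fit")
    if centerline_segment.length_mm < 10.0:
        raise DegenerateGeometryError("centerline segment must span at least 10 mm")

    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, sv, vt = np.linalg.svd(q, full_matrices=False)
    normal = vt[2]
    u_ax, v_ax = vt[0], vt[1]
    x = q @ u_ax
    y = q @ v_ax

    chord = float(np.linalg.norm(pts[-1] - pts[0]))

    # sagitta test: an arc of radius R over chord c deviates by h ~ c^2 / 8R,
    # so the degeneracy rule "radius > 10x chord" is h < c / 80; this also
    # catches exactly collinear points, where the algebraic fit is meaningless
    chord_dir = (pts[-1] - pts[0]) / max(chord, 1e-12)
    rel = pts - pts[0]
    perp = rel - np.outer(rel @ chord_dir, chord_dir)
    sagitta = float(np.linalg.norm(perp, axis=1).max())
    if sagitta < chord / 80.0:
        raise DegenerateGeometryError(
            f"degenerate: near-straight segment (max deviation {sagitta:.3g} mm over a "
            f"{chord:.1f} mm chord implies a curvature radius above 10x the chord length)"
        )

    # Kåsa algebraic fit: x^2+y^2 + D x + E y + F = 0
    a_mat = np.column_stack([x, y, np.ones_like(x)])
    b_vec = -(x**2 + y**2)
    try:
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateGeometryError(f"algebraic circle fit failed: {exc}") from exc
    cx0, cy0 = -sol[0] / 2.0, -sol[1] / 2.0
    r0_sq = cx0**2 + cy0**2 - sol[2]
    if not np.isfinite(r0_sq) or r0_sq <= 0:
        raise DegenerateGeometryError("degenerate: near-straight segment (algebraic fit collapsed)")
    r0 = float(np.sqrt(r0_sq))
    if r0 > 10.0 * chord:
        raise DegenerateGeometryError(
            f"degenerate: near-straight segment (algebraic radius {r0:.1f} mm exceeds "
            f"10x chord length {chord:.1f} mm)"
        )

    def resid(params):
        cx, cy, r = params
        return np.hypot(x - cx, y - cy) - r

    fit = least_squares(resid, x0=[cx0, cy0, r0], method="lm")
    cx, cy, r = fit.x
    res = resid(fit.x)
    # out-of-plane distances also count toward the residual
    oop = q @ normal
    rms = float(np.sqrt(np.mean(res**2 + oop**2)))
    center = centroid + cx * u_ax + cy * v_ax
    return CurvatureFit(
        circle_center_mm=center,
        radius_mm=float(abs(r)),
        rms_residual_mm=rms,
        plane_normal=normal,
    )
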