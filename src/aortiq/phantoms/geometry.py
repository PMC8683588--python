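"""Candy-cane tube phantoms with analytic ground truth.

The phantom aorta is a tube of (optionally varying) radius swept along a
"candy cane": a circular arc of the requested ascending curvature radius
(covering the ascending aorta S1 and the arch S2) joined tangentially to a
straight descending limb (S3 + S4).  Because the sweep path is known in
closed form, segment lengths, maximal mean diameters and the ascending
curvature radius are all available as exact ground truth, which is what makes
the downstream morphometry testable without any imaging data.

Geometry lives in world millimeters.  The cane lies in the y = 0 plane by
default; an optional rigid tilt takes it out of axis alignment so that plane
and circle fitting are exercised on genuinely 3D data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ..errors import SelfIntersectionError
from ..morphometry import SEGMENT_LABELS, LumenMask

__all__ = [
    "GeometryPhantomSpec",
    "GeometryGroundTruth",
    "make_geometry_phantom",
    "make_cylinder_phantom",
    "make_elliptic_cylinder_mask",
    "gaussian_bulge",
]


@dataclass(frozen=True)
class GeometryPhantomSpec:
    """Parameters of the candy-cane phantom.

    Defaults reflect a typical thoracic-aneurysm aorta: ascending curvature
    radius 45.9 mm (population mean in the cohort this pipeline targets) and a
    40 mm lumen diameter.
    """

    ascending_curvature_radius_mm: float = 45.9
    ascending_tube_radius_mm: float = 20.0
    arc_sweep_deg: float = 180.0
    descending_length_mm: float = 150.0
    arc_split_fraction: float = 0.5
    descending_split_fraction: float = 0.72
    radius_profile: Callable[[np.ndarray], np.ndarray] | None = None
    tilt_deg: float = 0.0
    voxel_size_mm: float = 1.0
    noise: float = 0.0  # SDF jitter amplitude, in voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ascending_curvature_radius_mm <= self.ascending_tube_radius_mm:
            raise SelfIntersectionError(
                "tube self-intersects: curvature radius "
                f"{self.ascending_curvature_radius_mm} mm must exceed tube radius "
                f"{self.ascending_tube_radius_mm} mm"
            )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not (0.0 < self.arc_sweep_deg <= 270.0):
            raise ValueError("arc_sweep_deg must be in (0, 270]")
        if self.descending_length_mm <= 0:
            raise ValueError("descending_length_mm must be positive")
        if not (0.0 < self.arc_split_fraction < 1.0 and 0.0 < self.descending_split_fraction < 1.0):
            raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class GeometryGroundTruth:
    """Exact construction geometry paired with a phantom mask."""

    centerline_points_mm: np.ndarray
    arc_length_mm: np.ndarray
    segment_boundaries_mm: tuple[float, float, float]
    true_segment_lengths_mm: dict[str, float]
    true_max_mean_diameters_mm: dict[str, float]
    true_curvature_radius_mm: float
    endpoints_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = self.segment_boundaries_mm
        if not (b[0] < b[1] < b[2]):
            raise ValueError("segment boundaries must be strictly increasing")
        if self.endpoints_mm is None:
            self.endpoints_mm = np.vstack(
                [self.centerline_points_mm[0], self.centerline_points_mm[-1]]
            )


def _candycane_path(spec: GeometryPhantomSpec, step_mm: float = 0.25):
    """Dense centerline samples (points, arc lengths, local tube radii)."""
    r_arc = spec.ascending_curvature_radius_mm
    sweep = np.deg2rad(spec.arc_sweep_deg)
    arc_len = r_arc * sweep
    total = arc_len + spec.descending_length_mm
    n = max(int(np.ceil(total / step_mm)) + 1, 8)
    s = np.linspace(0.0, total, n)

    pts = np.empty((n, 3))
    on_arc = s <= arc_len
    # arc: theta runs from (pi/2 - sweep) to pi/2; tangent at the end is -z
    theta = (np.pi / 2.0 - sweep) + s[on_arc] / r_arc
    pts[on_arc] = np.column_stack(
        [r_arc * np.sin(theta), np.zeros(on_arc.sum()), r_arc * np.cos(theta)]
    )
    t_str = s[~on_arc] - arc_len
    pts[~on_arc] = np.column_stack(
        [np.full((~on_arc).sum(), r_arc), np.zeros((~on_arc).sum()), -t_str]
    )
    if spec.tilt_deg:
        rot = Rotation.from_rotvec(
            np.deg2rad(spec.tilt_deg) * np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
        )
        pts = rot.apply(pts)

    radii = np.full(n, spec.ascending_tube_radius_mm)
    if spec.radius_profile is not None:
        radii = radii * np.asarray(spec.radius_profile(s), dtype=float)
    return pts, s, radii, arc_len, total


def _check_self_intersection(pts: np.ndarray, s: np.ndarray, radii: np.ndarray) -> None:
    """Reject path geometries where non-adjacent tube sections would merge."""
    stride = max(len(pts) // 400, 1)
    p = pts[::stride]
    ss = s[::stride]
    rr = radii[::stride]
    d = cdist(p, p)
    ds = np.abs(ss[:, None] - ss[None, :])
    rsum = rr[:, None] + rr[None, :]
    far_along = ds > 1.5 * np.maximum(rsum, 1.0)
    too_close = d < rsum
    if np.any(far_along & too_close):
        raise SelfIntersectionError(
            "tube self-intersection: non-adjacent centerline sections come closer "
            "than the sum of their tube radii"
        )


def make_geometry_phantom(spec: GeometryPhantomSpec) -> tuple[LumenMask, GeometryGroundTruth]:
    """Voxelize the candy-cane tube and return it with exact ground truth.

    The mask is built from the signed distance to the swept tube (distance to
    the centerline minus the local radius, clipped by flat end planes), so that
    boundary jitter — Gaussian noise added to the signed distance before
    thresholding — perturbs the wall without breaking the tube's topology.
    """
    pts, s, radii, arc_len, total = _candycane_path(spec)
    _check_self_intersection(pts, s, radii)

    vox = spec.voxel_size_mm
    margin = radii.max() + 3.0 * vox
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.ceil((hi - lo) / vox).astype(int) + 1
    origin = lo

    idx = np.indices(shape).reshape(3, -1).T
    world = origin + idx * vox
    tree = cKDTree(pts)
    dist, nearest = tree.query(world, workers=-1)
    sdf = dist - radii[nearest]

    # flat openings: clip by the end planes, but only for voxels whose nearest
    # centerline sample lies near that end — a global half-space would cut off
    # distant parts of the curved tube
    t0 = pts[1] - pts[0]
    t0 /= np.linalg.norm(t0)
    t1 = pts[-1] - pts[-2]
    t1 /= np.linalg.norm(t1)
    near_start = s[nearest] < 2.0 * radii[0]
    near_end = s[nearest] > total - 2.0 * radii[-1]
    beyond_start = -(world - pts[0]) @ t0
    beyond_end = (world - pts[-1]) @ t1
    sdf = np.where(near_start, np.maximum(sdf, beyond_start), sdf)
    sdf = np.where(near_end, np.maximum(sdf, beyond_end), sdf)

    if spec.noise > 0:
        # spatially correlated jitter (~1 voxel correlation length): displaces
        # the wall by the requested amplitude without punching sub-voxel
        # tunnels or cavities the way iid voxel noise would
        rng = np.random.default_rng(spec.seed)
        noise_field = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=1.0, mode="nearest"
        )
        noise_field *= spec.noise * vox / max(noise_field.std(), 1e-12)
        sdf = sdf + noise_field.ravel()

    vol = (sdf < 0).reshape(shape)
    if spec.noise > 0:
        # jitter may detach boundary specks or pinch off sub-voxel cavities at
        # the wall; restore tube topology (a segmentation tool would too)
        vol = ndimage.binary_fill_holes(vol)
        lab, n = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            vol = lab == (1 + int(np.argmax(sizes)))

    mask = LumenMask(vol, np.full(3, vox), origin)

    b1 = arc_len * spec.arc_split_fraction
    b2 = arc_len
    b3 = arc_len + spec.descending_length_mm * spec.descending_split_fraction
    boundaries = (float(b1), float(b2), float(b3))
    edges = (0.0, *boundaries, float(total))
    lengths = {
        seg: edges[i + 1] - edges[i] for i, seg in enumerate(SEGMENT_LABELS)
    }
    diameters = {}
    for i, seg in enumerate(SEGMENT_LABELS):
        in_seg = (s >= edges[i]) & (s <= edges[i + 1])
        diameters[seg] = float(2.0 * radii[in_seg].max())
    truth = GeometryGroundTruth(
        centerline_points_mm=pts,
        arc_length_mm=s,
        segment_boundaries_mm=boundaries,
        true_segment_lengths_mm=lengths,
        true_max_mean_diameters_mm=diameters,
        true_curvature_radius_mm=spec.ascending_curvature_radius_mm,
    )
    return mask, truth


def make_cylinder_phantom(
    tube_radius_mm: float = 20.0,
    length_mm: float = 100.0,
    voxel_size_mm: float = 1.0,
    axis: int = 2,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[LumenMask, GeometryGroundTruth]:
    """Straight circular tube: the degenerate (zero-curvature) phantom."""
    vox = voxel_size_mm
    margin = tube_radius_mm + 3.0 * vox
    n_ax = int(np.ceil(length_mm / vox)) + 1
    n_perp = int(np.ceil(2 * margin / vox)) + 1
    shape = [n_perp, n_perp, n_perp]
    shape[axis] = n_ax
    origin = np.full(3, -margin)
    origin[axis] = 0.0
    idx = np.indices(shape).astype(float)
    world = [origin[k] + idx[k] * vox for k in range(3)]
    perp = [k for k in range(3) if k != axis]
    r2 = world[perp[0]] ** 2 + world[perp[1]] ** 2
    sdf = np.sqrt(r2) - tube_radius_mm
    sdf = np.maximum(sdf, -world[axis])
    sdf = np.maximum(sdf, world[axis] - length_mm)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sdf = sdf + rng.normal(0.0, noise * vox, size=sdf.shape)
    mask = LumenMask(sdf < 0, np.full(3, vox), origin)

    s = np.linspace(0.0, length_mm, max(int(length_mm / 0.5), 4))
    pts = np.zeros((len(s), 3))
    pts[:, axis] = s
    b = (0.25 * length_mm, 0.5 * length_mm, 0.75 * length_mm)
    truth = GeometryGroundTruth(
        centerline_points_mm=pts,
        arc_length_mm=s,
        segment_boundaries_mm=b,
        true_segment_lengths_mm={seg: length_mm / 4.0 for seg in SEGMENT_LABELS},
        true_max_mean_diameters_mm={seg: 2.0 * tube_radius_mm for seg in SEGMENT_LABELS},
        true_curvature_radius_mm=float("inf"),
    )
    return mask, truth


def make_elliptic_cylinder_mask(
    semi_axis_a_mm: float,
    semi_axis_b_mm: float,
    length_mm: float = 40.0,
    voxel_size_mm: float = 1.0,
) -> LumenMask:
    """Elliptic straight tube (axis = z) for cross-section diameter oracles."""
    vox = voxel_size_mm
    margin = max(semi_axis_a_mm, semi_axis_b_mm) + 3.0 * vox
    n_ax = int(np.ceil(length_mm / vox)) + 1
    n_perp = int(np.ceil(2 * margin / vox)) + 1
    shape = (n_perp, n_perp, n_ax)
    origin = np.array([-margin, -margin, 0.0])
    idx = np.indices(shape).astype(float)
    x = origin[0] + idx[0] * vox
    y = origin[1] + idx[1] * vox
    inside = (x / semi_axis_a_mm) ** 2 + (y / semi_axis_b_mm) ** 2 <= 1.0
    return LumenMask(inside, np.full(3, vox), origin)


def gaussian_bulge(
    center_mm: float, amplitude: float, width_mm: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Radius-profile factory: multiplicative Gaussian bulge at an arc-length position."""

    def profile(s: np.ndarray) -> np.ndarray:
        return 1.0 + amplitude * np.exp(-0.5 * ((np.asarray(s) - center_mm) / width_mm) ** 2)

    return profile
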