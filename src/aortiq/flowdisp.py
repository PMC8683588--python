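"""Normalized flow displacement from 2D through-plane velocity fields.

Flow displacement is a flow-eccentricity marker measured on a through-plane
phase-contrast slice of the ascending aorta: the distance between the
geometric center of the lumen and the velocity-weighted centroid of forward
flow at peak systole, normalized to the lumen diameter.  A centered,
axisymmetric jet gives 0; a jet hugging the outer wall gives values toward
the geometric bound of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import FlowFieldError


@dataclass
class FlowField2D:
    """Through-plane velocity (cm/s, signed, forward positive) plus lumen mask."""

    velocity_cm_per_s: np.ndarray
    lumen_mask: np.ndarray
    pixel_spacing_mm: np.ndarray
    phase_time_ms: float | None = None

    def __post_init__(self) -> None:
        self.velocity_cm_per_s = np.asarray(self.velocity_cm_per_s, dtype=float)
        self.lumen_mask = np.asarray(self.lumen_mask).astype(bool)
        self.pixel_spacing_mm = np.broadcast_to(
            np.asarray(self.pixel_spacing_mm, dtype=float), (2,)
        ).copy()
        if self.velocity_cm_per_s.shape != self.lumen_mask.shape:
            raise ValueError("velocity and lumen mask shapes differ")
        if self.velocity_cm_per_s.ndim != 2:
            raise ValueError("flow field must be 2D")
        if not np.all(self.pixel_spacing_mm > 0):
            raise ValueError("pixel spacing must be positive")
        _, n = ndimage.label(self.lumen_mask)
        if n != 1:
            raise ValueError(f"lumen mask must be one connected component, found {n}")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass
class FlowDisplacementResult:
    geometric_center_mm: np.ndarray
    forward_flow_center_mm: np.ndarray
    lumen_diameter_mm: float
    normalized_fd: float
    peak_phase_index: int | None = field(default=None)


def select_peak_systole(stack: list[FlowField2D]) -> tuple[FlowField2D, int]:
    """Pick the phase with maximal net forward flow (sum of positive velocities x area).

    Net forward flow is more robust to single-pixel noise than the raw peak
    velocity.  Raises FlowFieldError when no phase carries net forward flow.
    """
    if len(stack) < 3:
        raise FlowFieldError("need at least 3 phases to pick peak systole")
    flows = []
    for f in stack:
        v = f.velocity_cm_per_s[f.lumen_mask]
        flows.append(float(np.sum(v[v > 0])) * f.pixel_area_mm2)
    k = int(np.argmax(flows))
    if flows[k] <= 0:
        raise FlowFieldError("no phase has forward flow; cannot identify peak systole")
    return stack[k], k


def normalized_flow_displacement(field: FlowField2D) -> FlowDisplacementResult:
    """Normalized flow displacement of a single (peak-systolic) flow field.

    geometric center: unweighted centroid of lumen pixels;
    forward-flow center: centroid of velocity > 0 pixels weighted by velocity;
    lumen diameter: effective circular diameter 2*sqrt(area / pi), which is
    orientation-independent;
    normalized FD: Euclidean distance between the centers / diameter.
    """
    lumen = field.lumen_mask
    n_lumen = int(lumen.sum())
    if n_lumen < 10:
        raise FlowFieldError(f"lumen area of {n_lumen} pixels is too small to be reliable")
    v = field.velocity_cm_per_s
    forward = lumen & (v > 0)
    if not forward.any():
        raise FlowFieldError("no forward-flow pixels in the lumen")

    coords = np.argwhere(lumen).astype(float) * field.pixel_spacing_mm
    geo = coords.mean(axis=0)

    fwd_coords = np.argwhere(forward).astype(float) * field.pixel_spacing_mm
    w = v[forward]
    flow_center = (fwd_coords * w[:, None]).sum(axis=0) / w.sum()

    area = n_lumen * field.pixel_area_mm2
    diameter = 2.0 * np.sqrt(area / np.pi)
    fd = float(np.linalg.norm(flow_center - geo) / diameter)
    return FlowDisplacementResult(
        geometric_center_mm=geo,
        forward_flow_center_mm=flow_center,
        lumen_diameter_mm=float(diameter),
        normalized_fd=fd,
    )


def flow_displacement_at_peak(stack: list[FlowField2D]) -> FlowDisplacementResult:
    """Convenience: select peak systole, then measure flow displacement there."""
    peak, k = select_peak_systole(stack)
    res = normalized_flow_displacement(peak)
    res.peak_phase_index = k
    return res
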