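"""File formats: NIfTI masks, JSON sidecars, CSV/NPZ arrays, cohort CSVs.

Masks travel as NIfTI-1 with the voxel spacing in the affine (world
millimeters; the affine maps a voxel index to the world position of that
voxel's center).  Phantom ground truth travels as a JSON sidecar.  Velocity
series and flow fields are NPZ containers with a JSON metadata block; cohorts
are plain CSV with a documented column dictionary.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .flowdisp import FlowField2D
from .morphometry import LumenMask
from .phantoms.cohort import COLUMN_DICTIONARY
from .phantoms.geometry import GeometryGroundTruth
from .pwv import VelocityEncodedSeries


def save_mask(mask: LumenMask, path: str | Path) -> None:
    affine = np.diag([*mask.spacing_mm, 1.0])
    affine[:3, 3] = mask.origin_mm
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> LumenMask:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) masks are supported")
    return LumenMask(
        np.asanyarray(img.dataobj) > 0,
        spacing_mm=spacing,
        origin_mm=affine[:3, 3],
    )


def save_ground_truth(truth: GeometryGroundTruth, path: str | Path) -> None:
    payload = {
        "centerline_points_mm": truth.centerline_points_mm.tolist(),
        "arc_length_mm": truth.arc_length_mm.tolist(),
        "segment_boundaries_mm": list(truth.segment_boundaries_mm),
        "true_segment_lengths_mm": truth.true_segment_lengths_mm,
        "true_max_mean_diameters_mm": truth.true_max_mean_diameters_mm,
        "true_curvature_radius_mm": truth.true_curvature_radius_mm,
        "endpoints_mm": truth.endpoints_mm.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path: str | Path) -> GeometryGroundTruth:
    d = json.loads(Path(path).read_text())
    return GeometryGroundTruth(
        centerline_points_mm=np.asarray(d["centerline_points_mm"]),
        arc_length_mm=np.asarray(d["arc_length_mm"]),
        segment_boundaries_mm=tuple(d["segment_boundaries_mm"]),
        true_segment_lengths_mm=d["true_segment_lengths_mm"],
        true_max_mean_diameters_mm=d["true_max_mean_diameters_mm"],
        true_curvature_radius_mm=d["true_curvature_radius_mm"],
        endpoints_mm=np.asarray(d["endpoints_mm"]),
    )


def save_velocity_series(series: VelocityEncodedSeries, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "temporal_resolution_ms": series.temporal_resolution_ms,
        "venc_cm_per_s": series.venc_cm_per_s,
    }
    kwargs = dict(
        chord_arc_length_mm=series.chord_arc_length_mm,
        waveforms=series.waveforms,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    if series.segment_labels is not None:
        kwargs["segment_labels"] = np.asarray(series.segment_labels, dtype="U8")
    np.savez_compressed(path, **kwargs)


def load_velocity_series(path: str | Path) -> VelocityEncodedSeries:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        labels = z["segment_labels"] if "segment_labels" in z.files else None
        return VelocityEncodedSeries(
            chord_arc_length_mm=z["chord_arc_length_mm"],
            waveforms=z["waveforms"],
            temporal_resolution_ms=float(meta["temporal_resolution_ms"]),
            venc_cm_per_s=float(meta["venc_cm_per_s"]),
            segment_labels=labels,
        )


def save_flow_field(field: FlowField2D, path: str | Path) -> None:
    meta = {"pixel_spacing_mm": field.pixel_spacing_mm.tolist(), "sign": "forward-positive"}
    np.savez_compressed(
        Path(path),
        velocity_cm_per_s=field.velocity_cm_per_s,
        lumen_mask=field.lumen_mask.astype(np.uint8),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_flow_field(path: str | Path) -> FlowField2D:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return FlowField2D(
            velocity_cm_per_s=z["velocity_cm_per_s"],
            lumen_mask=z["lumen_mask"] > 0,
            pixel_spacing_mm=np.asarray(meta["pixel_spacing_mm"]),
        )


def save_cohort(table: pd.DataFrame, path: str | Path, with_dictionary: bool = True) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    if with_dictionary:
        dic = path.with_suffix(".dictionary.json")
        dic.write_text(json.dumps(COLUMN_DICTIONARY, indent=2))


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
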