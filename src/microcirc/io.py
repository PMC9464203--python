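"""File formats: annotation tables, cohort CSVs, calibrated diagram images.

All formats are plain text plus standard images:

* annotations — a segment CSV (one row per vessel segment) next to a JSON
  header carrying video identity and field geometry;
* cohorts — a long-format CSV (patient_id, group, timepoint, video_id,
  metric, value), an optional per-video quality CSV with the six Massey
  factor columns, and a JSON sidecar for parameters and planted truth;
* space-time diagrams — 16-bit grayscale PNG or TIFF with a JSON sidecar
  holding the spatial (um/px) and temporal (s/row) calibration;
* deposited datasets — a schema-mapped adapter that converts an external
  table to the canonical cohort layout using a declared column mapping
  (columns are never guessed silently).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .cohort import CohortDataset, COHORT_COLUMNS
from .metrics import VesselSegment, VideoAnnotation
from .quality import MASSEY_FACTORS
from .velocity import SpaceTimeDiagram

__all__ = [
    "write_annotation",
    "read_annotation",
    "write_cohort",
    "read_cohort",
    "write_diagram",
    "read_diagram",
    "load_deposited_cohort",
]


def write_annotation(annotation: VideoAnnotation, csv_path: str | Path) -> None:
    """Segment table as CSV plus a ``.json`` header with field geometry."""
    csv_path = Path(csv_path)
    rows = []
    for s in annotation.segments:
        rows.append(
            {
                "segment_id": s.segment_id,
                "diameter_um": s.diameter_um,
                "flow_grade": s.flow_grade,
                "length_mm": s.length_mm,
                "quadrant": s.quadrant if s.polyline is None else None,
                "polyline": (
                    ";".join(f"{x:.6f},{y:.6f}" for x, y in s.polyline)
                    if s.polyline is not None
                    else None
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=["segment_id", "diameter_um", "flow_grade", "length_mm",
                 "quadrant", "polyline"],
    ).to_csv(csv_path, index=False)
    header = {
        "video_id": annotation.video_id,
        "patient_id": annotation.patient_id,
        "timepoint": annotation.timepoint,
        "field_width_mm": annotation.field_width_mm,
        "field_height_mm": annotation.field_height_mm,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_annotation(csv_path: str | Path) -> VideoAnnotation:
    csv_path = Path(csv_path)
    header = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    segments = []
    for _, row in df.iterrows():
        polyline = None
        if isinstance(row.get("polyline"), str) and row["polyline"]:
            polyline = np.array(
                [[float(v) for v in pt.split(",")] for pt in row["polyline"].split(";")]
            )
        quadrant = row.get("quadrant")
        segments.append(
            VesselSegment(
                segment_id=str(row["segment_id"]),
                diameter_um=float(row["diameter_um"]),
                flow_grade=int(row["flow_grade"]),
                polyline=polyline,
                length_mm=None if polyline is not None else float(row["length_mm"]),
                quadrant=None if pd.isna(quadrant) else int(quadrant),
            )
        )
    return VideoAnnotation(
        video_id=header["video_id"],
        patient_id=header["patient_id"],
        timepoint=header["timepoint"],
        field_width_mm=header["field_width_mm"],
        field_height_mm=header["field_height_mm"],
        segments=segments,
    )


def write_cohort(cohort: CohortDataset, out_dir: str | Path,
                 sidecar: dict | None = None) -> None:
    """Cohort as ``cohort.csv`` (+ ``quality.csv``, ``hemodynamics.csv``,
    ``cohort.json`` sidecar) in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(out / "cohort.csv", index=False)
    if cohort.quality is not None:
        cohort.quality.to_csv(out / "quality.csv", index=False)
    if cohort.hemodynamics is not None:
        cohort.hemodynamics.to_csv(out / "hemodynamics.csv", index=False)
    payload = {"meta": cohort.meta}
    if sidecar:
        payload.update(sidecar)
    (out / "cohort.json").write_text(json.dumps(payload, indent=2, default=str))


def read_cohort(in_dir: str | Path) -> CohortDataset:
    in_dir = Path(in_dir)
    data = pd.read_csv(in_dir / "cohort.csv")
    quality = None
    if (in_dir / "quality.csv").exists():
        quality = pd.read_csv(in_dir / "quality.csv")
    hemo = None
    if (in_dir / "hemodynamics.csv").exists():
        hemo = pd.read_csv(in_dir / "hemodynamics.csv")
    meta = {}
    if (in_dir / "cohort.json").exists():
        meta = json.loads((in_dir / "cohort.json").read_text()).get("meta", {})
    return CohortDataset(data=data, quality=quality, hemodynamics=hemo, meta=meta)


def write_diagram(diagram: SpaceTimeDiagram, image_path: str | Path) -> None:
    """16-bit grayscale PNG/TIFF plus a JSON calibration sidecar."""
    image_path = Path(image_path)
    img = diagram.intensity
    lo, hi = float(img.min()), float(img.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    quantized = np.round((img - lo) * scale).astype(np.uint16)
    iio.imwrite(image_path, quantized)
    sidecar = {
        "spatial_calibration_um_per_px": diagram.spatial_calibration_um_per_px,
        "temporal_calibration_s_per_row": diagram.temporal_calibration_s_per_row,
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    image_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_diagram(image_path: str | Path) -> SpaceTimeDiagram:
    image_path = Path(image_path)
    sidecar = json.loads(image_path.with_suffix(".json").read_text())
    img = np.asarray(iio.imread(image_path), dtype=float)
    img = img / sidecar.get("intensity_scale", 1.0) + sidecar.get("intensity_offset", 0.0)
    return SpaceTimeDiagram(
        intensity=img,
        spatial_calibration_um_per_px=sidecar["spatial_calibration_um_per_px"],
        temporal_calibration_s_per_row=sidecar["temporal_calibration_s_per_row"],
    )


def load_deposited_cohort(
    path: str | Path,
    column_map: Mapping[str, str],
    group_map: Mapping[str, str] | None = None,
    timepoint_map: Mapping[str, str] | None = None,
    metric_columns: Mapping[str, str] | None = None,
) -> CohortDataset:
    """Adapt an externally deposited table to the canonical cohort layout.

    ``column_map`` declares the source columns for ``patient_id``, ``group``,
    ``timepoint`` and ``video_id``.  A long source additionally maps
    ``metric`` and ``value``; a wide source instead declares
    ``metric_columns`` ({canonical metric -> source column}).  ``group_map``
    and ``timepoint_map`` translate source labels to the canonical ones.
    Missing declared columns raise ``KeyError`` naming them — nothing is
    sniffed silently.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    required = ["patient_id", "group", "timepoint", "video_id"]
    long_mode = metric_columns is None
    if long_mode:
        required += ["metric", "value"]
    missing_keys = [k for k in required if k not in column_map]
    if missing_keys:
        raise KeyError(f"column_map must declare source columns for: {missing_keys}")
    missing_cols = [column_map[k] for k in required if column_map[k] not in df.columns]
    if not long_mode and metric_columns:
        missing_cols += [c for c in metric_columns.values() if c not in df.columns]
    if missing_cols:
        raise KeyError(f"deposited table lacks declared columns: {missing_cols}")

    if long_mode:
        out = pd.DataFrame({k: df[column_map[k]] for k in required})
    else:
        frames = []
        for metric, col in metric_columns.items():
            frame = pd.DataFrame({k: df[column_map[k]] for k in required})
            frame["metric"] = metric
            frame["value"] = pd.to_numeric(df[col], errors="coerce")
            frames.append(frame)
        out = pd.concat(frames, ignore_index=True).dropna(subset=["value"])

    if group_map:
        out["group"] = out["group"].map(lambda g: group_map.get(g, g))
    if timepoint_map:
        out["timepoint"] = out["timepoint"].map(lambda t: timepoint_map.get(t, t))
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    out = out.dropna(subset=["value"]).loc[:, COHORT_COLUMNS].reset_index(drop=True)

    quality = None
    if all(f in df.columns for f in MASSEY_FACTORS):
        quality = df[[column_map["video_id"], *MASSEY_FACTORS]].rename(
            columns={column_map["video_id"]: "video_id"}
        ).drop_duplicates("video_id")
    return CohortDataset(data=out, quality=quality, meta={"source": str(path)})
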