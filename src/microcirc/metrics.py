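"""Consensus sublingual microcirculation metrics.

Per-video metrics from vessel-segment annotations of incident dark-field
(IDF) videomicroscopy:

* TVD — total vessel density, mm of small-vessel (diameter <= 20 um) length
  per mm^2 of field of view;
* PPV — proportion of perfused vessels, the length-weighted percentage of
  small-vessel length carrying continuous or sluggish flow;
* PVD — perfused vessel density, perfused small-vessel length per mm^2,
  so that PVD = TVD * PPV / 100 identically;
* MFI — microvascular flow index, the mean over the four field quadrants of
  the predominant (modal) semiquantitative flow grade (0 no flow,
  1 intermittent, 2 sluggish, 3 continuous);
* MHI — microcirculation heterogeneity index across same-timepoint videos,
  (max MFI - min MFI) / mean MFI.

Vessels wider than 30 um are excluded outright; venules (20-30 um) are kept
only for red-blood-cell velocimetry and contribute nothing to the density
metrics.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VesselSegment",
    "VideoAnnotation",
    "MicrocircMetrics",
    "TimepointSummary",
    "classify_vessel",
    "is_perfused",
    "compute_tvd",
    "compute_ppv",
    "compute_pvd",
    "compute_mfi",
    "compute_mhi",
    "compute_metrics",
    "summarize_timepoint",
]

SMALL_VESSEL_MAX_UM = 20.0   # inclusive upper bound for capillary class
VENULE_MAX_UM = 30.0         # inclusive upper bound for venule class
PERFUSED_GRADES = frozenset({2, 3})
VALID_GRADES = frozenset({0, 1, 2, 3})

Timepoint = Literal["baseline", "3min", "30min", "control"]


def polyline_length(points: np.ndarray) -> float:
    """Total euclidean length (mm) of a polyline given as an (N, 2) array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (N>=2, 2) array of mm coordinates")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class VesselSegment:
    """One annotated microvessel segment.

    Either ``polyline`` (mm coordinates within the field) or an explicit
    ``length_mm`` must be provided.  ``quadrant`` (0-3, row-major over a
    2 x 2 grid) is only needed in length mode when computing MFI.
    """

    segment_id: str
    diameter_um: float
    flow_grade: int
    polyline: np.ndarray | None = None
    length_mm: float | None = None
    quadrant: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError(f"segment {self.segment_id}: diameter must be > 0 um")
        if self.flow_grade not in VALID_GRADES:
            raise ValueError(
                f"segment {self.segment_id}: flow grade {self.flow_grade} not in {{0,1,2,3}}"
            )
        if self.polyline is not None:
            self.polyline = np.asarray(self.polyline, dtype=float)
            self.length_mm = polyline_length(self.polyline)
        if self.length_mm is None:
            raise ValueError(f"segment {self.segment_id}: needs a polyline or length_mm")
        if self.length_mm < 0:
            raise ValueError(f"segment {self.segment_id}: length must be >= 0")

    def midpoint(self) -> np.ndarray:
        if self.polyline is None:
            raise ValueError(f"segment {self.segment_id}: no geometry available")
        return self.polyline.mean(axis=0)


@dataclass
class VideoAnnotation:
    """All segment annotations for one analyzable video clip."""

    video_id: str
    patient_id: str
    timepoint: str
    field_width_mm: float
    field_height_mm: float
    segments: list[VesselSegment] = field(default_factory=list)
    massey: "object | None" = None  # quality_gating.MasseyScore when scored

    def __post_init__(self) -> None:
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValueError(
                f"video {self.video_id}: field dimensions must be positive "
                f"(got {self.field_width_mm} x {self.field_height_mm} mm)"
            )

    @property
    def area_mm2(self) -> float:
        return self.field_width_mm * self.field_height_mm

    def segment_quadrant(self, seg: VesselSegment) -> int:
        """Quadrant index (2 x 2 grid, row-major) of a segment's midpoint."""
        if seg.quadrant is not None:
            return seg.quadrant
        x, y = seg.midpoint()
        col = int(x >= self.field_width_mm / 2)
        row = int(y >= self.field_height_mm / 2)
        return 2 * row + col


@dataclass(frozen=True)
class MicrocircMetrics:
    """Per-video consensus metrics. ``ppv``/``mfi`` are None when undefined."""

    video_id: str
    tvd: float
    pvd: float
    ppv: float | None
    mfi: float | None
    rbcv: float | None = None


@dataclass(frozen=True)
class TimepointSummary:
    """Across-video means for one patient-timepoint, plus the MHI."""

    n_videos: int
    tvd: float
    pvd: float
    ppv: float | None
    mfi: float | None
    mhi: float | None
    rbcv: float | None


def classify_vessel(diameter_um: float) -> str:
    """Vessel class by lumen diameter: 'small', 'venule' or 'excluded'.

    Small vessels (<= 20 um) enter TVD/PVD/PPV/MFI; venules (20, 30] um are
    used only for RBC velocimetry; anything wider is excluded.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    if diameter_um <= SMALL_VESSEL_MAX_UM:
        return "small"
    if diameter_um <= VENULE_MAX_UM:
        return "venule"
    return "excluded"


def is_perfused(flow_grade: int) -> bool:
    """Dichotomize a flow grade: sluggish/continuous (2, 3) count as perfused."""
    if flow_grade not in VALID_GRADES:
        raise ValueError(f"flow grade {flow_grade} not in {{0,1,2,3}}")
    return flow_grade in PERFUSED_GRADES


def _small_segments(annotation: VideoAnnotation) -> list[VesselSegment]:
    return [s for s in annotation.segments if classify_vessel(s.diameter_um) == "small"]


def compute_tvd(annotation: VideoAnnotation) -> float:
    """Total small-vessel length divided by field area, mm/mm^2."""
    total = sum(s.length_mm for s in _small_segments(annotation))
    return total / annotation.area_mm2


def compute_ppv(annotation: VideoAnnotation) -> float:
    """Length-weighted percentage of perfused small-vessel length.

    Raises ``ValueError`` when the video has no small-vessel length: the
    proportion is undefined rather than zero.
    """
    small = _small_segments(annotation)
    total = sum(s.length_mm for s in small)
    if total <= 0:
        raise ValueError(
            f"video {annotation.video_id}: PPV undefined, no small-vessel length"
        )
    perfused = sum(s.length_mm for s in small if is_perfused(s.flow_grade))
    # guard the physical bound against float round-off when perfused == total
    return 100.0 if perfused >= total else 100.0 * perfused / total


def compute_pvd(annotation: VideoAnnotation) -> float:
    """Perfused small-vessel length per field area, mm/mm^2."""
    perfused = sum(
        s.length_mm for s in _small_segments(annotation) if is_perfused(s.flow_grade)
    )
    return perfused / annotation.area_mm2


def compute_mfi(
    annotation: VideoAnnotation,
    method: Literal["quadrant", "vessel"] = "quadrant",
) -> float:
    """Microvascular flow index of one video.

    ``quadrant`` (default): mean over the four field quadrants of the modal
    small-vessel flow grade in each quadrant; modal ties break toward the
    lower grade (conservative). Quadrants with no small vessel are skipped
    with a warning. ``vessel``: plain mean grade over small vessels.
    """
    small = _small_segments(annotation)
    if not small:
        raise ValueError(f"video {annotation.video_id}: MFI undefined, no small vessels")
    if method == "vessel":
        return float(np.mean([s.flow_grade for s in small]))
    if method != "quadrant":
        raise ValueError(f"unknown MFI method {method!r}")

    modes: list[int] = []
    for q in range(4):
        grades = [
            s.flow_grade for s in small if annotation.segment_quadrant(s) == q
        ]
        if not grades:
            warnings.warn(
                f"video {annotation.video_id}: quadrant {q} has no small vessels; "
                "skipped in MFI",
                stacklevel=2,
            )
            continue
        counts = Counter(grades)
        top = max(counts.values())
        modes.append(min(g for g, c in counts.items() if c == top))
    return float(np.mean(modes))


def compute_mhi(mfis: Sequence[float]) -> float:
    """Heterogeneity of MFI across one timepoint's videos: (max - min) / mean."""
    vals = [float(m) for m in mfis if m is not None]
    if len(vals) < 2:
        raise ValueError("MHI needs MFIs from at least two videos")
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError("MHI undefined: mean MFI is zero")
    return (max(vals) - min(vals)) / mean


def compute_metrics(
    annotation: VideoAnnotation, mfi_method: str = "quadrant"
) -> MicrocircMetrics:
    """All per-video metrics; PPV/MFI are None for vessel-free fields."""
    tvd = compute_tvd(annotation)
    pvd = compute_pvd(annotation)
    try:
        ppv = compute_ppv(annotation)
    except ValueError:
        ppv = None
    try:
        mfi = compute_mfi(annotation, method=mfi_method)  # type: ignore[arg-type]
    except ValueError:
        mfi = None
    return MicrocircMetrics(annotation.video_id, tvd=tvd, pvd=pvd, ppv=ppv, mfi=mfi)


def summarize_timepoint(
    videos: Sequence[MicrocircMetrics],
) -> TimepointSummary:
    """Arithmetic mean of each metric over a timepoint's videos, plus MHI.

    MHI needs at least two videos with a defined MFI and is None otherwise.
    """
    if not videos:
        raise ValueError("no quality-passing videos to summarize")

    def _mean(vals: list[float]) -> float | None:
        return float(np.mean(vals)) if vals else None

    mfis = [m.mfi for m in videos if m.mfi is not None]
    mhi: float | None
    try:
        mhi = compute_mhi(mfis)
    except ValueError:
        mhi = None
    return TimepointSummary(
        n_videos=len(videos),
        tvd=float(np.mean([m.tvd for m in videos])),
        pvd=float(np.mean([m.pvd for m in videos])),
        ppv=_mean([m.ppv for m in videos if m.ppv is not None]),
        mfi=_mean(mfis),
        mhi=mhi,
        rbcv=_mean([m.rbcv for m in videos if m.rbcv is not None]),
    )
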