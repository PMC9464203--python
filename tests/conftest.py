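"""Shared fixtures: quick annotation builders and brute-force metric oracles."""

from __future__ import annotations

import numpy as np
import pytest

from microcirc.metrics import VesselSegment, VideoAnnotation


def make_annotation(
    segments: list[tuple[float, float, int]],
    area: tuple[float, float] = (1.0, 1.0),
    quadrants: list[int] | None = None,
    video_id: str = "v0",
) -> VideoAnnotation:
    """Length-mode annotation from (length_mm, diameter_um, grade) triples."""
    quadrants = quadrants or [i % 4 for i in range(len(segments))]
    segs = [
        VesselSegment(
            segment_id=f"s{i}",
            diameter_um=d,
            flow_grade=g,
            length_mm=length,
            quadrant=q,
        )
        for i, ((length, d, g), q) in enumerate(zip(segments, quadrants))
    ]
    return VideoAnnotation(
        video_id=video_id,
        patient_id="p0",
        timepoint="baseline",
        field_width_mm=area[0],
        field_height_mm=area[1],
        segments=segs,
    )


def brute_force_metrics(annotation: VideoAnnotation) -> dict:
    """Direct-loop recomputation of TVD/PVD/PPV/MFI, independent of the
    vectorized implementation paths."""
    area = annotation.field_width_mm * annotation.field_height_mm
    total = perfused = 0.0
    per_quadrant: dict[int, list[int]] = {}
    for seg in annotation.segments:
        if seg.diameter_um > 20.0:
            continue
        total += seg.length_mm
        if seg.flow_grade in (2, 3):
            perfused += seg.length_mm
        q = annotation.segment_quadrant(seg)
        per_quadrant.setdefault(q, []).append(seg.flow_grade)
    tvd = total / area
    pvd = perfused / area
    if total > 0:
        ppv = 100.0 if perfused >= total else 100.0 * perfused / total
    else:
        ppv = None
    modes = []
    for q in sorted(per_quadrant):
        grades = per_quadrant[q]
        best_count = max(grades.count(g) for g in set(grades))
        modes.append(min(g for g in set(grades) if grades.count(g) == best_count))
    mfi = sum(modes) / len(modes) if modes else None
    return {"tvd": tvd, "pvd": pvd, "ppv": ppv, "mfi": mfi}


def random_annotation(rng: np.random.Generator, max_segments: int = 60) -> VideoAnnotation:
    """Random length-mode annotation spanning all vessel classes and grades."""
    n = int(rng.integers(1, max_segments))
    segments = [
        (float(rng.uniform(0.01, 0.6)), float(rng.uniform(3.0, 40.0)), int(rng.integers(0, 4)))
        for _ in range(n)
    ]
    quadrants = rng.integers(0, 4, size=n).tolist()
    w = float(rng.uniform(0.5, 3.0))
    h = float(rng.uniform(0.5, 3.0))
    return make_annotation(segments, area=(w, h), quadrants=quadrants)


@pytest.fixture
def annotation_factory():
    return make_annotation


@pytest.fixture
def oracle():
    return brute_force_metrics
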