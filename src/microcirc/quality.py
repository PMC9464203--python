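"""Video quality gating and inter-rater agreement.

Each video clip is scored on six factors — illumination, duration, focus,
content, stability, pressure — with penalties 0 (good), 1 (acceptable) or
10 (unacceptable). A single unacceptable factor therefore pushes the total
to >= 10, and only videos with a total score strictly below 10 enter the
analysis.

Inter-rater agreement between metric coders is quantified with Bland-Altman
bias and 95% limits of agreement on a seeded 10% subsample of videos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MasseyScore",
    "AgreementResult",
    "total_massey",
    "gate_videos",
    "bland_altman",
    "sample_for_agreement",
    "MASSEY_FACTORS",
    "MASSEY_CUTOFF",
]

MASSEY_FACTORS = ("illumination", "duration", "focus", "content", "stability", "pressure")
ALLOWED_PENALTIES = frozenset({0, 1, 10})
MASSEY_CUTOFF = 10  # videos with total >= 10 are unanalyzable


@dataclass(frozen=True)
class MasseyScore:
    illumination: int = 0
    duration: int = 0
    focus: int = 0
    content: int = 0
    stability: int = 0
    pressure: int = 0

    def __post_init__(self) -> None:
        for name in MASSEY_FACTORS:
            v = getattr(self, name)
            if v not in ALLOWED_PENALTIES:
                raise ValueError(f"Massey factor {name}={v} not in {{0, 1, 10}}")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in MASSEY_FACTORS)


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    lower_loa: float
    upper_loa: float
    n_pairs: int


def total_massey(score: MasseyScore) -> int:
    """Sum of the six factor penalties."""
    return score.total


def gate_videos(videos: Sequence) -> tuple[list, list, dict]:
    """Split videos into quality-passing and excluded by the Massey gate.

    A video is kept iff its total Massey score is strictly below 10. Every
    video must carry a ``massey`` score; a missing one raises ``ValueError``
    naming the video. Returns ``(kept, excluded, counts)``.
    """
    kept, excluded = [], []
    for v in videos:
        score = getattr(v, "massey", None)
        if score is None:
            raise ValueError(f"video {getattr(v, 'video_id', v)!r} has no Massey score")
        (kept if score.total < MASSEY_CUTOFF else excluded).append(v)
    counts = {"kept": len(kept), "excluded": len(excluded), "total": len(videos)}
    return kept, excluded, counts


def bland_altman(
    coder_a: Sequence[float], coder_b: Sequence[float]
) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement for paired measurements.

    bias = mean(a - b); limits = bias +/- 1.96 * SD(a - b) (sample SD).
    """
    a = np.asarray(coder_a, dtype=float)
    b = np.asarray(coder_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        bias=bias,
        lower_loa=bias - 1.96 * sd,
        upper_loa=bias + 1.96 * sd,
        n_pairs=int(a.size),
    )


def sample_for_agreement(
    video_ids: Sequence[str], fraction: float = 0.10, seed: int = 0
) -> list[str]:
    """Seeded uniform draw without replacement of videos for double coding.

    The sample size is ``ceil(fraction * n)`` so a non-empty input always
    yields at least one video.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = list(video_ids)
    n = int(np.ceil(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(ids, size=n, replace=False).tolist())
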