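"""Long-format cohort container shared by the analysis stages.

The canonical table has one row per (patient, timepoint, video, metric)
observation with columns::

    patient_id, group, timepoint, video_id, metric, value

``group`` is ``control`` (preoperative, single ``control`` timepoint) or
``shock`` (postoperative, timepoints ``baseline``, ``3min``, ``30min``).
Optional side tables carry per-video Massey quality factors and per-patient
hemodynamic / vasoactive-dose series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortDataset", "COHORT_COLUMNS", "GROUPS", "SHOCK_TIMEPOINTS", "METRICS"]

COHORT_COLUMNS = ["patient_id", "group", "timepoint", "video_id", "metric", "value"]
GROUPS = ("control", "shock")
SHOCK_TIMEPOINTS = ("baseline", "3min", "30min")
METRICS = ("MFI", "TVD", "PPV", "PVD", "RBCv")


@dataclass
class CohortDataset:
    """Cohort of per-video metric observations plus optional side tables."""

    data: pd.DataFrame
    quality: pd.DataFrame | None = None        # video_id + six Massey factor columns
    hemodynamics: pd.DataFrame | None = None   # patient_id, timepoint, variable, value
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.data = self.data.loc[:, COHORT_COLUMNS].copy()

    def patients(self, group: str | None = None) -> list[str]:
        df = self.data if group is None else self.data[self.data["group"] == group]
        return sorted(df["patient_id"].unique().tolist())

    def replicates(self, patient_id: str, metric: str, timepoint: str) -> np.ndarray:
        """Per-video values of one metric for one patient-timepoint."""
        sel = self.data[
            (self.data["patient_id"] == patient_id)
            & (self.data["metric"] == metric)
            & (self.data["timepoint"] == timepoint)
        ]
        return sel["value"].to_numpy(dtype=float)

    def timepoint_means(self, metric: str) -> pd.DataFrame:
        """Patient x timepoint table of across-video means for one metric."""
        sub = self.data[self.data["metric"] == metric]
        return sub.pivot_table(
            index="patient_id", columns="timepoint", values="value", aggfunc="mean"
        )

    def group_values(self, metric: str, group: str, timepoint: str) -> np.ndarray:
        """Per-patient means of one metric for one group at one timepoint."""
        sub = self.data[
            (self.data["metric"] == metric)
            & (self.data["group"] == group)
            & (self.data["timepoint"] == timepoint)
        ]
        return sub.groupby("patient_id")["value"].mean().to_numpy(dtype=float)

    def apply_quality_gate(self, cutoff: int = 10) -> "CohortDataset":
        """Drop observations from videos whose total Massey score >= cutoff."""
        if self.quality is None:
            return self
        from .quality import MASSEY_FACTORS

        totals = self.quality[list(MASSEY_FACTORS)].sum(axis=1)
        bad = set(self.quality.loc[totals >= cutoff, "video_id"])
        kept = self.data[~self.data["video_id"].isin(bad)].reset_index(drop=True)
        return CohortDataset(
            data=kept,
            quality=self.quality,
            hemodynamics=self.hemodynamics,
            meta={**self.meta, "n_videos_excluded": len(bad)},
        )

    def subset_patients(self, patient_ids: Sequence[str]) -> "CohortDataset":
        keep = self.data["patient_id"].isin(set(patient_ids))
        return CohortDataset(
            data=self.data[keep].reset_index(drop=True),
            quality=self.quality,
            hemodynamics=self.hemodynamics,
            meta=dict(self.meta),
        )
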