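"""Individual pharmacodynamic responder statistic for the topical challenge.

A patient-specific response threshold is derived from measurement noise
alone: each shock patient contributes the sample variance of their three
baseline PVD video replicates, those variances are averaged (pooled) across
the cohort, and the pooled SD is the square root.  A patient is a responder
when their PVD increase from baseline to 3 minutes post-dose strictly
exceeds ``k`` pooled SDs, with the default ``k = 1.8`` chosen for a
one-sided 90% confidence bound (only an increase is anticipated).

The classifier follows the scikit-learn estimator protocol: ``fit`` learns
the pooled SD and threshold from baseline replicate arrays, ``predict``
labels PVD deltas.  :func:`classify_responders` wraps it for long-format
cohort tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortDataset

__all__ = [
    "BaselineTriplet",
    "ResponderResult",
    "ResponderClassifier",
    "pooled_baseline_sd",
    "response_threshold",
    "classify_responders",
    "audit_printed_threshold",
]

DEFAULT_K = 1.8  # one-sided 90% confidence multiplier


@dataclass(frozen=True)
class BaselineTriplet:
    """One patient's baseline PVD video replicates (normally three)."""

    patient_id: str
    pvd_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pvd_replicates) < 2:
            raise ValueError(
                f"patient {self.patient_id}: needs >= 2 baseline replicates for a variance"
            )
        if any(v < 0 for v in self.pvd_replicates):
            raise ValueError(f"patient {self.patient_id}: PVD cannot be negative")

    @property
    def variance(self) -> float:
        return float(np.var(self.pvd_replicates, ddof=1))


@dataclass
class ResponderResult:
    """Cohort-level responder classification output."""

    pooled_sd: float
    k: float
    threshold: float
    table: pd.DataFrame  # patient_id, delta_pvd, threshold, label
    n_responders: int
    n_nonresponders: int
    excluded: list[str]


def pooled_baseline_sd(triplets: list[BaselineTriplet]) -> float:
    """Pooled intra-patient baseline SD: sqrt of the mean of per-patient
    sample variances (n-1 denominator)."""
    if not triplets:
        raise ValueError("no baseline replicate sets supplied")
    return float(np.sqrt(np.mean([t.variance for t in triplets])))


def response_threshold(pooled_sd: float, k: float = DEFAULT_K) -> float:
    """Responder threshold on the PVD increase, ``k * pooled_sd`` mm/mm^2."""
    if pooled_sd < 0:
        raise ValueError("pooled SD cannot be negative")
    if k <= 0:
        raise ValueError("multiplier k must be positive")
    return k * pooled_sd


class ResponderClassifier(BaseEstimator):
    """Pooled-variance pharmacodynamic responder classifier.

    Parameters
    ----------
    k : float
        Threshold multiplier on the pooled baseline SD (default 1.8, the
        one-sided 90% confidence choice).

    Attributes (after ``fit``)
    --------------------------
    pooled_sd_ : float
        Pooled intra-patient baseline SD.
    threshold_ : float
        ``k * pooled_sd_``; a delta strictly above it is a response.
    n_patients_ : int
        Number of patients pooled.
    """

    def __init__(self, k: float = DEFAULT_K):
        self.k = k

    def fit(self, X, y=None) -> "ResponderClassifier":
        """Learn the threshold from baseline replicates.

        ``X`` is an (n_patients, n_replicates) array or a sequence of
        per-patient replicate sequences (each of length >= 2).
        """
        variances = []
        for i, reps in enumerate(X):
            reps = np.asarray(reps, dtype=float)
            if reps.size < 2:
                raise ValueError(f"patient index {i}: needs >= 2 baseline replicates")
            variances.append(np.var(reps, ddof=1))
        if not variances:
            raise ValueError("no baseline replicate sets supplied")
        self.pooled_sd_ = float(np.sqrt(np.mean(variances)))
        self.threshold_ = response_threshold(self.pooled_sd_, self.k)
        self.n_patients_ = len(variances)
        return self

    def predict(self, deltas) -> np.ndarray:
        """Label PVD deltas: True = responder (delta strictly > threshold)."""
        if not hasattr(self, "threshold_"):
            raise ValueError("classifier is not fitted")
        return np.asarray(deltas, dtype=float) > self.threshold_


def classify_responders(
    cohort: CohortDataset,
    metric: str = "PVD",
    k: float = DEFAULT_K,
    post_timepoint: str = "3min",
) -> ResponderResult:
    """Classify every shock patient of a cohort as responder / non-responder.

    The per-patient delta is the across-video mean at ``post_timepoint``
    minus the across-video mean at baseline.  Patients with fewer than two
    baseline replicates, or with no post-dose videos, are excluded with a
    warning and listed in the result.
    """
    shock = cohort.patients("shock")
    baselines: dict[str, np.ndarray] = {}
    deltas: dict[str, float] = {}
    excluded: list[str] = []
    for pid in shock:
        base = cohort.replicates(pid, metric, "baseline")
        post = cohort.replicates(pid, metric, post_timepoint)
        if base.size < 2:
            warnings.warn(
                f"patient {pid}: fewer than two baseline {metric} videos; excluded",
                stacklevel=2,
            )
            excluded.append(pid)
            continue
        if post.size == 0:
            warnings.warn(
                f"patient {pid}: no {post_timepoint} {metric} videos; excluded",
                stacklevel=2,
            )
            excluded.append(pid)
            continue
        baselines[pid] = base
        deltas[pid] = float(post.mean() - base.mean())

    if not baselines:
        raise ValueError("no shock patient has usable baseline replicates")

    clf = ResponderClassifier(k=k).fit(list(baselines.values()))
    pids = list(deltas)
    labels = clf.predict([deltas[p] for p in pids])
    table = pd.DataFrame(
        {
            "patient_id": pids,
            "delta_pvd": [deltas[p] for p in pids],
            "threshold": clf.threshold_,
            "label": np.where(labels, "responder", "non-responder"),
        }
    )
    return ResponderResult(
        pooled_sd=clf.pooled_sd_,
        k=k,
        threshold=clf.threshold_,
        table=table,
        n_responders=int(labels.sum()),
        n_nonresponders=int((~labels).sum()),
        excluded=excluded,
    )


def audit_printed_threshold(
    pooled_sd: float, printed_threshold: float, k: float = DEFAULT_K, decimals: int = 2
) -> dict:
    """Check a published threshold against the one derived from a pooled SD.

    Useful when a report prints both a rounded pooled SD and a threshold
    computed from the unrounded SD: ``1.8 * 3.03 = 5.454`` rounds to 5.45,
    so a printed 5.46 flags that the published value used more precision
    than the printed SD. Returns the derived threshold, both rounded forms
    and a ``consistent`` flag.
    """
    derived = response_threshold(pooled_sd, k)
    consistent = round(derived, decimals) == round(printed_threshold, decimals)
    return {
        "pooled_sd": pooled_sd,
        "k": k,
        "derived_threshold": derived,
        "printed_threshold": printed_threshold,
        "consistent": consistent,
        "rounding_mismatch": not consistent,
    }
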