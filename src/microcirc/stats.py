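"""Cohort-level statistics and report tables.

Implements the study-style statistical workflow on a gated cohort:

* normality-gated two-group comparisons (D'Agostino-Pearson omnibus test at
  alpha = 0.05 routing to Student t or Mann-Whitney U);
* one-way repeated-measures ANOVA over the three challenge timepoints with
  Tukey-adjusted pairwise contrasts against baseline (studentized-range
  distribution on the within-subject error term);
* vasoactive summary scores (vasopressor-inotrope score and norepinephrine
  equivalents) with configurable coefficient tables;
* report rendering: machine-readable control-vs-shock, challenge-timecourse
  and responder-vs-non-responder tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortDataset, METRICS

__all__ = [
    "GroupComparison",
    "RepeatedMeasuresResult",
    "VasoactiveRecord",
    "normality_gate",
    "compare_groups",
    "repeated_measures",
    "vis_score",
    "norepinephrine_equivalents",
    "patient_mhi",
    "render_report",
    "DEFAULT_VIS_COEFFICIENTS",
    "DEFAULT_NOREPI_EQUIVALENCE",
]

NORMALITY_ALPHA = 0.05
NORMALITY_MIN_N = 8  # validity floor of the D'Agostino-Pearson omnibus test


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str          # "t", "mann-whitney" or "none"
    p_value: float | None


@dataclass(frozen=True)
class RepeatedMeasuresResult:
    metric: str
    timepoints: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    n_patients: int
    n_dropped: int
    f_statistic: float
    df_effect: float
    df_error: float
    p_omnibus: float
    pairwise_vs_baseline: dict  # timepoint -> Tukey-adjusted p


@dataclass(frozen=True)
class VasoactiveRecord:
    drug: str
    dose: float
    unit: str  # "ug/kg/min", "ug/min", "units/min" or "units/kg/min"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"{self.drug}: dose cannot be negative")


def normality_gate(values: Sequence[float]) -> str:
    """Classify a sample as 'normal' or 'non-normal' at alpha = 0.05.

    Uses the D'Agostino-Pearson omnibus test.  Below its validity floor of
    eight observations, or for a constant sample, the gate defaults to
    'non-normal' with a warning, routing downstream comparisons to the
    rank-based test.
    """
    x = np.asarray(values, dtype=float)
    if x.size < NORMALITY_MIN_N:
        warnings.warn(
            f"n={x.size} below the omnibus normality test's validity floor "
            f"({NORMALITY_MIN_N}); treating as non-normal",
            stacklevel=2,
        )
        return "non-normal"
    if np.ptp(x) == 0:
        warnings.warn("constant sample; treating as non-normal", stacklevel=2)
        return "non-normal"
    _, p = sps.normaltest(x)
    return "normal" if p >= NORMALITY_ALPHA else "non-normal"


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], metric: str = ""
) -> GroupComparison:
    """Two-group comparison with normality-gated test selection.

    Both groups normal by :func:`normality_gate` -> two-sided Student t test
    (equal variances); otherwise two-sided Mann-Whitney U.  Groups of size
    one get descriptives only (p undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    def _desc(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0

    mean_a, sd_a = _desc(a)
    mean_b, sd_b = _desc(b)

    if a.size == 1 or b.size == 1:
        return GroupComparison(metric, mean_a, sd_a, a.size, mean_b, sd_b, b.size, "none", None)

    if np.array_equal(np.sort(a), np.sort(b)):
        # Degenerate identical groups: no evidence of any difference.
        return GroupComparison(metric, mean_a, sd_a, a.size, mean_b, sd_b, b.size, "t", 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = normality_gate(a) == "normal" and normality_gate(b) == "normal"
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    p = 1.0 if np.isnan(p) else float(p)
    return GroupComparison(metric, mean_a, sd_a, a.size, mean_b, sd_b, b.size, test, p)


def repeated_measures(
    wide: pd.DataFrame,
    timepoints: Sequence[str] = ("baseline", "3min", "30min"),
    metric: str = "",
    greenhouse_geisser: bool = False,
) -> RepeatedMeasuresResult:
    """One-way repeated-measures ANOVA with Tukey contrasts against baseline.

    ``wide`` holds one row per patient and one column per timepoint.
    Patients missing any timepoint are dropped listwise (count reported).
    The omnibus F uses the standard within-subject decomposition,
    sphericity-uncorrected by default; ``greenhouse_geisser=True`` scales
    both degrees of freedom by the Greenhouse-Geisser epsilon.  Pairwise
    p-values use the studentized-range distribution with the ANOVA error
    mean square, i.e. Tukey's HSD on the within-subject error.
    """
    cols = list(timepoints)
    sub = wide.loc[:, cols].dropna(axis=0)
    n_dropped = len(wide) - len(sub)
    n, k = sub.shape
    if n < 3:
        raise ValueError(f"repeated-measures ANOVA needs >= 3 complete patients, got {n}")

    y = sub.to_numpy(dtype=float)
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_time = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = max(ss_total - ss_subj - ss_time, 0.0)
    df_time = float(k - 1)
    df_err = float((n - 1) * (k - 1))

    if greenhouse_geisser:
        import pingouin as pg

        eps = float(pg.epsilon(sub, correction="gg"))
        df_time *= eps
        df_err *= eps

    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_stat = np.inf if ms_time > 0 else 0.0
        p_omni = 0.0 if ms_time > 0 else 1.0
    else:
        f_stat = ms_time / ms_err
        p_omni = float(sps.f.sf(f_stat, df_time, df_err))

    pairwise: dict[str, float] = {}
    base = col_means[0]
    for j, tp in enumerate(cols[1:], start=1):
        if ms_err == 0:
            pairwise[tp] = 1.0 if col_means[j] == base else 0.0
            continue
        q = abs(col_means[j] - base) / np.sqrt(ms_err / n)
        pairwise[tp] = float(sps.studentized_range.sf(q, k, (n - 1) * (k - 1)))

    return RepeatedMeasuresResult(
        metric=metric,
        timepoints=tuple(cols),
        means=tuple(float(m) for m in col_means),
        sds=tuple(float(s) for s in y.std(axis=0, ddof=1)),
        n_patients=n,
        n_dropped=n_dropped,
        f_statistic=float(f_stat),
        df_effect=df_time,
        df_error=df_err,
        p_omnibus=p_omni,
        pairwise_vs_baseline=pairwise,
    )


# Vasopressor-inotrope score coefficients; each entry maps the drug to its
# weight and the dosing unit the weight applies to.
DEFAULT_VIS_COEFFICIENTS: dict[str, tuple[float, str]] = {
    "dopamine": (1.0, "ug/kg/min"),
    "dobutamine": (1.0, "ug/kg/min"),
    "epinephrine": (100.0, "ug/kg/min"),
    "norepinephrine": (100.0, "ug/kg/min"),
    "milrinone": (10.0, "ug/kg/min"),
    "vasopressin": (10000.0, "units/kg/min"),
    "phenylephrine": (10.0, "ug/kg/min"),
}

# Norepinephrine-equivalence factors, each on the drug's listed unit; the
# result is an equivalent norepinephrine rate in ug/kg/min.
DEFAULT_NOREPI_EQUIVALENCE: dict[str, tuple[float, str]] = {
    "norepinephrine": (1.0, "ug/kg/min"),
    "epinephrine": (1.0, "ug/kg/min"),
    "dopamine": (0.01, "ug/kg/min"),
    "phenylephrine": (0.1, "ug/kg/min"),
    "vasopressin": (2.5, "units/min"),
}

DEFAULT_WEIGHT_KG = 80.0


def _convert_dose(
    record: VasoactiveRecord, target_unit: str, weight_kg: float | None
) -> float:
    """Convert a dose to ``target_unit``, dividing or multiplying by patient
    weight where the units differ only by the /kg normalization."""
    if record.unit == target_unit:
        return record.dose
    per_kg_pairs = {("ug/min", "ug/kg/min"), ("units/min", "units/kg/min")}
    inv_pairs = {(b, a) for a, b in per_kg_pairs}
    if weight_kg is None:
        warnings.warn(
            f"{record.drug}: patient weight missing, assuming {DEFAULT_WEIGHT_KG} kg",
            stacklevel=3,
        )
        weight_kg = DEFAULT_WEIGHT_KG
    if (record.unit, target_unit) in per_kg_pairs:
        return record.dose / weight_kg
    if (record.unit, target_unit) in inv_pairs:
        return record.dose * weight_kg
    raise ValueError(
        f"{record.drug}: cannot convert dose unit {record.unit!r} to {target_unit!r}"
    )


def vis_score(
    records: Sequence[VasoactiveRecord],
    weight_kg: float | None = None,
    coefficients: Mapping[str, tuple[float, str]] | None = None,
) -> float:
    """Vasopressor-inotrope score: weighted sum of vasoactive infusion rates.

    Default coefficients: dopamine + dobutamine + 100 x epinephrine +
    100 x norepinephrine + 10 x milrinone (all ug/kg/min) + 10,000 x
    vasopressin (units/kg/min) + 10 x phenylephrine (ug/kg/min).  Doses
    reported without weight normalization (e.g. phenylephrine in ug/min)
    are divided by patient weight first.
    """
    coeffs = dict(coefficients or DEFAULT_VIS_COEFFICIENTS)
    total = 0.0
    for rec in records:
        if rec.drug not in coeffs:
            raise ValueError(
                f"unknown drug {rec.drug!r}; supported: {sorted(coeffs)}"
            )
        coef, unit = coeffs[rec.drug]
        total += coef * _convert_dose(rec, unit, weight_kg)
    return total


def norepinephrine_equivalents(
    records: Sequence[VasoactiveRecord],
    weight_kg: float | None = None,
    factors: Mapping[str, tuple[float, str]] | None = None,
) -> float:
    """Summed norepinephrine-equivalent infusion rate, ug/kg/min.

    The per-drug potency factors are configurable; the defaults treat
    epinephrine as equipotent, dopamine at 1:100, phenylephrine at 1:10 and
    vasopressin at 2.5 (ug/kg/min of norepinephrine per unit/min).
    """
    table = dict(factors or DEFAULT_NOREPI_EQUIVALENCE)
    total = 0.0
    for rec in records:
        if rec.drug not in table:
            raise ValueError(
                f"unknown drug {rec.drug!r}; supported: {sorted(table)}"
            )
        factor, unit = table[rec.drug]
        total += factor * _convert_dose(rec, unit, weight_kg)
    return total


def patient_mhi(cohort: CohortDataset, group: str, timepoint: str) -> pd.Series:
    """Per-patient MFI heterogeneity (max-min)/mean across a timepoint's
    videos; NaN where fewer than two MFI videos exist."""
    sub = cohort.data[
        (cohort.data["metric"] == "MFI")
        & (cohort.data["group"] == group)
        & (cohort.data["timepoint"] == timepoint)
    ]

    def _mhi(v: pd.Series) -> float:
        if len(v) < 2 or v.mean() == 0:
            return np.nan
        return (v.max() - v.min()) / v.mean()

    return sub.groupby("patient_id")["value"].apply(_mhi)


def _fmt(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def render_report(
    cohort: CohortDataset,
    responder_table: pd.DataFrame | None = None,
    metrics: Sequence[str] = METRICS,
) -> dict[str, pd.DataFrame]:
    """Emit the study-shaped summary tables from a gated cohort.

    Returns machine-readable DataFrames:

    * ``group_comparison`` — control vs shock baseline, per metric (+ MHI),
      with the test used and its p-value;
    * ``challenge_timecourse`` — shock baseline / 3 min / 30 min means with
      repeated-measures omnibus p and Tukey contrasts (``p_ntg`` for 3 min
      vs baseline, ``p_post`` for 30 min vs baseline);
    * ``responder_baseline`` — responder vs non-responder baseline values
      (only when a responder table is supplied).
    """
    all_metrics = list(metrics) + ["MHI"]

    def _values(metric: str, group: str, timepoint: str) -> np.ndarray:
        if metric == "MHI":
            return patient_mhi(cohort, group, timepoint).dropna().to_numpy()
        return cohort.group_values(metric, group, timepoint)

    rows = []
    for m in all_metrics:
        ctrl = _values(m, "control", "control")
        shock = _values(m, "shock", "baseline")
        if ctrl.size == 0 or shock.size == 0:
            warnings.warn(f"{m}: a group is empty; comparison skipped", stacklevel=2)
            continue
        c = compare_groups(ctrl, shock, metric=m)
        rows.append(
            {
                "metric": m,
                "control": _fmt(c.mean_a, c.sd_a),
                "shock": _fmt(c.mean_b, c.sd_b),
                "control_mean": c.mean_a,
                "control_sd": c.sd_a,
                "shock_mean": c.mean_b,
                "shock_sd": c.sd_b,
                "test": c.test,
                "p": c.p_value,
            }
        )
    group_comparison = pd.DataFrame(rows)

    rows = []
    for m in all_metrics:
        if m == "MHI":
            parts = {
                tp: patient_mhi(cohort, "shock", tp) for tp in ("baseline", "3min", "30min")
            }
            wide = pd.DataFrame(parts)
        else:
            wide = cohort.timepoint_means(m)
            wide = wide.loc[wide.index.isin(cohort.patients("shock"))]
            wide = wide.reindex(columns=["baseline", "3min", "30min"])
        try:
            rm = repeated_measures(wide, metric=m)
        except (ValueError, KeyError) as err:
            warnings.warn(f"{m}: repeated measures skipped ({err})", stacklevel=2)
            continue
        rows.append(
            {
                "metric": m,
                "baseline": _fmt(rm.means[0], rm.sds[0]),
                "3min": _fmt(rm.means[1], rm.sds[1]),
                "30min": _fmt(rm.means[2], rm.sds[2]),
                "p_omnibus": rm.p_omnibus,
                "p_ntg": rm.pairwise_vs_baseline["3min"],
                "p_post": rm.pairwise_vs_baseline["30min"],
                "n_patients": rm.n_patients,
            }
        )
    timecourse = pd.DataFrame(rows)

    report = {"group_comparison": group_comparison, "challenge_timecourse": timecourse}

    if responder_table is not None:
        resp = set(responder_table.loc[responder_table["label"] == "responder", "patient_id"])
        nonresp = set(
            responder_table.loc[responder_table["label"] == "non-responder", "patient_id"]
        )
        rows = []
        for m in all_metrics:
            if m == "MHI":
                series = patient_mhi(cohort, "shock", "baseline").dropna()
                a = series[series.index.isin(resp)].to_numpy()
                b = series[series.index.isin(nonresp)].to_numpy()
            else:
                sub = cohort.data[
                    (cohort.data["metric"] == m)
                    & (cohort.data["timepoint"] == "baseline")
                ]
                means = sub.groupby("patient_id")["value"].mean()
                a = means[means.index.isin(resp)].to_numpy()
                b = means[means.index.isin(nonresp)].to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            c = compare_groups(a, b, metric=m)
            rows.append(
                {
                    "metric": m,
                    "responder": _fmt(c.mean_a, c.sd_a),
                    "non_responder": _fmt(c.mean_b, c.sd_b),
                    "test": c.test,
                    "p": c.p_value,
                }
            )
        report["responder_baseline"] = pd.DataFrame(rows)

    return report
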