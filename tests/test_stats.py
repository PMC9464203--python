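"""Cohort statistics: test routing, repeated measures, vasoactive scores."""

import numpy as np
import pandas as pd
import pytest

from microcirc.responders import classify_responders
from microcirc.simulate import CohortParams, generate_cohort
from microcirc.stats import (
    VasoactiveRecord,
    compare_groups,
    norepinephrine_equivalents,
    normality_gate,
    render_report,
    repeated_measures,
    vis_score,
)


def test_normality_gate_on_gaussian_and_skewed_samples():
    rng = np.random.default_rng(0)
    normal_hits = sum(
        normality_gate(np.random.default_rng(s).normal(size=500)) == "normal"
        for s in range(40)
    )
    assert normal_hits >= 36  # nominal 5% level
    assert normality_gate(rng.exponential(size=500)) == "non-normal"


def test_normality_gate_validity_floor_and_constant_input():
    with pytest.warns(UserWarning, match="validity floor"):
        assert normality_gate([1.0, 2.0, 3.0, 4.0, 5.0]) == "non-normal"
    with pytest.warns(UserWarning, match="constant"):
        assert normality_gate([2.0] * 50) == "non-normal"


def test_identical_groups_compare_with_p_one():
    c = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.p_value == 1.0


def test_single_observation_group_gets_descriptives_only():
    c = compare_groups([5.0], [1.0, 2.0, 3.0])
    assert c.p_value is None and c.test == "none"
    assert c.mean_a == 5.0


def test_skewed_groups_route_to_mann_whitney():
    rng = np.random.default_rng(1)
    a = rng.exponential(size=100)
    b = rng.exponential(size=100) + 1.0
    c = compare_groups(a, b)
    assert c.test == "mann-whitney"
    assert c.p_value < 0.05


def test_planted_shift_detected_with_adequate_power():
    """A 1.3 SD shift at n=20/20 is significant in >= 80% of seeds."""
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(1.3, 1.0, size=20)
        c = compare_groups(a, b)
        hits += c.p_value is not None and c.p_value < 0.05
    assert hits / n_seeds >= 0.80


def test_table_calibrated_pvd_groups_differ():
    """Groups drawn at the study's control/shock baseline PVD distributions
    separate at p < 0.001 for most seeds."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        ctrl = rng.normal(24.81, 3.51, size=20)
        shock = rng.normal(20.44, 3.38, size=20)
        c = compare_groups(ctrl, shock)
        hits += c.p_value < 0.001
    # power at the p < 0.001 level is ~0.65 for these distributions
    assert hits >= 25


def _panel(rng, n=12, effect_3min=0.0, effect_30min=0.0, sd=1.0):
    subject = rng.normal(0, 2.0, size=n)
    return pd.DataFrame(
        {
            "baseline": subject + rng.normal(0, sd, size=n),
            "3min": subject + effect_3min + rng.normal(0, sd, size=n),
            "30min": subject + effect_30min + rng.normal(0, sd, size=n),
        }
    )


def test_repeated_measures_agrees_with_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(3)
    wide = _panel(rng, effect_3min=1.0)
    rm = repeated_measures(wide)
    long = wide.reset_index().melt(
        id_vars="index", var_name="timepoint", value_name="value"
    )
    ref = pg.rm_anova(data=long, dv="value", within="timepoint", subject="index")
    assert rm.f_statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
    assert rm.p_omnibus == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


def test_repeated_measures_flat_panel_and_minimum_size():
    wide = pd.DataFrame({"baseline": [1.0, 2.0, 3.0],
                         "3min": [1.0, 2.0, 3.0],
                         "30min": [1.0, 2.0, 3.0]})
    rm = repeated_measures(wide)
    assert rm.p_omnibus == 1.0
    with pytest.raises(ValueError, match="3 complete"):
        repeated_measures(wide.iloc[:2])


def test_transient_effect_shows_ntg_but_not_post_contrast():
    """A planted 3-minute effect that vanishes by 30 minutes yields a
    significant 3-min contrast and a non-significant 30-min contrast."""
    rng = np.random.default_rng(7)
    wide = _panel(rng, n=20, effect_3min=2.0, effect_30min=0.0, sd=0.8)
    rm = repeated_measures(wide)
    assert rm.p_omnibus < 0.001
    assert rm.pairwise_vs_baseline["3min"] < 0.01
    assert rm.pairwise_vs_baseline["30min"] > 0.05


def test_listwise_deletion_reported():
    rng = np.random.default_rng(11)
    wide = _panel(rng, n=10)
    wide.loc[0, "3min"] = np.nan
    rm = repeated_measures(wide)
    assert rm.n_patients == 9 and rm.n_dropped == 1


def test_permutation_destroys_significance_at_nominal_rate():
    """Permuting timepoint labels within patients leaves a true effect
    undetectable at roughly the nominal false-positive rate."""
    rng = np.random.default_rng(13)
    wide = _panel(rng, n=12, effect_3min=2.0, sd=0.8)
    hits = 0
    n_perm = 200
    for _ in range(n_perm):
        permuted = wide.to_numpy().copy()
        for row in permuted:
            rng.shuffle(row)
        pm = repeated_measures(pd.DataFrame(permuted, columns=wide.columns))
        hits += pm.p_omnibus < 0.05
    assert hits / n_perm == pytest.approx(0.05, abs=0.05)


def test_vis_score_coefficients():
    assert vis_score([]) == 0.0
    assert vis_score([VasoactiveRecord("epinephrine", 0.04, "ug/kg/min")]) == pytest.approx(4.0)
    combo = [
        VasoactiveRecord("epinephrine", 0.04, "ug/kg/min"),
        VasoactiveRecord("norepinephrine", 0.07, "ug/kg/min"),
    ]
    assert vis_score(combo) == pytest.approx(11.0)


def test_vis_score_is_linear_in_each_dose():
    rec = [VasoactiveRecord("milrinone", 0.125, "ug/kg/min")]
    doubled = [VasoactiveRecord("milrinone", 0.25, "ug/kg/min")]
    assert vis_score(doubled) == pytest.approx(2 * vis_score(rec))


def test_vis_score_weight_normalizes_per_minute_units():
    rec = [VasoactiveRecord("phenylephrine", 25.0, "ug/min")]
    assert vis_score(rec, weight_kg=100.0) == pytest.approx(10 * 25.0 / 100.0)
    with pytest.warns(UserWarning, match="80"):
        default = vis_score(rec)
    assert default == pytest.approx(10 * 25.0 / 80.0)


def test_vis_score_unknown_drug_lists_supported():
    with pytest.raises(ValueError, match="supported"):
        vis_score([VasoactiveRecord("caffeine", 1.0, "ug/kg/min")])


def test_norepinephrine_equivalents_defaults():
    assert norepinephrine_equivalents(
        [VasoactiveRecord("norepinephrine", 0.07, "ug/kg/min")]
    ) == pytest.approx(0.07)
    assert norepinephrine_equivalents(
        [VasoactiveRecord("epinephrine", 0.05, "ug/kg/min")]
    ) == pytest.approx(0.05)
    assert norepinephrine_equivalents([]) == 0.0


def test_render_report_tables_shape_and_pattern():
    """Tables rendered from a synthetic cohort sit near the calibration
    means, and the timecourse shows the transient challenge pattern."""
    cohort, _ = generate_cohort(CohortParams(seed=4, n_control=40, n_shock=40))
    gated = cohort.apply_quality_gate()
    responders = classify_responders(gated)
    tables = render_report(gated, responder_table=responders.table)
    gc = tables["group_comparison"].set_index("metric")
    assert gc.loc["PVD", "control_mean"] == pytest.approx(24.81, abs=2.0)
    assert gc.loc["PVD", "shock_mean"] == pytest.approx(20.44, abs=2.0)
    assert gc.loc["PVD", "p"] < 0.01
    tc = tables["challenge_timecourse"].set_index("metric")
    assert tc.loc["PVD", "p_ntg"] < 0.01      # 3-min effect present
    assert tc.loc["PVD", "p_post"] > 0.05     # reverted at 30 min
    rb = tables["responder_baseline"]
    assert set(rb.columns) >= {"metric", "responder", "non_responder", "p"}
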