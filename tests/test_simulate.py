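"""Generators: determinism, planted truth, distributional calibration."""

import numpy as np
import pytest

from microcirc.metrics import compute_metrics, compute_ppv, compute_tvd
from microcirc.simulate import (
    CohortParams,
    FlowProfile,
    VesselMapParams,
    assign_flow_grades,
    generate_cohort,
    generate_space_time_diagram,
    generate_vessel_map,
)


def test_empty_vessel_map_has_zero_truth():
    ann, truth = generate_vessel_map(
        VesselMapParams(n_small_vessels=0, n_venules=0, seed=0)
    )
    assert ann.segments == []
    assert truth.true_lengths_mm == {"small": 0.0, "venule": 0.0}


def test_target_tvd_controls_total_small_length():
    """At a target density of 22.47 mm/mm^2 on a 1.55 x 1.16 mm field the
    planted small-vessel length is 22.47 * 1.798 = 40.40 mm within 1%."""
    params = VesselMapParams(target_tvd=22.47, seed=1)
    ann, truth = generate_vessel_map(params)
    area = params.field_width_mm * params.field_height_mm
    assert truth.true_lengths_mm["small"] == pytest.approx(22.47 * area, rel=0.01)
    assert compute_tvd(ann) == pytest.approx(22.47, rel=0.01)


def test_vessel_map_is_deterministic_and_in_field():
    p = VesselMapParams(seed=42)
    ann1, _ = generate_vessel_map(p)
    ann2, _ = generate_vessel_map(p)
    assert len(ann1.segments) == len(ann2.segments)
    for s1, s2 in zip(ann1.segments, ann2.segments):
        assert np.array_equal(s1.polyline, s2.polyline)
        assert s1.diameter_um == s2.diameter_um
        assert np.all(s1.polyline[:, 0] >= 0) and np.all(s1.polyline[:, 0] <= p.field_width_mm)
        assert np.all(s1.polyline[:, 1] >= 0) and np.all(s1.polyline[:, 1] <= p.field_height_mm)


def test_vessel_map_rejects_degenerate_params():
    with pytest.raises(ValueError, match="zero-area|positive"):
        VesselMapParams(field_width_mm=0.0)
    with pytest.raises(ValueError):
        VesselMapParams(small_diameter_range_um=(10.0, 25.0))
    with pytest.raises(ValueError):
        VesselMapParams(n_small_vessels=-1)


def test_construction_consistency_of_metrics_on_noiseless_maps():
    """Metrics computed on a generated annotation equal the planted truth."""
    params = VesselMapParams(seed=3, target_tvd=20.0)
    ann, truth = generate_vessel_map(params)
    area = params.field_width_mm * params.field_height_mm
    m = compute_metrics(ann)
    assert m.tvd == pytest.approx(truth.true_lengths_mm["small"] / area, rel=1e-9)
    assert m.ppv == 100.0 and m.pvd == pytest.approx(m.tvd, rel=1e-9)


def test_flow_profile_validation():
    with pytest.raises(ValueError):
        FlowProfile((0.5, 0.5, 0.5, -0.5))
    with pytest.raises(ValueError):
        FlowProfile((0.3, 0.3, 0.3, 0.2))


def test_degenerate_flow_profiles_pin_ppv():
    ann, _ = generate_vessel_map(VesselMapParams(seed=4, n_venules=0))
    all3 = assign_flow_grades(ann, FlowProfile((0, 0, 0, 1)), seed=0)
    assert compute_ppv(all3) == 100.0
    all0 = assign_flow_grades(ann, FlowProfile((1, 0, 0, 0)), seed=0)
    assert compute_ppv(all0) == 0.0


def test_grade_frequencies_converge_to_profile():
    """Grade-3 fraction over 10,000 segments matches the profile within a
    few binomial standard errors (SE = sqrt(0.6*0.4/10000) = 0.0049)."""
    from conftest import make_annotation

    ann = make_annotation([(0.1, 10.0, 0)] * 10_000)
    graded = assign_flow_grades(ann, FlowProfile((0.1, 0.1, 0.2, 0.6)), seed=8)
    grades = np.array([s.flow_grade for s in graded.segments])
    assert np.mean(grades == 3) == pytest.approx(0.6, abs=0.015)


def test_diagram_slope_matches_closed_form():
    # 500 um/s at 1 um/px and 0.05 s/row advances 25 px per row
    _, truth = generate_space_time_diagram(500.0, 1.0, 0.05, seed=0)
    assert truth.true_slope_px_per_row == pytest.approx(25.0)


def test_noiseless_single_streak_is_a_clean_line():
    d, _ = generate_space_time_diagram(200.0, n_streaks=1, noise_sd=0.0, seed=1)
    # exactly one bump per row, amplitude ~1, zero background far away
    row = d.intensity[0]
    assert row.max() == pytest.approx(1.0, abs=0.01)
    assert np.sum(row > 0.5) <= 4


def test_cohort_is_deterministic_in_seed():
    c1, t1 = generate_cohort(CohortParams(seed=17))
    c2, t2 = generate_cohort(CohortParams(seed=17))
    assert c1.data.equals(c2.data)
    assert t1.patients.equals(t2.patients)
    c3, _ = generate_cohort(CohortParams(seed=18))
    assert not c1.data.equals(c3.data)


def test_cohort_structure_matches_study_design():
    params = CohortParams(seed=1)
    cohort, truth = generate_cohort(params)
    assert len(cohort.patients("control")) == 20
    assert len(cohort.patients("shock")) == 20
    pid = cohort.patients("shock")[0]
    assert len(cohort.replicates(pid, "PVD", "baseline")) == 3
    assert len(cohort.replicates(pid, "PVD", "3min")) == 3
    assert len(cohort.replicates(pid, "PVD", "30min")) == 3
    cid = cohort.patients("control")[0]
    assert set(cohort.data[cohort.data["patient_id"] == cid]["timepoint"]) == {"control"}
    assert truth.patients["responder"].sum() == 13


def test_zero_noise_zero_fraction_deltas_equal_nonresponder_mean():
    params = CohortParams(
        seed=0, responder_fraction=0.0, nonresponder_delta_pvd_mean=1.5,
        replicate_noise_sd_pvd=0.0,
    )
    cohort, _ = generate_cohort(params)
    for pid in cohort.patients("shock"):
        delta = (cohort.replicates(pid, "PVD", "3min").mean()
                 - cohort.replicates(pid, "PVD", "baseline").mean())
        assert delta == pytest.approx(1.5, abs=1e-9)
        # 30-min values revert to the patient's own baseline
        back = (cohort.replicates(pid, "PVD", "30min").mean()
                - cohort.replicates(pid, "PVD", "baseline").mean())
        assert back == pytest.approx(0.0, abs=1e-9)


def test_density_identity_holds_on_every_generated_video():
    cohort, _ = generate_cohort(CohortParams(seed=9))
    wide = cohort.data.pivot_table(
        index="video_id", columns="metric", values="value"
    )
    assert np.allclose(wide["PVD"], wide["TVD"] * wide["PPV"] / 100.0, rtol=1e-9)


def test_fractional_responder_count_warns_and_rounds():
    with pytest.warns(UserWarning, match="rounding"):
        _, truth = generate_cohort(CohortParams(seed=0, n_shock=10,
                                                responder_fraction=0.55))
    assert truth.patients["responder"].sum() in (5, 6)


def test_distributional_calibration_at_large_n():
    """Cohort-level means/SDs converge to the calibration tables."""
    params = CohortParams(seed=21, n_control=400, n_shock=400)
    cohort, _ = generate_cohort(params)
    pvd = cohort.group_values("PVD", "shock", "baseline")
    # SE of the mean = 3.38/sqrt(400) = 0.17; allow 4 SE
    assert pvd.mean() == pytest.approx(20.44, abs=0.7)
    assert pvd.std(ddof=1) == pytest.approx(3.38, rel=0.15)
    ctrl_ppv = cohort.group_values("PPV", "control", "control")
    assert ctrl_ppv.mean() == pytest.approx(95.89, abs=0.6)
    # cohort-mean 3-minute PVD increase reproduces the planted challenge effect
    delta = (cohort.group_values("PVD", "shock", "3min").mean()
             - cohort.group_values("PVD", "shock", "baseline").mean())
    assert delta == pytest.approx(5.97, abs=0.6)
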