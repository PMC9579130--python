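import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prftuning import synthetic, tuning
from prftuning.angles import wrap_angle, wrap_distance
from prftuning.vonmises import BIN_CENTERS


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


def _vertex_row(**kw):
    row = dict(
        participant=0, roi="V1", vertex=0, polar_angle=0.0, eccentricity=2.0,
        sigma=0.5, exponent=0.5, r2=0.5, x=0.0, y=2.0,
    )
    row.update(kw)
    return row


def test_polar_gate_keeps_vertex_within_one_sigma_of_stim_ecc():
    df = pd.DataFrame([_vertex_row(eccentricity=2.0, sigma=0.5)])
    assert len(tuning.select_vertices(df, "V1", mode="polar")) == 1


def test_polar_gate_excludes_vertex_beyond_its_sigma():
    df = pd.DataFrame([_vertex_row(eccentricity=3.0, sigma=0.5)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert len(tuning.select_vertices(df, "V1", mode="polar")) == 0


def test_low_r2_excluded_in_both_modes():
    df = pd.DataFrame([_vertex_row(r2=0.09)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert len(tuning.select_vertices(df, "V1", mode="polar")) == 0
        assert len(tuning.select_vertices(df, "V1", mode="eccentricity", stimulus_angle=0.0)) == 0


def test_eccentricity_gate_uses_circular_angle_window():
    near = _vertex_row(polar_angle=-175.0)
    far = _vertex_row(vertex=1, polar_angle=120.0)
    df = pd.DataFrame([near, far])
    out = tuning.select_vertices(df, "V1", mode="eccentricity", stimulus_angle=175.0)
    assert list(out["vertex"]) == [0]  # circular distance 10 deg <= 15


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def test_vertex_at_stimulus_angle_lands_in_bin_zero():
    assert tuning.assign_polar_bin(0.0) == 0.0


def test_wraparound_distance_bins_to_minus_20():
    d = wrap_distance(175.0 - (-175.0))
    assert d == -10.0
    assert tuning.assign_polar_bin(d) == -20.0  # edge ties go to the lower bin


@pytest.mark.parametrize("d,expected", [(10.0, 0.0), (-10.0, -20.0), (170.0, 160.0),
                                        (170.1, 180.0), (180.0, 180.0), (-169.9, -160.0),
                                        (-170.0, -180.0 + 360.0)])
def test_bin_edges_at_odd_multiples_of_ten(d, expected):
    assert tuning.assign_polar_bin(d) == expected


@settings(deadline=None)
@given(st.floats(-179.999, 180.0))
def test_assigned_bin_is_within_half_width(d):
    c = float(tuning.assign_polar_bin(d))
    dd = abs(wrap_distance(d - c))
    assert dd <= 10.0 + 1e-9


def test_bin_median_of_three_values():
    med, cnt = tuning.bin_polar_responses(
        polar_angles=np.array([1.0, 2.0, -3.0]),
        participants=np.array([0, 0, 0]),
        betas=np.array([[1.0], [5.0], [100.0]]),
        rotations=np.array([0.0]),
    )
    assert med.loc[0, 0.0] == 5.0
    assert cnt.loc[0, 0.0] == 3


# ---------------------------------------------------------------------------
# Norm averaging
# ---------------------------------------------------------------------------


def test_norm_average_identity_for_identical_participants():
    v = np.sin(np.linspace(0, np.pi, 18)) + 0.2
    df = pd.DataFrame([v, v, v])
    assert np.allclose(tuning.norm_average(df), v, atol=1e-12)


def test_norm_average_of_v_and_2v_is_1_5v():
    v = np.cos(np.linspace(0, np.pi, 18)) + 2.0
    group = tuning.norm_average(pd.DataFrame([v, 2.0 * v]))
    assert np.allclose(group, 1.5 * v, atol=1e-12)


def test_norm_average_single_participant_is_identity():
    v = np.arange(18, dtype=float) + 1
    assert np.allclose(tuning.norm_average(pd.DataFrame([v])), v)


def test_norm_average_drops_zero_norm_participant_with_warning():
    v = np.ones(18)
    with pytest.warns(UserWarning):
        group = tuning.norm_average(pd.DataFrame([v, np.zeros(18)]))
    assert np.allclose(group, v)


def test_norm_average_masks_bins_missing_for_any_participant():
    v = np.ones(18)
    w = v.copy()
    w[3] = np.nan
    group = tuning.norm_average(pd.DataFrame([v, w]))
    assert np.isnan(group[3]) and np.isfinite(group[0])


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _rf_from_rows(rows):
    df = pd.DataFrame(rows, columns=BIN_CENTERS)
    counts = pd.DataFrame(np.ones_like(df.to_numpy(), dtype=int), columns=BIN_CENTERS)
    rf = tuning.ResponseFunction(BIN_CENTERS.copy(), df, counts)
    rf.group = tuning.norm_average(df)
    return rf


def test_bootstrap_identical_participants_has_zero_width_cis():
    from prftuning.vonmises import vm_density

    v = 1.2 * vm_density(BIN_CENTERS, 0.0, 4.0) - 0.3 * vm_density(BIN_CENTERS, 0.0, 1.0)
    rf = _rf_from_rows([v, v, v])
    res = tuning.bootstrap_rf_fit(rf, n=50, seed=0)
    for metric in tuning.METRICS:
        lo, hi = res.ci95[metric]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_bootstrap_seed_determinism(fixture_table):
    a = tuning.bootstrap_group_fit(fixture_table, "V1", "perception", n=30, seed=11)
    b = tuning.bootstrap_group_fit(fixture_table, "V1", "perception", n=30, seed=11)
    assert a.draws.equals(b.draws)
    assert a.ci95 == b.ci95


def test_pipeline_invariant_to_vertex_row_order(fixture_table):
    shuffled = fixture_table.sample(frac=1.0, random_state=5).reset_index(drop=True)
    rf1 = tuning.participant_response_functions(fixture_table, "V1", "perception")
    rf2 = tuning.participant_response_functions(shuffled, "V1", "perception")
    assert np.allclose(rf1.group, rf2.group, atol=1e-12, equal_nan=True)


def test_stimulus_alignment_invariance(fixture_table):
    """Rotating all vertices by +90 deg while relabeling each stimulus by +90
    leaves the aligned group response functions unchanged."""
    rot = fixture_table.copy()
    rot["polar_angle"] = wrap_angle(rot["polar_angle"] + 90.0)
    mapping = {45.0: 135.0, 135.0: 225.0, 225.0: 315.0, 315.0: 45.0}
    renames = {}
    for kind in ("beta", "beta_median", "beta_se"):
        for task in ("perception", "memory"):
            for a, b in mapping.items():
                renames[f"{kind}_{task}_{a:g}"] = f"{kind}_{task}_{b:g}"
    rot = rot.rename(columns=renames)
    rf1 = tuning.participant_response_functions(fixture_table, "V1", "perception")
    rf2 = tuning.participant_response_functions(rot, "V1", "perception")
    assert np.allclose(
        rf1.per_participant.to_numpy(), rf2.per_participant.to_numpy(), atol=1e-12, equal_nan=True
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


class _FakeResult:
    def __init__(self, draws, point=None):
        self.draws = draws
        self.n_replicates = len(draws)
        from prftuning.vonmises import CurveMetrics

        p = point if point is not None else draws.mean()
        self.point_metrics = CurveMetrics(p["location"], p["amplitude"], p["fwhm"], True)


def _fake_results(values):
    out = {}
    for (roi, task), v in values.items():
        draws = pd.DataFrame({m: np.full(20, v) for m in tuning.METRICS})
        out[(roi, task)] = _FakeResult(draws)
    return out


def test_contrast_zero_task_effect_when_tasks_identical():
    values = {(r, t): i + 1.0 for i, r in enumerate(tuning.ROI_ORDER) for t in tuning.TASKS}
    res = tuning.bootstrap_contrasts(_fake_results(values), "amplitude")
    lo, hi = res.ci95["task"]
    assert lo == pytest.approx(0.0, abs=1e-10) and hi == pytest.approx(0.0, abs=1e-10)


def test_contrast_recovers_exact_linear_roi_effect():
    values = {(r, t): float(i + 1) for i, r in enumerate(tuning.ROI_ORDER) for t in tuning.TASKS}
    res = tuning.bootstrap_contrasts(_fake_results(values), "fwhm")
    assert res.point["roi"] == pytest.approx(1.0, abs=1e-10)
    assert res.point["task_x_roi"] == pytest.approx(0.0, abs=1e-10)


def test_contrast_mismatched_replicates_raise():
    values = {(r, t): 1.0 for r in tuning.ROI_ORDER for t in tuning.TASKS}
    results = _fake_results(values)
    results[("V1", "perception")].n_replicates = 7
    with pytest.raises(ValueError):
        tuning.bootstrap_contrasts(results, "amplitude")


# ---------------------------------------------------------------------------
# Individual fits
# ---------------------------------------------------------------------------


def test_individual_fit_removes_constant_offset():
    from prftuning.vonmises import vm_density

    f = 1.5 * vm_density(BIN_CENTERS, 0.0, 4.0) - 0.4 * vm_density(BIN_CENTERS, 0.0, 1.0)
    far = [list(BIN_CENTERS).index(b) for b in tuning.FAR_BINS]
    base = f - f[far].mean()
    rf = _rf_from_rows([base, base + 0.7])
    fits = tuning.individual_fits(rf)
    assert len(fits) == 2
    assert fits.iloc[0]["amplitude"] == pytest.approx(fits.iloc[1]["amplitude"], rel=1e-4)
    assert fits.iloc[1]["offset"] == pytest.approx(0.7, abs=1e-9)


def test_individual_fit_skips_participant_with_missing_far_bins():
    v = np.ones(18)
    w = v.copy()
    w[-1] = np.nan  # the 180-deg bin
    rf = _rf_from_rows([v, w])
    with pytest.warns(UserWarning):
        fits = tuning.individual_fits(rf)
    assert len(fits) == 1


# ---------------------------------------------------------------------------
# Eccentricity response functions
# ---------------------------------------------------------------------------


def test_eccentricity_binning_edges(fixture_table):
    res = tuning.eccentricity_response(fixture_table, "V1", "perception", n_boot=10, seed=0)
    assert res.bin_centers[0] == pytest.approx(0.75)
    assert len(res.bin_centers) == 15
    # a vertex at ecc 0.74 belongs to [0.5, 1.0)
    idx = np.searchsorted(res.bin_edges, 0.74, side="right") - 1
    assert res.bin_centers[idx] == pytest.approx(0.75)


def test_eccentricity_flat_profile_zero_ci_width():
    rows = []
    rng = np.random.default_rng(0)
    for p in (0, 1):
        for v in range(120):
            ecc = rng.uniform(0.6, 7.9)
            rows.append(
                _vertex_row(participant=p, vertex=v, eccentricity=ecc, sigma=1.0,
                            polar_angle=rng.uniform(40, 50))
            )
    df = pd.DataFrame(rows)
    for kind in ("beta", "beta_median", "beta_se"):
        for task in ("perception", "memory"):
            for a in (45, 135, 225, 315):
                df[f"{kind}_{task}_{a}"] = 1.0
    res = tuning.eccentricity_response(df, "V1", "perception", n_boot=25, seed=0)
    got = res.group[np.isfinite(res.group)]
    assert np.allclose(got, 1.0, atol=1e-9)
    ok = np.isfinite(res.ci95_low)
    assert np.allclose(res.ci95_high[ok] - res.ci95_low[ok], 0.0, atol=1e-9)


def test_eccentricity_peak_near_stimulus(full_table):
    res = tuning.eccentricity_response(full_table, "V1", "perception", n_boot=20, seed=0)
    peak_center = res.bin_centers[np.nanargmax(res.group)]
    assert abs(peak_center - 2.0) <= 0.5  # the stimulus eccentricity bin (or neighbor)


# ---------------------------------------------------------------------------
# Visual field maps
# ---------------------------------------------------------------------------


def test_visual_field_map_peak_near_stimulus(full_table):
    img, (xs, ys) = tuning.visual_field_map(full_table, "V1", "perception")
    iy, ix = np.unravel_index(np.nanargmax(img), img.shape)
    # stimulus rotated to the upper vertical meridian at 2 deg eccentricity
    assert abs(xs[ix] - 0.0) <= 0.5
    assert abs(ys[iy] - 2.0) <= 0.5


def test_visual_field_map_equivariance(fixture_table):
    rot = fixture_table.copy()
    rot["polar_angle"] = wrap_angle(rot["polar_angle"] + 90.0)
    mapping = {45.0: 135.0, 135.0: 225.0, 225.0: 315.0, 315.0: 45.0}
    renames = {
        f"{kind}_{task}_{a:g}": f"{kind}_{task}_{b:g}"
        for kind in ("beta", "beta_median", "beta_se")
        for task in ("perception", "memory")
        for a, b in mapping.items()
    }
    rot = rot.rename(columns=renames)
    img1, _ = tuning.visual_field_map(fixture_table, "V1", "perception")
    img2, _ = tuning.visual_field_map(rot, "V1", "perception")
    assert np.allclose(img1, img2, atol=1e-9, equal_nan=True)


def test_visual_field_map_constant_betas_flagged(fixture_table):
    df = fixture_table.copy()
    for task in ("perception",):
        for a in (45, 135, 225, 315):
            df[f"beta_{task}_{a}"] = 2.0
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            tuning.visual_field_map(df, "V1", "perception")


# ---------------------------------------------------------------------------
# Prediction evaluation
# ---------------------------------------------------------------------------


def test_r2_is_one_for_perfect_predictions():
    obs = np.array([0.1, 0.5, 1.0, 0.3, -0.2])
    out = tuning.evaluate_predictions(obs, obs)
    assert out["r2"] == pytest.approx(1.0)
    assert out["scale_factor"] == pytest.approx(1.0)


def test_overscaled_predictions_recover_after_rescale():
    obs = np.array([0.1, 0.5, 1.0, 0.3, -0.2])
    out = tuning.evaluate_predictions(10.0 * obs, obs)
    assert out["r2"] < 0
    assert out["scale_factor"] == pytest.approx(0.1)
    assert out["r2_rescaled"] == pytest.approx(1.0)


def test_constant_mean_prediction_gives_zero_r2():
    obs = np.array([0.1, 0.5, 1.0, 0.3, -0.2])
    pred = np.full_like(obs, obs.mean())
    assert tuning.coefficient_of_determination(pred, obs) == pytest.approx(0.0)


def test_zero_variance_observation_rejected():
    with pytest.raises(ValueError):
        tuning.coefficient_of_determination(np.ones(5), np.ones(5))


def test_pooled_scale_factor_closed_form():
    p1, o1 = np.array([1.0, 2.0]), np.array([0.5, 1.0])
    p2, o2 = np.array([4.0]), np.array([2.0])
    s = tuning.best_scale_factor([p1, p2], [o1, o2])
    assert s == pytest.approx((1 * 0.5 + 2 * 1 + 4 * 2) / (1 + 4 + 16))
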