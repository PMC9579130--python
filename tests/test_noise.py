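import numpy as np
import pandas as pd
import pytest

from prftuning import noise, tuning


def test_draw_correlated_zero_z_returns_medians(fixture_table):
    med, se = noise._median_se(fixture_table, "perception")
    z = np.zeros((3,) + med.shape)
    out = noise.draw_correlated(med, se, z)
    assert np.array_equal(out[0], med)


def test_draw_correlated_rejects_negative_se():
    with pytest.raises(ValueError):
        noise.draw_correlated(np.zeros((2, 4)), np.full((2, 4), -1.0), np.zeros((1, 2, 4)))


def test_within_roi_vertex_correlation_is_one(fixture_table):
    ds = noise.simulate_snr(fixture_table, "p", n_sims=200, seed=0)
    sub = fixture_table[(fixture_table.roi == "V1") & (fixture_table.participant == 0)]
    idx = fixture_table.index.get_indexer(sub.index)[:2]
    a = ds.betas[:, idx[0], 0]
    b = ds.betas[:, idx[1], 0]
    assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_snr_level_p_matches_perception_noise(fixture_table):
    se_p = noise._snr_target_se(fixture_table, "p")
    _, se = noise._median_se(fixture_table, "perception")
    assert np.array_equal(se_p, se)


def test_fractional_levels_scale_target_se(fixture_table):
    se_m = noise._snr_target_se(fixture_table, "m")
    se_m2 = noise._snr_target_se(fixture_table, "m/2")
    se_m8 = noise._snr_target_se(fixture_table, "m/8")
    assert np.allclose(se_m2, 2.0 * se_m, rtol=1e-9)
    assert np.allclose(se_m8, 8.0 * se_m, rtol=1e-9)


def test_level_zero_equivalence_across_families(fixture_table):
    """lapse 0%, associative 0% and angular sd 0 are dataset-identical to SNR level p."""
    base = noise.simulate_snr(fixture_table, "p", n_sims=15, seed=9)
    for family, level in (("lapse", 0), ("associative", 0), ("angular", 0.0)):
        ds = noise.simulate(family, fixture_table, level, n_sims=15, seed=9)
        assert np.array_equal(ds.betas, base.betas), family
        if ds.rotations is not None:
            assert np.allclose(ds.rotations, np.array(ds.stim_angles)[None, None, :])


def test_reproducibility_under_fixed_seed(fixture_table):
    a = noise.simulate_lapse(fixture_table, 50, n_sims=10, seed=4)
    b = noise.simulate_lapse(fixture_table, 50, n_sims=10, seed=4)
    assert np.array_equal(a.betas, b.betas)
    assert np.array_equal(a.extras["lapsed"], b.extras["lapsed"])


def test_lapse_counts_per_level(fixture_table):
    for level, k in ((0, 0), (25, 1), (50, 2), (100, 4)):
        ds = noise.simulate_lapse(fixture_table, level, n_sims=6, seed=1)
        assert (ds.extras["lapsed"].sum(axis=2) == k).all()


def test_full_lapse_zeroes_all_medians(fixture_table):
    ds = noise.simulate_lapse(fixture_table, 100, n_sims=4, seed=1)
    fits = noise.analyze_simulations(fixture_table, ds, rois=["V1"])
    amps = fits["amplitude"].to_numpy()
    # pure-noise datasets: tiny amplitude or outright fit failure
    assert np.all(np.isnan(amps) | (amps < 0.25))


def test_associative_substitutes_are_other_studied_stimuli(fixture_table):
    ds = noise.simulate_associative(fixture_table, 75, n_sims=10, seed=2)
    sub = ds.extras["substitute"]
    errs = sub >= 0
    stim_idx = np.broadcast_to(np.arange(4), sub.shape)
    # never the correct stimulus: errors are always a multiple of 90 deg away
    assert (sub[errs] != stim_idx[errs]).all()
    assert (ds.extras["substitute"].max() <= 3)


def test_full_associative_error_never_uses_correct_signal(fixture_table):
    ds = noise.simulate_associative(fixture_table, 100, n_sims=5, seed=2)
    sub = ds.extras["substitute"]
    stim_idx = np.broadcast_to(np.arange(4), sub.shape)
    assert (sub >= 0).all() and (sub != stim_idx).all()


def test_angular_offsets_distribution(fixture_table):
    ds = noise.simulate_angular(fixture_table, 60.0, n_sims=400, seed=3)
    offsets = ds.extras["offsets"] - np.array(ds.stim_angles)[None, None, :]
    frac = np.mean(np.abs(offsets) <= 45.0)
    assert frac == pytest.approx(noise.quadrant_probability(60.0), abs=0.02)


def test_angular_rotations_expand_per_row(fixture_table):
    ds = noise.simulate_angular(fixture_table, 30.0, n_sims=2, seed=3)
    assert ds.rotations.shape == ds.betas.shape


def test_quadrant_probability_closed_form_and_mc():
    p = noise.quadrant_probability(60.0)
    from scipy.stats import norm

    assert p == pytest.approx(2 * norm.cdf(0.75) - 1, abs=1e-12)
    assert p < 0.60
    assert noise.quadrant_probability(0.0) == 1.0
    mc = noise.quadrant_probability_mc(60.0, n=200_000, seed=0)
    assert mc == pytest.approx(p, abs=0.005)


def test_score_against_memory_counts_failures_as_misses(fixture_table):
    mem = {
        roi: tuning.bootstrap_group_fit(fixture_table, roi, "memory", n=40, seed=5)
        for roi in ("V1", "V3ab")
    }
    fits = pd.DataFrame(
        {
            "family": "snr",
            "level": "m",
            "sim": range(4),
            "roi": "V1",
            "location": [0.0, 0.0, np.nan, 500.0],
            "amplitude": 1.0,
            "fwhm": [mem["V1"].ci95["fwhm"][0] + 1e-6] * 4,
            "converged": [True, True, False, True],
        }
    )
    # widen the location CI so the first two sims land inside it
    mem["V1"].ci95["location"] = (-10.0, 10.0)
    score = noise.score_against_memory(fits, mem)
    row = score.iloc[0]
    assert row["n_failures"] == 1
    assert row["prop_location"] == pytest.approx(0.5)  # 2 of 4; NaN and 500 miss


def test_score_requires_memory_ci(fixture_table):
    fits = pd.DataFrame(
        {"family": "snr", "level": "m", "sim": [0], "roi": "V9",
         "location": [0.0], "amplitude": [1.0], "fwhm": [10.0], "converged": [True]}
    )
    with pytest.raises(KeyError):
        noise.score_against_memory(fits, {})


def test_self_coverage_of_memory_cis(fixture_table):
    """Simulations drawn at low noise from data matching memory stay inside the CIs."""
    mem = {"V1": tuning.bootstrap_group_fit(fixture_table, "V1", "memory", n=60, seed=5)}
    loc_lo, loc_hi = mem["V1"].ci95["location"]
    fw_lo, fw_hi = mem["V1"].ci95["fwhm"]
    fits = pd.DataFrame(
        {
            "family": "snr",
            "level": "p",
            "sim": range(10),
            "roi": "V1",
            "location": np.linspace(loc_lo, loc_hi, 10),
            "amplitude": 1.0,
            "fwhm": np.linspace(fw_lo, fw_hi, 10),
            "converged": True,
        }
    )
    score = noise.score_against_memory(fits, mem)
    assert score.iloc[0]["prop_location"] == 1.0
    assert score.iloc[0]["prop_fwhm"] == 1.0


def test_lapse_dispersion_nondecreasing_over_pooled_seeds(fixture_table):
    """Fitted-FWHM spread grows with the lapse rate (2 seeds pooled)."""
    sds = []
    for level in noise.PERCENT_LEVELS:
        fits = pd.concat(
            [
                noise.analyze_simulations(
                    fixture_table, noise.simulate_lapse(fixture_table, level, n_sims=60, seed=s)
                )
                for s in (0, 1)
            ]
        )
        sds.append(fits.groupby("roi")["fwhm"].std().mean())
    assert np.all(np.diff(sds) >= 0), sds


@pytest.mark.parametrize("family,top", [("associative", 100), ("angular", 180.0)])
def test_substitution_families_disperse_relative_to_level_zero(fixture_table, family, top):
    """Substitution-type confounds saturate rather than grow level by level,
    but their top level is clearly more dispersed than the zero level."""
    zero = {"associative": 0, "angular": 0.0}[family]
    out = {}
    for level in (zero, top):
        fits = noise.analyze_simulations(
            fixture_table, noise.simulate(family, fixture_table, level, n_sims=80, seed=4)
        )
        out[level] = fits.groupby("roi")["fwhm"].std().mean()
    assert out[top] > out[zero]


def test_invalid_levels_rejected(fixture_table):
    with pytest.raises(ValueError):
        noise.simulate_snr(fixture_table, "m/3", n_sims=1, seed=0)
    with pytest.raises(ValueError):
        noise.simulate_lapse(fixture_table, 30, n_sims=1, seed=0)
    with pytest.raises(ValueError):
        noise.simulate_angular(fixture_table, -5.0, n_sims=1, seed=0)
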