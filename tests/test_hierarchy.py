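import numpy as np
import pytest
from scipy.stats import norm

from prftuning.hierarchy import (
    HierarchyConfig,
    KernelOperator,
    feedback_cascade,
    feedforward_cascade,
    layer_metrics,
    parameter_sweep,
    profile_metrics,
    run_model,
)


class TestKernelOperator:
    def test_constant_preserved_in_interior(self):
        op = KernelOperator(sigma=5.0, grid_step=0.5)
        x = np.ones(500)
        y = op.apply(x)
        pad = op.kernel.size // 2
        assert np.allclose(y[pad:-pad], 1.0, atol=1e-12)

    def test_delta_response_is_discretized_gaussian(self):
        sigma, step = 5.0, 0.5  # step = sigma / 10
        op = KernelOperator(sigma, step)
        n = 801
        x = np.zeros(n)
        x[n // 2] = 1.0
        y = op.apply(x)
        pos = (np.arange(n) - n // 2) * step
        g = np.exp(-(pos**2) / (2 * sigma**2))
        g /= g.sum()
        assert np.max(np.abs(y - g)) < 1e-6

    def test_matrix_is_symmetric_and_matches_convolution(self):
        op = KernelOperator(sigma=3.0, grid_step=0.5)
        T = op.toarray(300)
        assert np.abs(T - T.T).max() == 0.0
        x = np.sin(np.linspace(0, 4 * np.pi, 300))
        assert np.allclose(T @ x, op.apply(x), atol=1e-12)

    def test_undersampled_kernel_warns(self):
        with pytest.warns(UserWarning):
            KernelOperator(sigma=0.2, grid_step=0.5)


class TestFeedforward:
    def test_layer1_peak_matches_gaussian_cdf_integral(self):
        # boxcar (width w, height 1) * Gaussian at 0 -> 2 Phi(w / 2 sigma) - 1
        cfg = HierarchyConfig(grid_step=0.05)
        ff = feedforward_cascade(cfg)
        want = 2 * norm.cdf(cfg.stimulus_width / 2 / cfg.kernel_sigma) - 1
        assert ff.layer(1).max() == pytest.approx(want, rel=0.01)

    def test_location_zero_at_every_layer(self):
        ff = feedforward_cascade(HierarchyConfig())
        assert np.allclose(ff.metrics["location"], 0.0)

    def test_fwhm_strictly_increasing(self):
        ff = feedforward_cascade(HierarchyConfig())
        assert np.all(np.diff(ff.metrics["fwhm"]) > 0)

    def test_activity_nonnegative(self):
        ff = feedforward_cascade(HierarchyConfig())
        assert ff.activity.min() >= 0.0

    def test_edge_guard_violation_raises(self):
        with pytest.raises(ValueError):
            feedforward_cascade(HierarchyConfig(extent=100.0)).positions


class TestFeedback:
    def test_top_layer_duplicates_feedforward(self):
        ff, fb = run_model(HierarchyConfig())
        assert np.array_equal(fb.layer(8), ff.layer(8))

    def test_duality_with_extended_cascade_oracle(self):
        cfg = HierarchyConfig()
        ff, fb = run_model(cfg)
        op = KernelOperator(cfg.kernel_sigma, cfg.grid_step)
        acts = [cfg.stimulus(ff.positions)]
        for _ in range(2 * cfg.n_layers):
            acts.append(op.apply(acts[-1]))
        for l in range(1, cfg.n_layers + 1):
            assert np.max(np.abs(fb.layer(l) - acts[2 * cfg.n_layers - l])) < 1e-10

    def test_feedback_layer1_wider_than_feedforward_layer1(self):
        ff, fb = run_model(HierarchyConfig())
        assert fb.metrics["fwhm"].iloc[0] > ff.metrics["fwhm"].iloc[0]

    def test_config_mismatch_rejected(self):
        ff = feedforward_cascade(HierarchyConfig())
        with pytest.raises(ValueError):
            feedback_cascade(ff, HierarchyConfig(n_layers=4))


class TestLayerMetrics:
    def test_discretized_gaussian_fwhm(self):
        pos = np.arange(-200, 200.25, 0.25)
        for sigma in (5.0, 15.0):
            m = profile_metrics(pos, np.exp(-(pos**2) / (2 * sigma**2)))
            assert m["fwhm"] == pytest.approx(2.3548 * sigma, abs=0.3)

    def test_rescaling_halves_amplitude_keeps_fwhm(self):
        pos = np.arange(-100, 100.5, 0.5)
        prof = np.exp(-(pos**2) / 50.0)
        m1 = profile_metrics(pos, prof)
        m2 = profile_metrics(pos, 0.5 * prof)
        assert m2["amplitude"] == pytest.approx(0.5 * m1["amplitude"])
        assert m2["fwhm"] == pytest.approx(m1["fwhm"], abs=1e-9)

    def test_symmetric_profile_location_zero(self):
        pos = np.arange(-50, 50.5, 0.5)
        m = profile_metrics(pos, np.cos(pos / 40.0))
        assert m["location"] == pytest.approx(0.0, abs=1e-12)

    def test_flat_profile_flagged(self):
        pos = np.arange(-10, 10.5, 0.5)
        m = profile_metrics(pos, np.ones_like(pos))
        assert not m["fwhm_defined"] and np.isnan(m["fwhm"])

    def test_argmax_ties_average(self):
        pos = np.array([-1.0, 0.0, 1.0, 2.0])
        m = profile_metrics(pos, np.array([0.0, 1.0, 1.0, 0.0]))
        assert m["location"] == pytest.approx(0.5)


def test_linearity_in_stimulus_height():
    ff1, fb1 = run_model(HierarchyConfig(stimulus_height=1.0))
    ff2, fb2 = run_model(HierarchyConfig(stimulus_height=2.0))
    assert np.allclose(ff2.activity, 2.0 * ff1.activity, atol=1e-12)
    assert np.allclose(fb2.metrics["amplitude"], 2.0 * fb1.metrics["amplitude"], rtol=1e-9)
    assert np.allclose(fb2.metrics["fwhm"], fb1.metrics["fwhm"], atol=1e-9)
    assert np.allclose(ff2.metrics["location"], ff1.metrics["location"], atol=1e-12)


def test_asymptotic_fwhm_scaling():
    """Deep feedforward layers approach the Gaussian FWHM 2.3548 sigma sqrt(n)."""
    cfg = HierarchyConfig()
    ff = feedforward_cascade(cfg)
    for n in (6, 7, 8):
        got = float(ff.metrics.loc[ff.metrics.layer == n, "fwhm"].iloc[0])
        want = 2.3548 * cfg.kernel_sigma * np.sqrt(n)
        assert got == pytest.approx(want, rel=0.05)


class TestParameterSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        return parameter_sweep()

    def test_grid_sweep_row_count(self, sweep):
        grid = sweep[sweep.sweep == "stimulus_kernel"]
        assert len(grid) == 16 * 8 * 2

    def test_layer_sweep_includes_base_model(self, sweep):
        layers = sweep[sweep.sweep == "layers"]
        assert set(layers.n_layers) == {4, 6, 8, 10}

    def test_feedforward_fwhm_nondecreasing_in_every_cell(self, sweep):
        ff = sweep[sweep.direction == "feedforward"]
        for _, cell in ff.groupby(["sweep", "n_layers", "stimulus_width", "kernel_sigma"]):
            fw = cell.sort_values("layer")["fwhm"].to_numpy()
            assert np.all(np.diff(fw) >= -1e-9)

    def test_no_feedback_cell_reverses_early_layer_trend(self, sweep):
        fb = sweep[sweep.direction == "feedback"]
        for _, cell in fb.groupby(["sweep", "n_layers", "stimulus_width", "kernel_sigma"]):
            c = cell.sort_values("layer")
            assert c["fwhm"].iloc[0] >= c["fwhm"].iloc[1] - 1e-9
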