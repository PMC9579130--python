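"""Bidirectional hierarchical Gaussian-pooling network on a 1D spatial axis.

A fully linear, untrained cascade: layer 1 activity is the boxcar stimulus
convolved with a fixed Gaussian kernel, and each further layer convolves the
previous layer with the same kernel. The feedback pass starts by duplicating
the final feedforward layer and applies the transpose of the same (symmetric
Toeplitz) pooling operator downward, so feedback layer l equals feedforward
layer 2L - l exactly. Per-layer location, amplitude and FWHM mirror the
metrics used on the fMRI tuning curves.

The axis is linear (wide grid with an edge guard), not circular: the
Toeplitz formulation is linear convolution. Kernel rows are unit-sum after
truncation at +/- 5 sigma, so pooling preserves a constant profile in the
interior and produces the decreasing peak amplitudes the cascade is meant to
show. Layer indices carry no claimed mapping onto cortical areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

DEFAULT_SWEEP_LAYERS = (4, 6, 8, 10)
DEFAULT_SWEEP_WIDTHS = (15.0, 30.0, 45.0, 60.0)
DEFAULT_SWEEP_SIGMAS = (5.0, 15.0, 30.0, 45.0)


@dataclass(frozen=True)
class HierarchyConfig:
    """Network size, stimulus and kernel geometry, and the spatial grid.

    ``extent`` (full grid width, deg) defaults to the edge-effect guard
    ``stimulus_width + 8 * sigma * sqrt(2 L)``: after 2L - 1 poolings the
    activity SD is ~ sigma * sqrt(2L), so +/- 4 SD of spread stays inside the
    grid.
    """

    n_layers: int = 8
    stimulus_width: float = 15.0  # deg, boxcar centered at 0
    stimulus_height: float = 1.0
    kernel_sigma: float = 15.0  # deg
    grid_step: float = 0.5  # deg
    extent: float | None = None

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if self.kernel_sigma <= 0 or self.stimulus_width <= 0 or self.grid_step <= 0:
            raise ValueError("sigma, stimulus width and grid step must be positive")

    @property
    def guard_extent(self) -> float:
        return self.stimulus_width + 8.0 * self.kernel_sigma * np.sqrt(2.0 * self.n_layers)

    def positions(self) -> np.ndarray:
        extent = self.extent if self.extent is not None else self.guard_extent
        if extent < self.guard_extent:
            raise ValueError(
                f"grid extent {extent:.1f} deg violates the edge guard "
                f"({self.guard_extent:.1f} deg)"
            )
        half = int(np.ceil(extent / 2.0 / self.grid_step))
        return np.arange(-half, half + 1) * self.grid_step

    def stimulus(self, positions: np.ndarray | None = None) -> np.ndarray:
        x = self.positions() if positions is None else positions
        return np.where(np.abs(x) <= self.stimulus_width / 2.0, self.stimulus_height, 0.0)


class KernelOperator:
    """Symmetric Toeplitz pooling operator with unit-sum Gaussian rows.

    The kernel is the Gaussian discretized at grid steps, truncated at
    +/- 5 sigma and normalized to unit sum; application is linear convolution
    restricted to the grid, identical to multiplying by the banded symmetric
    Toeplitz matrix (available via :meth:`toarray` for inspection).
    """

    def __init__(self, sigma: float, grid_step: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if sigma < grid_step:
            warnings.warn(
                f"kernel sigma {sigma} deg is below the grid step {grid_step} deg; "
                "the discretized kernel is undersampled"
            )
        self.sigma = float(sigma)
        self.grid_step = float(grid_step)
        half = int(np.ceil(5.0 * sigma / grid_step))
        offsets = np.arange(-half, half + 1) * grid_step
        k = np.exp(-(offsets**2) / (2.0 * sigma**2))
        self.kernel = k / k.sum()

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.convolve(np.asarray(x, dtype=float), self.kernel, mode="same")

    __matmul__ = apply

    def toarray(self, n: int) -> np.ndarray:
        half = (self.kernel.size - 1) // 2
        col = np.zeros(n)
        m = min(half + 1, n)
        col[:m] = self.kernel[half : half + m]
        return toeplitz(col)


@dataclass
class LayerProfiles:
    """Activity per layer plus per-layer metrics, for one cascade direction."""

    direction: str  # "feedforward" or "feedback"
    positions: np.ndarray
    activity: np.ndarray  # (n_layers, n_positions); row l-1 is layer l
    config: HierarchyConfig
    metrics: pd.DataFrame = field(default=None)

    @property
    def n_layers(self) -> int:
        return self.activity.shape[0]

    def layer(self, l: int) -> np.ndarray:
        return self.activity[l - 1]


def profile_metrics(positions: np.ndarray, profile: np.ndarray) -> dict:
    """Location (argmax; ties averaged), amplitude (max - min), interpolated FWHM."""
    pmax = float(profile.max())
    pmin = float(profile.min())
    peaks = positions[profile == pmax]
    location = float(peaks.mean())
    if pmax == pmin:
        return {"location": location, "amplitude": 0.0, "fwhm": np.nan, "fwhm_defined": False}
    half = pmax / 2.0
    if pmax <= 0:
        return {
            "location": location,
            "amplitude": pmax - pmin,
            "fwhm": np.nan,
            "fwhm_defined": False,
        }
    i_peak = int(np.argmax(profile))
    # walk right
    j = i_peak
    while j + 1 < profile.size and profile[j + 1] >= half:
        j += 1
    if j + 1 >= profile.size:
        right = positions[-1]
    else:
        frac = (profile[j] - half) / (profile[j] - profile[j + 1])
        right = positions[j] + frac * (positions[j + 1] - positions[j])
    # walk left
    i = i_peak
    while i - 1 >= 0 and profile[i - 1] >= half:
        i -= 1
    if i - 1 < 0:
        left = positions[0]
    else:
        frac = (profile[i] - half) / (profile[i] - profile[i - 1])
        left = positions[i] - frac * (positions[i] - positions[i - 1])
    return {
        "location": location,
        "amplitude": pmax - pmin,
        "fwhm": float(right - left),
        "fwhm_defined": True,
    }


def layer_metrics(profiles: LayerProfiles) -> pd.DataFrame:
    """Per-layer location/amplitude/FWHM table; flat profiles flagged."""
    rows = []
    for l in range(1, profiles.n_layers + 1):
        m = profile_metrics(profiles.positions, profiles.layer(l))
        rows.append({"direction": profiles.direction, "layer": l, **m})
    return pd.DataFrame(rows)


def feedforward_cascade(config: HierarchyConfig) -> LayerProfiles:
    """a_1 = K s; a_{l+1} = K a_l. Location stays at the stimulus center."""
    x = config.positions()
    op = KernelOperator(config.kernel_sigma, config.grid_step)
    act = np.empty((config.n_layers, x.size))
    act[0] = op.apply(config.stimulus(x))
    for l in range(1, config.n_layers):
        act[l] = op.apply(act[l - 1])
    out = LayerProfiles("feedforward", x, act, config)
    out.metrics = layer_metrics(out)
    return out


def feedback_cascade(ff: LayerProfiles, config: HierarchyConfig | None = None) -> LayerProfiles:
    """b_L = a_L (perfect reinstatement); b_{l-1} = K^T b_l = K b_l.

    The operator is symmetric, so feedback pooling is the same convolution,
    and b_l equals the layer-(2L - l) activity of an extended feedforward run.
    """
    config = config or ff.config
    if config != ff.config:
        raise ValueError("feedback config must match the feedforward cascade's")
    op = KernelOperator(config.kernel_sigma, config.grid_step)
    L = config.n_layers
    act = np.empty_like(ff.activity)
    act[L - 1] = ff.activity[L - 1]
    for l in range(L - 1, 0, -1):
        act[l - 1] = op.apply(act[l])
    out = LayerProfiles("feedback", ff.positions, act, config)
    out.metrics = layer_metrics(out)
    return out


def run_model(config: HierarchyConfig) -> tuple[LayerProfiles, LayerProfiles]:
    ff = feedforward_cascade(config)
    return ff, feedback_cascade(ff)


def parameter_sweep(
    base: HierarchyConfig | None = None,
    layers=DEFAULT_SWEEP_LAYERS,
    stimulus_widths=DEFAULT_SWEEP_WIDTHS,
    kernel_sigmas=DEFAULT_SWEEP_SIGMAS,
) -> pd.DataFrame:
    """Tidy per-layer metrics over the layer sweep and the stimulus x kernel sweep.

    The layer sweep varies depth at the base stimulus/kernel; the grid sweep
    runs every (stimulus width, kernel sigma) combination at the base depth.
    The base model appears in both. Columns: sweep, n_layers,
    stimulus_width, kernel_sigma, direction, layer, location, amplitude, fwhm.
    """
    base = base or HierarchyConfig()
    frames = []

    def run(cfg: HierarchyConfig, sweep: str):
        ff, fb = run_model(cfg)
        for prof in (ff, fb):
            m = prof.metrics.copy()
            m.insert(0, "sweep", sweep)
            m.insert(1, "n_layers", cfg.n_layers)
            m.insert(2, "stimulus_width", cfg.stimulus_width)
            m.insert(3, "kernel_sigma", cfg.kernel_sigma)
            frames.append(m)

    for L in layers:
        run(replace(base, n_layers=L, extent=None), "layers")
    for w in stimulus_widths:
        for s in kernel_sigmas:
            run(replace(base, stimulus_width=w, kernel_sigma=s, extent=None), "stimulus_kernel")
    return pd.concat(frames, ignore_index=True)
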