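"""Synthetic cortical vertex data with the statistical structure the analysis assumes.

Emulates the study design: 9 participants x 6 retinotopic maps (V1, V2, V3,
hV4, LO, V3ab) x 4 isoeccentric stimuli (45/135/225/315 deg polar angle,
2 deg eccentricity, 1.5 dva diameter). Perception responses are generated by
the pRF forward model plus per-vertex Gaussian noise; memory responses are
generated mechanistically as an attenuated, sigma-widened copy of the
forward prediction, so the tuning pipeline and the hierarchical network
model remain independently testable.

The generator's per-ROI pRF sizes increase from V1 to V3ab; polar angles are
uniform, eccentricities log-uniform on (0.5, 8) dva, and sigma is linear in
eccentricity with ROI-specific slope and intercept. The perception amplitude
scale is calibrated per ROI so the noiseless group tuning curve has the
configured peak-to-trough amplitude (the whole pipeline is linear in the
response scale, so the calibration is exact).

Randomness is PCG64 (`numpy.random.default_rng`) with substreams derived
from the master seed via `SeedSequence.spawn_key`, so identical configs give
bit-identical tables across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from prftuning.apertures import DEFAULT_EXTENT, DEFAULT_GRID_N, stimulus_apertures
from prftuning.forward import ForwardModelSpec, predict_all

# ---------------------------------------------------------------------------
# Experiment design constants
# ---------------------------------------------------------------------------

STIM_ANGLES = (45.0, 135.0, 225.0, 315.0)
STIM_ECCENTRICITY = 2.0  # deg
STIM_DIAMETER = 1.5  # dva
ROI_ORDER = ("V1", "V2", "V3", "hV4", "LO", "V3ab")
TASKS = ("perception", "memory")

#: Behavioral test locations: the 4 targets plus 20 lures, evenly spaced.
N_TEST_LOCATIONS = 24


def test_locations(n: int = N_TEST_LOCATIONS, targets=STIM_ANGLES) -> np.ndarray:
    """The n evenly spaced polar-angle test locations, anchored on the targets."""
    spacing = 360.0 / n
    locs = (targets[0] + spacing * np.arange(n)) % 360.0
    for t in targets:
        if not np.isclose(((locs - t) % 360.0), 0.0).any():
            raise ValueError(f"target {t} deg is not on the {n}-location grid")
    return np.sort(locs)


def nearest_lure_distance(n: int = N_TEST_LOCATIONS, targets=STIM_ANGLES) -> float:
    """Polar-angle distance from any target to its nearest lure location."""
    locs = test_locations(n, targets)
    lures = np.array([l for l in locs if not np.isclose((np.asarray(targets) - l) % 360.0, 0).any()])
    d = np.abs((lures[:, None] - np.asarray(targets)[None, :] + 180.0) % 360.0 - 180.0)
    return float(d.min())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: sigma = intercept + slope * eccentricity, increasing V1 -> V3ab. The
#: values are calibrated (at zero noise, default design) so the group
#: perception tuning curves reproduce the empirical FWHM ladder across the
#: hierarchy (~38 deg in V1 rising to ~97 deg in V3ab).
ROI_SIGMA_PARAMS = {
    "V1": (0.365, 0.0911),
    "V2": (0.474, 0.1240),
    "V3": (0.569, 0.1472),
    "hV4": (0.668, 0.1823),
    "LO": (0.771, 0.1927),
    "V3ab": (0.937, 0.1757),
}

#: Memory sigma widening per ROI: ~3x in V1 shrinking to 1x by V3ab, the
#: regime of the observed memory/perception FWHM ratios across the hierarchy.
ROI_WIDENING = {"V1": 3.0, "V2": 2.6, "V3": 2.2, "hV4": 1.8, "LO": 1.4, "V3ab": 1.0}


@dataclass(frozen=True)
class GroundTruthConfig:
    """Generator settings; defaults emulate the study's empirical regime."""

    n_participants: int = 9
    stim_angles: tuple = STIM_ANGLES
    stim_eccentricity: float = STIM_ECCENTRICITY
    stim_diameter: float = STIM_DIAMETER
    rois: tuple = ROI_ORDER
    n_vertices_per_roi: int = 500
    ecc_range: tuple = (0.5, 8.0)
    exponent_range: tuple = (0.3, 0.8)
    sigma_jitter: float = 0.10  # lognormal sigma of per-vertex size scatter
    low_r2_fraction: float = 0.15  # fraction of vertices failing the R2 >= 0.1 gate
    perception_amplitude: float = 0.9  # target group peak-to-trough, % signal change
    attenuation: float = 0.28  # memory amplitude scale, in (0, 1]
    widening: dict = field(default_factory=lambda: dict(ROI_WIDENING))
    noise_sd: float = 0.25  # per-vertex noise SD, % signal change
    participant_noise_spread: float = 0.5  # lognormal sigma of per-participant multipliers
    se_eccentricity_dependent: bool = False
    variant: str = "dog_css"  # the study's focal forward model
    extent: float = DEFAULT_EXTENT
    grid_n: int = DEFAULT_GRID_N
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in (0, 1]")
        if any(w < 1.0 for w in self.widening.values()):
            raise ValueError("widening factors must be >= 1")

    def widening_for(self, roi: str) -> float:
        return float(self.widening.get(roi, 1.0))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthConfig":
        d = dict(d)
        for key in ("stim_angles", "rois", "ecc_range", "exponent_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: GroundTruthConfig, *key: int) -> np.random.Generator:
    """Substream keyed on (seed; key...) — reproducible and platform-stable."""
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# pRF parameter generation
# ---------------------------------------------------------------------------


def generate_prf_params(
    config: GroundTruthConfig, roi: str, participant: int = 0
) -> pd.DataFrame:
    """Draw pRF parameters for one (participant, ROI) cell.

    Polar angle is uniform on [-180, 180); eccentricity log-uniform on the
    configured range; sigma is linear in eccentricity with the ROI's slope and
    intercept plus mild lognormal scatter; a configured fraction of vertices
    gets pRF-model R2 below 0.1 so downstream gating is exercised.
    """
    if roi not in ROI_SIGMA_PARAMS:
        raise ValueError(f"unknown ROI {roi!r}; expected one of {tuple(ROI_SIGMA_PARAMS)}")
    rng = _rng(config, 0, participant, ROI_ORDER.index(roi))
    n = config.n_vertices_per_roi
    polar = rng.uniform(-180.0, 180.0, n)
    lo, hi = config.ecc_range
    ecc = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    intercept, slope = ROI_SIGMA_PARAMS[roi]
    sigma = (intercept + slope * ecc) * np.exp(rng.normal(0.0, config.sigma_jitter, n))
    exponent = rng.uniform(*config.exponent_range, n)
    low = rng.random(n) < config.low_r2_fraction
    r2 = np.where(low, rng.uniform(0.0, 0.1, n), rng.uniform(0.1, 1.0, n))
    t = np.deg2rad(polar)
    return pd.DataFrame(
        {
            "participant": participant,
            "roi": roi,
            "vertex": np.arange(n),
            "polar_angle": polar,
            "eccentricity": ecc,
            "sigma": sigma,
            "exponent": exponent,
            "r2": r2,
            "x": ecc * np.sin(t),
            "y": ecc * np.cos(t),
        }
    )


# ---------------------------------------------------------------------------
# Task beta generation
# ---------------------------------------------------------------------------


def _calibrate_scale(
    prfs: pd.DataFrame, config: GroundTruthConfig, spec, stimuli, sigma_scale: float = 1.0
) -> float:
    """Per-ROI amplitude scale so the noiseless group curve hits the target.

    Runs the actual tuning pipeline (gate -> bin -> norm-average -> fit) on
    unit-scale noiseless predictions and divides the target amplitude by the
    resulting peak-to-trough; valid because every pipeline stage is
    positively homogeneous in the response scale. With ``sigma_scale`` > 1 the
    calibration measures the widened (memory-like) profile, so the
    attenuation factor acts on the group amplitude, matching the regime the
    defaults target (perception ~0.9, memory ~0.28 x 0.9 %sc).
    """
    from prftuning import tuning

    pred = predict_all(prfs, stimuli, spec, sigma_scale=sigma_scale)
    tmp = prfs.copy()
    for a in config.stim_angles:
        tmp[f"beta_perception_{a:g}"] = pred[f"pred_{a:g}"]
    roi = prfs["roi"].iloc[0]
    rf = tuning.participant_response_functions(tmp, roi, "perception", config.stim_angles)
    fit, metrics = tuning.fit_group_rf(rf)
    if not metrics.amplitude > 0:
        raise RuntimeError(f"calibration failed for {roi}: non-positive amplitude")
    return config.perception_amplitude / metrics.amplitude


def _participant_noise_multipliers(config: GroundTruthConfig) -> np.ndarray:
    """Per-participant lognormal noise multipliers (real participants vary in SNR)."""
    rng = _rng(config, 2)
    return np.exp(rng.normal(0.0, config.participant_noise_spread, config.n_participants))


def generate_task_betas(
    prfs: pd.DataFrame,
    config: GroundTruthConfig,
    spec: ForwardModelSpec | None = None,
    scales: dict | None = None,
) -> pd.DataFrame:
    """Attach perception and memory betas (noisy draw, truth median, SE).

    ``beta_<task>_<angle>`` is truth + Gaussian noise with the configured
    per-vertex SD; ``beta_median_*`` is the truth and ``beta_se_*`` the SD,
    playing the role of the bootstrap summaries that the noise simulations
    treat as signal and noise. Perception truth is the forward-model
    prediction at the calibrated per-ROI scale; memory truth is
    attenuation x the prediction computed with sigma multiplied by the ROI's
    widening factor (same calibrated scale).
    """
    spec = spec or ForwardModelSpec(variant=config.variant)
    stimuli = stimulus_apertures(
        config.stim_angles,
        config.stim_eccentricity,
        config.stim_diameter,
        extent=config.extent,
        n=config.grid_n,
    )
    if scales is None:
        scales = {}
        for roi in prfs["roi"].unique():
            roi_prfs = prfs[prfs["roi"] == roi]
            scales[roi] = (
                _calibrate_scale(roi_prfs, config, spec, stimuli),
                _calibrate_scale(
                    roi_prfs, config, spec, stimuli, sigma_scale=config.widening_for(roi)
                ),
            )
    mult = _participant_noise_multipliers(config)
    out = []
    for (participant, roi), cell in prfs.groupby(["participant", "roi"], sort=False):
        scale_p, scale_m = scales[roi]
        pred_p = predict_all(cell, stimuli, spec) * scale_p
        pred_m = predict_all(cell, stimuli, spec, sigma_scale=config.widening_for(roi)) * (
            scale_m * config.attenuation
        )
        rng_noise = _rng(config, 1, int(participant), ROI_ORDER.index(roi))
        se = np.full(len(cell), config.noise_sd * mult[int(participant)])
        if config.se_eccentricity_dependent:
            se = se * np.sqrt(cell["eccentricity"].to_numpy() / config.stim_eccentricity)
        block = cell.copy()
        for a in config.stim_angles:
            for task, pred in (("perception", pred_p), ("memory", pred_m)):
                truth = pred[f"pred_{a:g}"].to_numpy()
                block[f"beta_{task}_{a:g}"] = truth + rng_noise.normal(0.0, 1.0, len(cell)) * se
                block[f"beta_median_{task}_{a:g}"] = truth
                block[f"beta_se_{task}_{a:g}"] = se
        out.append(block)
    return pd.concat(out, ignore_index=True)


def generate_vertex_table(config: GroundTruthConfig | None = None, spec=None) -> pd.DataFrame:
    """Full synthetic vertex table: every participant, ROI, vertex, stimulus, task."""
    config = config or GroundTruthConfig()
    spec = spec or ForwardModelSpec(variant=config.variant)
    prfs = pd.concat(
        [
            generate_prf_params(config, roi, participant=p)
            for p in range(config.n_participants)
            for roi in config.rois
        ],
        ignore_index=True,
    )
    table = generate_task_betas(prfs, config, spec)
    return table[vertex_table_columns(config.stim_angles)]


# ---------------------------------------------------------------------------
# VertexTable schema and I/O
# ---------------------------------------------------------------------------

_ID_COLUMNS = [
    "participant",
    "roi",
    "vertex",
    "polar_angle",
    "eccentricity",
    "sigma",
    "exponent",
    "r2",
    "x",
    "y",
]


def vertex_table_columns(stim_angles=STIM_ANGLES) -> list:
    """Fixed, documented column order of the tab-separated interchange format."""
    cols = list(_ID_COLUMNS)
    for kind in ("beta", "beta_median", "beta_se"):
        for task in TASKS:
            for a in stim_angles:
                cols.append(f"{kind}_{task}_{a:g}")
    return cols


def validate_vertex_table(table: pd.DataFrame, stim_angles=STIM_ANGLES) -> None:
    """Raise on schema or invariant violations (duplicates, negative SE, NaNs)."""
    missing = set(vertex_table_columns(stim_angles)) - set(table.columns)
    if missing:
        raise ValueError(f"vertex table is missing columns: {sorted(missing)}")
    if table.duplicated(["participant", "roi", "vertex"]).any():
        raise ValueError("duplicate (participant, roi, vertex) rows")
    se_cols = [c for c in table.columns if c.startswith("beta_se_")]
    if (table[se_cols].to_numpy() < 0).any():
        raise ValueError("negative beta_se")
    beta_cols = [c for c in table.columns if c.startswith("beta")]
    if table[beta_cols].isna().any().any():
        raise ValueError("NaN betas")
    if not table["sigma"].gt(0).all():
        raise ValueError("non-positive sigma")
    if not table["r2"].between(0, 1).all():
        raise ValueError("r2 outside [0, 1]")


def write_vertex_table(table: pd.DataFrame, path, stim_angles=STIM_ANGLES) -> None:
    table[vertex_table_columns(stim_angles)].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_vertex_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_vertex_table(table)
    return table
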