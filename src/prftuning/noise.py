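"""Noise-confound simulations: could noisier perception data mimic memory data?

Four families of artificial datasets are generated from the perception
signal (per-vertex median) and noise (per-vertex SE):

- ``snr``: additive noise at the perception SNR (level ``p``), the memory
  SNR (``m``), or 1/2, 1/4, 1/8 of the memory SNR;
- ``lapse``: 0/25/50/75/100% of stimuli per participant are "lapsed" and
  drawn from a zero-signal distribution with perception noise;
- ``associative``: the same fractions of stimuli have their signal replaced
  by a uniformly chosen *other* stimulus's perception signal (errors are
  always a multiple of 90 deg, the stimulus spacing);
- ``angular``: responses are aligned downstream by an erroneous remembered
  angle drawn from Normal(true angle, sd) with sd in {0, 30, 60, 90, 180} deg.

Draws are deliberately correlated across vertices: one standard-normal scale
factor z is shared by every vertex of a (simulation, participant, ROI,
stimulus) cell, so each vertex's simulated value lies z SEs from its median.
This overcompensates for the spatial correlation of BOLD noise and is the
conservative choice — independent vertex noise would wash out of the
population tuning curves. The z stream is seeded independently of each
family's structural randomness, so the zero-noise level of every family is
dataset-identical to the SNR ``p`` level under a shared seed.

Each simulated dataset is pushed through the identical binning / averaging /
von Mises pipeline as real data and scored by the fraction of simulations
whose location and FWHM fall inside the memory data's 95% confidence
intervals (fit failures count as misses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from prftuning import tuning
from prftuning.vonmises import curve_metrics, fit_diff_von_mises_batch

SNR_LEVELS = ("p", "m", "m/2", "m/4", "m/8")
PERCENT_LEVELS = (0, 25, 50, 75, 100)
ANGULAR_LEVELS = (0.0, 30.0, 60.0, 90.0, 180.0)
FAMILIES = ("snr", "lapse", "associative", "angular")
DEFAULT_N_SIMULATIONS = 100

STIM_ANGLES = (45.0, 135.0, 225.0, 315.0)


def family_levels(family: str):
    return {
        "snr": SNR_LEVELS,
        "lapse": PERCENT_LEVELS,
        "associative": PERCENT_LEVELS,
        "angular": ANGULAR_LEVELS,
    }[family]


# ---------------------------------------------------------------------------
# Correlated draws
# ---------------------------------------------------------------------------


def draw_correlated(median: np.ndarray, se: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Simulated betas ``median + z * se`` with z shared across vertices.

    ``median``/``se`` are (n_rows, n_stim); ``z`` is (n_sims, n_rows, n_stim)
    but constant across the rows of any (participant, ROI) cell — the caller
    expands one draw per (simulation, participant, ROI, stimulus).
    """
    if np.any(se < 0):
        raise ValueError("negative SE")
    return median[None, :, :] + z * se[None, :, :]


def _cell_codes(table: pd.DataFrame):
    p_codes, _ = pd.factorize(table["participant"], sort=True)
    r_codes, _ = pd.factorize(table["roi"], sort=True)
    return p_codes, r_codes


def _z_draws(table: pd.DataFrame, n_sims: int, n_stim: int, rng) -> np.ndarray:
    """One z per (simulation, participant, ROI, stimulus), expanded to rows."""
    p_codes, r_codes = _cell_codes(table)
    z = rng.standard_normal((n_sims, p_codes.max() + 1, r_codes.max() + 1, n_stim))
    return z[:, p_codes, r_codes, :]


def _streams(seed):
    """(z stream, structural stream): z is family-independent by construction."""
    ss = np.random.SeedSequence(seed)
    z_ss, struct_ss = ss.spawn(2)
    return np.random.default_rng(z_ss), np.random.default_rng(struct_ss)


def _median_se(table: pd.DataFrame, task: str, stim_angles=STIM_ANGLES):
    med = table[[f"beta_median_{task}_{a:g}" for a in stim_angles]].to_numpy(dtype=float)
    se = table[[f"beta_se_{task}_{a:g}" for a in stim_angles]].to_numpy(dtype=float)
    return med, se


@dataclass
class SimulatedDataset:
    """A stack of simulated perception-like datasets for one family and level."""

    family: str
    level: object
    betas: np.ndarray  # (n_sims, n_rows, n_stim)
    stim_angles: tuple = STIM_ANGLES
    rotations: np.ndarray | None = None  # (n_sims, n_rows, n_stim); angular family only
    extras: dict = field(default_factory=dict)

    @property
    def n_sims(self) -> int:
        return self.betas.shape[0]


# ---------------------------------------------------------------------------
# The four families
# ---------------------------------------------------------------------------


def _snr_target_se(table: pd.DataFrame, level: str, stim_angles=STIM_ANGLES) -> np.ndarray:
    """Per-vertex SE achieving the target SNR, with SNR = |median| / SE.

    Level ``p`` keeps the perception SE. Level ``m`` solves
    ``|perception median| / SE = memory SNR``; fractional levels ``m/k``
    multiply that SE by k. Vertices whose perception or memory median is
    near zero (SNR inversion ill-posed) get the ROI's median target SE.
    """
    perc_med, perc_se = _median_se(table, "perception", stim_angles)
    if level == "p":
        return perc_se
    mem_med, mem_se = _median_se(table, "memory", stim_angles)
    frac = {"m": 1.0, "m/2": 0.5, "m/4": 0.25, "m/8": 0.125}[level]
    if (mem_se <= 0).any():
        raise ValueError("zero memory SE; cannot invert SNR target")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.abs(perc_med) * mem_se / np.abs(mem_med) / frac
    out = raw.copy()
    _, r_codes = _cell_codes(table)
    for r in np.unique(r_codes):
        rows = r_codes == r
        abs_p = np.abs(perc_med[rows])
        abs_m = np.abs(mem_med[rows])
        bad = (
            ~np.isfinite(raw[rows])
            | (abs_p < 0.05 * np.median(abs_p))
            | (abs_m < 0.05 * np.median(abs_m))
        )
        good = raw[rows][~bad]
        floor = np.median(good) if good.size else np.median(perc_se[rows])
        block = out[rows]
        block[bad] = floor
        out[rows] = block
    return out


def simulate_snr(
    table: pd.DataFrame,
    level: str,
    n_sims: int = DEFAULT_N_SIMULATIONS,
    seed: int | None = 0,
    stim_angles=STIM_ANGLES,
) -> SimulatedDataset:
    """Perception signal with additive correlated noise at a target SNR level."""
    if level not in SNR_LEVELS:
        raise ValueError(f"unknown SNR level {level!r}")
    rng_z, _ = _streams(seed)
    med, _ = _median_se(table, "perception", stim_angles)
    se = _snr_target_se(table, level, stim_angles)
    z = _z_draws(table, n_sims, len(stim_angles), rng_z)
    return SimulatedDataset("snr", level, draw_correlated(med, se, z), tuple(stim_angles))


def _designate(rng, n_sims: int, n_participants: int, n_stim: int, k: int) -> np.ndarray:
    """Boolean (n_sims, n_participants, n_stim) mask with exactly k True per cell."""
    mask = np.zeros((n_sims, n_participants, n_stim), dtype=bool)
    if k == 0:
        return mask
    for s in range(n_sims):
        for p in range(n_participants):
            mask[s, p, rng.permutation(n_stim)[:k]] = True
    return mask


def simulate_lapse(
    table: pd.DataFrame,
    level: int,
    n_sims: int = DEFAULT_N_SIMULATIONS,
    seed: int | None = 0,
    stim_angles=STIM_ANGLES,
) -> SimulatedDataset:
    """Retrieval lapses: designated stimuli are drawn from zero signal.

    ``level``% of trials lapse, i.e. level/25 of the 4 stimuli per
    (simulation, participant); lapsed stimuli keep the perception noise but
    have median 0.
    """
    if level not in PERCENT_LEVELS:
        raise ValueError(f"unknown lapse level {level!r}")
    rng_z, rng_struct = _streams(seed)
    med, se = _median_se(table, "perception", stim_angles)
    p_codes, _ = _cell_codes(table)
    k = level // 25
    lapsed = _designate(rng_struct, n_sims, p_codes.max() + 1, len(stim_angles), k)
    lapsed_rows = lapsed[:, p_codes, :]  # (n_sims, n_rows, n_stim)
    z = _z_draws(table, n_sims, len(stim_angles), rng_z)
    med_eff = np.where(lapsed_rows, 0.0, med[None, :, :])
    betas = med_eff + z * se[None, :, :]
    return SimulatedDataset(
        "lapse", level, betas, tuple(stim_angles), extras={"lapsed": lapsed}
    )


def simulate_associative(
    table: pd.DataFrame,
    level: int,
    n_sims: int = DEFAULT_N_SIMULATIONS,
    seed: int | None = 0,
    stim_angles=STIM_ANGLES,
) -> SimulatedDataset:
    """Associative errors: designated stimuli take another stimulus's signal.

    For each error stimulus one of the three other studied stimuli is chosen
    uniformly and its perception median substitutes the correct one (the SE
    is unchanged); the substituted identity is recorded in
    ``extras['substitute']`` (-1 where no error).
    """
    if level not in PERCENT_LEVELS:
        raise ValueError(f"unknown associative level {level!r}")
    rng_z, rng_struct = _streams(seed)
    med, se = _median_se(table, "perception", stim_angles)
    p_codes, _ = _cell_codes(table)
    n_stim = len(stim_angles)
    k = level // 25
    errs = _designate(rng_struct, n_sims, p_codes.max() + 1, n_stim, k)
    # uniformly one of the three other stimuli
    offsets = rng_struct.integers(1, n_stim, size=errs.shape)
    substitute = np.where(errs, (np.arange(n_stim)[None, None, :] + offsets) % n_stim, -1)
    z = _z_draws(table, n_sims, n_stim, rng_z)
    sub_rows = substitute[:, p_codes, :]
    stim_idx = np.broadcast_to(np.arange(n_stim), sub_rows.shape)
    take = np.where(sub_rows >= 0, sub_rows, stim_idx)
    med_eff = med[np.arange(med.shape[0])[None, :, None], take]
    betas = med_eff + z * se[None, :, :]
    return SimulatedDataset(
        "associative", level, betas, tuple(stim_angles), extras={"substitute": substitute}
    )


def simulate_angular(
    table: pd.DataFrame,
    sd: float,
    n_sims: int = DEFAULT_N_SIMULATIONS,
    seed: int | None = 0,
    stim_angles=STIM_ANGLES,
) -> SimulatedDataset:
    """Angular memory error: align by a remembered angle ~ Normal(truth, sd).

    The simulated betas are plain perception-SNR draws; the error enters
    downstream, where each (participant, stimulus) response is rotated by the
    drawn offset instead of the true stimulus angle.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng_z, rng_struct = _streams(seed)
    med, se = _median_se(table, "perception", stim_angles)
    p_codes, _ = _cell_codes(table)
    n_stim = len(stim_angles)
    z = _z_draws(table, n_sims, n_stim, rng_z)
    offsets = rng_struct.normal(
        np.asarray(stim_angles, dtype=float)[None, None, :],
        sd,
        size=(n_sims, p_codes.max() + 1, n_stim),
    )
    return SimulatedDataset(
        "angular",
        float(sd),
        draw_correlated(med, se, z),
        tuple(stim_angles),
        rotations=offsets[:, p_codes, :],
        extras={"offsets": offsets},
    )


def simulate(family: str, table: pd.DataFrame, level, **kwargs) -> SimulatedDataset:
    fn = {
        "snr": simulate_snr,
        "lapse": simulate_lapse,
        "associative": simulate_associative,
        "angular": simulate_angular,
    }[family]
    return fn(table, level, **kwargs)


# ---------------------------------------------------------------------------
# Analysis of simulated datasets
# ---------------------------------------------------------------------------


def analyze_simulations(
    table: pd.DataFrame,
    ds: SimulatedDataset,
    rois=None,
    fwhm_reference: str = "zero",
) -> pd.DataFrame:
    """Fit every simulated dataset with the same pipeline as real data.

    Returns one row per (simulation, ROI) with the fitted location,
    amplitude, FWHM and a ``converged`` flag (False also when FWHM is
    undefined).
    """
    rois = list(rois) if rois is not None else sorted(table["roi"].unique())
    angles = np.asarray(ds.stim_angles, dtype=float)
    records = []
    for roi in rois:
        sub = tuning.select_vertices(table, roi=roi, mode="polar")
        idx = table.index.get_indexer(sub.index)
        pol = sub["polar_angle"].to_numpy()
        part = sub["participant"].to_numpy()
        groups = np.empty((ds.n_sims, tuning.BIN_CENTERS.size))
        for s in range(ds.n_sims):
            rot = angles if ds.rotations is None else ds.rotations[s][idx]
            med, _ = tuning.bin_polar_responses(pol, part, ds.betas[s][idx], rot)
            groups[s] = tuning.norm_average(med)
        fits = fit_diff_von_mises_batch(tuning.BIN_CENTERS, groups)
        for s, fit in enumerate(fits):
            m = curve_metrics(fit, fwhm_reference=fwhm_reference)
            ok = fit.converged and not fit.degenerate and m.fwhm_defined
            records.append(
                {
                    "family": ds.family,
                    "level": ds.level,
                    "sim": s,
                    "roi": roi,
                    "location": m.location if ok else np.nan,
                    "amplitude": m.amplitude if ok else np.nan,
                    "fwhm": m.fwhm if ok else np.nan,
                    "converged": ok,
                }
            )
    return pd.DataFrame.from_records(records)


def score_against_memory(fits: pd.DataFrame, memory_results: dict) -> pd.DataFrame:
    """Proportion of simulations whose metrics fall inside the memory 95% CIs.

    ``memory_results`` maps ROI -> :class:`~prftuning.tuning.BootstrapResult`
    for the memory task. Failed fits count as outside the interval; the
    denominator is always the full simulation count.
    """
    rows = []
    for (family, level, roi), grp in fits.groupby(["family", "level", "roi"], sort=False):
        if roi not in memory_results:
            raise KeyError(f"no memory confidence interval for ROI {roi!r}")
        res = memory_results[roi]
        n = len(grp)
        fails = int((~grp["converged"]).sum())
        props = {}
        for metric in ("location", "fwhm"):
            lo, hi = res.ci95[metric]
            inside = grp[metric].between(lo, hi) & grp["converged"]
            props[f"prop_{metric}"] = float(inside.sum()) / n
        rows.append(
            {
                "family": family,
                "level": level,
                "roi": roi,
                "n_simulations": n,
                "n_failures": fails,
                **props,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Closed-form check on angular error magnitude
# ---------------------------------------------------------------------------


def quadrant_probability(sd: float, half_width: float = 45.0) -> float:
    """P(|Normal(0, sd)| <= half_width): chance an angular error stays in quadrant.

    At sd = 60 deg this is 2*Phi(0.75) - 1 ~= 0.547, i.e. a simulated memory
    lands in the correct quadrant less than 60% of the time.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return 1.0
    return float(2.0 * norm.cdf(half_width / sd) - 1.0)


def quadrant_probability_mc(
    sd: float, half_width: float = 45.0, n: int = 1_000_000, seed: int | None = 0
) -> float:
    """Monte Carlo counterpart of :func:`quadrant_probability`."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return float(np.mean(np.abs(draws) <= half_width))
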