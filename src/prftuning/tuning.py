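"""Polar-angle response functions, group fits, and bootstrap inference.

The analysis chain is: gate vertices on eccentricity and pRF-model R2,
bin each vertex's evoked response by the signed circular distance between
its pRF polar angle and the stimulus angle (pooling the four isoeccentric
stimuli after alignment), take per-participant bin medians, norm-average
across participants, fit a difference of two von Mises functions, and read
location / amplitude / FWHM off the fitted curve. Inference resamples
participants with replacement and repeats the averaging + fitting per
replicate, reporting 68% and 95% percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prftuning.angles import wrap_distance
from prftuning.vonmises import (
    BIN_CENTERS,
    CurveMetrics,
    DiffVonMisesFit,
    curve_metrics,
    fit_diff_von_mises,
    fit_diff_von_mises_batch,
)

STIM_ECCENTRICITY = 2.0  # deg
ECC_RANGE = (0.5, 8.0)  # deg, vertex gating window
MIN_PRF_R2 = 0.1
ECC_MODE_ANGLE_WINDOW = 15.0  # deg of polar angle, eccentricity-mode gate
ECC_BIN_EDGES = np.arange(0.5, 8.01, 0.5)  # 15 bins of 0.5 dva

METRICS = ("location", "amplitude", "fwhm")


# ---------------------------------------------------------------------------
# Vertex gating and binning
# ---------------------------------------------------------------------------


def select_vertices(
    table: pd.DataFrame,
    roi: str | None = None,
    mode: str = "polar",
    stimulus_angle: float | None = None,
    stim_eccentricity: float = STIM_ECCENTRICITY,
    ecc_range=ECC_RANGE,
    min_r2: float = MIN_PRF_R2,
) -> pd.DataFrame:
    """Gate vertices for tuning analyses.

    All modes require eccentricity inside ``ecc_range`` and pRF-model R2 of at
    least ``min_r2``. Polar mode keeps vertices whose pRF eccentricity lies
    within one (vertex-specific) sigma of the stimulus eccentricity.
    Eccentricity mode keeps vertices within 15 deg of polar angle of the
    given stimulus. An empty result warns but does not raise.
    """
    sub = table if roi is None else table[table["roi"] == roi]
    keep = (
        (sub["eccentricity"] >= ecc_range[0])
        & (sub["eccentricity"] <= ecc_range[1])
        & (sub["r2"] >= min_r2)
    )
    if mode == "polar":
        keep &= (sub["eccentricity"] - stim_eccentricity).abs() <= sub["sigma"]
    elif mode == "eccentricity":
        if stimulus_angle is None:
            raise ValueError("eccentricity mode requires a stimulus angle")
        d = np.abs(wrap_distance(sub["polar_angle"].to_numpy() - stimulus_angle))
        keep &= d <= ECC_MODE_ANGLE_WINDOW
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = sub[keep]
    if out.empty:
        warnings.warn(f"vertex selection returned no rows (roi={roi}, mode={mode})")
    return out


def assign_polar_bin(distance) -> np.ndarray:
    """Nearest 20-deg bin center for signed circular distances in (-180, 180].

    Bin edges sit at odd multiples of 10 deg; a distance exactly on an edge
    goes to the lower (more negative) bin, and -180 maps to the 180 bin.
    """
    d = np.asarray(distance, dtype=float)
    c = 20.0 * np.ceil((d - 10.0) / 20.0)
    return np.where(c == -180.0, 180.0, c)


@dataclass
class ResponseFunction:
    """Binned 1D response profile, per participant and group-averaged."""

    bin_centers: np.ndarray
    per_participant: pd.DataFrame  # index: participant, columns: bin centers
    counts: pd.DataFrame  # contributing vertices per (participant, bin)
    group: np.ndarray = field(default=None)  # norm-averaged; NaN where undefined

    @property
    def participants(self):
        return list(self.per_participant.index)


def bin_polar_responses(
    polar_angles: np.ndarray,
    participants: np.ndarray,
    betas: np.ndarray,
    rotations,
    bin_centers: np.ndarray = BIN_CENTERS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool stimuli after alignment and take per-participant bin medians.

    Parameters
    ----------
    polar_angles, participants
        Per-vertex pRF polar angle (deg) and participant label, length n.
    betas
        (n, n_stimuli) evoked responses, one column per stimulus.
    rotations
        Either a length-``n_stimuli`` sequence of alignment angles (normally
        the true stimulus angles) or an (n, n_stimuli) array of per-row
        alignment angles (used by the angular-error simulation, which rotates
        by the erroneous remembered location instead of the true one).

    Returns
    -------
    (medians, counts)
        DataFrames indexed by participant with one column per bin center.
    """
    betas = np.asarray(betas, dtype=float)
    n, n_stim = betas.shape
    rot = np.asarray(rotations, dtype=float)
    if rot.ndim == 1:
        rot = np.broadcast_to(rot, (n, n_stim))
    d = wrap_distance(np.asarray(polar_angles, dtype=float)[:, None] - rot)
    bins = assign_polar_bin(d)
    long = pd.DataFrame(
        {
            "participant": np.repeat(np.asarray(participants), n_stim),
            "bin": bins.ravel(),
            "beta": betas.ravel(),
        }
    )
    grouped = long.groupby(["participant", "bin"])["beta"]
    med = grouped.median().unstack("bin")
    cnt = grouped.size().unstack("bin")
    med = med.reindex(columns=bin_centers)
    cnt = cnt.reindex(columns=bin_centers).fillna(0).astype(int)
    return med, cnt


def participant_response_functions(
    table: pd.DataFrame,
    roi: str,
    task: str,
    stimulus_angles=(45.0, 135.0, 225.0, 315.0),
    beta_prefix: str = "beta",
) -> ResponseFunction:
    """Per-participant polar-angle response functions for one ROI and task."""
    sub = select_vertices(table, roi=roi, mode="polar")
    cols = [f"{beta_prefix}_{task}_{a:g}" for a in stimulus_angles]
    med, cnt = bin_polar_responses(
        sub["polar_angle"].to_numpy(),
        sub["participant"].to_numpy(),
        sub[cols].to_numpy(),
        np.asarray(stimulus_angles, dtype=float),
    )
    rf = ResponseFunction(bin_centers=BIN_CENTERS.copy(), per_participant=med, counts=cnt)
    rf.group = norm_average(med)
    return rf


# ---------------------------------------------------------------------------
# Group averaging and fitting
# ---------------------------------------------------------------------------


def norm_average(per_participant: pd.DataFrame) -> np.ndarray:
    """Normed mean across participants: mean of unit vectors times mean norm.

    Each participant's response vector is divided by its L2 norm before
    averaging, then the average is multiplied by the mean norm, so a
    participant with globally large responses cannot dominate. Bins missing
    for any participant are undefined (NaN) in the group profile; norms are
    taken over the commonly defined bins. Zero-norm participants are dropped
    with a warning.
    """
    values = per_participant.to_numpy(dtype=float)
    valid = np.all(np.isfinite(values), axis=0)
    out = np.full(values.shape[1], np.nan)
    if not valid.any():
        return out
    v = values[:, valid]
    norms = np.linalg.norm(v, axis=1)
    keep = norms > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-norm participant vector(s)")
    if not keep.any():
        return out
    v, norms = v[keep], norms[keep]
    out[valid] = (v / norms[:, None]).mean(axis=0) * norms.mean()
    return out


def fit_group_rf(rf: ResponseFunction, fwhm_reference: str = "zero"):
    """Fit the group profile and return (fit, metrics)."""
    fit = fit_diff_von_mises(rf.bin_centers, rf.group)
    return fit, curve_metrics(fit, fwhm_reference=fwhm_reference)


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Point fit plus participant-bootstrap draws and percentile intervals."""

    point_fit: DiffVonMisesFit
    point_metrics: CurveMetrics
    draws: pd.DataFrame  # columns: location, amplitude, fwhm; NaN for failed fits
    ci68: dict
    ci95: dict
    n_replicates: int
    n_failures: int
    seed: int | None = None

    def ci(self, metric: str, level: int = 95):
        return (self.ci95 if level == 95 else self.ci68)[metric]


def _percentile_ci(x: np.ndarray, level: float):
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (np.nan, np.nan)
    alpha = (100.0 - level) / 2.0
    return tuple(np.percentile(x, [alpha, 100.0 - alpha]))


def bootstrap_rf_fit(
    rf: ResponseFunction,
    n: int = 500,
    seed: int | None = 0,
    fwhm_reference: str = "zero",
    max_failure_fraction: float = 0.5,
) -> BootstrapResult:
    """Resample participants with replacement; re-average, re-fit, re-measure.

    Per-participant binned profiles are deterministic given the participant,
    so they are computed once and the resampling draws rows. Fit failures
    (degenerate or non-converged fits, undefined FWHM) yield NaN draws; more
    than ``max_failure_fraction`` failures is a hard error.
    """
    n_participants = rf.per_participant.shape[0]
    if n_participants < 2:
        raise ValueError("bootstrap requires at least 2 participants")
    rng = np.random.default_rng(seed)
    values = rf.per_participant.to_numpy(dtype=float)
    groups = np.empty((n, values.shape[1]))
    for b in range(n):
        idx = rng.integers(0, n_participants, n_participants)
        groups[b] = norm_average(pd.DataFrame(values[idx]))
    fits = fit_diff_von_mises_batch(rf.bin_centers, groups)
    rows = []
    failures = 0
    for fit in fits:
        if fit.degenerate or not fit.converged:
            failures += 1
            rows.append((np.nan, np.nan, np.nan))
            continue
        m = curve_metrics(fit, fwhm_reference=fwhm_reference)
        rows.append((m.location, m.amplitude, m.fwhm if m.fwhm_defined else np.nan))
    if failures > max_failure_fraction * n:
        raise RuntimeError(f"{failures}/{n} bootstrap replicate fits failed")
    draws = pd.DataFrame(rows, columns=list(METRICS))
    point_fit, point_metrics = fit_group_rf(rf, fwhm_reference=fwhm_reference)
    ci68 = {m: _percentile_ci(draws[m].to_numpy(), 68.0) for m in METRICS}
    ci95 = {m: _percentile_ci(draws[m].to_numpy(), 95.0) for m in METRICS}
    return BootstrapResult(
        point_fit=point_fit,
        point_metrics=point_metrics,
        draws=draws,
        ci68=ci68,
        ci95=ci95,
        n_replicates=n,
        n_failures=failures,
        seed=seed,
    )


def bootstrap_group_fit(
    table: pd.DataFrame,
    roi: str,
    task: str,
    n: int = 500,
    seed: int | None = 0,
    fwhm_reference: str = "zero",
) -> BootstrapResult:
    """Convenience wrapper: gate + bin + bootstrap for one (ROI, task) cell."""
    rf = participant_response_functions(table, roi, task)
    return bootstrap_rf_fit(rf, n=n, seed=seed, fwhm_reference=fwhm_reference)


# ---------------------------------------------------------------------------
# Contrast regressions over bootstrap replicates
# ---------------------------------------------------------------------------

ROI_ORDER = ("V1", "V2", "V3", "hV4", "LO", "V3ab")  # hierarchy coding 1..6

TASKS = ("perception", "memory")


@dataclass
class ContrastResult:
    """Task / ROI / interaction coefficients with percentile CIs.

    Task is coded +0.5 (perception) / -0.5 (memory); ROI is its numeric
    hierarchy position (V1 = 1 ... V3ab = 6), centered. Coefficients are
    ordinary least squares over the 12 (ROI x task) cells, one regression per
    bootstrap replicate; intervals are percentiles over replicates.
    """

    terms: tuple = ("intercept", "task", "roi", "task_x_roi")
    point: dict = field(default_factory=dict)
    ci68: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    draws: pd.DataFrame = None
    n_used: int = 0


def _contrast_design(roi_order=ROI_ORDER, tasks=TASKS) -> tuple[np.ndarray, list]:
    cells = [(roi, task) for roi in roi_order for task in tasks]
    roi_code = {roi: i + 1 for i, roi in enumerate(roi_order)}
    roi_centered = np.array([roi_code[r] for r, _ in cells], dtype=float)
    roi_centered -= roi_centered.mean()
    task_code = np.array([0.5 if t == "perception" else -0.5 for _, t in cells])
    X = np.column_stack(
        [np.ones(len(cells)), task_code, roi_centered, task_code * roi_centered]
    )
    return X, cells


def bootstrap_contrasts(
    results: dict,
    metric: str,
    roi_order=ROI_ORDER,
    tasks=TASKS,
) -> ContrastResult:
    """OLS contrasts of a tuning metric across the 12 (ROI, task) cells.

    ``results`` maps (roi, task) -> :class:`BootstrapResult` with matched
    replicate indices (same bootstrap seed per cell is fine; what matters is
    equal replicate counts). Replicates with a failed fit in any cell are
    dropped.
    """
    X, cells = _contrast_design(roi_order, tasks)
    counts = {results[c].n_replicates for c in cells}
    if len(counts) != 1:
        raise ValueError(f"mismatched replicate counts across cells: {sorted(counts)}")
    Y = np.column_stack([results[c].draws[metric].to_numpy() for c in cells]).T  # 12 x n
    ok = np.all(np.isfinite(Y), axis=0)
    pinv = np.linalg.pinv(X)
    coefs = pinv @ Y[:, ok]  # 4 x n_used
    point_y = np.array([getattr(results[c].point_metrics, metric) for c in cells])
    point = pinv @ point_y
    out = ContrastResult(n_used=int(ok.sum()))
    out.draws = pd.DataFrame(coefs.T, columns=list(out.terms))
    for i, term in enumerate(out.terms):
        out.point[term] = float(point[i])
        out.ci68[term] = _percentile_ci(coefs[i], 68.0)
        out.ci95[term] = _percentile_ci(coefs[i], 95.0)
    return out


# ---------------------------------------------------------------------------
# Individual-participant fits
# ---------------------------------------------------------------------------

FAR_BINS = (-160.0, 160.0, 180.0)  # bins farthest from the stimulus


def individual_fits(
    rf: ResponseFunction, fwhm_reference: str = "zero"
) -> pd.DataFrame:
    """Baseline-removed difference-of-von-Mises fit per participant.

    Each participant's profile is shifted so the mean response in the three
    bins farthest from the stimulus (-160, 160, 180 deg) is exactly 0% signal
    change, absorbing participant-specific offsets the group procedure does
    not model. Participants with missing far bins are skipped with a warning.
    """
    records = []
    far_idx = [list(rf.bin_centers).index(b) for b in FAR_BINS]
    for participant, row in rf.per_participant.iterrows():
        y = row.to_numpy(dtype=float)
        far = y[far_idx]
        if not np.all(np.isfinite(far)):
            warnings.warn(f"participant {participant}: far bins missing, skipped")
            continue
        shifted = y - far.mean()
        fit = fit_diff_von_mises(rf.bin_centers, shifted)
        m = curve_metrics(fit, fwhm_reference=fwhm_reference)
        records.append(
            {
                "participant": participant,
                "location": m.location,
                "amplitude": m.amplitude,
                "fwhm": m.fwhm,
                "fit_r2": fit.fit_r2,
                "converged": fit.converged and not fit.degenerate,
                "offset": far.mean(),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Eccentricity response functions
# ---------------------------------------------------------------------------


@dataclass
class EccentricityResponse:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    per_participant: pd.DataFrame
    group: np.ndarray
    ci95_low: np.ndarray = None
    ci95_high: np.ndarray = None


def eccentricity_response(
    table: pd.DataFrame,
    roi: str,
    task: str,
    stimulus_angles=(45.0, 135.0, 225.0, 315.0),
    n_boot: int = 500,
    seed: int | None = 0,
    beta_prefix: str = "beta",
) -> EccentricityResponse:
    """Median response in 0.5-dva eccentricity bins, norm-averaged, with CIs.

    Vertices are gated per stimulus (within 15 deg of polar angle of that
    stimulus) and pooled; no parametric curve is fit -- the binned estimates
    are the profile, with percentile CIs from participant resampling.
    """
    edges = ECC_BIN_EDGES
    centers = (edges[:-1] + edges[1:]) / 2.0
    frames = []
    for a in stimulus_angles:
        sub = select_vertices(table, roi=roi, mode="eccentricity", stimulus_angle=a)
        if sub.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "participant": sub["participant"].to_numpy(),
                    "ecc": sub["eccentricity"].to_numpy(),
                    "beta": sub[f"{beta_prefix}_{task}_{a:g}"].to_numpy(),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    # right-open bins [e, e + 0.5); the top edge closes the last bin
    idx = np.clip(np.searchsorted(edges, long["ecc"].to_numpy(), side="right") - 1, 0, len(centers) - 1)
    long["bin"] = centers[idx]
    med = long.groupby(["participant", "bin"])["beta"].median().unstack("bin")
    med = med.reindex(columns=centers)
    group = norm_average(med)
    rng = np.random.default_rng(seed)
    values = med.to_numpy(dtype=float)
    boots = np.empty((n_boot, len(centers)))
    for b in range(n_boot):
        take = rng.integers(0, values.shape[0], values.shape[0])
        boots[b] = norm_average(pd.DataFrame(values[take]))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return EccentricityResponse(
        bin_edges=edges,
        bin_centers=centers,
        per_participant=med,
        group=group,
        ci95_low=lo,
        ci95_high=hi,
    )


# ---------------------------------------------------------------------------
# 2D visual field maps
# ---------------------------------------------------------------------------


def visual_field_map(
    table: pd.DataFrame,
    roi: str,
    task: str,
    stimulus_angles=(45.0, 135.0, 225.0, 315.0),
    half_extent: float = 8.0,
    step: float = 0.25,
    beta_prefix: str = "beta",
):
    """Group-average evoked response interpolated over visual-field coordinates.

    Per participant and stimulus, scattered (x, y, beta) data are linearly
    interpolated onto a fixed grid after rotating the vertex coordinates so
    the stimulus maps to the upper vertical meridian; each image is z-scored
    over its valid pixels, then averaged across stimuli and participants.

    Returns ``(image, (xs, ys))``; pixels never covered by the convex hull of
    any participant's vertices are NaN.
    """
    from scipy.interpolate import griddata

    sub = table[(table["roi"] == roi) & (table["r2"] >= MIN_PRF_R2)]
    xs = np.arange(-half_extent, half_extent + step / 2, step)
    ys = xs.copy()
    gx, gy = np.meshgrid(xs, ys)
    images = []
    for participant, psub in sub.groupby("participant"):
        per_stim = []
        for a in stimulus_angles:
            theta = psub["polar_angle"].to_numpy() - a  # align stimulus to 0 (up)
            ecc = psub["eccentricity"].to_numpy()
            px = ecc * np.sin(np.deg2rad(theta))
            py = ecc * np.cos(np.deg2rad(theta))
            beta = psub[f"{beta_prefix}_{task}_{a:g}"].to_numpy()
            if len(psub) < 3:
                continue
            img = griddata((px, py), beta, (gx, gy), method="linear")
            valid = np.isfinite(img)
            sd = np.nanstd(img)
            if not valid.any() or sd <= 1e-12 * max(1.0, float(abs(np.nanmean(img)))):
                warnings.warn(
                    f"degenerate visual-field image (participant {participant}, stim {a})"
                )
                continue
            per_stim.append((img - np.nanmean(img)) / sd)
        if per_stim:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
                images.append(np.nanmean(np.stack(per_stim), axis=0))
    if not images:
        raise ValueError("no participant produced a valid visual-field image")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        group = np.nanmean(np.stack(images), axis=0)
    return group, (xs, ys)


# ---------------------------------------------------------------------------
# Model-vs-data evaluation
# ---------------------------------------------------------------------------


def coefficient_of_determination(pred: np.ndarray, obs: np.ndarray) -> float:
    """R2 of predictions against observations (1 - SSres/SStot; can be negative)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observations have zero variance; R2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def best_scale_factor(preds, obss) -> float:
    """Single least-squares rescale s* = sum(pred*obs) / sum(pred^2), pooled.

    ``preds``/``obss`` may be single arrays or lists of arrays (one per ROI);
    pooling across ROIs yields the one shared factor applied everywhere.
    """
    if isinstance(preds, (list, tuple)):
        p = np.concatenate([np.ravel(np.asarray(a, dtype=float)) for a in preds])
        o = np.concatenate([np.ravel(np.asarray(a, dtype=float)) for a in obss])
    else:
        p = np.ravel(np.asarray(preds, dtype=float))
        o = np.ravel(np.asarray(obss, dtype=float))
    ok = np.isfinite(p) & np.isfinite(o)
    p, o = p[ok], o[ok]
    denom = np.sum(p * p)
    if denom == 0:
        raise ValueError("all-zero predictions; scale factor undefined")
    return float(np.sum(p * o) / denom)


def evaluate_predictions(pred: np.ndarray, obs: np.ndarray, scale: float | None = None) -> dict:
    """R2 before and after applying a (possibly pooled) rescale factor."""
    if scale is None:
        scale = best_scale_factor(pred, obs)
    return {
        "r2": coefficient_of_determination(pred, obs),
        "r2_rescaled": coefficient_of_determination(np.asarray(pred, dtype=float) * scale, obs),
        "scale_factor": float(scale),
    }
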