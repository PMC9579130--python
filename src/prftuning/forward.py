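"""pRF forward model: from binary contrast apertures to predicted BOLD amplitudes.

Three variants are supported. The *linear* model sums the stimulus aperture
under an isotropic 2D Gaussian receptive field and scales by beta. The *CSS*
(compressive spatial summation) model additionally applies a power-law
exponent n in (0, 1] to the summed drive before scaling, boosting small
responses; n = 1 recovers the linear model. The *DoG + CSS* model replaces
the Gaussian with a difference of two Gaussians sharing a center: the
surround is twice as wide and half as high as the center in peak terms, and
the center is pre-rescaled (sigma * sqrt(2), beta * 2) so the composite kernel
keeps the FWHM and peak amplitude of the original Gaussian while adding
suppressive flanks.

Normalization: Gaussians are normalized to unit sum over the grid, so a
full-field stimulus drives a linear/CSS vertex at exactly beta. The DoG
kernel is scaled so its peak equals the peak of the unit-sum original-sigma
Gaussian (its plane integral is negative by construction, so no positive
full-field normalizer exists).

Negative DoG drive is passed through the compressive exponent with the
signed-power rule sign(d) * |d|**n, so surround suppression survives the
nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from prftuning.apertures import ApertureGrid
from prftuning.params import PRFParams

VARIANTS = ("linear", "css", "dog_css")


@dataclass(frozen=True)
class ForwardModelSpec:
    """Which pRF variant to run and its fixed structural ratios.

    ``surround_sigma_ratio`` and ``surround_height_ratio`` are the DoG's
    fixed surround:center size (2:1) and height (1:2, i.e. 0.5) ratios;
    ``center_sigma_rescale``/``center_beta_rescale`` are the pre-conversion
    rescalings (sqrt(2), 2) that keep the composite kernel's FWHM and peak
    equal to the original Gaussian's.
    """

    variant: str = "css"
    beta: float = 1.0
    surround_sigma_ratio: float = 2.0
    surround_height_ratio: float = 0.5
    center_sigma_rescale: float = float(np.sqrt(2.0))
    center_beta_rescale: float = 2.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")


# ---------------------------------------------------------------------------
# Gaussian and DoG kernels
# ---------------------------------------------------------------------------


def _grid_sum_1d(centers: np.ndarray, mu, sigma) -> np.ndarray:
    """Sum of exp(-(c - mu)^2 / (2 sigma^2)) over grid centers, vectorized over mu/sigma."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))[:, None]
    return np.exp(-((centers[None, :] - mu) ** 2) / (2.0 * sigma**2)).sum(axis=1)


def gaussian_field(prf: PRFParams, grid: ApertureGrid) -> np.ndarray:
    """Isotropic 2D Gaussian at pixel centers, normalized to unit sum over the grid."""
    if not prf.sigma > 0:
        raise ValueError("sigma must be > 0")
    xx, yy = grid.pixel_coords()
    g = np.exp(-((xx - prf.x) ** 2 + (yy - prf.y) ** 2) / (2.0 * prf.sigma**2))
    return g / g.sum()


@dataclass(frozen=True)
class DoGKernel:
    """Difference-of-Gaussians kernel in unit-peak component terms.

    ``kernel(r) = center_height * exp(-r^2 / (2 center_sigma^2))
                 - surround_height * exp(-r^2 / (2 surround_sigma^2))``
    """

    center_sigma: float
    center_height: float
    surround_sigma: float
    surround_height: float
    source_sigma: float
    source_beta: float

    def evaluate(self, r) -> np.ndarray:
        r2 = np.asarray(r, dtype=float) ** 2
        return self.center_height * np.exp(
            -r2 / (2.0 * self.center_sigma**2)
        ) - self.surround_height * np.exp(-r2 / (2.0 * self.surround_sigma**2))

    @property
    def peak_height(self) -> float:
        return self.center_height - self.surround_height

    def plane_integral(self) -> float:
        """Analytic integral over the plane; negative whenever source_beta > 0."""
        return float(
            2.0 * np.pi * (
                self.center_height * self.center_sigma**2
                - self.surround_height * self.surround_sigma**2
            )
        )


def dog_from_gaussian(prf: PRFParams, beta: float = 1.0, spec: ForwardModelSpec | None = None) -> DoGKernel:
    """Convert a Gaussian pRF to a DoG pRF with fixed 1:2 size and 2:1 height ratios.

    The original sigma is multiplied by sqrt(2) and the original beta by 2
    before subtracting a surround that is twice as wide and half as high,
    which leaves the composite kernel with the same FWHM and peak amplitude
    as the original unit-peak Gaussian scaled by ``beta``.
    """
    if not prf.sigma > 0:
        raise ValueError("sigma must be > 0")
    spec = spec or ForwardModelSpec(variant="dog_css")
    center_sigma = prf.sigma * spec.center_sigma_rescale
    center_height = beta * spec.center_beta_rescale
    return DoGKernel(
        center_sigma=center_sigma,
        center_height=center_height,
        surround_sigma=center_sigma * spec.surround_sigma_ratio,
        surround_height=center_height * spec.surround_height_ratio,
        source_sigma=prf.sigma,
        source_beta=beta,
    )


# ---------------------------------------------------------------------------
# Drive and response prediction
# ---------------------------------------------------------------------------


def _drive_arrays(
    aperture: ApertureGrid, x: np.ndarray, y: np.ndarray, sigma: np.ndarray, variant: str,
    spec: ForwardModelSpec,
) -> np.ndarray:
    """Stimulus drive per vertex: sum of the (unit-sum-normalized) kernel over lit pixels.

    Only the aperture's active pixels contribute, so the cost is
    n_vertices x n_active_pixels; the unit-sum normalizer uses the exact
    separable full-grid sum.
    """
    px, py = aperture.active_coords()
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[:, None]
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("all sigmas must be > 0")
    d2 = (px[None, :] - x) ** 2 + (py[None, :] - y) ** 2
    if variant in ("linear", "css"):
        if px.size == 0:
            return np.zeros(x.shape[0])
        norm = _grid_sum_1d(aperture.x_centers, x[:, 0], sigma) * _grid_sum_1d(
            aperture.y_centers, y[:, 0], sigma
        )
        g = np.exp(-d2 / (2.0 * sigma[:, None] ** 2))
        return g.sum(axis=1) / norm
    # dog_css: unit-peak DoG components, scaled to the unit-sum original peak
    cs = sigma * spec.center_sigma_rescale
    ss = cs * spec.surround_sigma_ratio
    ch = spec.center_beta_rescale
    sh = ch * spec.surround_height_ratio
    norm_orig = _grid_sum_1d(aperture.x_centers, x[:, 0], sigma) * _grid_sum_1d(
        aperture.y_centers, y[:, 0], sigma
    )
    if px.size == 0:
        return np.zeros(x.shape[0])
    dog = ch * np.exp(-d2 / (2.0 * cs[:, None] ** 2)) - sh * np.exp(
        -d2 / (2.0 * ss[:, None] ** 2)
    )
    return dog.sum(axis=1) / norm_orig


def _apply_output_nonlinearity(drive, exponent, beta, variant: str):
    drive = np.asarray(drive, dtype=float)
    n = np.asarray(exponent, dtype=float)
    if variant == "linear":
        return beta * drive
    # signed power: sign(d) * |d|^n keeps suppression suppressive
    return beta * np.sign(drive) * np.abs(drive) ** n


def predict_response(aperture: ApertureGrid, prf: PRFParams, spec: ForwardModelSpec) -> float:
    """Predicted BOLD amplitude (% signal change) of one vertex to one aperture."""
    drive = _drive_arrays(
        aperture,
        np.array([prf.x]),
        np.array([prf.y]),
        np.array([prf.sigma]),
        spec.variant,
        spec,
    )
    exponent = 1.0 if spec.variant == "linear" else prf.exponent
    return float(_apply_output_nonlinearity(drive, exponent, spec.beta, spec.variant)[0])


def predict_table(
    x, y, sigma, exponent, aperture: ApertureGrid, spec: ForwardModelSpec, beta=None
) -> np.ndarray:
    """Vectorized prediction for arrays of pRF parameters against one aperture."""
    drive = _drive_arrays(aperture, x, y, sigma, spec.variant, spec)
    n = 1.0 if spec.variant == "linear" else np.asarray(exponent, dtype=float)
    b = spec.beta if beta is None else np.asarray(beta, dtype=float)
    return _apply_output_nonlinearity(drive, n, b, spec.variant)


def predict_all(
    vertices: pd.DataFrame, stimuli: dict, spec: ForwardModelSpec, sigma_scale=1.0, beta=None
) -> pd.DataFrame:
    """Predict responses of every vertex row to every stimulus aperture.

    Parameters
    ----------
    vertices
        Vertex table with ``x``, ``y``, ``sigma``, ``exponent`` columns.
    stimuli
        Mapping of stimulus polar angle -> :class:`ApertureGrid`; all four
        experimental stimuli must be present and share geometry.
    sigma_scale
        Optional multiplier on every sigma (used to widen memory profiles).
    beta
        Optional per-row amplitude scale overriding ``spec.beta``.

    Returns
    -------
    DataFrame indexed like ``vertices`` with one ``pred_<angle>`` column per
    stimulus. Predictions are row-order invariant.
    """
    if len(stimuli) < 1:
        raise ValueError("no stimulus apertures supplied")
    grids = list(stimuli.values())
    for g in grids[1:]:
        if not grids[0].same_geometry(g):
            raise ValueError("stimulus apertures disagree on grid geometry")
    out = pd.DataFrame(index=vertices.index)
    sig = vertices["sigma"].to_numpy() * sigma_scale
    for angle, grid in stimuli.items():
        out[f"pred_{angle:g}"] = predict_table(
            vertices["x"].to_numpy(),
            vertices["y"].to_numpy(),
            sig,
            vertices["exponent"].to_numpy(),
            grid,
            spec,
            beta=beta,
        )
    return out
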