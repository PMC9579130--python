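"""Binary contrast apertures on the 101 x 101 stimulus grid.

Stimuli are represented the way pRF models consume them: a square
field of view centered on fixation, rasterized to a binary contrast
aperture. Pixel *centers* define the degree mapping; row 0 / col 0 is the
upper-left pixel and +y is up in degree space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prftuning.angles import polar_to_cartesian

DEFAULT_GRID_N = 101
#: Field-of-view width in degrees; the retinotopy stimulus covered a circular
#: aperture of radius 12 dva, i.e. the central 24 deg.
DEFAULT_EXTENT = 24.0


@dataclass(frozen=True)
class ApertureGrid:
    """A binary contrast aperture with its degree geometry.

    Parameters
    ----------
    values
        (n, n) array with entries in {0, 1}.
    extent
        Side length of the square field of view in degrees, centered on
        fixation.
    """

    values: np.ndarray
    extent: float = DEFAULT_EXTENT

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"aperture must be square, got shape {v.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("aperture values must be binary (0/1)")
        if not self.extent > 0:
            raise ValueError("field extent must be positive")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def pixel_size(self) -> float:
        return self.extent / self.n

    @property
    def x_centers(self) -> np.ndarray:
        """x coordinate (deg) of each column's pixel centers, left to right."""
        half = self.extent / 2.0
        return -half + (np.arange(self.n) + 0.5) * self.pixel_size

    @property
    def y_centers(self) -> np.ndarray:
        """y coordinate (deg) of each row's pixel centers, top to bottom (+y up)."""
        half = self.extent / 2.0
        return half - (np.arange(self.n) + 0.5) * self.pixel_size

    def pixel_coords(self):
        """Dense (n, n) arrays of pixel-center x and y coordinates."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def active_coords(self):
        """(x, y) coordinates (deg) of pixels set to 1."""
        rows, cols = np.nonzero(self.values)
        return self.x_centers[cols], self.y_centers[rows]

    def same_geometry(self, other: "ApertureGrid") -> bool:
        return self.n == other.n and np.isclose(self.extent, other.extent)

    # -- plain-text and PNG round trips ------------------------------------

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# extent_deg={self.extent:.10g}\n")
            np.savetxt(fh, self.values, fmt="%d")

    @classmethod
    def from_text(cls, path) -> "ApertureGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# extent_deg="):
                raise ValueError(f"{path}: missing extent header")
            extent = float(header.split("=", 1)[1])
            values = np.loadtxt(fh, dtype=int)
        return cls(values=values, extent=extent)

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.values * np.uint8(255), mode="L").save(path)

    @classmethod
    def from_png(cls, path, extent: float = DEFAULT_EXTENT) -> "ApertureGrid":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return cls(values=(arr > 127).astype(np.uint8), extent=extent)


def make_disk_aperture(
    polar_angle: float,
    eccentricity: float,
    diameter: float,
    extent: float = DEFAULT_EXTENT,
    n: int = DEFAULT_GRID_N,
) -> ApertureGrid:
    """Rasterize a circular stimulus into a binary contrast aperture.

    A pixel is set iff its center lies within ``diameter / 2`` of the disk
    center placed at (``polar_angle``, ``eccentricity``).

    Raises
    ------
    ValueError
        If the disk does not fit inside the field of view.
    """
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    if eccentricity + diameter / 2.0 > extent / 2.0:
        raise ValueError(
            f"disk at eccentricity {eccentricity} deg with diameter {diameter} deg "
            f"extends outside the {extent} deg field of view"
        )
    x0, y0 = polar_to_cartesian(polar_angle, eccentricity)
    grid = ApertureGrid(values=np.zeros((n, n), dtype=np.uint8), extent=extent)
    xx, yy = grid.pixel_coords()
    inside = (xx - x0) ** 2 + (yy - y0) ** 2 <= (diameter / 2.0) ** 2
    return ApertureGrid(values=inside.astype(np.uint8), extent=extent)


def stimulus_apertures(
    angles=(45.0, 135.0, 225.0, 315.0),
    eccentricity: float = 2.0,
    diameter: float = 1.5,
    extent: float = DEFAULT_EXTENT,
    n: int = DEFAULT_GRID_N,
) -> dict:
    """The experiment's four isoeccentric stimulus apertures, keyed by angle."""
    return {
        float(a): make_disk_aperture(a, eccentricity, diameter, extent=extent, n=n)
        for a in angles
    }
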