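"""Shared containers and exceptions for the histology–dMRI pipeline.

The pipeline passes scalar maps between stages on two kinds of grid: the
high-resolution histology pixel grid (~0.5 μm/px) and the MR voxel grid
(200 μm). Both are represented by :class:`ParameterMap`, a value array plus a
physical resolution and a validity mask. All physical lengths are carried in
μm and all diffusivities in mm²/s; unit conversions happen at I/O time only.

Grid convention: arrays are indexed ``(row, col)`` = ``(y, x)``, 0-based, and
the physical center of cell ``(r, c)`` sits at ``((c + 0.5)·res, (r + 0.5)·res)``
in (x, y) μm relative to the grid origin. The histology section plane is the
MR (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class MesohistError(Exception):
    """Base class for pipeline errors."""


class ShapeError(MesohistError):
    """Arrays that must share a grid do not."""


class ParameterError(MesohistError):
    """A parameter is outside its documented range or mode is unknown."""


class IdentifiabilityError(MesohistError):
    """The diffusion encoding design does not identify the tensor."""


class ResolutionError(MesohistError):
    """Grid resolutions are inconsistent (e.g. non-integer block ratio)."""


class DataError(MesohistError):
    """Not enough (or degenerate) data for the requested fit/statistic."""


class ZeroVarianceError(DataError):
    """A variance in a denominator is zero (undefined statistic)."""


class DegenerateLandmarksError(MesohistError):
    """Landmark configuration is degenerate (too few, coincident, collinear)."""


class SchemaError(MesohistError):
    """A CSV/config file is missing required columns or malformed."""


class NormalizationError(MesohistError):
    """Normalization is undefined (e.g. empty centroid set, zero maximum)."""


class ConfigError(MesohistError):
    """A phantom/run configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Grids and maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid2D:
    """A 2D analysis grid: shape ``(ny, nx)``, cell size and origin in μm."""

    shape: Tuple[int, int]
    resolution_um: float
    origin_um: Tuple[float, float] = (0.0, 0.0)

    @property
    def extent_um(self) -> Tuple[float, float]:
        """(width, height) of the grid in μm."""
        ny, nx = self.shape
        return (nx * self.resolution_um, ny * self.resolution_um)

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates in μm, each shaped ``(ny, nx)``."""
        ny, nx = self.shape
        ox, oy = self.origin_um
        x = ox + (np.arange(nx) + 0.5) * self.resolution_um
        y = oy + (np.arange(ny) + 0.5) * self.resolution_um
        return np.meshgrid(x, y)


@dataclass
class ParameterMap:
    """A scalar map on a regular grid with a validity mask.

    Parameters
    ----------
    values
        Scalar value per grid cell; any dimensionality (2D maps for the
        section plane, 3D for volumetric MR maps).
    resolution_um
        Isotropic cell size in μm.
    units
        Free-text units label, e.g. ``"mm^2/s"`` or ``"1"``.
    mask
        Boolean validity mask, same shape as ``values``. ``None`` means
        "valid wherever finite".
    name
        Optional short name (``"MD"``, ``"FA_IP"``, ``"SA"``, ``"CD"``...).
    """

    values: np.ndarray
    resolution_um: float
    units: str = "1"
    mask: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ShapeError(
                    f"mask shape {self.mask.shape} != values shape "
                    f"{self.values.shape}"
                )
        if self.resolution_um <= 0:
            raise ParameterError("resolution_um must be positive")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """Values at valid cells, flattened."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, **kw) -> "ParameterMap":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def copy(self) -> "ParameterMap":
        return ParameterMap(
            self.values.copy(), self.resolution_um, self.units,
            self.mask.copy(), self.name,
        )


def check_same_grid(*maps: ParameterMap) -> None:
    """Raise :class:`ShapeError` unless all maps share shape and resolution."""
    ref = maps[0]
    for m in maps[1:]:
        if m.shape != ref.shape:
            raise ShapeError(f"map shapes differ: {m.shape} vs {ref.shape}")
        if not np.isclose(m.resolution_um, ref.resolution_um):
            raise ResolutionError(
                f"map resolutions differ: {m.resolution_um} vs "
                f"{ref.resolution_um} μm"
            )


def masked_gaussian_smooth(
    values: np.ndarray,
    mask: np.ndarray,
    sigma_cells: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mask-aware Gaussian smoothing (normalized convolution).

    Invalid cells contribute zero weight; the result is the Gaussian-weighted
    mean of valid neighbors, so a constant map stays constant and values never
    leave the input range. Reflect padding at borders.

    Returns (smoothed values, output mask). Cells with (numerically) no valid
    support are invalid in the output.
    """
    from scipy.ndimage import gaussian_filter

    if sigma_cells < 0:
        raise ParameterError("smoothing sigma must be >= 0")
    if sigma_cells == 0:
        return values.copy(), mask.copy()
    w = mask.astype(float)
    v = np.where(mask, values, 0.0)
    num = gaussian_filter(v, sigma_cells, mode="reflect")
    den = gaussian_filter(w, sigma_cells, mode="reflect")
    out = np.full_like(num, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out, ok & mask
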