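"""Histology-derived maps: structure anisotropy (SA) and cell density (CD).

Structure tensor analysis mirrors diffusion tensor analysis with diffusion
encodings replaced by spatial derivatives: per pixel,

    H = [[Hxx, Hxy], [Hxy, Hyy]],   Hab = Gσi * (∂a I · ∂b I)

where the gradients are Gaussian derivatives at a fine scale (σ = 0.25 μm)
and the products are integrated at a mesoscopic scale (σ = 15 μm). The field
is then downsampled to the MR grid (200 μm) and SA = (λ1 − λ2)/(λ1 + λ2) is
computed from the eigenvalues of the downsampled tensor, followed by the same
final σ = 40 μm smoothing as the dMRI maps.

Cell density is the nucleus-centroid count per MR-voxel-sized area,
normalized by the sample maximum. Nucleus detection itself is external —
centroid tables are an input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import (
    Grid2D,
    NormalizationError,
    ParameterError,
    ParameterMap,
    ResolutionError,
    ShapeError,
)
from .dti import _eig2x2

# Rec. 709 luma weights for RGB -> relative luminance.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

# Normalized hematoxylin absorbance vector (Ruifrok & Johnston stain basis).
_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
_HEMATOXYLIN = _HEMATOXYLIN / np.linalg.norm(_HEMATOXYLIN)


@dataclass
class HistologyImage:
    """An RGB histology section with physical pixel size.

    ``rgb`` is ``(ny, nx, 3)``, either 8-bit or already normalized to [0, 1].
    """

    rgb: np.ndarray
    pixel_size_um: float = 0.5
    tissue_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ShapeError("histology image must be (ny, nx, 3) RGB")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel size must be positive")

    def normalized(self) -> np.ndarray:
        """RGB as float in [0, 1] regardless of input dtype."""
        if np.issubdtype(self.rgb.dtype, np.integer):
            return self.rgb.astype(float) / 255.0
        return np.clip(self.rgb.astype(float), 0.0, 1.0)


@dataclass
class StructureTensorField:
    """Per-cell structure tensor components on a stated-resolution grid."""

    h_xx: np.ndarray
    h_xy: np.ndarray
    h_yy: np.ndarray
    resolution_um: float
    mode: str = "pixel"  # "pixel" | "tensor-average" | "eigenvalue-average"
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.h_xx.shape, dtype=bool)

    def eigenvalues(self) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted eigenvalues (λ1 ≥ λ2), clamped to ≥ 0."""
        l1, l2 = _eig2x2(self.h_xx, self.h_yy, self.h_xy)
        return np.clip(l1, 0.0, None), np.clip(l2, 0.0, None)

    def orientation(self) -> np.ndarray:
        """Structure (coherence) direction: angle of the *minor* eigenvector.

        Image gradients run perpendicular to stripes, so the eigenvector of
        the smaller eigenvalue of H points along the structures — the axis a
        diffusion tensor's major eigenvector would take. Radians, mod π.
        """
        major = 0.5 * np.arctan2(2.0 * self.h_xy, self.h_xx - self.h_yy)
        return np.mod(major + 0.5 * np.pi, np.pi)


@dataclass
class CentroidSet:
    """Nucleus centroid positions (μm) within a stated image extent (μm)."""

    x_um: np.ndarray
    y_um: np.ndarray
    extent_um: Tuple[float, float]

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float).ravel()
        self.y_um = np.asarray(self.y_um, dtype=float).ravel()
        if self.x_um.shape != self.y_um.shape:
            raise ShapeError("x and y centroid arrays differ in length")

    def __len__(self) -> int:
        return self.x_um.size


def to_intensity(image: HistologyImage, mode: str = "luminance") -> np.ndarray:
    """Collapse RGB to a single channel in [0, 1].

    ``luminance`` uses Rec. 709 relative luminance. ``hematoxylin_od``
    projects per-pixel optical density onto the hematoxylin stain vector
    (nuclear contrast), rescaled into [0, 1] by clipping at OD 1.
    """
    rgb = image.normalized()
    if mode == "luminance":
        return rgb @ _LUMA
    if mode == "hematoxylin_od":
        od = -np.log10(np.clip(rgb, 1e-6, 1.0))
        return np.clip(od @ _HEMATOXYLIN, 0.0, 1.0)
    raise ParameterError(f"unknown intensity mode: {mode!r}")


def structure_tensor_highres(
    intensity: np.ndarray,
    pixel_size_um: float = 0.5,
    sigma_derivative_um: float = 0.25,
    sigma_integration_um: float = 15.0,
) -> StructureTensorField:
    """Pixel-resolution structure tensor of a scalar histology image.

    Gaussian-derivative gradients at the derivative scale; each gradient
    product then Gaussian-integrated at the integration scale. Reflect
    padding at borders. Axis convention: x = columns, y = rows.
    """
    if sigma_derivative_um < 0 or sigma_integration_um < 0:
        raise ParameterError("sigma values must be >= 0")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ShapeError("intensity image must be 2D")
    s_d = sigma_derivative_um / pixel_size_um
    s_i = sigma_integration_um / pixel_size_um
    if min(intensity.shape) < 6 * max(s_i, 1.0):
        raise ShapeError(
            f"image {intensity.shape} smaller than 6× the integration scale "
            f"({s_i:.1f} px)"
        )
    # order=(0,1): Gaussian-smoothed derivative along columns (x), etc.
    gx = gaussian_filter(intensity, s_d, order=(0, 1), mode="reflect")
    gy = gaussian_filter(intensity, s_d, order=(1, 0), mode="reflect")
    h_xx = gaussian_filter(gx * gx, s_i, mode="reflect")
    h_yy = gaussian_filter(gy * gy, s_i, mode="reflect")
    h_xy = gaussian_filter(gx * gy, s_i, mode="reflect")
    return StructureTensorField(h_xx, h_xy, h_yy, pixel_size_um, mode="pixel")


def downsample_structure_tensor(
    field: StructureTensorField,
    mr_resolution_um: float = 200.0,
    mode: str = "tensor-average",
) -> StructureTensorField:
    """Average the structure tensor into MR-voxel-sized blocks.

    ``tensor-average`` (default) averages the components Hxx, Hxy, Hyy per
    block, preserving orientation for DEC rendering. ``eigenvalue-average``
    averages the *sorted eigenvalues* per block into an axis-free diagonal
    tensor diag(λ̄1, λ̄2) — orientation is then undefined. Blocks are aligned
    to the grid origin; trailing partial blocks are dropped (the MR grid
    covers full blocks only).
    """
    ratio = mr_resolution_um / field.resolution_um
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ResolutionError(
            f"MR cell size {mr_resolution_um} μm is not an integer multiple "
            f"of the pixel size {field.resolution_um} μm"
        )
    ny, nx = field.h_xx.shape
    by, bx = ny // n, nx // n
    if by == 0 or bx == 0:
        raise ShapeError("image smaller than one MR cell")

    def block_mean(a: np.ndarray) -> np.ndarray:
        return a[: by * n, : bx * n].reshape(by, n, bx, n).mean(axis=(1, 3))

    if mode == "tensor-average":
        out = StructureTensorField(
            block_mean(field.h_xx),
            block_mean(field.h_xy),
            block_mean(field.h_yy),
            mr_resolution_um,
            mode=mode,
        )
    elif mode == "eigenvalue-average":
        l1, l2 = field.eigenvalues()
        out = StructureTensorField(
            block_mean(l1),
            np.zeros((by, bx)),
            block_mean(l2),
            mr_resolution_um,
            mode=mode,
        )
    else:
        raise ParameterError(f"unknown downsampling mode: {mode!r}")
    return out


def map_sa(
    field: StructureTensorField,
    smooth_sigma_um: float = 40.0,
) -> ParameterMap:
    """Structure anisotropy SA = (λ1 − λ2)/(λ1 + λ2) at MR resolution.

    Defined as 0 where λ1 + λ2 = 0 (featureless block); followed by the same
    σ = 40 μm Gaussian smoothing as the dMRI maps to absorb small
    coregistration errors.
    """
    from .dti import smooth_map

    l1, l2 = field.eigenvalues()
    s = l1 + l2
    sa = np.zeros_like(s)
    nz = s > 0
    sa[nz] = (l1[nz] - l2[nz]) / s[nz]
    sa = np.clip(sa, 0.0, 1.0)
    pmap = ParameterMap(
        np.where(field.mask, sa, np.nan),
        field.resolution_um,
        units="1",
        mask=field.mask.copy(),
        name="SA",
    )
    if smooth_sigma_um > 0:
        pmap = smooth_map(pmap, smooth_sigma_um)
        pmap.name = "SA"
    return pmap


def map_structure_dec(
    field: StructureTensorField, sa: ParameterMap
) -> np.ndarray:
    """DEC rendering of the structure orientation, intensity scaled by SA.

    Hue comes from the minor eigenvector of H (along-stripe direction);
    x → red, y → green. Requires component ("tensor-average" or pixel)
    tensors — eigenvalue-averaged fields carry no orientation.
    """
    from .dti import map_dec

    if field.mode == "eigenvalue-average":
        raise ParameterError(
            "orientation is undefined after eigenvalue-average downsampling"
        )
    ang = field.orientation()
    vec = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return map_dec(vec, sa)


def map_cell_density(
    centroids: CentroidSet,
    grid: Grid2D,
    normalize: bool = True,
) -> ParameterMap:
    """Rasterize nucleus centroids into per-MR-cell counts (optionally
    normalized by the sample maximum so the map peaks at 1).

    Bin membership is half-open ``[left, right)`` per axis; centroids exactly
    on the far grid boundary fall outside, so the unnormalized counts sum to
    the number of in-grid centroids exactly.
    """
    ny, nx = grid.shape
    res = grid.resolution_um
    ox, oy = grid.origin_um
    cx = np.floor((centroids.x_um - ox) / res).astype(int)
    cy = np.floor((centroids.y_um - oy) / res).astype(int)
    # floor() can put right-edge points into bin nx; the explicit upper bound
    # enforces the half-open convention.
    inside = (
        (centroids.x_um >= ox) & (centroids.x_um < ox + nx * res)
        & (centroids.y_um >= oy) & (centroids.y_um < oy + ny * res)
    )
    counts = np.zeros((ny, nx), dtype=float)
    np.add.at(counts, (cy[inside], cx[inside]), 1.0)
    if normalize:
        peak = counts.max() if counts.size else 0.0
        if peak <= 0:
            raise NormalizationError(
                "cannot normalize cell density: no centroids inside the grid"
            )
        counts = counts / peak
        units = "1"
    else:
        units = "count"
    return ParameterMap(counts, res, units=units, name="CD")
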