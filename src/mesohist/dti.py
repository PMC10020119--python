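"""Diffusion tensor estimation and scalar map derivation.

Per voxel, the signal follows the monoexponential tensor model
``S = S0 · exp(−b gᵀ D g)``. Taking logs makes the model linear in
``(ln S0, D_xx, D_yy, D_zz, D_xy, D_xz, D_yz)``, which is estimated by
ordinary least squares over all measurements jointly (all three shells;
no separate b0 image is assumed — the lowest shell anchors the amplitude).

From the fitted tensor we derive:

* MD — mean diffusivity, trace/3 (mm²/s), computed from the raw components
  so that clamping does not bias it;
* FA — fractional anisotropy of the three (clamped) eigenvalues;
* FA_IP — in-plane fractional anisotropy ``(λ1 − λ2)/(λ1 + λ2)`` of the 2×2
  sub-tensor restricted to the section (x, y) plane; insensitive by
  construction to the through-plane components D_zz, D_xz, D_yz;
* DEC — directionally encoded color maps, |principal axis| as RGB scaled by
  the anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .containers import (
    IdentifiabilityError,
    ParameterError,
    ParameterMap,
    ShapeError,
    masked_gaussian_smooth,
)

# Electrostatically optimized six-direction scheme (icosahedral vertices);
# the classic minimal DTI direction set. Overridable from protocol files.
DEFAULT_SIX_DIRECTIONS = np.array(
    [
        [1.0, 0.0, 1.0],
        [-1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
        [1.0, 1.0, 0.0],
        [-1.0, 1.0, 0.0],
    ]
) / np.sqrt(2.0)

#: The acquisition shells used throughout: three b-values on six directions.
DEFAULT_B_VALUES = (100.0, 1000.0, 3000.0)


@dataclass
class DiffusionProtocol:
    """Diffusion encoding: b-value (s/mm²) and unit direction per measurement.

    Gradient timing (δ, Δ, t_eff in ms) is descriptive metadata only — the
    Gaussian tensor model does not use it.
    """

    b_values: np.ndarray
    directions: np.ndarray
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.b_values.size, 3):
            raise ShapeError(
                f"directions shape {self.directions.shape} incompatible with "
                f"{self.b_values.size} b-values"
            )
        nz = self.b_values > 0
        norms = np.linalg.norm(self.directions[nz], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ParameterError(
                "gradient directions must be unit vectors for b > 0 "
                f"(worst deviation {np.abs(norms - 1.0).max():.2e})"
            )

    def __len__(self) -> int:
        return self.b_values.size

    def design_matrix(self) -> np.ndarray:
        """Rows ``[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]``.

        Multiplying a row by ``(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` gives
        ``ln S`` under the tensor model.
        """
        b = self.b_values
        g = self.directions
        gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx**2,
                -b * gy**2,
                -b * gz**2,
                -2 * b * gx * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
            ]
        )

    def check_identifiable(self) -> None:
        """Raise unless the design has full column rank (tensor + amplitude)."""
        A = self.design_matrix()
        rank = np.linalg.matrix_rank(A)
        if rank < 7:
            with np.printoptions(precision=3, suppress=True):
                dirs = str(self.directions[self.b_values > 0])
            raise IdentifiabilityError(
                f"diffusion encoding design has rank {rank} < 7; the "
                f"directions do not span enough of tensor space:\n{dirs}"
            )

    @classmethod
    def three_shell(
        cls,
        b_values: Tuple[float, ...] = DEFAULT_B_VALUES,
        directions: Optional[np.ndarray] = None,
        **metadata: float,
    ) -> "DiffusionProtocol":
        """The standard protocol: each shell applied on all six directions."""
        d = DEFAULT_SIX_DIRECTIONS if directions is None else np.asarray(directions)
        b = np.repeat(np.asarray(b_values, dtype=float), len(d))
        g = np.tile(d, (len(b_values), 1))
        return cls(b, g, dict(metadata))


@dataclass
class SignalVolume:
    """dMRI intensities on a spatial grid × measurement index (last axis)."""

    intensities: np.ndarray
    voxel_size_um: float
    protocol: Optional[DiffusionProtocol] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.protocol is not None and (
            self.intensities.shape[-1] != len(self.protocol)
        ):
            raise ShapeError(
                f"{self.intensities.shape[-1]} measurements vs protocol of "
                f"length {len(self.protocol)}"
            )


# Component order used throughout: xx, yy, zz, xy, xz, yz.
_COMP = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (six unique components) + S0.

    ``components`` has shape ``grid + (6,)`` in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), units mm²/s.
    """

    components: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    voxel_size_um: float

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3×3 matrices, shape ``grid + (3, 3)``."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m


@dataclass
class InPlaneTensorField:
    """The 2×2 (x, y)-plane restriction of a tensor field: Dxx, Dyy, Dxy."""

    d_xx: np.ndarray
    d_yy: np.ndarray
    d_xy: np.ndarray
    mask: np.ndarray
    voxel_size_um: float


@dataclass
class EigenSystem:
    """Sorted eigendecomposition of a tensor field with clamping bookkeeping.

    ``values`` are clamped to ≥ 0 (descending λ1 ≥ λ2 ≥ λ3); ``raw_values``
    keep the unclamped numbers; ``clamped`` flags voxels where clamping fired.
    ``vectors[..., :, k]`` is the eigenvector of ``values[..., k]``.
    """

    values: np.ndarray
    raw_values: np.ndarray
    vectors: np.ndarray
    clamped: np.ndarray
    mask: np.ndarray


def fit_dti(signals: SignalVolume, protocol: DiffusionProtocol) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    Voxels with any nonpositive or non-finite intensity are masked invalid
    (the log model is undefined there) rather than floored.
    """
    if signals.intensities.shape[-1] != len(protocol):
        raise ShapeError(
            f"signal volume has {signals.intensities.shape[-1]} measurements, "
            f"protocol has {len(protocol)}"
        )
    protocol.check_identifiable()

    S = signals.intensities
    valid = np.all(np.isfinite(S) & (S > 0), axis=-1)
    A = protocol.design_matrix()
    # One pseudoinverse serves every voxel: coef = pinv(A) @ ln S.
    pinvA = np.linalg.pinv(A)
    logS = np.where(valid[..., None], np.log(np.where(S > 0, S, 1.0)), 0.0)
    coef = logS @ pinvA.T  # grid + (7,)

    s0 = np.where(valid, np.exp(coef[..., 0]), np.nan)
    comp = np.where(valid[..., None], coef[..., 1:7], np.nan)
    return TensorField(comp, s0, valid, signals.voxel_size_um)


def tensor_eigensystem(field: TensorField) -> EigenSystem:
    """Eigen-decompose every tensor; sort descending; clamp negatives to 0.

    Non-finite tensors are masked invalid. Raw (pre-clamp) eigenvalues are
    retained so MD and reconstruction checks stay exact.
    """
    mats = field.as_matrices()
    finite = np.all(np.isfinite(mats), axis=(-2, -1))
    mask = field.mask & finite
    safe = np.where(mask[..., None, None], mats, np.eye(3))
    w, v = np.linalg.eigh(safe)  # ascending
    w = w[..., ::-1]
    v = v[..., :, ::-1]
    clamped = mask & np.any(w < 0, axis=-1)
    w_cl = np.clip(w, 0.0, None)
    nanize = lambda a: np.where(mask[..., None], a, np.nan)
    return EigenSystem(
        values=nanize(w_cl),
        raw_values=nanize(w),
        vectors=np.where(mask[..., None, None], v, np.nan),
        clamped=clamped,
        mask=mask,
    )


def map_md(field: TensorField) -> ParameterMap:
    """Mean diffusivity = (Dxx + Dyy + Dzz)/3, from the raw components."""
    md = (field.components[..., 0] + field.components[..., 1]
          + field.components[..., 2]) / 3.0
    return ParameterMap(md, field.voxel_size_um, units="mm^2/s",
                        mask=field.mask & np.isfinite(md), name="MD")


def map_fa(field: TensorField, eig: Optional[EigenSystem] = None) -> ParameterMap:
    """Fractional anisotropy from the clamped eigenvalues.

    FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖, defined as 0 where all eigenvalues vanish.
    """
    if eig is None:
        eig = tensor_eigensystem(field)
    lam = eig.values
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    fa = np.zeros(den.shape)
    nz = den > 0
    fa[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    fa = np.where(eig.mask, np.clip(fa, 0.0, 1.0), np.nan)
    return ParameterMap(fa, field.voxel_size_um, units="1",
                        mask=eig.mask, name="FA")


def extract_inplane(field: TensorField) -> InPlaneTensorField:
    """Restrict the tensor to the section (x, y) plane: copy Dxx, Dyy, Dxy."""
    c = field.components
    return InPlaneTensorField(
        d_xx=c[..., 0].copy(),
        d_yy=c[..., 1].copy(),
        d_xy=c[..., 3].copy(),
        mask=field.mask.copy(),
        voxel_size_um=field.voxel_size_um,
    )


def _eig2x2(axx: np.ndarray, ayy: np.ndarray, axy: np.ndarray):
    """Closed-form eigenvalues (λ1 ≥ λ2) of symmetric 2×2 fields."""
    half_tr = 0.5 * (axx + ayy)
    rad = np.sqrt((0.5 * (axx - ayy)) ** 2 + axy**2)
    return half_tr + rad, half_tr - rad


def inplane_eigenvalues(inplane: InPlaneTensorField) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted, nonnegative-clamped eigenvalues of the in-plane tensor."""
    l1, l2 = _eig2x2(inplane.d_xx, inplane.d_yy, inplane.d_xy)
    return np.clip(l1, 0.0, None), np.clip(l2, 0.0, None)


def map_fa_ip(inplane: InPlaneTensorField) -> ParameterMap:
    """In-plane FA: (λ1 − λ2)/(λ1 + λ2) of the 2×2 tensor, 0 when λ1 + λ2 = 0."""
    l1, l2 = inplane_eigenvalues(inplane)
    s = l1 + l2
    fa = np.zeros_like(s)
    nz = s > 0
    fa[nz] = (l1[nz] - l2[nz]) / s[nz]
    valid = inplane.mask & np.isfinite(s)
    fa = np.where(valid, np.clip(fa, 0.0, 1.0), np.nan)
    return ParameterMap(fa, inplane.voxel_size_um, units="1",
                        mask=valid, name="FA_IP")


def inplane_principal_angle(inplane: InPlaneTensorField) -> np.ndarray:
    """Angle (rad, mod π) of the major in-plane eigenvector vs the x-axis."""
    ang = 0.5 * np.arctan2(2.0 * inplane.d_xy, inplane.d_xx - inplane.d_yy)
    return np.mod(ang, np.pi)


def map_dec(
    principal_vectors: np.ndarray,
    anisotropy: ParameterMap,
) -> np.ndarray:
    """Directionally encoded color map.

    Channel k = |component k of the principal eigenvector| × anisotropy.
    3-vectors give RGB = (|x|, |y|, |z|); in-plane 2-vectors map x → red and
    y → green with blue = 0. Values are clipped to [0, 1]; invalid voxels are
    rendered black.
    """
    v = np.asarray(principal_vectors, dtype=float)
    ncomp = v.shape[-1]
    if ncomp not in (2, 3):
        raise ShapeError("principal vectors must have 2 or 3 components")
    a = np.where(anisotropy.mask, anisotropy.values, 0.0)
    rgb = np.zeros(a.shape + (3,))
    rgb[..., :ncomp] = np.abs(np.nan_to_num(v)) * np.clip(a, 0.0, 1.0)[..., None]
    return np.clip(rgb, 0.0, 1.0)


def map_dec_inplane(
    inplane: InPlaneTensorField, anisotropy: ParameterMap
) -> np.ndarray:
    """DEC map for the in-plane tensor (major eigenvector hue × FA_IP)."""
    ang = inplane_principal_angle(inplane)
    vec = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    return map_dec(vec, anisotropy)


def smooth_map(pmap: ParameterMap, sigma_um: float) -> ParameterMap:
    """Gaussian-smooth a parameter map (mask-aware normalized convolution).

    The default final smoothing scale for the MR-grid maps is σ = 40 μm
    (0.2 voxels at 200 μm), applied to derived maps rather than raw signals.
    """
    if sigma_um < 0:
        raise ParameterError("sigma_um must be >= 0")
    sigma_cells = sigma_um / pmap.resolution_um
    values, mask = masked_gaussian_smooth(pmap.values, pmap.mask, sigma_cells)
    out = pmap.with_values(np.where(mask, values, np.nan))
    out.mask = mask
    return out
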