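"""Landmark-based 2D coregistration: rigid (Procrustes) then thin-plate spline.

Histology sections are deformed during preparation, so alignment to the MR
grid proceeds in two stages: a least-squares rigid (optionally similarity)
transform from paired landmarks, then a thin-plate spline (TPS) fitted on the
rigid-prealigned points to absorb the non-linear residual. Landmark pairs are
given in μm, ``moving`` = histology, ``fixed`` = MR.

Resampling uses the *pullback* convention: to fill a target (MR) grid we need
a transform sending target coordinates into the source image. Rigid
transforms invert analytically; for TPS the pullback is fitted directly on
the swapped landmark pairs (fixed → moving), which is exact at the landmarks
for zero regularization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .containers import (
    DegenerateLandmarksError,
    Grid2D,
    ParameterError,
    ParameterMap,
)


@dataclass
class LandmarkPairs:
    """Paired 2D landmarks (μm): columns moving_x, moving_y, fixed_x, fixed_y."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if self.moving.shape != self.fixed.shape or self.moving.shape[1] != 2:
            raise DegenerateLandmarksError(
                "moving and fixed landmarks must be matching (n, 2) arrays"
            )

    def __len__(self) -> int:
        return self.moving.shape[0]

    def swapped(self) -> "LandmarkPairs":
        """The reverse correspondence (fixed → moving), for pullback fits."""
        return LandmarkPairs(self.fixed.copy(), self.moving.copy())


@dataclass
class Transform2D:
    """A fitted 2D transform: ``rigid`` (R, t, s) or ``tps`` coefficients."""

    kind: str
    rotation: Optional[np.ndarray] = None      # rigid: 2×2 orthonormal
    translation: Optional[np.ndarray] = None   # rigid: (2,) μm
    scale: float = 1.0
    control_points: Optional[np.ndarray] = None  # tps: (n, 2) μm
    kernel_weights: Optional[np.ndarray] = None  # tps: (n, 2)
    affine: Optional[np.ndarray] = None          # tps: (3, 2) rows [1, x, y]
    regularization: float = 0.0
    residual_rms: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "rigid":
            return points @ (self.scale * self.rotation).T + self.translation
        if self.kind == "tps":
            return _tps_apply(points, self.control_points,
                              self.kernel_weights, self.affine)
        raise ParameterError(f"unknown transform kind: {self.kind!r}")

    def inverse(self) -> "Transform2D":
        """Analytic inverse (rigid/similarity only)."""
        if self.kind != "rigid":
            raise ParameterError(
                "only rigid transforms invert analytically; fit the TPS on "
                "swapped landmark pairs instead"
            )
        Rinv = self.rotation.T / self.scale
        return Transform2D(
            kind="rigid",
            rotation=self.rotation.T,
            translation=-(Rinv @ self.translation),
            scale=1.0 / self.scale,
        )

    @property
    def rotation_angle(self) -> float:
        """Rigid rotation angle in radians."""
        if self.kind != "rigid":
            raise ParameterError("rotation angle is defined for rigid only")
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))

    def bending_energy(self) -> float:
        """TPS bending energy wᵀ K w (0 for an exactly affine mapping)."""
        if self.kind != "tps":
            return 0.0
        K = _tps_kernel_matrix(self.control_points, self.control_points)
        return float(np.sum(self.kernel_weights * (K @ self.kernel_weights)))

    # -- JSON serialization -------------------------------------------------

    def to_json(self, path) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        record = {
            "kind": self.kind,
            "rotation": arr(self.rotation),
            "translation": arr(self.translation),
            "scale": self.scale,
            "control_points": arr(self.control_points),
            "kernel_weights": arr(self.kernel_weights),
            "affine": arr(self.affine),
            "regularization": self.regularization,
            "residual_rms": self.residual_rms,
        }
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Transform2D":
        with open(path) as fh:
            record = json.load(fh)
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)
        return cls(
            kind=record["kind"],
            rotation=arr(record["rotation"]),
            translation=arr(record["translation"]),
            scale=record["scale"],
            control_points=arr(record["control_points"]),
            kernel_weights=arr(record["kernel_weights"]),
            affine=arr(record["affine"]),
            regularization=record["regularization"],
            residual_rms=record["residual_rms"],
        )


def rigid_from_landmarks(
    pairs: LandmarkPairs, allow_scale: bool = False
) -> Transform2D:
    """Least-squares rigid (or similarity) transform from landmark pairs.

    Closed-form 2D Procrustes: rotation from the SVD of the centered
    cross-covariance with a reflection guard, optional isotropic scale,
    translation from the centroids. Residual RMS is stored on the transform.
    """
    if len(pairs) < 2:
        raise DegenerateLandmarksError("rigid fit needs at least 2 pairs")
    m, f = pairs.moving, pairs.fixed
    mc, fc = m.mean(axis=0), f.mean(axis=0)
    M, F = m - mc, f - fc
    norm_m = np.sum(M**2)
    if norm_m <= 1e-24:
        raise DegenerateLandmarksError("all moving landmarks coincide")
    U, S, Vt = np.linalg.svd(F.T @ M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    s = float(np.sum(S * np.diag(D)) / norm_m) if allow_scale else 1.0
    t = fc - s * (R @ mc)
    out = Transform2D(kind="rigid", rotation=R, translation=t, scale=s)
    out.residual_rms = float(
        np.sqrt(np.mean(np.sum((out(m) - f) ** 2, axis=1)))
    )
    return out


def _tps_kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r² log r (0 at r = 0) between point sets a (n,2) and b (m,2)."""
    r2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 0.5 * r2 * np.log(r2)  # r² log r = ½ r² log r²
    k[r2 == 0] = 0.0
    return k


def _tps_apply(points, control, weights, affine):
    K = _tps_kernel_matrix(points, control)
    P = np.column_stack([np.ones(len(points)), points])
    return K @ weights + P @ affine


def tps_from_landmarks(
    pairs: LandmarkPairs, regularization: float = 0.0
) -> Transform2D:
    """Thin-plate spline from landmark pairs.

    Solves the standard bordered system with kernel r² log r; with zero
    regularization the transform interpolates the landmarks exactly, and for
    affine-consistent pairs the kernel weights vanish (pure affine limit).
    """
    if regularization < 0:
        raise ParameterError("TPS regularization must be >= 0")
    n = len(pairs)
    if n < 3:
        raise DegenerateLandmarksError("TPS needs at least 3 pairs")
    m, f = pairs.moving, pairs.fixed
    # duplicated moving points: identical targets are redundant, conflicting
    # targets are unsatisfiable — both leave the system singular.
    _, idx, counts = np.unique(m, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 1):
        raise DegenerateLandmarksError("duplicated moving landmark positions")
    P = np.column_stack([np.ones(n), m])
    if np.linalg.matrix_rank(P) < 3:
        raise DegenerateLandmarksError("landmarks are collinear")
    K = _tps_kernel_matrix(m, m) + regularization * np.eye(n)
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = f
    sol = np.linalg.solve(L, rhs)
    out = Transform2D(
        kind="tps",
        control_points=m.copy(),
        kernel_weights=sol[:n],
        affine=sol[n:],
        regularization=regularization,
    )
    out.residual_rms = float(np.sqrt(np.mean(np.sum((out(m) - f) ** 2, axis=1))))
    return out


def apply_transform(
    source: ParameterMap,
    pullback: Transform2D,
    target_grid: Grid2D,
    order: int = 1,
    source_origin_um: Tuple[float, float] = (0.0, 0.0),
) -> ParameterMap:
    """Resample a source map onto a target grid through a pullback transform.

    ``pullback`` must map target (fixed) coordinates into source (moving)
    coordinates — use ``rigid.inverse()`` or a TPS fitted on
    ``pairs.swapped()``. Interpolation is bilinear for scalar maps
    (``order=1``; never exceeds the source range) or nearest for masks
    (``order=0``). Cells falling outside the source extent — or on invalid
    source cells — come back invalid.
    """
    if order not in (0, 1):
        raise ParameterError("order must be 0 (nearest) or 1 (bilinear)")
    X, Y = target_grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    src = pullback(pts)
    res = source.resolution_um
    ox, oy = source_origin_um
    # physical μm -> fractional pixel indices (pixel centers at (i + 0.5)·res)
    cols = (src[:, 0] - ox) / res - 0.5
    rows = (src[:, 1] - oy) / res - 0.5
    coords = np.vstack([rows, cols])

    filled = np.where(source.mask, source.values, np.nan)
    vals = map_coordinates(filled, coords, order=order,
                           mode="constant", cval=np.nan)
    ny, nx = source.values.shape
    inside = (rows >= -0.5) & (rows <= ny - 0.5) & (cols >= -0.5) & (cols <= nx - 0.5)
    vals[~inside] = np.nan
    out_vals = vals.reshape(target_grid.shape)
    out_mask = np.isfinite(out_vals)
    if not out_mask.any():
        warnings.warn("resampled output is empty: no overlap with the source")
    return ParameterMap(
        out_vals, target_grid.resolution_um, units=source.units,
        mask=out_mask, name=source.name,
    )


def register_landmarks(
    pairs: LandmarkPairs,
    allow_scale: bool = False,
    tps_regularization: float = 0.0,
) -> Tuple[Transform2D, Transform2D, Transform2D]:
    """Fit the full rigid-then-TPS registration.

    Returns ``(rigid, tps, pullback_tps)``: the forward rigid moving→fixed
    transform, the forward TPS fitted on rigid-prealigned moving points, and
    the pullback TPS (fixed → rigid-prealigned moving) used for resampling;
    compose the pullback with ``rigid.inverse()`` to land in raw moving
    coordinates.
    """
    rigid = rigid_from_landmarks(pairs, allow_scale=allow_scale)
    prealigned = LandmarkPairs(rigid(pairs.moving), pairs.fixed)
    tps = tps_from_landmarks(prealigned, tps_regularization)
    pullback = tps_from_landmarks(prealigned.swapped(), tps_regularization)
    return rigid, tps, pullback
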