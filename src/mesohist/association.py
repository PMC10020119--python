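"""Histology–dMRI association statistics.

This is the analysis core: within-tumor ROI construction, the small family
of predictor→response models (polynomials of degree 1–3, a quadratic
constrained to be monotone decreasing over the data range, and an
origin-constrained line), out-of-sample R² over repeated random 80/20
train/test splits, the relative RR² against any benchmark predictor,
whole-sample (inter-tumor) association, variability correlations, residual
maps, and per-sample summary statistics.

Out-of-sample R² is

    R²_OS = 1 − MSE_model / MSE_μ,

where both mean squared errors are computed on held-out test voxels and
MSE_μ scores the mean of the *measured test values* as predictor. Numerator
and denominator therefore have the same degrees of freedom, making the score
comparable across model families of very different complexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .containers import (
    DataError,
    ParameterError,
    ParameterMap,
    ShapeError,
    ZeroVarianceError,
    check_same_grid,
)

MODEL_FAMILIES = (
    "poly1", "poly2", "poly3", "monotone_decreasing_quad", "origin_linear",
)


@dataclass
class SampleBundle:
    """One sample's coregistered maps on a shared MR grid, plus its ROI.

    ``maps`` holds ParameterMaps keyed by name (MD, FA, FA_IP, SA, CD);
    ``roi`` is the within-tumor mask and must sit inside every map's
    validity mask.
    """

    maps: Dict[str, ParameterMap]
    roi: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=bool)
        names = list(self.maps)
        check_same_grid(*[self.maps[n] for n in names])
        for n in names:
            m = self.maps[n]
            if m.shape != self.roi.shape:
                raise ShapeError(f"ROI shape differs from map {n!r}")
            if np.any(self.roi & ~m.mask):
                raise ShapeError(f"ROI extends outside valid cells of {n!r}")

    def roi_values(self, name: str) -> np.ndarray:
        return self.maps[name].values[self.roi]


@dataclass(frozen=True)
class ModelSpec:
    """A model family applied to one predictor→response pair."""

    family: str
    predictor: str = "x"
    response: str = "y"

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ParameterError(
                f"unknown model family {self.family!r}; expected one of "
                f"{MODEL_FAMILIES}"
            )


@dataclass
class ModelFit:
    """Fitted coefficients (ascending powers) for one training set."""

    spec: ModelSpec
    coefficients: np.ndarray
    train_index: Optional[np.ndarray] = None
    train_mse: float = np.nan

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(x, dtype=float), self.coefficients
        )


@dataclass
class SplitEvaluation:
    """Per-repeat out-of-sample R² over random train/test splits."""

    r2_os: np.ndarray
    mse_model: np.ndarray
    mse_mu: np.ndarray
    train_fraction: float
    repeats: int
    seed: int
    spec: ModelSpec

    @property
    def median(self) -> float:
        return float(np.median(self.r2_os))

    @property
    def iqr(self) -> float:
        q25, q75 = np.percentile(self.r2_os, [25, 75])
        return float(q75 - q25)

    def summary(self) -> str:
        """Median ± interquartile range, the reporting format used here."""
        return f"{self.median:.2f} ± {self.iqr:.2f}"


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

def within_tumor_roi(
    mask_mr: np.ndarray,
    mask_histo: np.ndarray,
    erosion_radius_cells: int = 1,
) -> np.ndarray:
    """Eroded intersection of the MR and histology tissue masks.

    The disk structuring element of the given radius (0 → pure intersection)
    strips the tumor margin so intra-tumor statistics see interior voxels
    only. An empty result is allowed but warned about.
    """
    mask_mr = np.asarray(mask_mr, dtype=bool)
    mask_histo = np.asarray(mask_histo, dtype=bool)
    if mask_mr.shape != mask_histo.shape:
        raise ShapeError(
            f"mask shapes differ: {mask_mr.shape} vs {mask_histo.shape}"
        )
    if erosion_radius_cells < 0:
        raise ParameterError("erosion radius must be >= 0")
    roi = mask_mr & mask_histo
    if erosion_radius_cells > 0:
        r = erosion_radius_cells
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = xx**2 + yy**2 <= r**2
        roi = ndimage.binary_erosion(roi, structure=disk)
    if not roi.any():
        warnings.warn("within-tumor ROI is empty")
    return roi


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _poly_degree(family: str) -> int:
    return {"poly1": 1, "poly2": 2, "poly3": 3,
            "monotone_decreasing_quad": 2, "origin_linear": 1}[family]


def _monotone_decreasing_quad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares quadratic with derivative ≤ 0 over [min x, max x].

    For a quadratic, c1 + 2 c2 t is linear in t, so nonpositivity on the
    interval is equivalent to nonpositivity at both endpoints: two linear
    inequality constraints. The convex QP is solved exactly by enumerating
    the four possible active sets and keeping the feasible candidate with
    the smallest residual.
    """
    V = np.column_stack([np.ones_like(x), x, x**2])
    a, b = float(x.min()), float(x.max())
    constraints = np.array([[0.0, 1.0, 2.0 * a], [0.0, 1.0, 2.0 * b]])
    tol = 1e-10 * max(1.0, abs(a), abs(b))

    def solve_eq(active: Sequence[int]) -> Optional[np.ndarray]:
        if not active:
            return np.linalg.lstsq(V, y, rcond=None)[0]
        A = constraints[list(active)]
        # parameterize the constraint nullspace and solve there
        _, s, vt = np.linalg.svd(A)
        null = vt[np.sum(s > 1e-12) :].T
        if null.shape[1] == 0:
            return np.zeros(3)
        z = np.linalg.lstsq(V @ null, y, rcond=None)[0]
        return null @ z

    best, best_sse = None, np.inf
    for active in ((), (0,), (1,), (0, 1)):
        c = solve_eq(active)
        if c is None or not np.all(np.isfinite(c)):
            continue
        if np.any(constraints @ c > tol):
            continue
        sse = float(np.sum((V @ c - y) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = c, sse
    if best is None:  # pragma: no cover - feasible set always contains ȳ
        best = np.array([float(y.mean()), 0.0, 0.0])
    return best


def fit_model(x: np.ndarray, y: np.ndarray, spec: ModelSpec) -> ModelFit:
    """Fit one model family to (x, y) training data.

    Unconstrained polynomials by ordinary least squares; the monotone
    decreasing quadratic by exact constrained least squares; the origin
    line by no-intercept least squares.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError("x and y lengths differ")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in model fit input")
    deg = _poly_degree(spec.family)
    if x.size < deg + 2:
        raise DataError(
            f"{spec.family} needs at least {deg + 2} points, got {x.size}"
        )
    if spec.family != "origin_linear" and np.ptp(x) == 0:
        raise DataError("zero predictor variance: slope is unidentifiable")

    if spec.family in ("poly1", "poly2", "poly3"):
        coef = np.polynomial.polynomial.polyfit(x, y, deg)
    elif spec.family == "monotone_decreasing_quad":
        coef = _monotone_decreasing_quad(x, y)
    else:  # origin_linear
        denom = float(np.sum(x * x))
        if denom == 0:
            raise DataError("origin_linear: all predictor values are zero")
        coef = np.array([0.0, float(np.sum(x * y) / denom)])
    fit = ModelFit(spec=spec, coefficients=np.asarray(coef, dtype=float))
    fit.train_mse = float(np.mean((fit.predict(x) - y) ** 2))
    return fit


# ---------------------------------------------------------------------------
# Out-of-sample evaluation
# ---------------------------------------------------------------------------

def mse(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error Σ(measured − predicted)² / n."""
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.shape != predicted.shape:
        raise ShapeError("measured and predicted lengths differ")
    return float(np.mean((measured - predicted) ** 2))


def r2_os(measured_test: np.ndarray, predicted_test: np.ndarray) -> float:
    """Out-of-sample R² = 1 − MSE_model / MSE_μ on held-out data.

    MSE_μ scores the mean of the measured test values; the statistic is ≤ 1
    and unbounded below.
    """
    measured_test = np.asarray(measured_test, dtype=float).ravel()
    predicted_test = np.asarray(predicted_test, dtype=float).ravel()
    if measured_test.size < 2:
        raise DataError("out-of-sample R² needs at least 2 test points")
    mse_mu = mse(measured_test, np.full_like(measured_test,
                                             measured_test.mean()))
    if mse_mu == 0:
        raise ZeroVarianceError("measured test values have zero variance")
    return 1.0 - mse(measured_test, predicted_test) / mse_mu


def rr2_os(mse_feature_model: float, mse_benchmark: float) -> float:
    """Relative out-of-sample R² = 1 − MSE_feature / MSE_benchmark.

    Negative values mean the feature model predicts worse than the benchmark
    (values below −0.3 read as substantially worse).
    """
    if mse_feature_model < 0 or mse_benchmark < 0:
        raise ParameterError("MSEs must be nonnegative")
    if mse_benchmark == 0:
        raise ZeroVarianceError("benchmark MSE is zero: RR²_OS undefined")
    return 1.0 - mse_feature_model / mse_benchmark


def evaluate_splits(
    x: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    repeats: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitEvaluation:
    """Repeated random train/test evaluation of one model on paired vectors.

    Each repeat draws a uniform random partition with ⌊train_fraction·n⌋
    training points, fits on the training part, and scores R²_OS on the
    rest. Fully reproducible from the seed.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError("x and y lengths differ")
    n = x.size
    if n < 10:
        raise DataError(f"need at least 10 cells for split evaluation, got {n}")
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    if n_train < _poly_degree(spec.family) + 2 or n - n_train < 2:
        raise DataError("split leaves too few training or test points")

    rng = np.random.default_rng(seed)
    r2 = np.empty(repeats)
    mse_model = np.empty(repeats)
    mse_mu = np.empty(repeats)
    for i in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        fit = fit_model(x[tr], y[tr], spec)
        pred = fit.predict(x[te])
        mse_model[i] = mse(y[te], pred)
        mse_mu[i] = mse(y[te], np.full(te.size, y[te].mean()))
        r2[i] = 1.0 - mse_model[i] / mse_mu[i]
    return SplitEvaluation(
        r2_os=r2, mse_model=mse_model, mse_mu=mse_mu,
        train_fraction=train_fraction, repeats=repeats, seed=seed, spec=spec,
    )


def split_evaluate(
    bundle: SampleBundle,
    spec: ModelSpec,
    repeats: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitEvaluation:
    """Repeated-split evaluation on a sample bundle's within-tumor ROI."""
    x = bundle.roi_values(spec.predictor)
    y = bundle.roi_values(spec.response)
    return evaluate_splits(x, y, spec, repeats=repeats,
                           train_fraction=train_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Inter-tumor association and variability
# ---------------------------------------------------------------------------

def whole_sample_association(
    bundles: Iterable[SampleBundle],
    predictor: str = "CD",
    response: str = "MD",
):
    """Per-sample ROI means of one map pair, with Pearson r and R² = r².

    This is the inter-tumor (whole-sample) analysis: each sample contributes
    one (mean predictor, mean response) point.
    """
    import pandas as pd

    rows = []
    for b in bundles:
        rows.append(
            {
                "sample": b.metadata.get("id", len(rows)),
                f"mean_{predictor}": float(b.roi_values(predictor).mean()),
                f"mean_{response}": float(b.roi_values(response).mean()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise DataError("whole-sample association needs at least 3 samples")
    xm = table[f"mean_{predictor}"].to_numpy()
    ym = table[f"mean_{response}"].to_numpy()
    if np.ptp(xm) == 0 or np.ptp(ym) == 0:
        raise ZeroVarianceError("sample means have zero variance")
    r, p = stats.pearsonr(xm, ym)
    return table, float(r), float(r**2), float(p)


def variability_correlation(
    r2os_per_sample: np.ndarray, sd_per_sample: np.ndarray
) -> Tuple[float, float]:
    """Pearson r (and two-sided p) between per-sample R²_OS and the response
    map's within-sample standard deviation.

    A strong correlation means the model only fails where there is little
    variance to explain.
    """
    a = np.asarray(r2os_per_sample, dtype=float).ravel()
    b = np.asarray(sd_per_sample, dtype=float).ravel()
    if a.shape != b.shape:
        raise ShapeError("vectors differ in length")
    if a.size < 3:
        raise DataError("correlation needs at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("constant vector: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Residuals and summaries
# ---------------------------------------------------------------------------

def residual_map(
    measured: ParameterMap,
    predicted: ParameterMap,
    roi: np.ndarray,
) -> Tuple[ParameterMap, np.ndarray]:
    """Signed residual ε = measured − predicted inside the ROI, plus an RGB
    rendering: red where the model under-predicts (ε > 0), green where it
    over-predicts (ε < 0), black at zero; intensity ∝ |ε| scaled by the
    robust (99th-percentile) maximum.
    """
    check_same_grid(measured, predicted)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != measured.shape:
        raise ShapeError("ROI shape differs from the maps")
    eps = np.where(roi, measured.values - predicted.values, np.nan)
    emap = ParameterMap(eps, measured.resolution_um,
                        units=measured.units, mask=roi & np.isfinite(eps),
                        name=f"residual_{measured.name}")
    rgb = np.zeros(eps.shape + (3,))
    vals = eps[emap.mask]
    if vals.size:
        scale = float(np.percentile(np.abs(vals), 99))
        if scale > 0:
            norm = np.clip(np.nan_to_num(eps) / scale, -1.0, 1.0)
            rgb[..., 0] = np.where(emap.mask, np.clip(norm, 0, 1), 0.0)
            rgb[..., 1] = np.where(emap.mask, np.clip(-norm, 0, 1), 0.0)
    return emap, rgb


def sample_summary_stats(pmap: ParameterMap, roi: np.ndarray) -> Dict[str, float]:
    """Mean, population SD, and coefficient of variation over the ROI.

    The CoV = SD/mean summarizes intra-sample variability; maps with
    CoV below ~0.2 have little variance for any predictor to explain.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.shape:
        raise ShapeError("ROI shape differs from the map")
    vals = pmap.values[roi]
    if vals.size == 0:
        raise DataError("empty ROI")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if mean == 0:
        raise ZeroVarianceError("zero mean: CoV undefined")
    return {"mean": mean, "sd": sd, "cov": sd / mean}
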