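"""Paired ground-truth phantoms: microstructure fields, stylized histology,
centroid sets, diffusion tensors, and noisy dMRI signals.

The generator emulates the statistical structure the analysis assumes in a
fixed-composition tumor section: a smooth intracellular-volume-fraction
(ICVF) field linked to cell count, a smooth fiber orientation field with
controllable orientation dispersion, and optional mesoscopic features
(vessel-like corridors, microcyst clusters, psammoma-like signal voids).

The ground-truth diffusion tensor follows the volume-fraction picture of
mean diffusivity: with near-zero intracellular diffusivity,

    MD = d_free · (1 − ICVF)

exactly on feature-free cells. In-plane anisotropy is attenuated by the
circular variance of a wrapped-normal orientation distribution:
FA_IP,true = a_max · exp(−2σ_θ²) for dispersion SD σ_θ (radians, axial
statistics on the doubled angle). Signals follow the monoexponential tensor
model with Rician noise (σ = S0 / SNR, SNR defined at b = 0).

Histology rendering is stylized, not photorealistic: an oriented cosine
fiber texture plus dark nuclear ellipses at the stamped centroid positions —
sufficient for the structure-tensor and centroid-count code paths, which is
all the downstream pipeline consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import ConfigError, Grid2D, ParameterError, ShapeError
from .dti import DiffusionProtocol, SignalVolume
from .histology import CentroidSet, HistologyImage

FEATURE_LABELS = {"tissue": 0, "vessel": 1, "microcyst": 2, "psammoma": 3}


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic sample.

    Lengths in μm, diffusivities in mm²/s. Defaults give a 40×40-cell MR
    grid at 200 μm (the acquisition voxel size) with 0.5 μm histology pixels
    (400 px per MR cell), a smooth ICVF field spanning 0.10–0.70, maximal
    in-plane anisotropy 0.6, and SNR 50 at b = 0.
    """

    n_cells: Tuple[int, int] = (40, 40)          # MR grid (ny, nx)
    pixels_per_cell: int = 400
    pixel_size_um: float = 0.5
    icvf_range: Tuple[float, float] = (0.10, 0.70)
    icvf_corr_cells: float = 4.0                 # correlation length, MR cells
    d_free: float = 1.0e-3                       # free diffusivity, mm²/s
    density_max: float = 150.0                   # nuclei per cell at ICVF = 1
    large_cell_mode: bool = False                # decouple count from ICVF
    large_cell_icvf: float = 0.40
    anisotropy_max: float = 0.6                  # FA_IP at zero dispersion
    orientation_corr_cells: float = 6.0
    dispersion_range: Tuple[float, float] = (0.10, 0.60)  # wrapped-normal SD, rad
    through_plane_scale: float = 1.0             # λ3 as a multiple of λ2
    vessel_density: float = 0.0                  # expected fraction of cells
    microcyst_density: float = 0.0
    psammoma_density: float = 0.0
    nucleus_radius_um: Tuple[float, float] = (2.5, 4.5)
    nucleus_min_spacing_um: float = 5.0
    fiber_period_um: float = 10.0
    s0: float = 1000.0
    snr: float = 50.0                            # np.inf for noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.icvf_range
        if not (0.0 <= lo <= hi <= 0.95):
            raise ConfigError("icvf_range must satisfy 0 <= lo <= hi <= 0.95")
        if self.snr <= 0:
            raise ConfigError("snr must be > 0 (np.inf for noiseless)")
        for name in ("pixel_size_um", "d_free", "s0", "fiber_period_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def mr_resolution_um(self) -> float:
        return self.pixels_per_cell * self.pixel_size_um

    @property
    def grid(self) -> Grid2D:
        return Grid2D(self.n_cells, self.mr_resolution_um)


@dataclass
class PhantomTruth:
    """Ground truth per MR cell, plus the tensor field in matrix form."""

    config: PhantomConfig
    icvf: np.ndarray                 # (ny, nx)
    counts: np.ndarray               # true nucleus count per cell (int)
    theta: np.ndarray                # fiber orientation, rad in [0, π)
    dispersion: np.ndarray           # wrapped-normal SD, rad
    feature_label: np.ndarray        # FEATURE_LABELS codes
    md_true: np.ndarray              # mm²/s
    fa_ip_true: np.ndarray
    d_true: np.ndarray               # (ny, nx, 3, 3)
    s0_scale: np.ndarray             # amplitude factor (≈0 at psammoma)

    @property
    def grid(self) -> Grid2D:
        return self.config.grid

    def tissue(self) -> np.ndarray:
        return self.feature_label == FEATURE_LABELS["tissue"]


def _smooth_unit_field(
    rng: np.random.Generator, shape: Tuple[int, int], corr_cells: float
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to exactly span [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    span = np.ptp(f)
    if span == 0:  # pragma: no cover - degenerate 1-cell grid
        return np.full(shape, 0.5)
    return (f - f.min()) / span


def _smooth_angle_field(
    rng: np.random.Generator, shape: Tuple[int, int], corr_cells: float
) -> np.ndarray:
    """Smooth axial orientation field in [0, π): filter a random 2-vector
    field and halve its angle (axial data live on the doubled circle)."""
    a = gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    b = gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    return np.mod(0.5 * np.arctan2(b, a), np.pi)


def _stamp_features(
    rng: np.random.Generator, cfg: PhantomConfig
) -> np.ndarray:
    """Feature label map on the MR grid: vessels as thin line corridors,
    microcysts as disk clusters, psammoma-like inclusions as single cells."""
    ny, nx = cfg.n_cells
    label = np.zeros((ny, nx), dtype=int)
    total = ny * nx

    def n_features(density: float, cells_each: float) -> int:
        return int(round(density * total / max(cells_each, 1.0)))

    # vessels: random chords rasterized one cell wide
    for _ in range(n_features(cfg.vessel_density, cells_each=8.0)):
        r0, c0 = rng.integers(0, ny), rng.integers(0, nx)
        ang = rng.uniform(0, np.pi)
        length = rng.integers(5, max(6, min(ny, nx) // 2))
        t = np.arange(length)
        rr = np.clip(np.round(r0 + t * np.sin(ang)).astype(int), 0, ny - 1)
        cc = np.clip(np.round(c0 + t * np.cos(ang)).astype(int), 0, nx - 1)
        label[rr, cc] = FEATURE_LABELS["vessel"]
    # microcysts: disks of radius 1-2 cells
    for _ in range(n_features(cfg.microcyst_density, cells_each=7.0)):
        r0, c0 = rng.integers(0, ny), rng.integers(0, nx)
        rad = rng.integers(1, 3)
        yy, xx = np.mgrid[0:ny, 0:nx]
        disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        label[disk] = FEATURE_LABELS["microcyst"]
    # psammoma-like inclusions: isolated cells
    for _ in range(n_features(cfg.psammoma_density, cells_each=1.0)):
        label[rng.integers(0, ny), rng.integers(0, nx)] = (
            FEATURE_LABELS["psammoma"]
        )

    if np.count_nonzero(label) > 0.5 * total:
        raise ConfigError(
            "feature masks cover more than 50% of the grid; lower the "
            "feature densities"
        )
    return label


def _assemble_tensors(
    md: np.ndarray,
    fa_ip: np.ndarray,
    theta: np.ndarray,
    through_plane_scale: float,
) -> np.ndarray:
    """Build SPD tensors with given MD, in-plane FA and principal angle.

    In-plane eigenvalues (λ1, λ2) satisfy (λ1−λ2)/(λ1+λ2) = fa_ip; the
    through-plane eigenvalue is λ3 = tp·λ2, and the in-plane sum is chosen
    so the trace gives exactly 3·MD.
    """
    tp = through_plane_scale
    s = 3.0 * md / (1.0 + 0.5 * tp * (1.0 - fa_ip))
    d = fa_ip * s
    lam1 = 0.5 * (s + d)
    lam2 = 0.5 * (s - d)
    lam3 = tp * lam2
    c, sn = np.cos(theta), np.sin(theta)
    D = np.zeros(md.shape + (3, 3))
    D[..., 0, 0] = lam1 * c**2 + lam2 * sn**2
    D[..., 1, 1] = lam1 * sn**2 + lam2 * c**2
    D[..., 0, 1] = D[..., 1, 0] = (lam1 - lam2) * c * sn
    D[..., 2, 2] = lam3
    return D


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate one ground-truth phantom, reproducible from ``config.seed``.

    Feature cells override the tissue model: vessel corridors are nearly
    free water (low ICVF, high MD), microcysts are tightly packed low-MD
    clusters, psammoma-like inclusions are signal voids. On feature-free
    cells MD = d_free·(1 − ICVF) holds exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.n_cells

    lo, hi = cfg.icvf_range
    icvf = lo + (hi - lo) * _smooth_unit_field(rng, (ny, nx), cfg.icvf_corr_cells)
    theta = _smooth_angle_field(rng, (ny, nx), cfg.orientation_corr_cells)
    dlo, dhi = cfg.dispersion_range
    dispersion = dlo + (dhi - dlo) * _smooth_unit_field(
        rng, (ny, nx), cfg.orientation_corr_cells
    )

    if cfg.large_cell_mode:
        # large-cell regime: counts vary while ICVF (hence MD) stays flat
        icvf = np.full((ny, nx), cfg.large_cell_icvf)
        count_factor = 0.2 + 0.8 * _smooth_unit_field(
            rng, (ny, nx), cfg.icvf_corr_cells
        )
        counts = np.round(cfg.density_max * count_factor).astype(int)
    else:
        counts = np.round(cfg.density_max * icvf).astype(int)

    label = _stamp_features(rng, cfg)
    vessel = label == FEATURE_LABELS["vessel"]
    cyst = label == FEATURE_LABELS["microcyst"]
    psammoma = label == FEATURE_LABELS["psammoma"]

    md = cfg.d_free * (1.0 - icvf)
    md = np.where(vessel, 0.95 * cfg.d_free, md)
    md = np.where(cyst, 0.30 * cfg.d_free, md)
    md = np.where(psammoma, 0.10 * cfg.d_free, md)
    counts = np.where(vessel | cyst, int(round(0.1 * cfg.density_max)), counts)
    counts = np.where(psammoma, 0, counts)

    # wrapped-normal circular variance attenuates the voxel-scale anisotropy
    fa_ip = cfg.anisotropy_max * np.exp(-2.0 * dispersion**2)
    fa_ip = np.where(vessel | cyst | psammoma, 0.0, fa_ip)

    d_true = _assemble_tensors(md, fa_ip, theta, cfg.through_plane_scale)
    s0_scale = np.where(psammoma, 1e-3, 1.0)

    return PhantomTruth(
        config=cfg, icvf=icvf, counts=counts, theta=theta,
        dispersion=dispersion, feature_label=label, md_true=md,
        fa_ip_true=fa_ip, d_true=d_true, s0_scale=s0_scale,
    )


# ---------------------------------------------------------------------------
# Centroid placement and histology rendering
# ---------------------------------------------------------------------------

def sample_centroids(
    truth: PhantomTruth, rng: Optional[np.random.Generator] = None
) -> Tuple[CentroidSet, np.ndarray]:
    """Place nuclei per MR cell by dart throwing at the minimum spacing.

    Returns the exact stamped centroid positions (μm) and the per-cell
    shortfall (requested − placed) where spacing made counts unplaceable.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    res = cfg.mr_resolution_um
    min_d2 = cfg.nucleus_min_spacing_um**2
    xs, ys = [], []
    ny, nx = cfg.n_cells
    shortfall = np.zeros((ny, nx), dtype=int)
    for r in range(ny):
        for c in range(nx):
            want = int(truth.counts[r, c])
            if want == 0:
                continue
            placed: list = []
            attempts = 0
            while len(placed) < want and attempts < 40 * want:
                attempts += 1
                px = (c + rng.uniform(0.01, 0.99)) * res
                py = (r + rng.uniform(0.01, 0.99)) * res
                if all((px - qx) ** 2 + (py - qy) ** 2 >= min_d2
                       for qx, qy in placed):
                    placed.append((px, py))
            shortfall[r, c] = want - len(placed)
            xs.extend(p[0] for p in placed)
            ys.extend(p[1] for p in placed)
    if shortfall.any():
        import warnings

        warnings.warn(
            f"nucleus spacing shortfall on {np.count_nonzero(shortfall)} "
            f"cells (total {int(shortfall.sum())} nuclei)"
        )
    extent = truth.grid.extent_um
    return CentroidSet(np.array(xs), np.array(ys), extent), shortfall


def render_histology(
    truth: PhantomTruth,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[HistologyImage, CentroidSet]:
    """Render a stylized H&E-like section and its exact centroid list.

    Background: eosin-toned cosine fiber texture along the local orientation
    θ, with phase jitter proportional to the local dispersion. Features:
    near-white lumina for vessels/microcysts, dark concentric rings for
    psammoma-like bodies. Nuclei: dark basophilic ellipses at the stamped
    centroid positions.
    """
    from skimage.draw import ellipse

    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ppc = cfg.pixels_per_cell
    ny, nx = cfg.n_cells
    H, W = ny * ppc, nx * ppc
    px = cfg.pixel_size_um

    # upsample the orientation smoothly (bilinear on the doubled-angle
    # vector) so the fiber texture has no seams at MR cell boundaries
    from scipy.ndimage import zoom

    c2 = zoom(np.cos(2 * truth.theta), ppc, order=1, grid_mode=True,
              mode="nearest")
    s2 = zoom(np.sin(2 * truth.theta), ppc, order=1, grid_mode=True,
              mode="nearest")
    theta = np.mod(0.5 * np.arctan2(s2, c2), np.pi)
    disp = zoom(truth.dispersion, ppc, order=1, grid_mode=True,
                mode="nearest")
    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    x_um = (cols + 0.5) * px
    y_um = (rows + 0.5) * px
    phase = (-x_um * np.sin(theta) + y_um * np.cos(theta)) / cfg.fiber_period_um
    jitter = gaussian_filter(rng.standard_normal((H, W)), 0.02 * ppc,
                             mode="reflect")
    jitter = jitter / max(jitter.std(), 1e-12)
    texture = np.cos(2 * np.pi * phase + 2.5 * disp * jitter)

    base = np.array([0.93, 0.80, 0.86])  # eosin-toned background
    rgb = np.empty((H, W, 3))
    rgb[:] = base
    rgb += 0.10 * texture[..., None]

    # mesoscopic features
    label_px = np.repeat(np.repeat(truth.feature_label, ppc, axis=0),
                         ppc, axis=1)
    lumina = (label_px == FEATURE_LABELS["vessel"]) | (
        label_px == FEATURE_LABELS["microcyst"]
    )
    rgb[lumina] = 0.97
    psa_cells = np.argwhere(truth.feature_label == FEATURE_LABELS["psammoma"])
    for r, c in psa_cells:
        sl = (slice(r * ppc, (r + 1) * ppc), slice(c * ppc, (c + 1) * ppc))
        yy, xx = np.mgrid[0:ppc, 0:ppc]
        rad = np.hypot(yy - ppc / 2, xx - ppc / 2) * px
        rings = 0.35 + 0.25 * np.cos(2 * np.pi * rad / 12.0)
        inside = rad < 0.45 * ppc * px
        for k in range(3):
            ch = rgb[sl][..., k]
            ch[inside] = (rings * np.array([0.55, 0.45, 0.65])[k])[inside]
            rgb[sl][..., k] = ch

    centroids, _ = sample_centroids(truth, rng)
    nuc_color = np.array([0.26, 0.16, 0.45])  # hematoxylin-toned nuclei
    r_lo, r_hi = cfg.nucleus_radius_um
    for cx, cy in zip(centroids.x_um, centroids.y_um):
        r_px = min(int(cy / px), H - 1)
        c_px = min(int(cx / px), W - 1)
        # nuclei in fibrous tissue elongate along the local fiber axis,
        # with angular jitter growing with the local dispersion
        axis = theta[r_px, c_px] + rng.normal(0.0, disp[r_px, c_px])
        minor = rng.uniform(r_lo, r_hi) / px
        major = minor * rng.uniform(1.6, 2.2)
        # skimage's rotation is opposite-signed relative to the
        # (x = cols, y = rows) angle convention used everywhere else
        rr, cc = ellipse(cy / px - 0.5, cx / px - 0.5, minor, major,
                         shape=(H, W), rotation=-axis)
        rgb[rr, cc] = nuc_color * rng.uniform(0.85, 1.1)

    rgb = np.clip(rgb, 0.0, 1.0)
    return HistologyImage(rgb, pixel_size_um=px), centroids


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude of a complex Gaussian perturbation of the signal:
    √((S + n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) independent."""
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_dmri_signal(
    truth: PhantomTruth,
    protocol: Optional[DiffusionProtocol] = None,
    snr: Optional[float] = None,
    seed: Optional[int] = None,
) -> SignalVolume:
    """Forward-simulate dMRI signals from the ground-truth tensor field.

    Noiseless signal S = S0·exp(−b gᵀ D g) per measurement, then Rician
    noise at σ = S0/SNR (SNR at b = 0); ``snr = inf`` returns the exact
    noiseless signals. The volume is the single section plane: shape
    ``(ny, nx, 1, n_meas)``.
    """
    cfg = truth.config
    if protocol is None:
        protocol = DiffusionProtocol.three_shell()
    if snr is None:
        snr = cfg.snr
    if seed is None:
        seed = cfg.seed + 2
    if snr <= 0:
        raise ParameterError("snr must be > 0 (np.inf for noiseless)")
    eigs = np.linalg.eigvalsh(truth.d_true)
    if np.any(eigs < -1e-15):
        raise ParameterError("ground-truth tensors must be positive semidefinite")

    b = protocol.b_values
    g = protocol.directions
    # quadratic form g^T D g for every cell and measurement
    quad = np.einsum("mi,yxij,mj->yxm", g, truth.d_true, g)
    s = cfg.s0 * truth.s0_scale[..., None] * np.exp(-b * quad)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        s = rician_noise(s, cfg.s0 / snr, rng)
    vol = s[:, :, None, :]  # one slice
    return SignalVolume(vol, cfg.mr_resolution_um, protocol)


# ---------------------------------------------------------------------------
# Bundle export
# ---------------------------------------------------------------------------

def export_bundle(
    out_dir,
    truth: PhantomTruth,
    signals: SignalVolume,
    maps: Dict[str, "ParameterMap"],
    roi: Optional[np.ndarray] = None,
    histology: Optional[HistologyImage] = None,
    centroids: Optional[CentroidSet] = None,
    metadata: Optional[Dict[str, object]] = None,
) -> "pathlib.Path":
    """Write a complete sample bundle (manifest + files) to a directory.

    Files: NIfTI parameter maps and signal volume, bval/bvec sidecars,
    centroid CSV, optional histology TIFF, ground-truth sidecars for test
    assertions, and a JSON manifest listing exactly what was written.
    """
    import json
    import pathlib

    from . import core_io
    from .containers import ParameterMap

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ny, nx = truth.config.n_cells
    for name, pmap in maps.items():
        if pmap.shape[:2] != (ny, nx):
            raise ShapeError(f"map {name!r} is not on the phantom grid")

    manifest: Dict[str, object] = {
        "resolution_um": truth.config.mr_resolution_um,
        "seed": truth.config.seed,
        "metadata": dict(metadata or {}),
        "files": {},
    }
    files = manifest["files"]

    for name, pmap in maps.items():
        path = out / f"{name.lower()}.nii.gz"
        core_io.write_parameter_map(path, pmap)
        files[name] = path.name
    if roi is not None:
        roi_map = ParameterMap(roi.astype(float), truth.config.mr_resolution_um,
                               units="1", name="ROI")
        core_io.write_parameter_map(out / "roi.nii.gz", roi_map)
        files["ROI"] = "roi.nii.gz"

    core_io.write_signal_volume(out / "signals.nii.gz", signals)
    core_io.write_protocol(out / "protocol.bval", out / "protocol.bvec",
                           signals.protocol)
    files["signals"] = "signals.nii.gz"
    files["bval"] = "protocol.bval"
    files["bvec"] = "protocol.bvec"

    if centroids is not None:
        core_io.write_centroids(out / "centroids.csv", centroids)
        files["centroids"] = "centroids.csv"
    if histology is not None:
        core_io.write_histology(out / "histology.tif", histology)
        files["histology"] = "histology.tif"

    truth_maps = {
        "icvf": truth.icvf, "md_true": truth.md_true,
        "fa_ip_true": truth.fa_ip_true, "theta": truth.theta,
        "dispersion": truth.dispersion,
        "counts": truth.counts.astype(float),
        "feature_label": truth.feature_label.astype(float),
    }
    for name, arr in truth_maps.items():
        path = out / f"truth_{name}.nii.gz"
        core_io.write_parameter_map(
            path, ParameterMap(arr, truth.config.mr_resolution_um, name=name)
        )
        files[f"truth_{name}"] = path.name

    cfgdict = dataclasses.asdict(truth.config)
    manifest["config"] = {
        k: (list(v) if isinstance(v, tuple) else
            (None if isinstance(v, float) and not np.isfinite(v) else v))
        for k, v in cfgdict.items()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    files["manifest"] = "manifest.json"
    return out
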