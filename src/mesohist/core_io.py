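"""Shared I/O: NIfTI maps and signal volumes, bval/bvec protocols, TIFF/PNG
images, centroid and landmark CSVs, run configuration, and provenance
records.

Conventions: MR-grid maps travel as NIfTI with the voxel size in the header
(stored in mm, carried in μm inside the package); invalid cells are NaN in
the value volume (an explicit mask file is optional). Pixel-grid images
travel as TIFF/PNG with the pixel size from config or a sidecar. CSVs carry
μm coordinates with documented headers.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .containers import (
    MesohistError,
    ParameterError,
    ParameterMap,
    ResolutionError,
    SchemaError,
)
from .dti import DiffusionProtocol, SignalVolume
from .histology import CentroidSet, HistologyImage
from .registration import LandmarkPairs


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-stage parameters with their standard values.

    σ values in μm: 0.25 (structure-tensor derivative), 15 (integration),
    40 (final map smoothing); 200 μm MR grid; 80/20 split repeated 1000
    times. All seeds are recorded in every output's provenance record.
    """

    mr_resolution_um: float = 200.0
    pixel_size_um: float = 0.5
    sigma_derivative_um: float = 0.25
    sigma_integration_um: float = 15.0
    sigma_smooth_um: float = 40.0
    downsample_mode: str = "tensor-average"
    intensity_mode: str = "luminance"
    erosion_radius_cells: int = 1
    model_family: str = "poly2"
    repeats: int = 1000
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mr_resolution_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("sigma_derivative_um", "sigma_integration_um",
                     "sigma_smooth_um"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (by extension)."""
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# NIfTI maps and signal volumes
# ---------------------------------------------------------------------------

def _affine(resolution_um: float) -> np.ndarray:
    mm = resolution_um / 1000.0
    return np.diag([mm, mm, mm, 1.0])


def write_parameter_map(path, pmap: ParameterMap) -> None:
    """Write a parameter map as float32 NIfTI; invalid cells become NaN."""
    import nibabel as nib

    data = np.where(pmap.mask, pmap.values, np.nan).astype(np.float32)
    if data.ndim == 2:
        data = data[..., None]
    img = nib.Nifti1Image(data, _affine(pmap.resolution_um))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"{pmap.name}|{pmap.units}".encode()[:79]
    nib.save(img, str(path))


def read_parameter_map(
    path, expected_resolution_um: Optional[float] = None
) -> ParameterMap:
    """Read a parameter map written by :func:`write_parameter_map`.

    NaN cells are invalid. If ``expected_resolution_um`` is given and
    conflicts with the header, a :class:`ResolutionError` is raised.
    """
    import nibabel as nib

    img = nib.load(str(path))
    res_um = float(img.header.get_zooms()[0]) * 1000.0
    if expected_resolution_um is not None and not np.isclose(
        res_um, expected_resolution_um, rtol=1e-4
    ):
        raise ResolutionError(
            f"{path}: header resolution {res_um:.3f} μm conflicts with "
            f"configured {expected_resolution_um:.3f} μm"
        )
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
    name, _, units = descrip.partition("|")
    return ParameterMap(data, res_um, units=units or "1", name=name)


def write_signal_volume(path, signals: SignalVolume) -> None:
    """Write a 4D signal volume (last axis = measurement index)."""
    import nibabel as nib

    data = signals.intensities.astype(np.float32)
    if data.ndim == 3:  # (ny, nx, n_meas) single slice
        data = data[:, :, None, :]
    img = nib.Nifti1Image(data, _affine(signals.voxel_size_um))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_signal_volume(
    path, protocol: Optional[DiffusionProtocol] = None
) -> SignalVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    res_um = float(img.header.get_zooms()[0]) * 1000.0
    return SignalVolume(data, res_um, protocol)


# ---------------------------------------------------------------------------
# Protocol files (FSL bval/bvec dialect, or a single CSV)
# ---------------------------------------------------------------------------

def write_protocol(bval_path, bvec_path, protocol: DiffusionProtocol) -> None:
    """FSL dialect: whitespace-separated b-values; bvec rows = x, y, z."""
    np.savetxt(bval_path, protocol.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, protocol.directions.T, fmt="%.10g")


def read_protocol(bval_path, bvec_path, **metadata) -> DiffusionProtocol:
    b = np.loadtxt(bval_path).ravel()
    g = np.atleast_2d(np.loadtxt(bvec_path))
    if g.shape == (3, b.size):  # FSL dialect: rows are x, y, z components
        g = g.T
    return DiffusionProtocol(b, g, dict(metadata))


def read_protocol_csv(path, **metadata) -> DiffusionProtocol:
    """CSV with header columns b, gx, gy, gz."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("b", "gx", "gy", "gz"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return DiffusionProtocol(
        df["b"].to_numpy(), df[["gx", "gy", "gz"]].to_numpy(), dict(metadata)
    )


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_histology(path, image: HistologyImage) -> None:
    """Write an RGB histology image as 8-bit TIFF with μm pixel size tags."""
    import tifffile

    rgb8 = (np.clip(image.normalized(), 0, 1) * 255).astype(np.uint8)
    px = image.pixel_size_um
    tifffile.imwrite(
        str(path), rgb8,
        resolution=(1e4 / px, 1e4 / px), resolutionunit="CENTIMETER",
    )


def read_histology(path, pixel_size_um: Optional[float] = None) -> HistologyImage:
    """Read TIFF/PNG; pixel size from the TIFF tags unless given explicitly."""
    import tifffile

    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            rgb = page.asarray()
            if pixel_size_um is None:
                tag = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if tag is None:
                    raise ParameterError(
                        f"{path}: no resolution tag; pass pixel_size_um"
                    )
                num, den = tag.value
                per_unit = num / den
                unit_um = 1e4 if (unit and unit.value == 3) else 2.54e4
                pixel_size_um = unit_um / per_unit
    else:
        import imageio.v3 as iio

        rgb = iio.imread(str(path))
        if pixel_size_um is None:
            raise ParameterError(f"{path}: pass pixel_size_um for PNG input")
    if rgb.ndim == 3 and rgb.shape[-1] == 4:
        rgb = rgb[..., :3]
    return HistologyImage(rgb, pixel_size_um=pixel_size_um)


def write_png(path, rgb: np.ndarray) -> None:
    """Write a float RGB array in [0, 1] as an 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_centroids(
    path, extent_um: Optional[Tuple[float, float]] = None
) -> CentroidSet:
    """Read a centroid CSV with header ``x_um,y_um``.

    If an extent is given (or found as ``# extent_um: W H`` in the header
    comment), rows outside it are reported with their line numbers.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    bad = df.index[~np.isfinite(df["x_um"]) | ~np.isfinite(df["y_um"])]
    if len(bad):
        raise SchemaError(
            f"{path}: malformed rows at lines {[int(i) + 2 for i in bad]}"
        )
    if extent_um is None:
        first = pathlib.Path(path).read_text().splitlines()[0]
        if first.startswith("# extent_um:"):
            w, h = first.split(":")[1].split()
            extent_um = (float(w), float(h))
        else:
            extent_um = (float(df["x_um"].max()) + 1.0,
                         float(df["y_um"].max()) + 1.0)
    out_rows = df.index[
        (df["x_um"] < 0) | (df["x_um"] > extent_um[0])
        | (df["y_um"] < 0) | (df["y_um"] > extent_um[1])
    ]
    if len(out_rows):
        raise SchemaError(
            f"{path}: centroids outside the declared extent at lines "
            f"{[int(i) + 2 for i in out_rows]}"
        )
    return CentroidSet(df["x_um"].to_numpy(), df["y_um"].to_numpy(), extent_um)


def write_centroids(path, centroids: CentroidSet) -> None:
    w, h = centroids.extent_um
    with open(path, "w") as fh:
        fh.write(f"# extent_um: {w:.6g} {h:.6g}\n")
        fh.write("x_um,y_um\n")
        for x, y in zip(centroids.x_um, centroids.y_um):
            fh.write(f"{x:.4f},{y:.4f}\n")


LANDMARK_COLUMNS = ("moving_x_um", "moving_y_um", "fixed_x_um", "fixed_y_um")


def read_landmarks(path) -> LandmarkPairs:
    """Read a landmark CSV with columns moving_x_um,...,fixed_y_um."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for col in LANDMARK_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return LandmarkPairs(
        df[["moving_x_um", "moving_y_um"]].to_numpy(),
        df[["fixed_x_um", "fixed_y_um"]].to_numpy(),
    )


def write_landmarks(path, pairs: LandmarkPairs) -> None:
    import pandas as pd

    pd.DataFrame(
        np.hstack([pairs.moving, pairs.fixed]), columns=LANDMARK_COLUMNS
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample bundles and provenance
# ---------------------------------------------------------------------------

def read_bundle(bundle_dir):
    """Read a sample bundle written by :func:`mesohist.phantom.export_bundle`."""
    from .association import SampleBundle

    bundle_dir = pathlib.Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    res = manifest["resolution_um"]
    maps = {}
    roi = None
    for name, fname in manifest["files"].items():
        if name in ("MD", "FA", "FA_IP", "SA", "CD"):
            maps[name] = read_parameter_map(bundle_dir / fname,
                                            expected_resolution_um=res)
            maps[name].name = name
        elif name == "ROI":
            roi_map = read_parameter_map(bundle_dir / fname)
            roi = roi_map.mask & (roi_map.values > 0.5)
    if roi is None:
        ref = next(iter(maps.values()))
        roi = np.ones(ref.shape, dtype=bool)
        for m in maps.values():
            roi &= m.mask
    return SampleBundle(maps, roi, metadata=manifest.get("metadata", {}))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path,
    config: Dict[str, object],
    seed: Optional[int] = None,
    inputs: Optional[Dict[str, str]] = None,
) -> None:
    """Record how an output was produced: config, seed, version, input digests."""
    from . import __version__

    record = {
        "package": "mesohist",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_sha256": {
            k: sha256_of(v) for k, v in (inputs or {}).items()
            if pathlib.Path(v).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
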