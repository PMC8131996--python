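"""Shared data model, coordinate conventions, and file I/O.

Coordinate convention used throughout the package:

* ``x`` is the fast axis (A-scan position within a B-scan),
* ``y`` is the B-scan index (slow axis),
* ``z`` is depth, increasing posteriorly, 0-based.

Volumes are stored as ``(nz, ny, nx)`` arrays.  Layer surfaces store the
axial position of a boundary in micrometres measured from the first
(anterior) voxel plane, as an ``(ny, nx)`` grid.  Physical units are fixed:
µm for depth, pitch and thickness; mm² and mm³ for areas and volumes.
Unit conversion happens only when scalar metrics are emitted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ScanGrid",
    "OctVolume",
    "FlowVolume",
    "Surface",
    "EnFaceImage",
    "BinaryMask",
    "EyeVisitMetrics",
    "METRIC_COLUMNS",
    "QcError",
    "read_volume",
    "write_volume",
    "read_surface",
    "write_surface",
    "read_mask",
    "write_mask",
    "read_metrics",
    "write_metrics",
]

SURFACE_NAMES = {"outer_retina", "rpe", "bm", "csi", "cc_inner"}


def remove_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    from scipy import ndimage

    if min_px <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[labels]

#: Days per month used for all monthly rates (365.25 / 12).
DAYS_PER_MONTH = 30.44


class QcError(ValueError):
    """Raised when an input fails a quality-control gate."""


@dataclass(frozen=True)
class ScanGrid:
    """Geometry of a raster scan.

    Parameters
    ----------
    nx, ny
        Pixel counts along the fast (x) and slow (y) axes.
    pitch_x, pitch_y
        Lateral sampling in µm/pixel.
    pitch_z
        Axial sampling in µm/voxel.
    fovea_xy
        Pixel coordinates (x, y) of the foveal center.  Defaults to the
        grid center.
    """

    nx: int
    ny: int
    pitch_x: float
    pitch_y: float
    pitch_z: float
    fovea_xy: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("pixel counts must be positive")
        if min(self.pitch_x, self.pitch_y, self.pitch_z) <= 0:
            raise ValueError("all pitches must be positive")
        if self.fovea_xy is None:
            object.__setattr__(
                self, "fovea_xy", ((self.nx - 1) / 2.0, (self.ny - 1) / 2.0)
            )
        fx, fy = self.fovea_xy
        if not (0 <= fx <= self.nx - 1 and 0 <= fy <= self.ny - 1):
            raise ValueError(f"fovea {self.fovea_xy} outside the grid")

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the scan in mm."""
        return (self.nx * self.pitch_x / 1000.0, self.ny * self.pitch_y / 1000.0)

    @property
    def pixel_area_um2(self) -> float:
        return self.pitch_x * self.pitch_y

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_area_um2 * 1e-6

    def validate_extent(self, extent_mm: tuple[float, float]) -> None:
        """Check a claimed extent against pitch × pixel count (± one pixel)."""
        for claimed, actual, pitch in zip(
            extent_mm, self.extent_mm, (self.pitch_x, self.pitch_y)
        ):
            if abs(claimed - actual) * 1000.0 > pitch:
                raise ValueError(
                    f"extent {claimed} mm inconsistent with grid ({actual:.4f} mm)"
                )


def _check_voxels(voxels: np.ndarray, grid: ScanGrid) -> np.ndarray:
    voxels = np.asarray(voxels, dtype=np.float64)
    if voxels.ndim != 3:
        raise ValueError("volume must be 3-D (nz, ny, nx)")
    if voxels.shape[1:] != (grid.ny, grid.nx):
        raise ValueError(
            f"volume lateral shape {voxels.shape[1:]} != grid ({grid.ny}, {grid.nx})"
        )
    if not np.isfinite(voxels).all():
        raise ValueError("volume contains non-finite intensities")
    if (voxels < 0).any():
        raise ValueError("volume contains negative intensities")
    return voxels


@dataclass
class OctVolume:
    """Structural OCT intensity volume on a :class:`ScanGrid`."""

    voxels: np.ndarray
    grid: ScanGrid
    signal_strength: Optional[int] = None

    def __post_init__(self) -> None:
        self.voxels = _check_voxels(self.voxels, self.grid)

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    @property
    def depth_um(self) -> float:
        return self.nz * self.grid.pitch_z


@dataclass
class FlowVolume(OctVolume):
    """OCTA decorrelation (flow) volume on a :class:`ScanGrid`."""


@dataclass
class Surface:
    """Per-(x, y) axial position of a named layer boundary, in µm from the top."""

    name: str
    z_um: np.ndarray
    grid: Optional[ScanGrid] = None

    def __post_init__(self) -> None:
        if self.name not in SURFACE_NAMES:
            raise ValueError(f"unknown surface name {self.name!r}")
        self.z_um = np.asarray(self.z_um, dtype=np.float64)
        if self.z_um.ndim != 2:
            raise ValueError("surface must be a 2-D (ny, nx) grid")
        if self.grid is not None and self.z_um.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("surface shape does not match grid")
        if not np.isfinite(self.z_um).all():
            bad = np.argwhere(~np.isfinite(self.z_um))[0]
            raise ValueError(f"non-finite surface value at (y={bad[0]}, x={bad[1]})")


@dataclass
class EnFaceImage:
    """2-D en face projection on a :class:`ScanGrid`."""

    pixels: np.ndarray
    grid: ScanGrid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("en face shape does not match grid")
        if not np.isfinite(self.pixels).all():
            raise ValueError("en face image contains non-finite values")


@dataclass
class BinaryMask:
    """2-D boolean mask on a :class:`ScanGrid` with a provenance label."""

    pixels: np.ndarray
    grid: ScanGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("mask shape does not match grid")

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.grid.pixel_area_mm2


# Stable column order for the metrics table; units documented in the CSV header.
METRIC_COLUMNS = [
    "mnv_area_mm2",
    "sqrt_mnv_area_mm",
    "fd_pct_r1",
    "fd_pct_r2",
    "fd_pct_r3",
    "fd_pct_excl_mnv",
    "mean_fd_area_um2_r1",
    "mean_fd_area_um2_r2",
    "mean_fd_area_um2_r3",
    "mean_fd_area_um2_excl_mnv",
    "vad",
    "vsd",
    "ped_area_mm2",
    "ped_volume_mm3",
    "mnv_ped_area_mm2",
    "mnv_ped_volume_mm3",
    "sqrt_mnv_ped_area_mm",
    "cubert_mnv_ped_volume_mm",
    "mct_um",
    "cvi",
]

_METRIC_UNITS = {
    "mnv_area_mm2": "mm^2",
    "sqrt_mnv_area_mm": "mm",
    "fd_pct_r1": "%",
    "fd_pct_r2": "%",
    "fd_pct_r3": "%",
    "fd_pct_excl_mnv": "%",
    "mean_fd_area_um2_r1": "um^2",
    "mean_fd_area_um2_r2": "um^2",
    "mean_fd_area_um2_r3": "um^2",
    "mean_fd_area_um2_excl_mnv": "um^2",
    "vad": "ratio",
    "vsd": "ratio",
    "ped_area_mm2": "mm^2",
    "ped_volume_mm3": "mm^3",
    "mnv_ped_area_mm2": "mm^2",
    "mnv_ped_volume_mm3": "mm^3",
    "sqrt_mnv_ped_area_mm": "mm",
    "cubert_mnv_ped_volume_mm": "mm",
    "mct_um": "um",
    "cvi": "ratio",
}


@dataclass
class EyeVisitMetrics:
    """All per-eye, per-visit scalar biomarkers feeding the cohort statistics.

    A metric that could not be computed (missing input family, empty mask)
    is ``None`` and serialized as an empty cell.
    """

    eye_id: str = ""
    visit_date: str = ""
    mnv_area_mm2: Optional[float] = None
    sqrt_mnv_area_mm: Optional[float] = None
    fd_pct_r1: Optional[float] = None
    fd_pct_r2: Optional[float] = None
    fd_pct_r3: Optional[float] = None
    fd_pct_excl_mnv: Optional[float] = None
    mean_fd_area_um2_r1: Optional[float] = None
    mean_fd_area_um2_r2: Optional[float] = None
    mean_fd_area_um2_r3: Optional[float] = None
    mean_fd_area_um2_excl_mnv: Optional[float] = None
    vad: Optional[float] = None
    vsd: Optional[float] = None
    ped_area_mm2: Optional[float] = None
    ped_volume_mm3: Optional[float] = None
    mnv_ped_area_mm2: Optional[float] = None
    mnv_ped_volume_mm3: Optional[float] = None
    sqrt_mnv_ped_area_mm: Optional[float] = None
    cubert_mnv_ped_volume_mm: Optional[float] = None
    mct_um: Optional[float] = None
    cvi: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("fd_pct_r1", "fd_pct_r2", "fd_pct_r3", "fd_pct_excl_mnv"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.vad is not None and self.vsd is not None:
            if not (0.0 <= self.vsd <= self.vad <= 1.0):
                raise ValueError(f"expected 0 <= vsd <= vad <= 1, got {self.vsd}, {self.vad}")
        if self.cvi is not None and not (0.0 <= self.cvi <= 1.0):
            raise ValueError(f"cvi={self.cvi} outside [0, 1]")
        for name in (
            "mnv_area_mm2", "ped_area_mm2", "ped_volume_mm3",
            "mnv_ped_area_mm2", "mnv_ped_volume_mm3", "mct_um",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def _grid_from_sidecar(meta: dict) -> ScanGrid:
    grid = ScanGrid(
        nx=int(meta["nx"]),
        ny=int(meta["ny"]),
        pitch_x=float(meta["pitch_x_um"]),
        pitch_y=float(meta["pitch_y_um"]),
        pitch_z=float(meta["pitch_z_um"]),
        fovea_xy=(float(meta["fovea_x"]), float(meta["fovea_y"]))
        if "fovea_x" in meta
        else None,
    )
    return grid


def read_volume(path, kind: str = "flow", min_signal_strength: int = 7):
    """Read a multi-page TIFF or NIfTI volume plus its sidecar JSON metadata.

    TIFF pages are B-scans of shape ``(nz, nx)``; the returned volume is
    ``(nz, ny, nx)``.  The sidecar (``<file>.json`` next to the stack) must
    provide ``nx, ny, nz, pitch_x_um, pitch_y_um, pitch_z_um`` and may provide
    ``fovea_x, fovea_y, signal_strength``.

    Raises
    ------
    QcError
        If the recorded signal strength is below ``min_signal_strength``.
    """
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    grid = _grid_from_sidecar(meta)

    ss = meta.get("signal_strength")
    if ss is not None and ss < min_signal_strength:
        raise QcError(
            f"signal strength {ss} below the minimum of {min_signal_strength}; "
            "scan excluded by quality control"
        )

    if path.suffix in {".nii", ".gz"}:
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)  # (nx, ny, nz)
        voxels = np.transpose(data, (2, 1, 0))
    else:
        pages = tifffile.imread(str(path))  # (ny, nz, nx)
        if pages.ndim == 2:
            pages = pages[None]
        voxels = np.transpose(pages, (1, 0, 2))

    nz, ny, nx = voxels.shape
    for claimed, actual, axis in ((meta["nx"], nx, "nx"), (meta["ny"], ny, "ny"),
                                  (meta["nz"], nz, "nz")):
        if int(claimed) != actual:
            raise ValueError(f"sidecar {axis}={claimed} but stack has {actual}")
    if "extent_mm" in meta:
        grid.validate_extent(tuple(meta["extent_mm"]))

    cls = FlowVolume if kind == "flow" else OctVolume
    return cls(voxels=voxels, grid=grid, signal_strength=ss)


def write_volume(volume: OctVolume, path) -> Path:
    """Write a volume as a multi-page TIFF (page = B-scan) plus sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.transpose(volume.voxels, (1, 0, 2)).astype(np.float32)
    tifffile.imwrite(str(path), pages)
    meta = {
        "nx": volume.grid.nx,
        "ny": volume.grid.ny,
        "nz": volume.nz,
        "pitch_x_um": volume.grid.pitch_x,
        "pitch_y_um": volume.grid.pitch_y,
        "pitch_z_um": volume.grid.pitch_z,
        "fovea_x": volume.grid.fovea_xy[0],
        "fovea_y": volume.grid.fovea_xy[1],
        "signal_strength": volume.signal_strength,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_surface(path, grid: ScanGrid, name: str = "rpe", inpaint: bool = False) -> Surface:
    """Read a layer surface from a CSV (ny rows × nx cols, µm) or JSON file.

    ``NaN`` cells are rejected by default; with ``inpaint=True`` they are
    filled by nearest-neighbour interpolation.
    """
    path = Path(path)
    if path.suffix == ".json":
        z = np.asarray(json.loads(path.read_text()), dtype=np.float64)
    else:
        z = np.loadtxt(str(path), delimiter=",", dtype=np.float64, ndmin=2)
    if z.shape != (grid.ny, grid.nx):
        raise ValueError(f"surface shape {z.shape} != grid ({grid.ny}, {grid.nx})")
    bad = ~np.isfinite(z)
    if bad.any():
        if not inpaint:
            y, x = np.argwhere(bad)[0]
            raise ValueError(f"non-finite surface value at (y={y}, x={x}) in {path.name}")
        from scipy import ndimage

        idx = ndimage.distance_transform_edt(bad, return_distances=False,
                                             return_indices=True)
        z = z[tuple(idx)]
    return Surface(name=name, z_um=z, grid=grid)


def write_surface(surface: Surface, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path), surface.z_um, delimiter=",", fmt="%.17g")
    return path


def read_mask(path, grid: ScanGrid, provenance: str = "") -> BinaryMask:
    """Read a binary mask from a single-page PNG/TIFF; nonzero pixels are true."""
    arr = iio.imread(str(path))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr.max(axis=-1)
    return BinaryMask(pixels=arr > 0, grid=grid, provenance=provenance or str(path))


def write_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))
    return path


def write_metrics(records: list[EyeVisitMetrics], path) -> Path:
    """Write eye-visit metric records as CSV with a unit-documenting header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["eye_id", "visit_date"] + METRIC_COLUMNS
    df = pd.DataFrame([r.to_dict() for r in records], columns=cols)
    header = "# octamnv eye-visit metrics v1; units: " + ", ".join(
        f"{k}={v}" for k, v in _METRIC_UNITS.items()
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
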