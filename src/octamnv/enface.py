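"""Slab extraction, projection-artifact removal, and structural compensation.

The two named slabs of the analysis are available as presets:

* ``orcc`` — outer retinal boundary down to the innermost choriocapillaris,
  resolved as Bruch's membrane + 4 µm so that it abuts the CC slab;
* ``cc_16um`` — a 16-µm-thick slab whose anterior boundary sits 4 µm beneath
  Bruch's membrane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import BinaryMask, EnFaceImage, OctVolume, Surface

__all__ = [
    "SlabDefinition",
    "SLAB_PRESETS",
    "extract_enface",
    "remove_projection_artifacts",
    "compensate_cc",
]


@dataclass(frozen=True)
class SlabDefinition:
    """A depth slab bounded by layer surfaces with µm offsets.

    ``top`` and ``bottom`` are ``(surface_name, offset_um)``; alternatively
    ``thickness_um`` fixes the bottom at a constant depth below the top.
    """

    top: tuple[str, float]
    bottom: Optional[tuple[str, float]] = None
    thickness_um: Optional[float] = None
    projection: str = "mean"

    def __post_init__(self) -> None:
        if (self.bottom is None) == (self.thickness_um is None):
            raise ValueError("specify exactly one of bottom / thickness_um")
        if self.projection not in {"mean", "max"}:
            raise ValueError("projection must be 'mean' or 'max'")


SLAB_PRESETS: dict[str, SlabDefinition] = {
    # outer retina to the innermost aspect of the CC (= BM + 4 µm)
    "orcc": SlabDefinition(top=("outer_retina", 0.0), bottom=("bm", 4.0)),
    # 16-µm CC slab starting 4 µm beneath Bruch's membrane
    "cc_16um": SlabDefinition(top=("bm", 4.0), thickness_um=16.0),
}


def _resolve_bounds(
    slab: SlabDefinition, surfaces: dict[str, Surface], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    name, off = slab.top
    if name not in surfaces:
        raise KeyError(f"slab references missing surface {name!r}")
    top = surfaces[name].z_um + off
    if slab.bottom is not None:
        bname, boff = slab.bottom
        if bname not in surfaces:
            raise KeyError(f"slab references missing surface {bname!r}")
        bottom = surfaces[bname].z_um + boff
    else:
        bottom = top + slab.thickness_um
    if not (bottom > top).all():
        raise ValueError("slab bottom is not posterior to its top everywhere")
    if top.shape != shape or bottom.shape != shape:
        raise ValueError("surface shape does not match volume")
    return top, bottom


def extract_enface(
    volume: OctVolume,
    slab: SlabDefinition,
    surfaces: dict[str, Surface],
    max_clipped_fraction: float = 0.01,
) -> EnFaceImage:
    """Project voxels with z in [top, bottom) onto the en face plane.

    Mean projection integrates the piecewise-constant A-scan profile between
    the two boundaries, so sub-voxel boundary offsets are resolved linearly;
    a boundary that falls mid-voxel contributes that voxel fractionally.
    Fails if more than ``max_clipped_fraction`` of the requested slab depth
    lies outside the volume.
    """
    grid = volume.grid
    top, bottom = _resolve_bounds(slab, surfaces, (grid.ny, grid.nx))
    dz = grid.pitch_z
    depth = volume.nz * dz

    a = np.clip(top, 0.0, depth)
    b = np.clip(bottom, 0.0, depth)
    requested = bottom - top
    clipped = requested - (b - a)
    clipped_fraction = float(clipped.sum() / requested.sum())
    if clipped_fraction > max_clipped_fraction:
        raise ValueError(
            f"slab exits the volume: {100 * clipped_fraction:.2f}% of the "
            f"requested depth is clipped (limit {100 * max_clipped_fraction:.2f}%)"
        )

    if slab.projection == "max":
        out = np.full((grid.ny, grid.nx), -np.inf)
        k0 = np.floor(a / dz).astype(int)
        k1 = np.ceil(b / dz).astype(int) - 1
        for k in range(int(k0.min()), int(k1.max()) + 1):
            sel = (k0 <= k) & (k <= k1)
            out[sel] = np.maximum(out[sel], volume.voxels[k][sel])
        out[~np.isfinite(out)] = 0.0
        return EnFaceImage(out, grid)

    # cumulative integral of the A-scan profile at voxel-plane boundaries
    cum = np.concatenate(
        [np.zeros((1, grid.ny, grid.nx)), np.cumsum(volume.voxels, axis=0) * dz]
    )

    def integral_to(z: np.ndarray) -> np.ndarray:
        k = np.clip(np.floor(z / dz).astype(int), 0, volume.nz - 1)
        base = np.take_along_axis(cum, k[None], axis=0)[0]
        plane = np.take_along_axis(volume.voxels, k[None], axis=0)[0]
        return base + (z - k * dz) * plane

    thickness = np.maximum(b - a, 1e-12)
    mean = (integral_to(b) - integral_to(a)) / thickness
    return EnFaceImage(mean, grid)


def remove_projection_artifacts(
    flow_enface: EnFaceImage,
    retinal_vessel_mask: BinaryMask,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> EnFaceImage:
    """Replace pixels under the retinal-vessel mask by harmonic inpainting.

    Masked pixels are iteratively set to the mean of their 8-neighbours
    (Jacobi relaxation with the unmasked pixels as fixed boundary values)
    until convergence, which removes decorrelation tails projected from the
    overlying retinal circulation.  Non-masked pixels are untouched, and the
    operation is idempotent on its own output.
    """
    mask = retinal_vessel_mask.pixels
    if mask.shape != flow_enface.pixels.shape:
        raise ValueError("mask and image are on different grids")
    frac = mask.mean()
    if frac > 0.5:
        raise ValueError(f"retinal-vessel mask covers {100 * frac:.0f}% of the image")
    if not mask.any():
        return EnFaceImage(flow_enface.pixels.copy(), flow_enface.grid)

    img = flow_enface.pixels.copy()
    img[mask] = img[~mask].mean()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    scale = float(img[~mask].std() + 1e-12)
    for _ in range(max_iter):
        neigh = ndimage.convolve(img, kernel, mode="nearest")
        cnt = ndimage.convolve(np.ones_like(img), kernel, mode="nearest")
        new = neigh / cnt
        delta = np.abs(new[mask] - img[mask]).max(initial=0.0)
        img[mask] = new[mask]
        if delta <= tol * scale:
            break
    return EnFaceImage(img, flow_enface.grid)


def compensate_cc(
    cc_flow: EnFaceImage,
    cc_structure: EnFaceImage,
    smooth_sigma_px: float = 3.0,
    floor_percentile: float = 1.0,
) -> EnFaceImage:
    """Compensate CC flow for signal loss using the structural slab.

    The flow image is divided by a smoothed, floored version of the en face
    structure normalized to its global mean, then rescaled so the global mean
    flow is preserved.  Multiplying the structure by a constant changes
    nothing (scale equivariance).
    """
    if cc_flow.pixels.shape != cc_structure.pixels.shape:
        raise ValueError("flow and structure are on different grids")
    s = cc_structure.pixels
    if not (s > 0).any():
        raise ValueError("structure image is all-zero")
    smooth = ndimage.gaussian_filter(s, smooth_sigma_px)
    floor = np.percentile(smooth, floor_percentile)
    if floor <= 0:
        floor = smooth[smooth > 0].min()
    smooth = np.maximum(smooth, floor)
    out = cc_flow.pixels * (smooth.mean() / smooth)
    mean_in = cc_flow.pixels.mean()
    mean_out = out.mean()
    if mean_out > 0:
        out = out * (mean_in / mean_out)
    return EnFaceImage(out, cc_flow.grid)
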