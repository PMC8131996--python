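"""Pigment-epithelial-detachment volumetry from RPE and BM surfaces.

The PED height map is the anterior displacement of the RPE above Bruch's
membrane.  With z increasing posteriorly, an elevated RPE has *smaller* z
than BM, so height = BM − RPE, floored at zero.  Restricting the height map
to the MNV footprint separates lesion-associated PED volume from drusen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BinaryMask, ScanGrid, Surface

__all__ = [
    "PedMap",
    "ped_height_map",
    "ped_metrics",
    "mnv_ped_metrics",
    "stabilize",
]


@dataclass
class PedMap:
    height_um: np.ndarray
    grid: ScanGrid


def ped_height_map(rpe: Surface, bm: Surface, grid: Optional[ScanGrid] = None) -> PedMap:
    """RPE elevation above BM in µm, non-negative (posterior RPE floored at 0)."""
    if rpe.z_um.shape != bm.z_um.shape:
        raise ValueError("RPE and BM surfaces are on different grids")
    grid = grid or rpe.grid or bm.grid
    if grid is None:
        raise ValueError("a ScanGrid is required")
    height = np.maximum(bm.z_um - rpe.z_um, 0.0)
    return PedMap(height_um=height, grid=grid)


def ped_metrics(
    heights: PedMap, grid: Optional[ScanGrid] = None, min_height_um: float = 0.0
) -> tuple[float, float]:
    """(area mm², volume mm³) of the detachment.

    Area counts pixels with height strictly above ``min_height_um`` (default
    0: any positive elevation counts); volume integrates the height over
    those pixels.
    """
    if min_height_um < 0:
        raise ValueError("min_height_um must be non-negative")
    grid = grid or heights.grid
    sel = heights.height_um > min_height_um
    area_mm2 = float(sel.sum()) * grid.pixel_area_mm2
    # height µm → mm (1e-3) times pixel area mm²
    volume_mm3 = float(heights.height_um[sel].sum()) * 1e-3 * grid.pixel_area_mm2
    return area_mm2, volume_mm3


def mnv_ped_metrics(
    heights: PedMap,
    mnv_mask: BinaryMask,
    grid: Optional[ScanGrid] = None,
    min_height_um: float = 0.0,
) -> tuple[float, float]:
    """PED area/volume restricted to the MNV footprint (MNV–PED metrics)."""
    if heights.height_um.shape != mnv_mask.pixels.shape:
        raise ValueError("height map and MNV mask are on different grids")
    grid = grid or heights.grid
    masked = np.where(mnv_mask.pixels, heights.height_um, 0.0)
    return ped_metrics(PedMap(masked, grid), grid, min_height_um)


def stabilize(area_mm2: float, volume_mm3: float) -> tuple[float, float]:
    """Variance-stabilizing transforms: √area (mm) and ∛volume (mm).

    These remove the dependence of test–retest variability on lesion size.
    """
    if area_mm2 < 0 or volume_mm3 < 0:
        raise ValueError("areas and volumes must be non-negative")
    return float(np.sqrt(area_mm2)), float(np.cbrt(volume_mm3))
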