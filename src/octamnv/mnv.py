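"""MNV lesion segmentation and lesion-level metrics.

The lesion is detected as elevated decorrelation within the artifact-removed
outer-retina-to-CC en face image.  Background flow statistics are estimated
far (> 600 µm) from any provisional lesion so that the detection threshold
is not contaminated by lesion flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .core import (
    DAYS_PER_MONTH,
    BinaryMask,
    EnFaceImage,
    ScanGrid,
    remove_small_components,
)

__all__ = [
    "LesionSet",
    "segment_mnv",
    "lesion_metrics",
    "eligibility",
    "count_foci",
    "enlargement_rate",
    "analyze_lesion",
]

#: connectivity structure for all 2-D component labelling (8-connectivity)
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LesionFocus:
    area_mm2: float
    centroid_xy: tuple[float, float]


@dataclass
class LesionSet:
    mask: BinaryMask
    foci: list[LesionFocus]
    gld_um: Optional[float]
    area_mm2: float
    sqrt_area_mm: float
    n_foci: int


def segment_mnv(
    orcc_enface: EnFaceImage,
    k_sigma: float = 2.0,
    closing_radius_px: int = 2,
    min_component_mm2: float = 0.01,
    background_margin_um: float = 600.0,
) -> BinaryMask:
    """Threshold-based lesion segmentation of the ORCC en face flow image.

    Steps: provisional foreground by Otsu; background statistics from pixels
    more than ``background_margin_um`` outside the provisional foreground;
    threshold at background mean + ``k_sigma``·SD; morphological closing
    (disk radius 2 px); hole filling; removal of components smaller than
    ``min_component_mm2``.
    """
    grid = orcc_enface.grid
    img = orcc_enface.pixels

    if np.ptp(img) == 0:
        return BinaryMask(np.zeros_like(img, dtype=bool), grid, "segment_mnv")
    provisional = img > threshold_otsu(img)
    if provisional.any() and not provisional.all():
        d = ndimage.distance_transform_edt(
            ~provisional, sampling=(grid.pitch_y, grid.pitch_x)
        )
        background = d > background_margin_um
        if not background.any():
            background = ~provisional
    else:
        background = np.ones_like(provisional)
    thr = img[background].mean() + k_sigma * img[background].std()

    mask = img > thr
    if closing_radius_px > 0:
        fp = disk(closing_radius_px)
        mask = ndimage.binary_erosion(
            ndimage.binary_dilation(mask, structure=fp), structure=fp, border_value=1
        )
    mask = ndimage.binary_fill_holes(mask)
    min_px = int(np.ceil(min_component_mm2 * 1e6 / grid.pixel_area_um2))
    mask = remove_small_components(mask, min_px)
    return BinaryMask(mask, grid, "segment_mnv")


def _boundary_points_um(mask: np.ndarray, grid: ScanGrid) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=STRUCT8, border_value=0)
    yy, xx = np.nonzero(mask & ~inner)
    return np.column_stack([xx * grid.pitch_x, yy * grid.pitch_y])


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute force below
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def lesion_metrics(mask: BinaryMask, grid: Optional[ScanGrid] = None):
    """Lesion area (mm²), its square root (mm), and the greatest linear
    dimension (µm) of the lesion complex.

    The GLD is the maximum pairwise distance between boundary-pixel centers;
    it is ``None`` for an empty mask.
    """
    grid = grid or mask.grid
    n = int(mask.pixels.sum())
    area_mm2 = n * grid.pixel_area_mm2
    sqrt_area = float(np.sqrt(area_mm2))
    if n == 0:
        return area_mm2, sqrt_area, None
    gld = _max_pairwise_distance(_boundary_points_um(mask.pixels, grid))
    return area_mm2, sqrt_area, gld


def eligibility(
    mask: BinaryMask,
    grid: Optional[ScanGrid] = None,
    min_gld_um: float = 250.0,
    min_area_mm2: float = 0.2,
) -> dict:
    """Study eligibility of a lesion on a 6 × 6-mm scan.

    A lesion is ineligible if it is too small to measure reproducibly
    (GLD < 250 µm or area < 0.2 mm²) or if it is not fully contained in the
    scan (mask touches the border).
    """
    grid = grid or mask.grid
    area_mm2, _, gld = lesion_metrics(mask, grid)
    reasons = []
    if mask.pixels.sum() == 0:
        reasons.append("empty_mask")
    else:
        if gld is not None and gld < min_gld_um:
            reasons.append(f"gld<{min_gld_um:g}um")
        if area_mm2 < min_area_mm2:
            reasons.append(f"area<{min_area_mm2:g}mm2")
        m = mask.pixels
        if m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any():
            reasons.append("touches_scan_border")
    return {"eligible": not reasons, "reasons": reasons}


def count_foci(
    mask: BinaryMask,
    grid: Optional[ScanGrid] = None,
    merge_distance_um: float = 600.0,
) -> int:
    """Number of discrete neovascular foci.

    Connected components (8-connectivity) whose boundary-to-boundary distance
    is below ``merge_distance_um`` are considered lobulations of one lesion
    and merged; only components separated by at least that distance count as
    separate foci.
    """
    grid = grid or mask.grid
    labels, n = ndimage.label(mask.pixels, structure=STRUCT8)
    if n <= 1:
        return n
    # union-find over components closer than the merge distance
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dist_maps = []
    for i in range(1, n + 1):
        dist_maps.append(
            ndimage.distance_transform_edt(
                labels != i, sampling=(grid.pitch_y, grid.pitch_x)
            )
        )
    for i in range(n):
        for j in range(i + 1, n):
            d = dist_maps[i][labels == j + 1].min()
            if d < merge_distance_um:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(n)})


def enlargement_rate(v1: float, v2: float, days: float) -> float:
    """Monthly change (v2 − v1) / (days / 30.44); works on any scale
    (mm²/month for areas, mm/month for square-root areas)."""
    if days <= 0:
        raise ValueError("days between visits must be positive")
    return (v2 - v1) / (days / DAYS_PER_MONTH)


def analyze_lesion(mask: BinaryMask, grid: Optional[ScanGrid] = None) -> LesionSet:
    """Bundle the per-lesion outputs: mask, per-focus areas, GLD, focus count."""
    grid = grid or mask.grid
    area_mm2, sqrt_area, gld = lesion_metrics(mask, grid)
    labels, n = ndimage.label(mask.pixels, structure=STRUCT8)
    foci = []
    for i in range(1, n + 1):
        comp = labels == i
        yy, xx = np.nonzero(comp)
        foci.append(
            LesionFocus(
                area_mm2=float(comp.sum()) * grid.pixel_area_mm2,
                centroid_xy=(float(xx.mean()), float(yy.mean())),
            )
        )
    return LesionSet(
        mask=mask,
        foci=foci,
        gld_um=gld,
        area_mm2=area_mm2,
        sqrt_area_mm=sqrt_area,
        n_foci=count_foci(mask, grid),
    )
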