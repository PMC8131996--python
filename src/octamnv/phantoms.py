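"""Seeded synthetic phantoms with known ground truth.

Every generator here produces the inputs one stage of the quantification
pipeline consumes, together with ground truth obtained by construction or
brute-force pixel/voxel counting.  The truth computations deliberately share
no code with the measurement modules, so they can serve as independent
oracles in recovery tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .core import (
    DAYS_PER_MONTH,
    BinaryMask,
    EnFaceImage,
    FlowVolume,
    OctVolume,
    ScanGrid,
    Surface,
)

__all__ = [
    "LesionPhantom",
    "CcPhantom",
    "PedPhantom",
    "ChoroidPhantom",
    "make_lesion_phantom",
    "make_cc_phantom",
    "cc_phantom_volume",
    "make_ped_phantom",
    "make_choroid_phantom",
    "make_cohort",
    "random_fd_disks",
    "DEFAULT_COHORT_MOMENTS",
]


def _disk_mask(grid: ScanGrid, cx_px: float, cy_px: float, radius_um: float) -> np.ndarray:
    """Rasterize a disk by pixel-center membership, respecting anisotropic pitch."""
    y, x = np.mgrid[0 : grid.ny, 0 : grid.nx]
    d2 = ((x - cx_px) * grid.pitch_x) ** 2 + ((y - cy_px) * grid.pitch_y) ** 2
    return d2 <= radius_um**2


def _speckle(rng: np.random.Generator, img: np.ndarray, sd: float) -> np.ndarray:
    """Multiplicative Gaussian speckle, clipped at zero."""
    if sd <= 0:
        return img
    return np.clip(img * (1.0 + sd * rng.standard_normal(img.shape)), 0.0, None)


# ---------------------------------------------------------------------------
# MNV lesion phantom (ORCC band)
# ---------------------------------------------------------------------------


@dataclass
class LesionPhantom:
    volume: FlowVolume
    truth_mnv: BinaryMask
    truth_vessels: BinaryMask
    truth_skeleton: BinaryMask
    enface: EnFaceImage


def _grow_tree(
    rng: np.random.Generator,
    grid: ScanGrid,
    cx: float,
    cy: float,
    radius_um: float,
    n_branches: int,
    tortuosity: float,
    branch_prob: float = 0.15,
) -> np.ndarray:
    """Random branching polylines radiating from the lesion center, 1 px wide.

    Branches start slightly off-center in separated angular sectors so that
    the rendered tubes stay mostly non-overlapping — the rasterized polyline
    pixel count is then an honest centerline-length ground truth.
    """
    skel = np.zeros((grid.ny, grid.nx), dtype=bool)
    radius_px = radius_um / grid.pitch_x
    step = max(2.0, radius_px / 12.0)
    r0 = min(6.0, radius_px / 4.0)

    def walk(x: float, y: float, theta: float, remaining: float, depth: int) -> None:
        while remaining > 0:
            theta += tortuosity * rng.standard_normal()
            nx_, ny_ = x + step * np.cos(theta), y + step * np.sin(theta)
            r_um = np.hypot((nx_ - cx) * grid.pitch_x, (ny_ - cy) * grid.pitch_y)
            if r_um > radius_um * 0.95:
                return
            rr, cc = draw_line(int(round(y)), int(round(x)), int(round(ny_)), int(round(nx_)))
            ok = (rr >= 0) & (rr < grid.ny) & (cc >= 0) & (cc < grid.nx)
            skel[rr[ok], cc[ok]] = True
            x, y = nx_, ny_
            remaining -= step
            if depth < 1 and rng.random() < branch_prob:
                walk(x, y, theta + rng.choice([-1, 1]) * 0.9, remaining * 0.6, depth + 1)

    for i in range(n_branches):
        theta0 = 2 * np.pi * (i + 0.3 * rng.random()) / n_branches
        walk(cx + r0 * np.cos(theta0), cy + r0 * np.sin(theta0), theta0,
             radius_px * 1.2, 0)
    return skel


def make_lesion_phantom(
    grid: ScanGrid,
    seed: int = 0,
    center_px: Optional[tuple[float, float]] = None,
    radius_um: float = 1000.0,
    n_branches: int = 5,
    vessel_width_px: int = 3,
    tortuosity: float = 0.12,
    vessel_level: float = 220.0,
    interior_level: float = 60.0,
    background_level: float = 10.0,
    noise_sd: float = 0.0,
    nz: int = 8,
    empty: bool = False,
) -> LesionPhantom:
    """Flow phantom of an MNV lesion inside the outer-retina-to-CC band.

    The lesion is a disk containing a random branching vessel tree; flow is
    high on the tree, moderately elevated on the rest of the lesion, and a low
    noise floor outside.  Truth masks (lesion disk, dilated vessel tree, and
    its 1-px centerlines) are returned for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if center_px is None:
        center_px = ((grid.nx - 1) / 2.0, (grid.ny - 1) / 2.0)
    cx, cy = center_px

    if empty:
        mnv = np.zeros((grid.ny, grid.nx), dtype=bool)
        skel = np.zeros_like(mnv)
        vessels = np.zeros_like(mnv)
        enface = np.full((grid.ny, grid.nx), background_level)
    else:
        if radius_um < 2 * min(grid.pitch_x, grid.pitch_y):
            raise ValueError("lesion radius below 2 pixels")
        half_w = min(cx, grid.nx - 1 - cx) * grid.pitch_x
        half_h = min(cy, grid.ny - 1 - cy) * grid.pitch_y
        if radius_um > min(half_w, half_h):
            raise ValueError("lesion does not fit inside the grid")
        mnv = _disk_mask(grid, cx, cy, radius_um)
        skel = _grow_tree(rng, grid, cx, cy, radius_um, n_branches, tortuosity)
        vessels = ndimage.binary_dilation(
            skel, structure=disk_footprint(max(1, vessel_width_px // 2))
        ) & mnv
        skel &= mnv
        enface = np.full((grid.ny, grid.nx), background_level)
        enface[mnv] = interior_level
        enface[vessels] = vessel_level

    enface = _speckle(rng, enface, noise_sd)
    voxels = np.broadcast_to(enface, (nz, grid.ny, grid.nx)).copy()
    return LesionPhantom(
        volume=FlowVolume(voxels=voxels, grid=grid, signal_strength=10),
        truth_mnv=BinaryMask(mnv, grid, "phantom:truth_mnv"),
        truth_vessels=BinaryMask(vessels, grid, "phantom:truth_vessels"),
        truth_skeleton=BinaryMask(skel, grid, "phantom:truth_skeleton"),
        enface=EnFaceImage(enface, grid),
    )


# ---------------------------------------------------------------------------
# Choriocapillaris phantom
# ---------------------------------------------------------------------------


@dataclass
class CcPhantom:
    cc_flow: EnFaceImage
    cc_structure: EnFaceImage
    truth_fd: BinaryMask


def random_fd_disks(
    grid: ScanGrid,
    rng: np.random.Generator,
    n: int = 300,
    diameter_um: tuple[float, float] = (30.0, 180.0),
    forbidden: Optional[np.ndarray] = None,
    margin_um: float = 60.0,
    max_tries: int = 200_000,
) -> list[tuple[float, float, float]]:
    """Sample pairwise-disjoint deficit disks ``(x_px, y_px, diameter_um)``.

    Disk supports avoid each other, the scan border, and an optional
    forbidden mask (e.g. the MNV lesion).  The defaults cover roughly 8% of
    a 6 × 6-mm scan, in the range of reported choriocapillaris deficit
    fractions.
    """
    if forbidden is not None:
        fdist = ndimage.distance_transform_edt(
            ~forbidden, sampling=(grid.pitch_y, grid.pitch_x)
        ) if forbidden.any() else None
    else:
        fdist = None
    xs = np.empty(0)
    ys = np.empty(0)
    rs = np.empty(0)  # radii in µm
    sep_pad = 2 * max(grid.pitch_x, grid.pitch_y)
    tries = 0
    while len(xs) < n and tries < max_tries:
        tries += 1
        d = rng.uniform(*diameter_um)
        r = d / 2.0
        x = rng.uniform((r + margin_um) / grid.pitch_x,
                        grid.nx - 1 - (r + margin_um) / grid.pitch_x)
        y = rng.uniform((r + margin_um) / grid.pitch_y,
                        grid.ny - 1 - (r + margin_um) / grid.pitch_y)
        if fdist is not None:
            if fdist[int(round(y)), int(round(x))] < r + margin_um / 2:
                continue
        sep = np.hypot((x - xs) * grid.pitch_x, (y - ys) * grid.pitch_y)
        if (sep < rs + r + sep_pad).any():
            continue
        xs = np.append(xs, x)
        ys = np.append(ys, y)
        rs = np.append(rs, r)
    if len(xs) < n:
        raise RuntimeError(f"could only place {len(xs)}/{n} disjoint deficit disks")
    return [(float(x), float(y), float(2 * r)) for x, y, r in zip(xs, ys, rs)]


def make_cc_phantom(
    grid: ScanGrid,
    seed: int = 0,
    fd_disks: Sequence[tuple[float, float, float]] = (),
    background_level: float = 180.0,
    deficit_level: float = 40.0,
    speckle_sd: float = 0.0,
    shading: Optional[np.ndarray] = None,
    structure_level: float = 200.0,
) -> CcPhantom:
    """CC en face flow/structure pair with inserted deficits of known geometry.

    ``fd_disks`` are ``(x_px, y_px, diameter_um)``; the truth mask is their
    rasterized union (pixel-center membership).  An optional multiplicative
    ``shading`` field models signal loss from overlying anatomy: both the flow
    and the structure image are attenuated by it, which is the situation the
    structural compensation step is meant to undo.
    """
    rng = np.random.default_rng(seed)
    truth = np.zeros((grid.ny, grid.nx), dtype=bool)
    flow = np.full((grid.ny, grid.nx), float(background_level))
    for (x, y, d) in fd_disks:
        r = d / 2.0
        if (x * grid.pitch_x < r or y * grid.pitch_y < r
                or (grid.nx - 1 - x) * grid.pitch_x < r
                or (grid.ny - 1 - y) * grid.pitch_y < r):
            raise ValueError("deficit disk extends beyond the grid")
        # rasterize within the disk's bounding box only
        x0 = max(0, int(np.floor(x - r / grid.pitch_x)) - 1)
        x1 = min(grid.nx, int(np.ceil(x + r / grid.pitch_x)) + 2)
        y0 = max(0, int(np.floor(y - r / grid.pitch_y)) - 1)
        y1 = min(grid.ny, int(np.ceil(y + r / grid.pitch_y)) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        m = ((xx - x) * grid.pitch_x) ** 2 + ((yy - y) * grid.pitch_y) ** 2 <= r**2
        if not m.any():
            raise ValueError(f"deficit disk at ({x:.1f},{y:.1f}) rasterizes to nothing")
        truth[y0:y1, x0:x1] |= m
        flow[y0:y1, x0:x1][m] = deficit_level

    structure = np.full((grid.ny, grid.nx), float(structure_level))
    if shading is not None:
        shading = np.asarray(shading, dtype=np.float64)
        flow = flow * shading
        structure = structure * shading
    flow = _speckle(rng, flow, speckle_sd)
    return CcPhantom(
        cc_flow=EnFaceImage(flow, grid),
        cc_structure=EnFaceImage(structure, grid),
        truth_fd=BinaryMask(truth, grid, "phantom:truth_fd"),
    )


def cc_phantom_volume(
    cc_flow: EnFaceImage, bm_z_um: float = 300.0, margin_planes: int = 2
) -> tuple[FlowVolume, Surface]:
    """Embed a CC en face image in a z-constant flow volume plus a flat BM.

    Any slab projection through the band reproduces the en face image, which
    makes this the fixture for slab-extraction tests.
    """
    grid = cc_flow.grid
    nz = int(np.ceil((bm_z_um + 4 + 16) / grid.pitch_z)) + margin_planes
    voxels = np.broadcast_to(cc_flow.pixels, (nz, grid.ny, grid.nx)).copy()
    bm = Surface("bm", np.full((grid.ny, grid.nx), bm_z_um), grid)
    return FlowVolume(voxels=voxels, grid=grid, signal_strength=10), bm


# ---------------------------------------------------------------------------
# PED phantom (RPE elevation above BM)
# ---------------------------------------------------------------------------


@dataclass
class PedPhantom:
    rpe: Surface
    bm: Surface
    truth_volumes_mm3: list[float]
    truth_total_mm3: float


def make_ped_phantom(
    grid: ScanGrid,
    bumps: Sequence[tuple[float, float, float, float]] = (),
    bm_z_um: float = 300.0,
) -> PedPhantom:
    """Flat BM with Gaussian RPE elevations of closed-form volume.

    ``bumps`` are ``(x_px, y_px, height_um, sigma_um)``.  The RPE is displaced
    anteriorly (towards smaller z), so elevation encodes a PED.  The analytic
    volume of each bump is ``2 π σ² h`` (µm³), converted to mm³.
    """
    bm = np.full((grid.ny, grid.nx), float(bm_z_um))
    rpe = bm.copy()
    y, x = np.mgrid[0 : grid.ny, 0 : grid.nx]
    truths = []
    for (cx, cy, h, sigma) in bumps:
        if sigma < min(grid.pitch_x, grid.pitch_y):
            raise ValueError("bump sigma below one pixel pitch")
        if not (0 <= cx <= grid.nx - 1 and 0 <= cy <= grid.ny - 1):
            raise ValueError("bump center outside the grid")
        r2 = ((x - cx) * grid.pitch_x) ** 2 + ((y - cy) * grid.pitch_y) ** 2
        rpe -= h * np.exp(-r2 / (2.0 * sigma**2))
        truths.append(2.0 * np.pi * sigma**2 * h * 1e-9)  # µm³ → mm³
    return PedPhantom(
        rpe=Surface("rpe", rpe, grid),
        bm=Surface("bm", bm, grid),
        truth_volumes_mm3=truths,
        truth_total_mm3=float(sum(truths)),
    )


# ---------------------------------------------------------------------------
# Choroid phantom
# ---------------------------------------------------------------------------


@dataclass
class ChoroidPhantom:
    volume: OctVolume
    bm: Surface
    csi: Surface
    truth_mct_um: float
    truth_cvi: float


def make_choroid_phantom(
    grid: ScanGrid,
    seed: int = 0,
    thickness_um: float | np.ndarray = 200.0,
    bm_z_um: float = 80.0,
    vessel_fraction: Optional[float] = None,
    n_cylinders: int = 0,
    cylinder_radius_um: tuple[float, float] = (30.0, 80.0),
    stroma_level: float = 200.0,
    vessel_level: float = 50.0,
    retina_level: float = 120.0,
    sclera_level: float = 80.0,
    circle_diameter_mm: float = 5.0,
) -> ChoroidPhantom:
    """Choroidal band of known thickness and vessel fraction.

    Vessels are dark (low intensity) against a brighter stroma, matching their
    appearance on structural OCT.  Two vessel models are available:

    * ``vessel_fraction``: the anterior ``f`` fraction of each A-scan's slab is
      vessel — gives an exactly constructed fraction;
    * ``n_cylinders`` > 0: x-axis-aligned dark cylinders at random (y, z).

    Ground-truth MCT and CVI inside the fovea-centered circle are computed
    here by brute-force voxel counting (pixel/voxel-center membership),
    independently of the measurement module.
    """
    rng = np.random.default_rng(seed)
    thick = np.broadcast_to(np.asarray(thickness_um, dtype=np.float64),
                            (grid.ny, grid.nx)).copy()
    if (thick <= 0).any():
        raise ValueError("thickness field must be positive")
    csi_z = bm_z_um + thick
    nz = int(np.ceil((csi_z.max() + 40.0) / grid.pitch_z))

    zc = (np.arange(nz) + 0.5) * grid.pitch_z  # voxel-center depths
    slab = (zc[:, None, None] >= bm_z_um) & (zc[:, None, None] < csi_z[None])

    vessel = np.zeros((nz, grid.ny, grid.nx), dtype=bool)
    if vessel_fraction is not None:
        if vessel_fraction > 0.95:
            raise ValueError("vessel fraction above 0.95 is not supported")
        # anterior round(f·n) slab voxels of each A-scan are vessel, which
        # makes the constructed fraction exact whenever f·n is an integer
        order = np.cumsum(slab, axis=0)
        n_slab_col = slab.sum(axis=0)
        m = np.round(vessel_fraction * n_slab_col).astype(int)
        vessel = slab & (order <= m[None])
    if n_cylinders:
        for _ in range(n_cylinders):
            r = rng.uniform(*cylinder_radius_um)
            cy = rng.uniform(0, grid.ny - 1)
            czmin = bm_z_um + r
            czmax = csi_z.min() - r
            if czmax <= czmin:
                raise ValueError("cylinder radius too large for the band")
            cz = rng.uniform(czmin, czmax)
            yy = (np.arange(grid.ny) - cy) * grid.pitch_y
            d2 = (zc[:, None] - cz) ** 2 + yy[None, :] ** 2
            vessel |= (d2 <= r * r)[:, :, None] & slab

    voxels = np.full((nz, grid.ny, grid.nx), float(retina_level))
    below = zc[:, None, None] >= csi_z[None]
    voxels[below] = sclera_level
    voxels[slab] = stroma_level
    voxels[vessel] = vessel_level

    # brute-force truth inside the fovea-centered circle
    y, x = np.mgrid[0 : grid.ny, 0 : grid.nx]
    fx, fy = grid.fovea_xy
    r_um = circle_diameter_mm * 1000.0 / 2.0
    circle = ((x - fx) * grid.pitch_x) ** 2 + ((y - fy) * grid.pitch_y) ** 2 <= r_um**2
    if not circle[0].any() and not circle[-1].any():
        pass
    slab_in = slab & circle[None]
    n_slab = int(slab_in.sum())
    n_ves = int((vessel & circle[None]).sum())
    truth_cvi = n_ves / n_slab if n_slab else 0.0
    truth_mct = float(thick[circle].mean())

    return ChoroidPhantom(
        volume=OctVolume(voxels=voxels, grid=grid, signal_strength=10),
        bm=Surface("bm", np.full((grid.ny, grid.nx), bm_z_um), grid),
        csi=Surface("csi", csi_z, grid),
        truth_mct_um=truth_mct,
        truth_cvi=truth_cvi,
    )


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: Per-metric (visit-2, monthly-rate) group moments emulating the studied
#: cohort of 12 non-exudating vs 9 exudating eyes.  Layout:
#: metric -> {"v2": {"no": (mean, sd), "yes": (mean, sd)}, "rate": {...}}
DEFAULT_COHORT_MOMENTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "mnv_area_mm2": {
        "v2": {"no": (3.59, 2.89), "yes": (2.09, 2.13)},
        "rate": {"no": (0.023, 0.102), "yes": (0.038, 0.110)},
    },
    "sqrt_mnv_area_mm": {
        "v2": {"no": (1.74, 0.79), "yes": (1.28, 0.71)},
        "rate": {"no": (0.01, 0.03), "yes": (0.01, 0.04)},
    },
    "fd_pct_r1": {
        "v2": {"no": (26.4, 14.1), "yes": (27.2, 13.6)},
        "rate": {"no": (-0.6, 2.6), "yes": (2.0, 3.5)},
    },
    "vad": {
        "v2": {"no": (0.515, 0.054), "yes": (0.390, 0.104)},
        "rate": {"no": (0.005, 0.014), "yes": (-0.006, 0.022)},
    },
    "vsd": {
        "v2": {"no": (0.189, 0.024), "yes": (0.149, 0.030)},
        "rate": {"no": (0.002, 0.003), "yes": (-0.003, 0.005)},
    },
    "cubert_mnv_ped_volume_mm": {
        "v2": {"no": (0.403, 0.143), "yes": (0.268, 0.133)},
        "rate": {"no": (0.008, 0.010), "yes": (0.010, 0.019)},
    },
    "mct_um": {
        "v2": {"no": (192.8, 83.9), "yes": (244.7, 95.3)},
        "rate": {"no": (0.72, 3.19), "yes": (-1.64, 10.5)},
    },
    "cvi": {
        "v2": {"no": (0.614, 0.037), "yes": (0.627, 0.042)},
        "rate": {"no": (-0.002, 0.006), "yes": (-0.001, 0.007)},
    },
}

#: Mean ± SD inter-visit interval, in months, per group (no / yes exudation).
DEFAULT_VISIT_INTERVAL_MONTHS = {"no": (3.6, 2.1), "yes": (2.7, 1.7)}


def _draw(
    rng: np.random.Generator, mean: float, sd: float, n: int, distribution: str
) -> np.ndarray:
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd == 0:
        return np.full(n, mean)
    if distribution == "normal":
        return rng.normal(mean, sd, n)
    if distribution == "lognormal-shifted":
        # fixed log-scale shape, rescaled/shifted to the requested moments
        shape = 0.8
        raw = rng.lognormal(0.0, shape, n)
        lmean = np.exp(shape**2 / 2)
        lsd = np.sqrt((np.exp(shape**2) - 1) * np.exp(shape**2))
        return mean + (raw - lmean) * (sd / lsd)
    raise ValueError(f"unknown distribution {distribution!r}")


def make_cohort(
    seed: int = 0,
    n_no: int = 12,
    n_yes: int = 9,
    moments: Optional[dict] = None,
    distribution: str = "normal",
    interval_months: Optional[dict[str, tuple[float, float]]] = None,
) -> "pd.DataFrame":
    """Two-group visit-pair cohort with configured per-metric moments.

    For each eye, the visit-2 value and the monthly rate are drawn from the
    group's stated mean/SD; visit 1 is back-computed from the (positive,
    clipped) inter-visit interval.  Returns a tidy frame with one row per eye
    and ``<metric>_v1 / <metric>_v2`` columns plus ``days_between``.
    """
    import pandas as pd

    if min(n_no, n_yes) < 2:
        raise ValueError("need at least 2 eyes per group")
    moments = DEFAULT_COHORT_MOMENTS if moments is None else moments
    interval_months = interval_months or DEFAULT_VISIT_INTERVAL_MONTHS
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("no", n_no), ("yes", n_yes)):
        m_int, sd_int = interval_months[group]
        months = np.clip(rng.normal(m_int, sd_int, n), 0.5, None)
        days = months * DAYS_PER_MONTH
        for i in range(n):
            rows.append({
                "eye_id": f"{group}_{i:03d}",
                "group": "exudation" if group == "yes" else "no_exudation",
                "days_between": float(days[i]),
            })
        for metric, moms in moments.items():
            v2 = _draw(rng, *moms["v2"][group], n, distribution)
            rate = _draw(rng, *moms["rate"][group], n, distribution)
            v1 = v2 - rate * months
            for i in range(n):
                rows[-n + i][f"{metric}_v1"] = float(v1[i])
                rows[-n + i][f"{metric}_v2"] = float(v2[i])
    return pd.DataFrame(rows)
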