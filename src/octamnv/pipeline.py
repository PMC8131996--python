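"""Orchestration: per-eye quantification, visit-pair selection, and the
cohort report (group summaries and confidence-interval tables).

Every named constant of the analysis lives in :class:`StudyConfig` — slab
offsets, detection thresholds, the 24-µm deficit filter, the 300/600-µm
region radii, the 5-mm circle, the 30.44-day month, the 183-day buffer for
selecting stable visit pairs, and the bootstrap settings — and the config
(with its hash) is serialized next to every output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ccfd, choroid, enface, mnv, ped, stats, vascularity
from .core import DAYS_PER_MONTH, BinaryMask, EyeVisitMetrics

__all__ = [
    "StudyConfig",
    "run_eye_visit",
    "select_visit_pairs",
    "build_report",
]

PACKAGE_VERSION = "0.1.0"


@dataclass
class StudyConfig:
    # quality control
    min_signal_strength: int = 7
    # lesion detection / eligibility
    mnv_k_sigma: float = 2.0
    mnv_closing_radius_px: int = 2
    mnv_min_component_mm2: float = 0.01
    min_gld_um: float = 250.0
    min_lesion_area_mm2: float = 0.2
    focus_merge_um: float = 600.0
    # CC regions and deficits
    r1_um: float = 300.0
    r2_um: float = 600.0
    fd_strategy: str = "mean_minus_ksd"
    fd_k_sigma: float = 1.0
    fd_fixed_threshold: Optional[float] = None
    fd_min_equiv_diameter_um: float = 24.0
    cc_slab_offset_um: float = 4.0
    cc_slab_thickness_um: float = 16.0
    # vascularity
    hessian_scales_px: tuple[int, ...] = (1, 2)
    adaptive_window_px: int = 33
    vessel_combine: str = "union"
    # PED
    ped_min_height_um: float = 0.0
    # choroid
    circle_diameter_mm: float = 5.0
    choroid_compensate: bool = True
    compensation_exponent: float = 1.0
    # statistics
    bootstrap_B: int = 2000
    shapiro_alpha: float = 0.05
    seed: int = 7
    # temporal conventions
    days_per_month: float = DAYS_PER_MONTH
    followup_buffer_days: float = 183.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "hessian_scales_px" in data:
            data["hessian_scales_px"] = tuple(data["hessian_scales_px"])
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_eye_visit(
    inputs: dict,
    config: Optional[StudyConfig] = None,
) -> tuple[EyeVisitMetrics, dict]:
    """Quantify one eye-visit from whatever input families are present.

    Recognized ``inputs`` keys (all optional except a lesion source when
    lesion metrics are wanted): ``orcc_enface`` (or ``orcc_volume`` +
    ``surfaces``), ``retinal_vessel_mask``, ``mnv_mask`` (bypasses
    segmentation), ``cc_flow``/``cc_structure`` (or ``cc_volume`` +
    ``surfaces``), ``rpe``/``bm`` surfaces, ``choroid_volume`` /
    ``choroid_bm`` / ``choroid_csi``, plus ``eye_id`` and ``visit_date``.
    Missing families yield missing metrics, not failures; per-family status
    is returned in the flags dict.
    """
    config = config or StudyConfig()
    flags: dict = {"config_hash": config.hash(), "version": PACKAGE_VERSION}
    vals: dict = {}

    # --- lesion family -----------------------------------------------------
    orcc = inputs.get("orcc_enface")
    if orcc is None and "orcc_volume" in inputs:
        orcc = enface.extract_enface(
            inputs["orcc_volume"], enface.SLAB_PRESETS["orcc"], inputs["surfaces"]
        )
    mnv_mask: Optional[BinaryMask] = inputs.get("mnv_mask")
    if orcc is not None and inputs.get("retinal_vessel_mask") is not None:
        orcc = enface.remove_projection_artifacts(orcc, inputs["retinal_vessel_mask"])
    if mnv_mask is None and orcc is not None:
        mnv_mask = mnv.segment_mnv(
            orcc,
            k_sigma=config.mnv_k_sigma,
            closing_radius_px=config.mnv_closing_radius_px,
            min_component_mm2=config.mnv_min_component_mm2,
        )
        if not mnv_mask.pixels.any():
            flags["mnv_segmentation"] = "empty"

    if mnv_mask is not None:
        grid = mnv_mask.grid
        area, sqrt_area, gld = mnv.lesion_metrics(mnv_mask, grid)
        vals.update(mnv_area_mm2=area, sqrt_mnv_area_mm=sqrt_area)
        flags["gld_um"] = gld
        flags["eligibility"] = mnv.eligibility(
            mnv_mask, grid, config.min_gld_um, config.min_lesion_area_mm2
        )
        flags["n_foci"] = mnv.count_foci(mnv_mask, grid, config.focus_merge_um)

    # --- CC flow-deficit family -------------------------------------------
    cc_flow = inputs.get("cc_flow")
    if cc_flow is None and "cc_volume" in inputs:
        slab = enface.SlabDefinition(
            top=("bm", config.cc_slab_offset_um),
            thickness_um=config.cc_slab_thickness_um,
        )
        cc_flow = enface.extract_enface(inputs["cc_volume"], slab, inputs["surfaces"])
    if cc_flow is not None and mnv_mask is not None:
        if inputs.get("retinal_vessel_mask") is not None:
            cc_flow = enface.remove_projection_artifacts(
                cc_flow, inputs["retinal_vessel_mask"]
            )
        if inputs.get("cc_structure") is not None:
            cc_flow = enface.compensate_cc(cc_flow, inputs["cc_structure"])
        regions = ccfd.build_regions(mnv_mask, mnv_mask.grid, config.r1_um, config.r2_um)
        fd_mask = ccfd.segment_fd(
            cc_flow,
            strategy=config.fd_strategy,
            k_sigma=config.fd_k_sigma,
            fixed_threshold=config.fd_fixed_threshold,
            analysis_mask=regions.excl_mnv_mask,
        )
        result = ccfd.region_fd_metrics(fd_mask, regions)
        for key, out_pct, out_area in (
            ("r1", "fd_pct_r1", "mean_fd_area_um2_r1"),
            ("r2", "fd_pct_r2", "mean_fd_area_um2_r2"),
            ("r3", "fd_pct_r3", "mean_fd_area_um2_r3"),
            ("excl_mnv", "fd_pct_excl_mnv", "mean_fd_area_um2_excl_mnv"),
        ):
            vals[out_pct] = result.regions[key].fd_pct
            vals[out_area] = result.regions[key].mean_fd_area_um2

    # --- vascularity family -------------------------------------------------
    if orcc is not None and mnv_mask is not None and mnv_mask.pixels.any():
        maps = vascularity.quantify_vascularity(
            orcc,
            mnv_mask,
            hessian_scales_px=config.hessian_scales_px,
            adaptive_window_px=config.adaptive_window_px,
            combine=config.vessel_combine,
        )
        vals.update(vad=maps.vad, vsd=maps.vsd)

    # --- PED family ----------------------------------------------------------
    if "rpe" in inputs and "bm" in inputs:
        heights = ped.ped_height_map(inputs["rpe"], inputs["bm"])
        area, volume = ped.ped_metrics(heights, min_height_um=config.ped_min_height_um)
        vals.update(ped_area_mm2=area, ped_volume_mm3=volume)
        if mnv_mask is not None:
            marea, mvol = ped.mnv_ped_metrics(
                heights, mnv_mask, min_height_um=config.ped_min_height_um
            )
            s_area, s_vol = ped.stabilize(marea, mvol)
            vals.update(
                mnv_ped_area_mm2=marea,
                mnv_ped_volume_mm3=mvol,
                sqrt_mnv_ped_area_mm=s_area,
                cubert_mnv_ped_volume_mm=s_vol,
            )

    # --- choroid family -------------------------------------------------------
    if all(k in inputs for k in ("choroid_volume", "choroid_bm", "choroid_csi")):
        vol = inputs["choroid_volume"]
        if config.choroid_compensate:
            vol = choroid.attenuation_compensate(vol, config.compensation_exponent)
        vessels = choroid.segment_choroid_vessels(
            vol, inputs["choroid_bm"], inputs["choroid_csi"]
        )
        cm = choroid.cvi_metrics(
            vessels, vol, inputs["choroid_bm"], inputs["choroid_csi"],
            config.circle_diameter_mm,
        )
        vals.update(mct_um=cm.mct_um, cvi=cm.cvi)

    metrics = EyeVisitMetrics(
        eye_id=str(inputs.get("eye_id", "")),
        visit_date=str(inputs.get("visit_date", "")),
        **vals,
    )
    return metrics, flags


def select_visit_pairs(
    visits: pd.DataFrame,
    exudation_day: Optional[dict] = None,
    buffer_days: float = 183.0,
) -> tuple[dict, dict]:
    """Select the analysis visit pair for each eye.

    ``visits`` has columns ``eye_id`` and ``day`` (numeric study day).
    Eyes present in ``exudation_day`` (value = day exudation was documented,
    operationally the day anti-VEGF treatment began) contribute their last
    two visits strictly before that day.  For eyes without exudation, the
    latest consecutive visit pair whose second visit precedes the eye's last
    follow-up by at least ``buffer_days`` (6 months) is used, ensuring a
    buffer against near-future exudation.

    Returns ``(pairs, exclusions)``: ``pairs[eye_id] = (day1, day2)`` and a
    reason string per excluded eye.
    """
    exudation_day = exudation_day or {}
    pairs: dict = {}
    exclusions: dict = {}
    for eye_id, sub in visits.groupby("eye_id"):
        days = np.sort(sub["day"].to_numpy(dtype=float))
        if eye_id in exudation_day and exudation_day[eye_id] is not None:
            prior = days[days < exudation_day[eye_id]]
            if len(prior) < 2:
                exclusions[eye_id] = "fewer than two visits before exudation"
                continue
            pairs[eye_id] = (float(prior[-2]), float(prior[-1]))
        else:
            last = days[-1]
            ok = [
                (days[i], days[i + 1])
                for i in range(len(days) - 1)
                if last - days[i + 1] >= buffer_days
            ]
            if not ok:
                exclusions[eye_id] = (
                    f"no consecutive visit pair at least {buffer_days:g} days "
                    "before the last follow-up"
                )
                continue
            pairs[eye_id] = tuple(map(float, ok[-1]))
    return pairs, exclusions


def _summary_row(x: np.ndarray) -> dict:
    s = stats.summarize(x)
    return {"n": s.n, "mean": s.mean, "sd": s.sd, "median": s.median, "iqr": s.iqr}


def build_report(
    cohort: pd.DataFrame,
    metrics: Optional[list[str]] = None,
    config: Optional[StudyConfig] = None,
) -> dict:
    """Group summaries and between-group CI tables from a visit-pair cohort.

    ``cohort`` is tidy with one row per eye: ``group`` (``no_exudation`` /
    ``exudation``), ``days_between``, and ``<metric>_v1`` / ``<metric>_v2``
    columns.  For each metric, visit-1/visit-2/difference/rate rows are
    summarized per group (mean, SD, median, IQR), and the visit-2 and rate
    between-group differences (no-exudation minus exudation) get a 95% CI:
    pooled-t, or a seeded percentile bootstrap when Shapiro–Wilk rejects
    normality in either group.

    Returns ``{"summaries": DataFrame, "cis": DataFrame, "provenance": dict}``.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    if metrics is None:
        metrics = sorted(
            {c[:-3] for c in cohort.columns if c.endswith("_v2")
             if f"{c[:-3]}_v1" in cohort.columns}
        )
    groups = {
        "no_exudation": cohort[cohort["group"] == "no_exudation"],
        "exudation": cohort[cohort["group"] == "exudation"],
    }
    single_group = any(len(g) == 0 for g in groups.values())

    summary_rows = []
    ci_rows = []
    for metric in metrics:
        per_group: dict[str, dict[str, np.ndarray]] = {}
        for gname, g in groups.items():
            if len(g) == 0:
                continue
            v1 = g[f"{metric}_v1"].to_numpy(float)
            v2 = g[f"{metric}_v2"].to_numpy(float)
            days = g["days_between"].to_numpy(float)
            diff = v2 - v1
            rate = diff / (days / config.days_per_month)
            per_group[gname] = {"visit1": v1, "visit2": v2,
                                "difference": diff, "rate_per_month": rate}
            for row_type, x in per_group[gname].items():
                summary_rows.append(
                    {"metric": metric, "type": row_type, "group": gname,
                     **_summary_row(x)}
                )
        if single_group:
            continue
        for row_type in ("visit2", "rate_per_month"):
            x1 = per_group["no_exudation"][row_type]
            x2 = per_group["exudation"][row_type]
            if min(len(x1), len(x2)) < 3:
                continue
            gate = stats.normality_gate(x1, x2, alpha=config.shapiro_alpha)
            if gate["method"] == "pooled_t":
                ci = stats.pooled_t_ci_from_samples(x1, x2)
            else:
                ci = stats.bootstrap_ci(x1, x2, B=config.bootstrap_B, rng=rng)
            ci_rows.append(
                {"metric": metric, "type": row_type, "diff": ci.diff,
                 "ci_lo": ci.lo, "ci_hi": ci.hi, "method": ci.method,
                 "n_no_exudation": ci.n1, "n_exudation": ci.n2,
                 "shapiro_min_p": min(gate["shapiro_pvalues"])}
            )

    return {
        "summaries": pd.DataFrame(summary_rows),
        "cis": pd.DataFrame(ci_rows),
        "provenance": {
            "config_hash": config.hash(),
            "version": PACKAGE_VERSION,
            "seed": config.seed,
            "n_eyes": int(len(cohort)),
        },
    }
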