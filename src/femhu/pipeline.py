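"""End-to-end case runs and agreement studies.

``run_case`` chains reading, extraction, VOI cropping and report computation
for one volume; ``run_agreement_study`` compares two aligned lists of reports
— interobserver / intraobserver (ICC + Bland–Altman) or pre/post contrast
(paired t, Welch t, Bland–Altman) — over the fixed variable quartet
total volume, mean HU, HUHA_fat, HUHA_dense.  Every run records provenance
(config hash, package version, stage voxel counts); logs go to stderr and are
never mixed into machine outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .huha import VOIReport, compute_report
from .image_io import CTVolume, read_ct_volume, write_mask, write_voi_report
from .segmentation import DEFAULT_THRESHOLD_HU, extract_femur
from .stats import bland_altman, icc_absolute_single, paired_t, welch_t, RaterTable

logger = logging.getLogger(__name__)

#: fixed variable order of every study table
STUDY_VARIABLES = ("total_volume", "mean_hu", "huha_fat", "huha_dense")

STUDY_MODES = ("interobserver", "intraobserver", "pre_post")

__all__ = ["STUDY_VARIABLES", "STUDY_MODES", "CaseConfig", "AgreementStudy",
           "run_case", "run_agreement_study", "reports_to_frame"]


@dataclass
class CaseConfig:
    """Validated single-case configuration."""

    volume: str | None
    seed_voxel: tuple[int, int, int]
    threshold_hu: float
    cut_z_index: int | None
    cut_z_mm: float | None
    laterality: str = "unspecified"
    fat_strict: bool = False
    out_dir: str | None = None

    @classmethod
    def from_mapping(cls, cfg: dict, *, require_volume: bool = True) -> "CaseConfig":
        missing = [k for k in ("seed_voxel",) if k not in cfg]
        if require_volume and "volume" not in cfg:
            missing.append("volume")
        if "cut_z_index" not in cfg and "cut_z_mm" not in cfg:
            missing.append("cut_z_index|cut_z_mm")
        if missing:
            raise ValueError(f"config missing required key(s): {', '.join(missing)}")
        seed = tuple(int(c) for c in cfg["seed_voxel"])
        if len(seed) != 3:
            raise ValueError(f"seed_voxel must be a (z, y, x) triple, got {seed}")
        return cls(
            volume=cfg.get("volume"),
            seed_voxel=seed,
            threshold_hu=float(cfg.get("threshold_hu", DEFAULT_THRESHOLD_HU)),
            cut_z_index=(int(cfg["cut_z_index"]) if "cut_z_index" in cfg else None),
            cut_z_mm=(float(cfg["cut_z_mm"]) if "cut_z_mm" in cfg else None),
            laterality=cfg.get("laterality", "unspecified"),
            fat_strict=bool(cfg.get("fat_strict", False)),
            out_dir=cfg.get("out_dir"),
        )


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_case(config: dict | str | Path, volume: CTVolume | None = None) -> VOIReport:
    """Run one case: read → extract_femur → crop_voi → compute_report.

    ``config`` is a mapping or a YAML file path; an in-memory ``volume`` may be
    passed instead of a file path.  The report's provenance block records the
    config hash, landmark, threshold and stage voxel counts.
    """
    from .voi import crop_voi, landmark_from_mm

    if isinstance(config, (str, Path)):
        cfg_map = yaml.safe_load(Path(config).read_text())
    else:
        cfg_map = dict(config)
    case = CaseConfig.from_mapping(cfg_map, require_volume=volume is None)

    if volume is None:
        logger.info("run_case: reading %s", case.volume)
        volume = read_ct_volume(case.volume)
    mask = extract_femur(volume, case.seed_voxel, case.threshold_hu)
    mask.laterality = case.laterality
    cut = (case.cut_z_index if case.cut_z_index is not None
           else landmark_from_mm(volume, case.cut_z_mm))
    voi_mask = crop_voi(mask, cut)
    logger.info("run_case: envelope %d voxels, VOI %d voxels above z=%d",
                mask.voxel_count(), voi_mask.voxel_count(), cut)

    report = compute_report(
        volume, voi_mask, fat_strict=case.fat_strict,
        provenance={
            "config_hash": _config_hash(cfg_map),
            "femhu_version": __version__,
            "threshold_hu": case.threshold_hu,
            "cut_z_index": cut,
            "envelope_voxels": mask.voxel_count(),
            "laterality": case.laterality,
        })
    if case.out_dir:
        out = Path(case.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mask(voi_mask, out / "voi_mask.nii.gz")
        write_voi_report(report, out / "report")
        logger.info("run_case: wrote report and mask to %s", out)
    return report


# ---------------------------------------------------------------------------
# agreement studies
# ---------------------------------------------------------------------------

def reports_to_frame(reports: Sequence[VOIReport]) -> pd.DataFrame:
    """Stack reports into a subjects × variables table (fixed variable order)."""
    return pd.DataFrame([{v: getattr(r, v) for v in STUDY_VARIABLES}
                         for r in reports])


@dataclass
class AgreementStudy:
    mode: str
    table: pd.DataFrame  # one row per study variable, fixed order
    details: dict  # variable -> {"icc": ..., "bland_altman": ..., ...}


def run_agreement_study(reports_a, reports_b, mode: str) -> AgreementStudy:
    """Compare two aligned measurement lists per study variable.

    Agreement modes (interobserver/intraobserver) compute ICC(A,1) and
    Bland–Altman per variable; pre_post mode computes paired-t, Welch-t and
    Bland–Altman.  Inputs may be lists of VOIReports or DataFrames holding the
    four study variables.  Differences are oriented a − b (first − second).
    """
    if mode not in STUDY_MODES:
        raise ValueError(f"mode must be one of {STUDY_MODES}, got {mode!r}")
    frame_a = reports_a if isinstance(reports_a, pd.DataFrame) else reports_to_frame(reports_a)
    frame_b = reports_b if isinstance(reports_b, pd.DataFrame) else reports_to_frame(reports_b)
    if len(frame_a) != len(frame_b):
        raise ValueError(f"aligned lists required: {len(frame_a)} vs {len(frame_b)} cases")
    missing = [v for v in STUDY_VARIABLES
               if v not in frame_a.columns or v not in frame_b.columns]
    if missing:
        raise ValueError(f"missing study variable column(s): {missing}")

    rows, details = [], {}
    for var in STUDY_VARIABLES:
        a = frame_a[var].to_numpy(dtype=float)
        b = frame_b[var].to_numpy(dtype=float)
        ba = bland_altman(a, b)
        row = {
            "variable": var,
            "a_mean": a.mean(), "a_sd": a.std(ddof=1),
            "b_mean": b.mean(), "b_sd": b.std(ddof=1),
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        }
        detail = {"bland_altman": ba}
        if mode == "pre_post":
            pt = paired_t(a, b)
            wt = welch_t(a, b)
            row.update(t=pt.t, p_paired=pt.p, p_welch=wt.p)
            detail.update(paired=pt, welch=wt)
        else:
            icc = icc_absolute_single(RaterTable(np.column_stack([a, b])))
            row.update(icc=icc.icc, icc_ci_low=icc.ci_low, icc_ci_high=icc.ci_high,
                       icc_category=icc.category)
            detail.update(icc=icc)
        rows.append(row)
        details[var] = detail
    return AgreementStudy(mode=mode, table=pd.DataFrame(rows), details=details)
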