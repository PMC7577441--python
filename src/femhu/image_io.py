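"""Reading and writing CT volumes, bone masks, measurement reports and rater tables.

Volumes are kept in a fixed ``(z, y, x)`` axis convention with ``z`` increasing
toward superior; NIfTI data (stored ``(x, y, z)``) is reoriented to the closest
canonical (RAS+) orientation on read and then transposed.  Hounsfield units are
clamped to the CT analysis range [−1024, 3071] and stored as integers, which is
what calibrated 12-bit CT exports contain and what makes the 1-HU histogram an
exact summary of the voxel data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

HU_MIN = -1024
HU_MAX = 3071

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "CTVolume",
    "BoneMask",
    "read_ct_volume",
    "write_ct_volume",
    "read_mask",
    "write_mask",
    "write_voi_report",
    "read_voi_report",
    "read_rater_table",
]


def clamp_hu(values: np.ndarray) -> np.ndarray:
    """Round to integer HU and clamp to the [−1024, 3071] analysis range."""
    return np.clip(np.rint(values), HU_MIN, HU_MAX).astype(np.int16)


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield units, indexed ``(z, y, x)``, z superior-increasing.

    Parameters
    ----------
    values : ndarray
        HU values; rounded to integers and clamped to [−1024, 3071] on
        construction.
    voxel_spacing : (dz, dy, dx) in mm
    origin : physical coordinate (mm) of voxel (0, 0, 0)
    source : free-text provenance descriptor (file path, phantom seed, ...)
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source: str = ""

    def __post_init__(self) -> None:
        self.values = clamp_hu(np.asarray(self.values))
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        self.origin = tuple(float(s) for s in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_spacing
        return dz * dy * dx


@dataclass
class BoneMask:
    """Binary voxel mask on the same ``(z, y, x)`` grid as its parent volume."""

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    laterality: str = "unspecified"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.mask.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if self.laterality not in ("left", "right", "unspecified"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _affine_for(spacing_zyx: Sequence[float], origin_zyx: Sequence[float]) -> np.ndarray:
    dz, dy, dx = spacing_zyx
    oz, oy, ox = origin_zyx
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_ct_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (int16 HU), preserving spacing and origin."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values.T, dtype=np.int16),
                          _affine_for(volume.voxel_spacing, volume.origin))
    img.header.set_zooms(volume.voxel_spacing[::-1])
    nib.save(img, path)
    return path


def write_mask(mask: BoneMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.mask.T.astype(np.uint8),
                          _affine_for(mask.voxel_spacing, (0, 0, 0)))
    img.header.set_zooms(mask.voxel_spacing[::-1])
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> BoneMask:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return BoneMask(data.T > 0, voxel_spacing=tuple(float(z) for z in zooms[::-1]))


def read_ct_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a directory of single-series DICOM slices.

    DICOM stored values are converted to HU with the per-slice rescale
    slope/intercept; both paths clamp to [−1024, 3071].
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return CTVolume(
        values=data.T,
        voxel_spacing=tuple(float(z) for z in zooms[::-1]),
        origin=tuple(float(o) for o in origin[::-1]),
        source=str(path),
    )


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise ValueError(f"{directory}: no DICOM slices found")
    slices = [pydicom.dcmread(str(p)) for p in files]

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(series_uids) != 1:
        raise ValueError(f"{directory}: mixed series ({len(series_uids)} SeriesInstanceUIDs)")

    def z_of(ds) -> float:
        return float(ds.ImagePositionPatient[2])

    slices.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in slices])
    if len(zs) > 1:
        steps = np.diff(zs)
        if np.any(steps <= 0):
            raise ValueError(f"{directory}: non-monotone slice positions after sorting "
                             f"(duplicate z at {zs[np.where(steps <= 0)[0][0]]:g} mm)")
        if not np.allclose(steps, steps[0], atol=1e-3):
            gaps = zs[:-1][~np.isclose(steps, steps[0], atol=1e-3)]
            raise ValueError(f"{directory}: missing slices; gaps after z = "
                             + ", ".join(f"{g:g}" for g in gaps))
        dz = float(steps[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    stack = np.stack(planes, axis=0)  # (z, rows=y, cols=x)

    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    ipp = slices[0].ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return CTVolume(values=stack, voxel_spacing=(dz, dy, dx), origin=origin,
                    source=str(directory))


# ---------------------------------------------------------------------------
# VOI reports
# ---------------------------------------------------------------------------

_CSV_ROW_ORDER = ("total_volume", "mean_hu", "huha_fat", "huha_mid", "huha_dense")


def write_voi_report(report, path: str | Path) -> tuple[Path, Path]:
    """Serialize a VOIReport as JSON (full precision) and CSV (rounded to 0.01).

    ``path`` is used as a stem: ``<stem>.json`` and ``<stem>.csv`` are written.
    The JSON histogram is stored as (bin low edge, count) pairs for non-empty
    1-HU bins; re-reading the JSON reproduces every scalar exactly.
    """
    hist = np.asarray(report.histogram)
    if hist.sum() == 0:
        raise ValueError("refusing to write a report with an empty histogram")
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".json", ".csv") else path
    edges = np.arange(HU_MIN, HU_MAX + 1)
    nz = hist > 0
    payload = {
        "total_volume": float(report.total_volume),
        "mean_hu": float(report.mean_hu),
        "huha_fat": float(report.huha_fat),
        "huha_mid": float(report.huha_mid),
        "huha_dense": float(report.huha_dense),
        "voxel_count": int(report.voxel_count),
        "provenance": dict(report.provenance),
        "histogram": [[int(e), int(c)] for e, c in zip(edges[nz], hist[nz])],
    }
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    csv_path = stem.with_suffix(".csv")
    lines = ["metric,value"]
    lines += [f"{k},{getattr(report, k):.2f}" for k in _CSV_ROW_ORDER]
    csv_path.write_text("\n".join(lines) + "\n")
    return json_path, csv_path


def read_voi_report(path: str | Path):
    from .huha import VOIReport  # local import to avoid a cycle

    payload = json.loads(Path(path).read_text())
    hist = np.zeros(HU_MAX - HU_MIN + 1, dtype=np.int64)
    for edge, count in payload["histogram"]:
        hist[int(edge) - HU_MIN] = int(count)
    return VOIReport(
        total_volume=payload["total_volume"],
        mean_hu=payload["mean_hu"],
        huha_fat=payload["huha_fat"],
        huha_mid=payload["huha_mid"],
        huha_dense=payload["huha_dense"],
        histogram=hist,
        voxel_count=payload["voxel_count"],
        provenance=payload.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# rater tables
# ---------------------------------------------------------------------------

def read_rater_table(path: str | Path):
    """Read a subjects × raters CSV (header: subject_id, rater_1, ..., rater_k).

    Rows with any blank cell are dropped listwise (a warning reports the count);
    non-numeric cells are a hard parse error naming the offending row/column.
    """
    from .stats import RaterTable

    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need a subject_id column plus at least 2 rater columns")
    subject_col = df.columns[0]
    rater_cols = list(df.columns[1:])

    for col in rater_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row} (subject {df[subject_col].iloc[row]!r})")
        df[col] = coerced

    complete = df[rater_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} subject(s) with missing cells",
                      stacklevel=2)
    df = df[complete]
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 complete subjects after filtering")
    return RaterTable(
        values=df[rater_cols].to_numpy(dtype=float),
        subject_ids=list(df[subject_col].astype(str)),
        rater_labels=[str(c) for c in rater_cols],
    )
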