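"""The VOI measurement quartet: total volume, mean HU and histogram fractions.

HUHA (HU histogram analysis) partitions the VOI voxels by Hounsfield value:
``huha_fat`` is the percentage at or below 0 HU (assumed fatty marrow),
``huha_dense`` the percentage at or above 126 HU (dense cortical/trabecular
bone), and ``huha_mid`` the complement, so the three always sum to 100.  The
0 HU boundary counts as fat by default ("zero or less"); ``fat_strict=True``
gives the strictly-negative variant.  The histogram uses 1-HU bins over the
full [−1024, 3071] analysis range, and because volumes store integer HU it is
a lossless summary: the histogram-derived mean equals the voxel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import HU_MAX, HU_MIN, BoneMask, CTVolume

FAT_THRESHOLD_HU = 0
DENSE_THRESHOLD_HU = 126

N_BINS = HU_MAX - HU_MIN + 1  # one bin per integer HU value

__all__ = ["FAT_THRESHOLD_HU", "DENSE_THRESHOLD_HU", "VOIReport",
           "compute_report", "shift_volume"]


@dataclass
class VOIReport:
    """Measurement report for one VOI.

    total_volume in cm³; huha_* as percentages of the VOI voxel count;
    ``histogram[i]`` counts voxels with HU equal to ``−1024 + i``.
    """

    total_volume: float
    mean_hu: float
    huha_fat: float
    huha_mid: float
    huha_dense: float
    histogram: np.ndarray
    voxel_count: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.int64)
        if self.histogram.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} 1-HU bins")
        if self.voxel_count <= 0:
            raise ValueError("report must cover at least one voxel")
        if int(self.histogram.sum()) != int(self.voxel_count):
            raise ValueError("histogram counts do not sum to the voxel count")
        if not -1024 <= self.mean_hu <= 3071:
            raise ValueError(f"mean HU {self.mean_hu} outside [−1024, 3071]")
        if abs(self.huha_fat + self.huha_mid + self.huha_dense - 100.0) > 1e-9:
            raise ValueError("HUHA fractions must partition 100%")

    def as_dict(self) -> dict:
        return {
            "total_volume": self.total_volume,
            "mean_hu": self.mean_hu,
            "huha_fat": self.huha_fat,
            "huha_mid": self.huha_mid,
            "huha_dense": self.huha_dense,
            "voxel_count": self.voxel_count,
        }


def compute_report(volume: CTVolume, voi_mask: BoneMask, *,
                   fat_strict: bool = False,
                   provenance: dict | None = None) -> VOIReport:
    """Compute the measurement quartet of a VOI mask over a volume."""
    if volume.shape != voi_mask.shape:
        raise ValueError(f"mask grid {voi_mask.shape} does not match volume grid "
                         f"{volume.shape}")
    values = volume.values[voi_mask.mask]
    n = values.size
    if n == 0:
        raise ValueError("VOI mask is empty")

    hist = np.bincount(values.astype(np.int64) - HU_MIN, minlength=N_BINS)
    fat = values < FAT_THRESHOLD_HU if fat_strict else values <= FAT_THRESHOLD_HU
    n_fat = int(fat.sum())
    n_dense = int((values >= DENSE_THRESHOLD_HU).sum())

    prov = {"fat_strict": fat_strict, "source": volume.source}
    if provenance:
        prov.update(provenance)
    return VOIReport(
        total_volume=n * volume.voxel_volume_mm3 / 1000.0,
        mean_hu=float(values.mean(dtype=np.float64)),
        huha_fat=100.0 * n_fat / n,
        huha_mid=100.0 * (n - n_fat - n_dense) / n,
        huha_dense=100.0 * n_dense / n,
        histogram=hist,
        voxel_count=n,
        provenance=prov,
    )


def shift_volume(volume: CTVolume, c_hu: float) -> CTVolume:
    """Add a constant HU offset to every voxel (then clamp)."""
    if not np.isfinite(c_hu):
        raise ValueError("shift must be finite")
    return CTVolume(values=volume.values.astype(np.float64) + c_hu,
                    voxel_spacing=volume.voxel_spacing, origin=volume.origin,
                    source=volume.source)
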