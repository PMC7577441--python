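"""Seeded region growing and cavity filling for proximal-femur extraction.

The growth criterion is a fixed lower HU threshold (default 126 HU, the
dense-bone boundary, which cleanly separates cortex from ~40 HU soft tissue);
growth uses 26-connectivity while cavity detection uses 6-connectivity — the
standard asymmetric foreground/background pair of digital topology.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi

from .image_io import BoneMask, CTVolume

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HU = 126.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

__all__ = ["DEFAULT_THRESHOLD_HU", "SeedError", "region_grow", "fill_envelope",
           "extract_femur"]


class SeedError(ValueError):
    """The seed voxel cannot start a region growth."""


def _check_seed(volume: CTVolume, seed_voxel) -> tuple[int, int, int]:
    seed = tuple(int(c) for c in seed_voxel)
    if len(seed) != 3:
        raise SeedError(f"seed must be a (z, y, x) triple, got {seed_voxel!r}")
    if not all(0 <= c < n for c, n in zip(seed, volume.shape)):
        raise SeedError(f"seed {seed} lies outside the {volume.shape} grid")
    return seed


def region_grow(volume: CTVolume, seed_voxel,
                threshold_hu: float = DEFAULT_THRESHOLD_HU) -> BoneMask:
    """Maximal 26-connected component of voxels with HU >= threshold containing the seed."""
    seed = _check_seed(volume, seed_voxel)
    above = volume.values >= threshold_hu
    if not above[seed]:
        raise SeedError(
            f"seed not in bone: HU {int(volume.values[seed])} at {seed} is below "
            f"the {threshold_hu:g} HU growth threshold")
    labeled, _ = ndi.label(above, structure=_STRUCT_26)
    grown = labeled == labeled[seed]
    return BoneMask(grown, voxel_spacing=volume.voxel_spacing)


def fill_envelope(mask: BoneMask) -> BoneMask:
    """Fill interior cavities: add every background component that does not
    reach the volume border under 6-connectivity.  Idempotent; superset of the
    input."""
    if not mask.mask.any():
        raise ValueError("cannot fill an empty mask")
    filled = ndi.binary_fill_holes(mask.mask)  # default structure = 6-connectivity
    return BoneMask(filled, voxel_spacing=mask.voxel_spacing,
                    laterality=mask.laterality)


def extract_femur(volume: CTVolume, seed_voxel,
                  threshold_hu: float = DEFAULT_THRESHOLD_HU) -> BoneMask:
    """Grow from the seed at the threshold, then fill marrow cavities.

    Bridging into neighbouring bone (e.g. across the hip joint) is not broken
    automatically; if the envelope looks implausibly large, raise the
    threshold or edit the mask manually.
    """
    grown = region_grow(volume, seed_voxel, threshold_hu)
    envelope = fill_envelope(grown)
    logger.info("extract_femur: threshold %g HU, grown %d voxels, envelope %d voxels",
                threshold_hu, grown.voxel_count(), envelope.voxel_count())
    return envelope
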