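"""Cropping the extracted femur to the analysis VOI.

The VOI runs from the femoral head down to the inferior margin of the lesser
trochanter; the distal boundary is a single axial plane, supplied by the
operator as a slice index or a physical z coordinate, and the landmark slice
itself is included.
"""

from __future__ import annotations

import math

from .image_io import BoneMask, CTVolume

__all__ = ["crop_voi", "landmark_from_mm"]


def crop_voi(mask: BoneMask, cut_z_index: int) -> BoneMask:
    """Keep mask voxels with z >= cut_z_index (the cut slice is included)."""
    nz = mask.shape[0]
    cut = int(cut_z_index)
    if not 0 <= cut < nz:
        raise ValueError(f"cut plane index {cut} outside the z range [0, {nz})")
    out = mask.mask.copy()
    out[:cut] = False
    if not out.any():
        raise ValueError(f"VOI empty above cut plane z={cut}")
    return BoneMask(out, voxel_spacing=mask.voxel_spacing, laterality=mask.laterality)


def landmark_from_mm(volume: CTVolume, z_mm: float) -> int:
    """Nearest axial slice index to a physical z coordinate; ties round superior.

    Slice i sits at ``origin_z + i * dz``; a coordinate exactly between two
    slices maps to the superior one.
    """
    dz = volume.voxel_spacing[0]
    rel = (float(z_mm) - volume.origin[0]) / dz
    nz = volume.shape[0]
    if rel < -0.5 or rel > nz - 0.5:
        raise ValueError(f"z = {z_mm:g} mm outside the volume extent "
                         f"[{volume.origin[0]:g}, {volume.origin[0] + nz * dz:g}) mm")
    idx = int(math.floor(rel + 0.5))  # half-way ties go up, i.e. superior
    return min(max(idx, 0), nz - 1)
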