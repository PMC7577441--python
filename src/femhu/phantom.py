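"""Digital proximal-femur CT phantoms with exactly known tissue composition.

The phantom is a stylized femur — spherical head, oblique capsule neck,
vertical capsule shaft, ellipsoidal lesser-trochanter bump — embedded in a
soft-tissue body inside an air background.  A cortical shell of fixed physical
thickness encloses an interior whose voxels are assigned fatty marrow versus
trabecular bone by independent seeded draws, so the exact fat and dense-bone
fractions of the envelope are known before any noise is added.  Geometry is
deliberately schematic: only HU composition statistics feed the downstream
analysis, so anatomical realism buys nothing.

Compartment labels: 0 air, 1 soft tissue, 2 cortical, 3 trabecular,
4 fatty marrow, 5 adjacent bone (a non-touching acetabulum stand-in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import norm

from .image_io import HU_MAX, HU_MIN, CTVolume

AIR, SOFT_TISSUE, CORTICAL, TRABECULAR, FATTY_MARROW, ADJACENT_BONE = range(6)

LABEL_NAMES = {
    AIR: "air_background",
    SOFT_TISSUE: "soft_tissue",
    CORTICAL: "cortical",
    TRABECULAR: "trabecular",
    FATTY_MARROW: "fatty_marrow",
    ADJACENT_BONE: "adjacent_bone",
}

#: Default compartment HU means: air −1000, soft tissue +40, fatty marrow −80,
#: trabecular +250, cortical +1100 — consistent with the ≤0 HU fat and ≥126 HU
#: dense-bone analysis thresholds and with typical clinical CT values.
DEFAULT_HU_MEANS = {
    "air_background": -1000.0,
    "soft_tissue": 40.0,
    "cortical": 1100.0,
    "trabecular": 250.0,
    "fatty_marrow": -80.0,
}

DEFAULT_HU_SDS = {name: 0.0 for name in DEFAULT_HU_MEANS}

ENVELOPE_LABELS = (CORTICAL, TRABECULAR, FATTY_MARROW)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "ContrastModel",
    "generate_phantom",
    "apply_contrast",
    "simulate_rater_table",
    "sample_cohort_specs",
    "cortical_seed",
    "expected_threshold_fraction",
    "DEFAULT_HU_MEANS",
    "LABEL_NAMES",
    "AIR",
    "SOFT_TISSUE",
    "CORTICAL",
    "TRABECULAR",
    "FATTY_MARROW",
    "ADJACENT_BONE",
]


@dataclass
class PhantomSpec:
    """Geometry, composition and noise parameters of a synthetic femur CT.

    All lengths in mm; ``grid_shape`` is ``(z, y, x)`` voxels, z superior.
    ``lesser_trochanter_z_mm`` is the distance of the VOI cut plane (the
    inferior margin of the trochanter bump) from the inferior volume face.
    ``noise_sd`` is additive white scanner noise in HU; per-compartment
    ``hu_sds`` model tissue heterogeneity (default 0, keeping the zero-noise
    phantom exactly piecewise-constant).
    """

    grid_shape: tuple[int, int, int] = (128, 80, 120)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_radius_mm: float = 22.0
    neck_radius_mm: float = 12.0
    neck_length_mm: float = 40.0
    shaft_radius_mm: float = 14.0
    lesser_trochanter_z_mm: float = 40.0
    cortical_thickness_mm: float = 3.0
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_sds: dict = field(default_factory=lambda: dict(DEFAULT_HU_SDS))
    marrow_fat_fraction: float = 0.35
    noise_sd: float = 25.0
    include_adjacent_bone: bool = False
    random_seed: int = 0

    # -- derived geometry ---------------------------------------------------

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    def geometry(self) -> dict:
        """Shape centres/endpoints implied by the spec (all mm, (z, y, x))."""
        Z, Y, X = self.extent_mm()
        yc = Y / 2.0
        x_head = X / 2.0 + self.neck_length_mm / (2.0 * math.sqrt(2.0))
        head_center = np.array([Z - self.head_radius_mm - 8.0, yc, x_head])
        u = np.array([-1.0, 0.0, -1.0]) / math.sqrt(2.0)  # inferior + medial
        neck_end = head_center + self.neck_length_mm * u
        shaft_top = neck_end
        shaft_bottom = np.array([10.0 + self.shaft_radius_mm, yc, neck_end[2]])
        bump_semi = 0.6 * self.shaft_radius_mm
        bump_center = np.array([self.lesser_trochanter_z_mm + bump_semi, yc,
                                neck_end[2] - self.shaft_radius_mm])
        r_adj = 0.3 * self.head_radius_mm
        adj_center = np.array([head_center[0], yc,
                               x_head + self.head_radius_mm + 2.0 * r_adj])
        return {
            "head_center": head_center,
            "neck_end": neck_end,
            "shaft_top": shaft_top,
            "shaft_bottom": shaft_bottom,
            "bump_center": bump_center,
            "bump_semi_axes": np.array([bump_semi, bump_semi, bump_semi]),
            "adjacent_center": adj_center,
            "adjacent_radius": r_adj,
            "body_semi_axes": (0.49 * Y, 0.49 * X),
        }

    def validate(self) -> None:
        for name in ("head_radius_mm", "neck_radius_mm", "neck_length_mm",
                     "shaft_radius_mm", "cortical_thickness_mm",
                     "lesser_trochanter_z_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.marrow_fat_fraction < 1.0:
            raise ValueError(f"marrow_fat_fraction must lie in (0, 1), "
                             f"got {self.marrow_fat_fraction}")
        if self.noise_sd < 0 or any(sd < 0 for sd in self.hu_sds.values()):
            raise ValueError("noise SDs must be >= 0")
        if self.hu_means["fatty_marrow"] >= 0:
            raise ValueError("fatty_marrow HU mean must be negative")
        if self.hu_means["cortical"] < 126:
            raise ValueError("cortical HU mean must be >= 126 HU")

        g = self.geometry()
        extent = self.extent_mm()
        axis_names = "zyx"
        shapes = {
            "femoral head": (g["head_center"], self.head_radius_mm),
            "neck": (g["neck_end"], self.neck_radius_mm),
            "shaft": (g["shaft_bottom"], self.shaft_radius_mm),
            "trochanter bump": (g["bump_center"], float(g["bump_semi_axes"].max())),
        }
        if self.include_adjacent_bone:
            shapes["adjacent bone"] = (g["adjacent_center"], g["adjacent_radius"])
        for shape_name, (center, radius) in shapes.items():
            for ax in range(3):
                lo, hi = center[ax] - radius, center[ax] + radius
                if lo <= 0 or hi >= extent[ax]:
                    raise ValueError(
                        f"{shape_name} exceeds the grid along axis "
                        f"{axis_names[ax]!r} (spans {lo:.1f}..{hi:.1f} mm of "
                        f"{extent[ax]:.1f} mm)")


@dataclass
class GroundTruth:
    """Per-voxel compartment labels plus exact pre-noise composition."""

    label_volume: np.ndarray  # uint8, (z, y, x)
    voxel_spacing: tuple[float, float, float]
    counts: dict  # compartment name -> voxel count
    fat_fraction_pct: float  # % of envelope voxels with pre-noise HU <= 0
    dense_fraction_pct: float  # % of envelope voxels with pre-noise HU >= 126
    envelope_volume_cm3: float

    def envelope_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, ENVELOPE_LABELS)

    def counts_above(self, cut_z_index: int) -> dict:
        """Per-compartment envelope voxel counts at/above an axial cut plane."""
        sub = self.label_volume[cut_z_index:]
        return {LABEL_NAMES[lab]: int((sub == lab).sum()) for lab in ENVELOPE_LABELS}


@dataclass
class ContrastModel:
    """Additive HU enhancement per compartment (portal-venous style).

    Bone shifts default to 0: femoral-head blood supply is sparse, which is
    the premise behind opportunistic femoral HU screening on enhanced scans.
    """

    soft_tissue_shift: float = 0.0
    trabecular_shift: float = 0.0
    marrow_shift: float = 0.0
    cortical_shift: float = 0.0

    def shift_for(self, label: int) -> float:
        return {
            SOFT_TISSUE: self.soft_tissue_shift,
            TRABECULAR: self.trabecular_shift,
            FATTY_MARROW: self.marrow_shift,
            CORTICAL: self.cortical_shift,
            ADJACENT_BONE: self.cortical_shift,
        }.get(label, 0.0)


# ---------------------------------------------------------------------------
# geometry rasterization
# ---------------------------------------------------------------------------

def _coordinate_grids(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_spacing
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _sphere(zz, yy, xx, center, radius) -> np.ndarray:
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius ** 2


def _capsule(zz, yy, xx, a, b, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment a–b (a sphere-capped cylinder)."""
    ab = b - a
    denom = float(ab @ ab)
    pz, py, px = zz - a[0], yy - a[1], xx - a[2]
    t = (pz * ab[0] + py * ab[1] + px * ab[2]) / denom
    t = np.clip(t, 0.0, 1.0)
    d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
    return d2 <= radius ** 2


def _ellipsoid(zz, yy, xx, center, semi_axes) -> np.ndarray:
    return (((zz - center[0]) / semi_axes[0]) ** 2
            + ((yy - center[1]) / semi_axes[1]) ** 2
            + ((xx - center[2]) / semi_axes[2]) ** 2) <= 1.0


def rasterize_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Build the compartment label volume (marrow assignment consumes ``rng``)."""
    g = spec.geometry()
    zz, yy, xx = _coordinate_grids(spec)

    envelope = _sphere(zz, yy, xx, g["head_center"], spec.head_radius_mm)
    envelope |= _capsule(zz, yy, xx, g["head_center"], g["neck_end"],
                         spec.neck_radius_mm)
    envelope |= _capsule(zz, yy, xx, g["shaft_top"], g["shaft_bottom"],
                         spec.shaft_radius_mm)
    envelope |= _ellipsoid(zz, yy, xx, g["bump_center"], g["bump_semi_axes"])

    # interior: envelope voxels deeper than one cortical thickness from background
    depth = ndi.distance_transform_edt(envelope, sampling=spec.voxel_spacing)
    interior = depth > spec.cortical_thickness_mm

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    Z, Y, X = spec.extent_mm()
    by, bx = g["body_semi_axes"]
    body = (((yy - Y / 2.0) / by) ** 2 + ((xx - X / 2.0) / bx) ** 2) <= 1.0
    body = np.broadcast_to(body, spec.grid_shape)
    labels[body] = SOFT_TISSUE
    if spec.include_adjacent_bone:
        adjacent = _sphere(zz, yy, xx, g["adjacent_center"], g["adjacent_radius"])
        if (adjacent & envelope).any():
            raise ValueError("adjacent bone touches the femur envelope; "
                             "enlarge the grid or shrink the head radius")
        labels[adjacent] = ADJACENT_BONE
    labels[envelope] = CORTICAL
    interior_idx = np.flatnonzero(interior)
    is_fat = rng.random(interior_idx.size) < spec.marrow_fat_fraction
    flat = labels.reshape(-1)
    flat[interior_idx[is_fat]] = FATTY_MARROW
    flat[interior_idx[~is_fat]] = TRABECULAR
    return labels


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterize a phantom: compartment labels, then HU = mean + noise, clamped.

    Bit-identical output for identical spec + seed: the marrow assignment and
    the noise fields are drawn in a fixed order from one seeded generator.
    """
    spec.validate()
    rng = np.random.default_rng(spec.random_seed)
    labels = rasterize_labels(spec, rng)

    mean_map = np.empty(6)
    sd_map = np.empty(6)
    for lab, name in LABEL_NAMES.items():
        key = "cortical" if name == "adjacent_bone" else name
        mean_map[lab] = spec.hu_means[key]
        sd_map[lab] = spec.hu_sds.get(key, 0.0)
    values = mean_map[labels]
    if np.any(sd_map > 0):
        values = values + sd_map[labels] * rng.standard_normal(labels.shape)
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal(labels.shape)

    volume = CTVolume(values=values, voxel_spacing=spec.voxel_spacing,
                      source=f"phantom(seed={spec.random_seed})")

    counts = {name: int((labels == lab).sum()) for lab, name in LABEL_NAMES.items()}
    n_env = sum(counts[LABEL_NAMES[lab]] for lab in ENVELOPE_LABELS)
    # pre-noise HU: marrow (−80) is the only envelope compartment <= 0;
    # cortical and trabecular are both >= 126
    fat_pct = 100.0 * counts["fatty_marrow"] / n_env
    dense_pct = 100.0 * (counts["cortical"] + counts["trabecular"]) / n_env
    gt = GroundTruth(
        label_volume=labels,
        voxel_spacing=spec.voxel_spacing,
        counts=counts,
        fat_fraction_pct=fat_pct,
        dense_fraction_pct=dense_pct,
        envelope_volume_cm3=n_env * volume.voxel_volume_mm3 / 1000.0,
    )
    return volume, gt


def cortical_seed(gt: GroundTruth) -> tuple[int, int, int]:
    """A deterministic cortical-shell voxel usable as a region-growing seed."""
    idx = np.argmax(gt.label_volume == CORTICAL)
    if gt.label_volume.reshape(-1)[idx] != CORTICAL:
        raise ValueError("ground truth contains no cortical voxels")
    return tuple(int(c) for c in np.unravel_index(idx, gt.label_volume.shape))


def apply_contrast(volume: CTVolume, gt: GroundTruth,
                   model: ContrastModel) -> CTVolume:
    """Return a new volume with per-compartment HU shifts added, then clamped."""
    if volume.shape != gt.label_volume.shape:
        raise ValueError(f"volume grid {volume.shape} does not match label grid "
                         f"{gt.label_volume.shape}")
    shift_map = np.array([ContrastModel.shift_for(model, lab) for lab in range(6)])
    if not np.all(np.isfinite(shift_map)):
        raise ValueError("contrast shifts must be finite")
    shifted = volume.values.astype(np.float64) + shift_map[gt.label_volume]
    return CTVolume(values=shifted, voxel_spacing=volume.voxel_spacing,
                    origin=volume.origin, source=volume.source + "+contrast")


def simulate_rater_table(n_subjects: int, k_raters: int, subject_sd: float,
                         rater_bias_sds, residual_sd: float,
                         grand_mean: float = 0.0, seed: int | None = None):
    """Simulate a two-way crossed rater table and its analytic population ICC.

    entry(i, j) = grand_mean + subject_i + bias_j + eps_ij, with
    subject_i ~ N(0, subject_sd²), bias_j ~ N(0, sd_j²) and white residuals.
    Returns ``(RaterTable, analytic_icc)`` where the analytic single-measure
    absolute-agreement ICC is σ²_subject / (σ²_subject + σ²_rater + σ²_residual)
    with σ²_rater the mean of the per-rater bias variances.
    """
    from .stats import RaterTable

    if n_subjects < 2 or k_raters < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    bias_sds = np.broadcast_to(np.asarray(rater_bias_sds, dtype=float),
                               (k_raters,)).copy()
    if subject_sd < 0 or residual_sd < 0 or np.any(bias_sds < 0):
        raise ValueError("standard deviations must be >= 0")

    rng = np.random.default_rng(seed)
    subjects = subject_sd * rng.standard_normal(n_subjects)
    biases = bias_sds * rng.standard_normal(k_raters)
    eps = residual_sd * rng.standard_normal((n_subjects, k_raters))
    values = grand_mean + subjects[:, None] + biases[None, :] + eps

    var_s = subject_sd ** 2
    var_r = float(np.mean(bias_sds ** 2))
    var_e = residual_sd ** 2
    analytic_icc = var_s / (var_s + var_r + var_e)
    table = RaterTable(
        values=values,
        subject_ids=[f"S{i + 1:04d}" for i in range(n_subjects)],
        rater_labels=[f"rater_{j + 1}" for j in range(k_raters)],
    )
    return table, analytic_icc


def sample_cohort_specs(n: int, seed: int, base: PhantomSpec | None = None,
                        **overrides) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs with realistic between-subject geometry spread.

    Head radius varies with SD 1.2 mm, neck radius 0.6 mm, shaft radius 0.7 mm
    and neck length 2 mm around the base spec, truncated to safe ranges; each
    subject also gets its own noise/marrow seed.  This supplies the
    between-subject variance a reliability study needs.
    """
    base = base if base is not None else PhantomSpec()
    rng = np.random.default_rng(seed)

    def jitter(value: float, sd_at_default: float, default: float) -> float:
        # scale the spread with the base geometry, clip to ±20%
        sd = sd_at_default * value / default
        return float(np.clip(value + sd * rng.standard_normal(),
                             0.8 * value, 1.2 * value))

    specs = []
    for i in range(n):
        spec = replace(
            base,
            head_radius_mm=jitter(base.head_radius_mm, 1.2, 22.0),
            neck_radius_mm=jitter(base.neck_radius_mm, 0.6, 12.0),
            shaft_radius_mm=jitter(base.shaft_radius_mm, 0.7, 14.0),
            neck_length_mm=jitter(base.neck_length_mm, 2.0, 40.0),
            random_seed=int(rng.integers(0, 2 ** 31 - 1)),
            hu_means=dict(base.hu_means),
            hu_sds=dict(base.hu_sds),
            **overrides,
        )
        specs.append(spec)
    return specs


def expected_threshold_fraction(counts: dict, hu_means: dict, hu_sds: dict,
                                noise_sd: float, threshold: float,
                                side: str) -> float:
    """Expected % of envelope voxels beyond a HU threshold under Gaussian noise.

    HU values are rounded to integers before thresholding, so ``value <= t``
    happens iff the continuous draw falls below ``t + 0.5`` (and ``>= t`` iff
    above ``t − 0.5``); the Gaussian tail integrals use those half-integer
    continuity points.  With all SDs zero this reduces to the exact pre-noise
    indicator fractions.
    """
    if side not in ("le", "ge"):
        raise ValueError("side must be 'le' or 'ge'")
    total = sum(counts[LABEL_NAMES[lab]] for lab in ENVELOPE_LABELS)
    frac = 0.0
    for lab in ENVELOPE_LABELS:
        name = LABEL_NAMES[lab]
        w = counts[name] / total
        mu = hu_means[name]
        sd = math.hypot(hu_sds.get(name, 0.0), noise_sd)
        if sd == 0:
            p = float(mu <= threshold) if side == "le" else float(mu >= threshold)
        elif side == "le":
            p = norm.cdf((threshold + 0.5 - mu) / sd)
        else:
            p = norm.sf((threshold - 0.5 - mu) / sd)
        frac += w * p
    return 100.0 * frac
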