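"""Synthetic microcosm generator with known ground truth.

Generates phase-labelled 3D volumes emulating a barley-root microcosm
image: a centred cylindrical root, root hairs radiating from its surface,
a granular solid phase packed from digitised non-overlapping balls, and
the remaining space split between air-filled pores and a fine-textured
mixed phase.  All downstream metrics (annulus profiles, hair length
density, pore sizes, connectivity, transport) can therefore be checked
against prescribed values.

Default study conditions: a 2 × 2 × 1 mm region of interest at 5 μm
voxels, a 0.47 mm diameter root, ~24 hairs per mm of root at the surface
with hair extent decaying exponentially away from the root, bulk pore
fraction 0.22, mixed fraction 0.48 (saturated fluid fraction 0.70).

Key generator mechanics
-----------------------
* Hairs are straight thin cylinders in the plane spanned by the outward
  radial normal and the root axis, with the obliquity cosine drawn
  uniformly from [0.5, 1] and the axial tilt pointing at the farther
  axial boundary (minimising clipping by the region of interest).  When
  ``hair_decay_length`` is set, the hair's
  *radial reach* is exponential with that scale, which makes the total
  hair length per annulus decay with exactly the configured constant —
  the property the recovery tests measure.
* The pore/mixed split selects pore voxels per annulus by thresholding a
  spatial field at the annulus-specific quantile, so per-annulus pore
  fractions hit their targets up to rounding.  The field is correlated
  Gaussian noise by default ("pockets"), giving pore bodies of realistic
  tens-of-μm sizes; "uniform" gives the voxel-wise random split and
  "coating" concentrates the mixed phase around grains.
* With a compaction model attached, the per-annulus pore targets follow
  the predicted porosity-recovery curve instead of the bulk value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .compaction import DexterParameters, dexter_porosity
from .core import (
    AXIS_INDEX,
    HAIR,
    MIXED,
    PORE,
    ROOT,
    SOLID,
    LabelledVolume,
    config_hash,
)

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
ANNULUS_THICKNESS = 50.0  # μm, the profiling convention


@dataclass
class MicrocosmConfig:
    """Generator parameters (lengths in μm, densities per mm)."""

    volume_shape: tuple = (200, 400, 400)  # (z, y, x) voxels
    voxel_size: float = 5.0
    root_radius: float | None = 235.0
    root_axis: str = "z"
    hair_surface_density: float = 24.0  # hairs per mm of root length
    hair_length_mean: float = 800.0
    hair_length_sd: float = 150.0
    hair_diameter: float = 8.0
    hair_decay_length: float | None = 300.0
    target_bulk_porosity: float = 0.22
    mixed_fraction: float = 0.48
    solid_grain_diameter_range: tuple = (40.0, 160.0)
    compaction: DexterParameters | None = None
    mixed_arrangement: str = "pockets"
    pocket_correlation_um: float = 15.0
    hair_visibility: bool = False
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("volume_shape must be three positive voxel counts")
        self.volume_shape = shape
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (μm)")
        if self.root_axis not in AXIS_INDEX:
            raise ValueError("root_axis must be 'x', 'y' or 'z'")
        for name in ("target_bulk_porosity", "mixed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_bulk_porosity + self.mixed_fraction > 1.0 + 1e-12:
            raise ValueError("pore + mixed fractions exceed 1")
        lo, hi = self.solid_grain_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("invalid solid_grain_diameter_range")
        if self.has_root:
            ax = AXIS_INDEX[self.root_axis]
            transverse = [self.volume_shape[d] for d in range(3) if d != ax]
            half = 0.5 * min(transverse) * self.voxel_size
            if self.root_radius >= half:
                raise ValueError(
                    "root_radius must be smaller than half the smallest "
                    "transverse extent"
                )
        elif self.hair_surface_density > 0:
            raise ValueError("hairs require a root to radiate from")
        if self.mixed_arrangement not in ("pockets", "uniform", "coating"):
            raise ValueError("mixed_arrangement must be pockets|uniform|coating")

    @property
    def has_root(self) -> bool:
        return self.root_radius is not None and self.root_radius > 0

    @property
    def solid_fraction(self) -> float:
        return 1.0 - self.target_bulk_porosity - self.mixed_fraction

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.compaction is not None:
            d["compaction"] = asdict(self.compaction)
        return d


@dataclass
class GroundTruth:
    """Prescribed per-annulus quantities accompanying a generated volume."""

    annulus_thickness: float
    pore_fraction: np.ndarray  # intended pore fraction per annulus
    solid_fraction: np.ndarray  # realised (packed) solid fraction per annulus
    hair_length_mm: np.ndarray  # analytic hair length per annulus
    grain_diameters_um: np.ndarray
    n_hairs: int
    root_length_mm: float
    bulk_porosity: float
    hair_decay_length: float | None


# ---------------------------------------------------------------------------
# Internal builders
# ---------------------------------------------------------------------------

def _root_mask(config: MicrocosmConfig) -> np.ndarray:
    nz, ny, nx = config.volume_shape
    ax = AXIS_INDEX[config.root_axis]
    tdims = [d for d in range(3) if d != ax]
    shape = config.volume_shape
    centres = [(shape[d] - 1) / 2.0 for d in tdims]
    grids = np.meshgrid(
        *(np.arange(shape[d]) for d in tdims), indexing="ij"
    )
    r2 = (grids[0] - centres[0]) ** 2 + (grids[1] - centres[1]) ** 2
    disc = r2 <= (config.root_radius / config.voxel_size) ** 2
    mask = np.zeros(shape, dtype=bool)
    expand = [slice(None)] * 3
    expand[ax] = None
    # broadcast the transverse disc along the root axis
    mask[:] = np.expand_dims(disc, axis=ax)
    return mask


def _place_hairs(config: MicrocosmConfig, rng, labels):
    """Stamp straight hairs radiating from the root surface.

    Returns (per-annulus analytic length in mm over a generous annulus
    range, polyline list).  Draw order: per hair, obliquity μ, axial sign,
    radial reach (or arc length), jitter.
    """
    h = config.voxel_size
    ax = AXIS_INDEX[config.root_axis]
    tdims = [d for d in range(3) if d != ax]
    shape = config.volume_shape
    root_len_mm = shape[ax] * h * 1e-3
    n_hairs = int(round(config.hair_surface_density * root_len_mm))
    n_ann = 64
    gt_length_um = np.zeros(n_ann)
    if n_hairs == 0:
        return gt_length_um, 0
    centre_t = [(shape[d] - 1) / 2.0 for d in tdims]
    axial_span = shape[ax]
    global_phase = rng.uniform(0.0, 2.0 * np.pi)
    step = 0.4  # voxels, polyline sampling
    stamp_radius_vox = max(config.hair_diameter / 2.0 / h, 0.0)
    offsets = None
    if stamp_radius_vox >= 1.0:
        r = int(np.floor(stamp_radius_vox))
        og = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        keep = (og**2).sum(axis=0) <= stamp_radius_vox**2
        offsets = np.argwhere(keep) - r
    for i in range(n_hairs):
        mu = rng.uniform(0.5, 1.0)
        if config.hair_decay_length is not None:
            reach = max(rng.exponential(config.hair_decay_length), 2.0 * h)
        else:
            length = max(rng.normal(config.hair_length_mean, config.hair_length_sd), 2.0 * h)
            reach = length * mu
        jitter = rng.uniform(-0.4, 0.4)
        axial_pos = (i + 0.5 + jitter) / n_hairs * axial_span
        # tilt towards the farther axial boundary to minimise clipping
        axial_sign = 1.0 if axial_pos < axial_span / 2.0 else -1.0
        theta = global_phase + i * GOLDEN_ANGLE
        # anchor half a voxel inside the root surface so the stamped chain
        # (root voxels are skipped) starts right at the surface and the
        # radial reach is measured from the surface itself
        rho0 = config.root_radius / h - 0.5
        er = np.array([np.cos(theta), np.sin(theta)])
        arc_len_vox = ((config.root_radius + reach) / h - rho0) / mu
        n_steps = max(int(np.ceil(arc_len_vox / step)), 2)
        t = np.linspace(0.0, arc_len_vox, n_steps)  # arc length, voxels
        rho = rho0 + t * mu
        axial = axial_pos + t * np.sqrt(1.0 - mu * mu) * axial_sign
        pts = np.empty((n_steps, 3))
        pts[:, ax] = axial
        pts[:, tdims[0]] = centre_t[0] + rho * er[0]
        pts[:, tdims[1]] = centre_t[1] + rho * er[1]
        inside = np.all((pts >= 0) & (pts <= np.array(shape) - 1), axis=1)
        if not inside.any():
            continue
        pts_in = pts[inside]
        vox = np.round(pts_in).astype(int)
        if offsets is None:
            zz, yy, xx = vox[:, 0], vox[:, 1], vox[:, 2]
        else:
            expanded = (vox[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
            expanded = np.clip(expanded, 0, np.array(shape) - 1)
            zz, yy, xx = expanded[:, 0], expanded[:, 1], expanded[:, 2]
        sel = labels[zz, yy, xx] != ROOT
        if config.hair_visibility:
            sel &= labels[zz, yy, xx] == PORE
        labels[zz, yy, xx] = np.where(sel, HAIR, labels[zz, yy, xx])
        # analytic length bookkeeping on the in-domain polyline
        seg_mid_x = (rho[:-1] + rho[1:]) / 2.0 * h - config.root_radius
        seg_len = np.diff(t) * h
        seg_ok = inside[:-1] & inside[1:]
        ann_idx = np.floor(np.maximum(seg_mid_x, 0.0) / ANNULUS_THICKNESS).astype(int)
        ok = seg_ok & (ann_idx < n_ann)
        np.add.at(gt_length_um, ann_idx[ok], seg_len[ok])
    return gt_length_um, n_hairs


def _pack_grains(config: MicrocosmConfig, rng, labels, root):
    """Random sequential addition of non-overlapping digitised balls.

    Balls may be clipped by the domain boundary but never overlap the
    root or each other.  Raises when the target solid fraction cannot be
    reached with the given grain sizes.
    """
    h = config.voxel_size
    shape = np.array(config.volume_shape)
    target_fraction = config.solid_fraction
    if target_fraction <= 0:
        return np.zeros(0)
    n_outside = int((~root).sum())
    target_voxels = int(round(target_fraction * n_outside))
    lo, hi = config.solid_grain_diameter_range
    ax = AXIS_INDEX[config.root_axis] if config.has_root else None
    tdims = [d for d in range(3) if d != ax] if ax is not None else None
    centre_t = (
        [(config.volume_shape[d] - 1) / 2.0 for d in tdims] if ax is not None else None
    )
    centres = np.zeros((0, 3))
    radii = np.zeros(0)
    diameters = []
    placed = 0
    mean_grain_vox = 4.0 / 3.0 * np.pi * ((lo + hi) / 4.0 / h) ** 3
    max_attempts = int(50 * max(target_voxels / max(mean_grain_vox, 1.0), 1) + 5000)
    attempts = 0
    while placed < target_voxels and attempts < max_attempts:
        attempts += 1
        d_um = rng.uniform(lo, hi)
        r = d_um / 2.0 / h
        c = rng.uniform(0.0, 1.0, size=3) * (shape - 1)
        if ax is not None:
            rho = np.hypot(c[tdims[0]] - centre_t[0], c[tdims[1]] - centre_t[1])
            if rho < config.root_radius / h + r + 1.0:
                continue
        if centres.shape[0]:
            if np.any(np.linalg.norm(centres - c, axis=1) < radii + r):
                continue
        zlo = [max(int(np.floor(c[d] - r)), 0) for d in range(3)]
        zhi = [min(int(np.ceil(c[d] + r)) + 1, shape[d]) for d in range(3)]
        sub = np.mgrid[zlo[0] : zhi[0], zlo[1] : zhi[1], zlo[2] : zhi[2]]
        inside = (
            (sub[0] - c[0]) ** 2 + (sub[1] - c[1]) ** 2 + (sub[2] - c[2]) ** 2
        ) <= r * r
        region = labels[zlo[0] : zhi[0], zlo[1] : zhi[1], zlo[2] : zhi[2]]
        paint = inside & (region != ROOT) & (region != SOLID)
        n_new = int(paint.sum())
        if n_new == 0:
            continue
        region[paint] = SOLID
        placed += n_new
        centres = np.vstack([centres, c])
        radii = np.append(radii, r)
        diameters.append(d_um)
    if placed < target_voxels and (target_voxels - placed) / n_outside > 0.02:
        raise RuntimeError(
            "infeasible packing: solid fraction "
            f"{placed / n_outside:.3f} reached of target {target_fraction:.3f} "
            f"with grains of {lo}-{hi} μm after {attempts} attempts"
        )
    return np.array(diameters)


def _split_pore_mixed(config: MicrocosmConfig, rng, labels, root, ann_index, n_ann):
    """Assign pore vs mixed among the unassigned voxels, per annulus targets.

    Pore voxels are the top-q fraction of a spatial key field within each
    annulus, so realised pore fractions equal the targets up to rounding.
    Returns the per-annulus intended pore fractions.
    """
    h = config.voxel_size
    if config.mixed_arrangement == "pockets":
        key = rng.standard_normal(config.volume_shape).astype(np.float32)
        sigma = config.pocket_correlation_um / h
        key = ndimage.gaussian_filter(key, sigma)
    elif config.mixed_arrangement == "uniform":
        key = rng.random(config.volume_shape).astype(np.float32)
    else:  # coating: mixed hugs the grains, pores sit far from them
        key = ndimage.distance_transform_edt(labels != SOLID).astype(np.float32)
        key += rng.random(config.volume_shape).astype(np.float32) * 1e-3
    candidates = (labels != ROOT) & (labels != SOLID)
    if config.has_root and ann_index is not None:
        groups = ann_index.copy()
        groups[~candidates] = -1
    else:
        groups = np.where(candidates, 0, -1)
        n_ann = 1
    targets = np.empty(n_ann)
    for a in range(n_ann):
        if config.compaction is not None and config.has_root:
            x_mid = (a + 0.5) * ANNULUS_THICKNESS
            targets[a] = dexter_porosity(x_mid, config.compaction)
        else:
            targets[a] = config.target_bulk_porosity
    if config.has_root and ann_index is not None:
        total_out = np.bincount(ann_index[~root], minlength=n_ann)[:n_ann]
    else:
        total_out = np.array([int((~root).sum())])
    for a in range(n_ann):
        sel = groups == a
        n_cand = int(sel.sum())
        if n_cand == 0:
            continue
        n_pore = int(round(targets[a] * total_out[a]))
        n_pore = min(n_pore, n_cand)
        vals = key[sel]
        if n_pore == 0:
            labels[sel] = MIXED
            continue
        if n_pore >= n_cand:
            labels[sel] = PORE
            continue
        thr = np.partition(vals, n_cand - n_pore)[n_cand - n_pore]
        pore_sel = sel & (key >= thr)
        labels[sel] = MIXED
        labels[pore_sel] = PORE
    return targets


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate_microcosm(config: MicrocosmConfig):
    """Generate a labelled microcosm volume and its ground truth.

    Deterministic for a fixed seed: randomness flows from one generator in
    the order hairs → grains → pore/mixed key field.
    """
    rng = np.random.default_rng(config.seed)
    labels = np.full(config.volume_shape, MIXED, dtype=np.uint8)
    ann_index, dist_um, n_ann = None, None, 1
    if config.has_root:
        root = _root_mask(config)
        labels[root] = ROOT
        dist_um = ndimage.distance_transform_edt(
            ~root, sampling=config.voxel_size
        )
        ann_index = np.floor(dist_um / ANNULUS_THICKNESS).astype(np.int32)
        ann_index[root] = -1
        n_ann = int(ann_index.max()) + 1
    else:
        root = np.zeros(config.volume_shape, dtype=bool)

    # hairs are stamped after the soil phases (they may traverse any phase)
    # but their sub-seed is drawn first so the geometry is independent of
    # the soil draws
    gt_hair_um, n_hairs = np.zeros(64), 0
    hair_seed = (
        int(rng.integers(0, 2**31 - 1)) if config.hair_surface_density > 0 else None
    )

    grain_diameters = _pack_grains(config, rng, labels, root)
    pore_targets = _split_pore_mixed(config, rng, labels, root, ann_index, n_ann)

    if hair_seed is not None:
        hair_rng = np.random.default_rng(hair_seed)
        gt_hair_um, n_hairs = _place_hairs(config, hair_rng, labels)

    solid_frac = np.zeros(n_ann)
    if config.has_root:
        out = ann_index >= 0
        tot = np.bincount(ann_index[out], minlength=n_ann)[:n_ann].astype(float)
        sol = np.bincount(
            ann_index[out & (labels == SOLID)], minlength=n_ann
        )[:n_ann]
        with np.errstate(invalid="ignore", divide="ignore"):
            solid_frac = np.where(tot > 0, sol / tot, np.nan)
        root_len_mm = config.volume_shape[AXIS_INDEX[config.root_axis]] * config.voxel_size * 1e-3
    else:
        solid_frac = np.array([float((labels == SOLID).mean())])
        root_len_mm = 0.0

    volume = LabelledVolume(
        labels=labels,
        voxel_size=config.voxel_size,
        root_axis=config.root_axis if config.has_root else None,
        provenance=f"synthetic:{config_hash(config.to_dict())}:seed={config.seed}",
    )
    truth = GroundTruth(
        annulus_thickness=ANNULUS_THICKNESS,
        pore_fraction=pore_targets,
        solid_fraction=solid_frac,
        hair_length_mm=gt_hair_um * 1e-3,
        grain_diameters_um=grain_diameters,
        n_hairs=n_hairs,
        root_length_mm=root_len_mm,
        bulk_porosity=config.target_bulk_porosity,
        hair_decay_length=config.hair_decay_length,
    )
    return volume, truth


def apply_compaction_gradient(
    volume: LabelledVolume, dexter: DexterParameters, seed: int = 0
) -> LabelledVolume:
    """Convert pore to mixed phase near the root to match a compaction curve.

    Each pore voxel at distance x from the root surface is converted with
    probability 1 − φ(x)/φ_bulk, so the expected pore fraction follows the
    model.  Root and hair voxels are never touched.  Seed-controlled.
    """
    if not (volume.labels == ROOT).any():
        raise ValueError("compaction gradient requires a root in the volume")
    rng = np.random.default_rng(seed)
    out = volume.copy()
    dist = ndimage.distance_transform_edt(
        volume.labels != ROOT, sampling=volume.voxel_size
    )
    pore = out.labels == PORE
    phi = dexter_porosity(dist[pore], dexter)
    p_convert = np.clip(1.0 - phi / max(dexter.bulk_porosity, 1e-12), 0.0, 1.0)
    convert = rng.random(p_convert.size) < p_convert
    target = out.labels[pore]
    target[convert] = MIXED
    out.labels[pore] = target
    out.provenance = volume.provenance + f"+dexter(k_D={dexter.k_D},seed={seed})"
    return out
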