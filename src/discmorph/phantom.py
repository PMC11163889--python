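"""Labeled spine phantoms with known ground truth.

Because no public pediatric disk-segmentation cohort exists, validation
runs on synthetic spines: per level, an annulus modelled as an elliptic
cylinder with a superelliptic footprint (exponent 2.5, minor/major aspect
0.7 — a slightly squared-off disk outline) containing an ellipsoidal
nucleus, both sized from the calibrated growth-curve table.  Disks are
stacked along a fixed two-arc sagittal profile (thoracic kyphosis 30 deg,
lumbar lordosis 40 deg), optionally rotated rigidly as a whole, and
voxelized at anisotropic spacing typical of sagittal MRI (in-plane 0.5 mm,
slice 3.5 mm).  The generator returns the voxel phantom together with the
exact generative parameters so every downstream measurement has a
ground-truth twin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import gamma as _gamma

from .geometry import DiscFrame, Plane
from .growth import GrowthCurveTable, level_group_of
from .io import EXCLUSION_FLAGS, LabeledVolume, LabelSchema

log = logging.getLogger(__name__)

SUPERELLIPSE_EXPONENT = 2.5
AF_ASPECT = 0.7          # footprint minor/major semi-axis ratio b/a
NP_ASPECT = 0.7          # nucleus in-plane aspect q/p
NP_HEIGHT_FRACTION = 0.7  # nucleus z-diameter as fraction of disk height


def superellipse_area(a: float, b: float, n: float = SUPERELLIPSE_EXPONENT) -> float:
    """Area of |x/a|^n + |y/b|^n <= 1 (n=2 gives the ellipse pi*a*b)."""
    return 4.0 * a * b * _gamma(1 + 1 / n) ** 2 / _gamma(1 + 2 / n)


@dataclass
class PhantomSpec:
    """One synthetic scan: subject-level parameters of the generator.

    spacing_mm is in grid order (left-right slice axis first, then
    anterior-posterior and cranial-caudal in-plane axes).
    """

    age_years: float
    sex: str
    n_levels: int = 17
    spacing_mm: tuple[float, float, float] = (3.5, 0.5, 0.5)
    pose_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.age_years <= 18:
            raise ValueError("age must lie in [0, 18]")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class DiscGroundTruth:
    """Generative parameters of one phantom disk (its measurement twin)."""

    level_index: int
    af_semi_axes: tuple[float, float]          # (a, b) mm
    height_mm: float
    np_semi_axes: tuple[float, float, float]   # (p, q, r) mm
    np_offset_mm: tuple[float, float, float]   # (dx, dy, dz) in disk axes
    true_v_af: float
    true_v_np: float
    true_v_ivd: float
    true_a: float
    true_s: float
    superellipse_exponent: float = SUPERELLIPSE_EXPONENT
    frame_true: DiscFrame | None = None

    def __post_init__(self):
        if abs(self.true_v_ivd - (self.true_v_af + self.true_v_np)) > 1e-9:
            raise ValueError("true_v_ivd must equal true_v_af + true_v_np")
        if abs(self.true_s - self.height_mm / np.sqrt(self.true_a)) > 1e-12:
            raise ValueError("true_s inconsistent with height/sqrt(area)")
        if not _np_fits(self):
            raise ValueError("nucleus not contained in annulus envelope")

    @property
    def np_ratio(self) -> float:
        return self.true_v_np / self.true_v_ivd


def _np_fits_params(a: float, b: float, h: float, p: float, q: float, r: float,
                    offset, exponent: float = SUPERELLIPSE_EXPONENT,
                    margin: float = 0.995, n_phi: int = 256) -> bool:
    dx, dy, dz = offset
    if r + abs(dz) > margin * h / 2:
        return False
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    xs = np.abs(dx + p * np.cos(phi)) / a
    ys = np.abs(dy + q * np.sin(phi)) / b
    return bool(np.all(xs ** exponent + ys ** exponent <= margin))


def _np_fits(t: DiscGroundTruth, **kw) -> bool:
    a, b = t.af_semi_axes
    p, q, r = t.np_semi_axes
    return _np_fits_params(a, b, t.height_mm, p, q, r, t.np_offset_mm,
                           exponent=t.superellipse_exponent, **kw)


def sample_disc_params(table: GrowthCurveTable, age: float, sex: str,
                       level_index: int, rng: np.random.Generator | None = None,
                       jitter_sd: float = 0.0) -> DiscGroundTruth:
    """Draw one disk's ground truth from the growth table.

    The level group's curves are interpolated at ``age``; the annulus
    semi-axes are derived from the target cross-sectional area with fixed
    aspect b/a, and the nucleus ellipsoid is sized so V_NP/V_IVD equals
    the target ratio exactly (before voxelization).  Jitter is
    multiplicative log-normal, mean-corrected so a jitter_sd of 0.05 gives
    a coefficient of variation of ~5% while keeping all sizes positive.
    If jitter pushes the nucleus outside the annulus envelope it is shrunk
    back in with a logged warning.
    """
    group = level_group_of(level_index)
    base = table.at(group, sex, age)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requested but no rng supplied")
        sigma = float(np.sqrt(np.log1p(jitter_sd ** 2)))
        def jit():
            return float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
    else:
        def jit():
            return 1.0
    h = base["height_mm"] * jit()
    area = base["csa_mm2"] * jit()
    ratio = float(np.clip(base["np_ratio"] * jit(), 0.02, 0.45))
    off_y = base["np_offset_y_mm"] * jit()

    a = float(np.sqrt(area / (superellipse_area(1.0, AF_ASPECT))))
    b = AF_ASPECT * a
    v_ivd = area * h
    v_np = ratio * v_ivd
    r = NP_HEIGHT_FRACTION * h / 2
    p = float(np.sqrt(v_np / (4.0 / 3.0 * np.pi * NP_ASPECT * r)))
    q = NP_ASPECT * p
    offset = (0.0, float(off_y), 0.0)

    # clamp jittered nuclei back inside the annulus envelope
    for _ in range(50):
        if _np_fits_params(a, b, h, p, q, r, offset):
            break
        log.warning("level %d: jittered nucleus exceeds annulus envelope; shrinking", level_index)
        p, q, r = 0.97 * p, 0.97 * q, 0.97 * r
        offset = tuple(0.9 * o for o in offset)
    v_np = 4.0 / 3.0 * np.pi * p * q * r
    return DiscGroundTruth(
        level_index=level_index,
        af_semi_axes=(a, b), height_mm=h,
        np_semi_axes=(p, q, r), np_offset_mm=offset,
        true_v_af=v_ivd - v_np, true_v_np=v_np, true_v_ivd=v_ivd,
        true_a=area, true_s=h / np.sqrt(area),
    )


# ---------------------------------------------------------------------------
# voxelization


def _paint_disc(data: np.ndarray, spacing: np.ndarray, truth: DiscGroundTruth,
                center: np.ndarray, axes: np.ndarray,
                af_label: int, np_label: int) -> None:
    """Voxelize one disk into ``data`` (in place) over its bounding box.

    ``axes`` has the disk's x/y/z direction vectors as columns.  A voxel
    belongs to a structure when its centre lies inside the analytic solid.
    """
    a, b = truth.af_semi_axes
    h = truth.height_mm
    p, q, r = truth.np_semi_axes
    dx, dy, dz = truth.np_offset_mm
    exponent = truth.superellipse_exponent
    rb = float(np.sqrt(a ** 2 + b ** 2 + (h / 2) ** 2)) + float(spacing.max())
    lo = np.maximum(np.floor((center - rb) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + rb) / spacing).astype(int) + 1,
                    np.array(data.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(l, u) for l, u in zip(lo, hi)], indexing="ij")
    w = np.stack(grids, axis=-1) * spacing          # voxel centres, mm
    local = (w - center) @ axes                     # disk-local coordinates
    lx, ly, lz = local[..., 0], local[..., 1], local[..., 2]
    cyl = ((np.abs(lz) <= h / 2)
           & ((np.abs(lx) / a) ** exponent + (np.abs(ly) / b) ** exponent <= 1.0))
    npm = (((lx - dx) / p) ** 2 + ((ly - dy) / q) ** 2 + ((lz - dz) / r) ** 2 <= 1.0)
    region = tuple(slice(l, u) for l, u in zip(lo, hi))
    sub = data[region]
    sub[cyl & ~npm] = af_label
    sub[npm] = np_label
    data[region] = sub


def _check_representable(truth: DiscGroundTruth, z_axis: np.ndarray,
                         spacing: np.ndarray) -> None:
    voxel_extent = float(np.abs(z_axis) @ spacing)
    if truth.height_mm < 2 * voxel_extent:
        raise ValueError(
            f"level {truth.level_index}: spacing too coarse to represent the disk "
            f"(height {truth.height_mm:.2f} mm < 2 voxels of {voxel_extent:.2f} mm "
            "along the disk axis)")


def rasterize_single_disc(truth: DiscGroundTruth, spacing_mm,
                          rotation: np.ndarray | None = None,
                          margin_mm: float = 3.0,
                          af_label: int = 1, np_label: int = 2,
                          ) -> tuple[LabeledVolume, DiscGroundTruth]:
    """Voxelize one disk on its own grid (axcodes L, A, S).

    ``rotation`` (3x3, columns = posed disk axes) poses the disk; the
    returned ground truth carries the posed frame on the new grid.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    a, b = truth.af_semi_axes
    rb = float(np.sqrt(a ** 2 + b ** 2 + (truth.height_mm / 2) ** 2)) + margin_mm
    shape = np.ceil(2 * rb / spacing).astype(int) + 2
    # sub-voxel incommensurate offset: keeps analytic surfaces off the
    # voxel-centre planes (exact alignment is a degenerate, measure-zero
    # configuration for real data but systematic for centred grids)
    center = (shape - 1) / 2.0 * spacing + spacing * 0.2137
    _check_representable(truth, R[:, 2], spacing)
    data = np.zeros(shape, dtype=np.int16)
    _paint_disc(data, spacing, truth, center, R, af_label, np_label)
    frame = DiscFrame(origin=center, x=R[:, 0], y=R[:, 1], z=R[:, 2])
    vol = LabeledVolume(data=data, spacing_mm=spacing, axcodes=("L", "A", "S"))
    return vol, replace(truth, frame_true=frame)


def true_sagittal_plane(truth: DiscGroundTruth) -> Plane:
    """Mid-sagittal plane of a posed disk (normal = its left-right axis)."""
    if truth.frame_true is None:
        raise ValueError("disk has no posed frame; rasterize it first")
    return Plane(point=truth.frame_true.origin, normal=truth.frame_true.x)


def _sagittal_tilts(n_levels: int, kyphosis_deg: float, lordosis_deg: float) -> np.ndarray:
    """Per-level tangent tilt (deg, anterior positive) of the spine axis."""
    n_thoracic = min(12, n_levels)
    tilts = []
    for k in range(1, n_levels + 1):
        if k <= n_thoracic:
            t = 0.0 if n_thoracic == 1 else (k - 1) / (n_thoracic - 1)
            tilts.append(-kyphosis_deg / 2 + kyphosis_deg * t)
        else:
            n_lumbar = n_levels - n_thoracic
            t = (k - n_thoracic) / n_lumbar
            tilts.append(kyphosis_deg / 2 - lordosis_deg * t)
    return np.array(tilts)


def rasterize_spine(spec: PhantomSpec, truths: list[DiscGroundTruth],
                    kyphosis_deg: float = 30.0, lordosis_deg: float = 40.0,
                    schema: LabelSchema | None = None,
                    margin_mm: float = 5.0,
                    ) -> tuple[LabeledVolume, list[DiscGroundTruth]]:
    """Stack disks along the curved spine axis and voxelize the scan.

    Disks are spaced by their heights plus a vertebral-body gap, follow a
    fixed two-arc sagittal profile, and the whole spine is rotated by
    ``spec.pose_deg`` (extrinsic xyz Euler angles).  Labels follow the
    schema (default: AF of level k -> 2k-1, NP -> 2k).  The returned
    truths carry post-pose frames on the output grid.
    """
    if len(truths) != spec.n_levels:
        raise ValueError("need one ground truth per level")
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    if schema is None:
        schema = LabelSchema.default(spec.n_levels)

    tilts = np.deg2rad(_sagittal_tilts(spec.n_levels, kyphosis_deg, lordosis_deg))
    axes_list, centers = [], []
    pos = np.zeros(3)
    for i, (beta, t) in enumerate(zip(tilts, truths)):
        z = np.array([0.0, -np.sin(beta), np.cos(beta)])   # cranial-ish
        y = np.array([0.0, np.cos(beta), np.sin(beta)])    # anterior
        x = np.array([1.0, 0.0, 0.0])                      # left (slice axis)
        axes_list.append(np.column_stack([x, y, z]))
        centers.append(pos.copy())
        if i + 1 < spec.n_levels:
            h0, h1 = truths[i].height_mm, truths[i + 1].height_mm
            vb = 1.2 * (h0 + h1) / 2 + 6.0                 # vertebral-body gap
            step = h0 / 2 + vb + h1 / 2
            beta_mid = (tilts[i] + tilts[i + 1]) / 2
            caudal = -np.array([0.0, -np.sin(beta_mid), np.cos(beta_mid)])
            pos = pos + step * caudal

    centers = np.array(centers)
    pose = Rotation.from_euler("xyz", spec.pose_deg, degrees=True).as_matrix()
    mid = centers.mean(axis=0)
    centers = (centers - mid) @ pose.T
    axes_list = [pose @ A for A in axes_list]

    radii = np.array([np.sqrt(t.af_semi_axes[0] ** 2 + t.af_semi_axes[1] ** 2
                              + (t.height_mm / 2) ** 2) for t in truths])
    lo = (centers - radii[:, None]).min(axis=0) - margin_mm
    hi = (centers + radii[:, None]).max(axis=0) + margin_mm
    centers = centers - lo                                  # grid coords start at 0
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    data = np.zeros(shape, dtype=np.int16)
    posed = []
    for t, c, A in zip(truths, centers, axes_list):
        _check_representable(t, A[:, 2], spacing)
        _paint_disc(data, spacing, t, c, A,
                    schema.label_of(t.level_index, "AF"),
                    schema.label_of(t.level_index, "NP"))
        posed.append(replace(t, frame_true=DiscFrame(origin=c, x=A[:, 0], y=A[:, 1], z=A[:, 2])))
    vol = LabeledVolume(data=data, spacing_mm=spacing, axcodes=("L", "A", "S"))
    return vol, posed


def generate_phantom(table: GrowthCurveTable, spec: PhantomSpec,
                     **raster_kwargs) -> tuple[LabeledVolume, list[DiscGroundTruth]]:
    """Sample all levels of one subject and rasterize the spine."""
    rng = np.random.default_rng(spec.seed)
    truths = [sample_disc_params(table, spec.age_years, spec.sex, k, rng, spec.jitter_sd)
              for k in range(1, spec.n_levels + 1)]
    return rasterize_spine(spec, truths, **raster_kwargs)


# ---------------------------------------------------------------------------
# cohort manifests


def generate_cohort_manifest(n_total: int,
                             exclusion_counts: dict[str, int] | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Synthetic cohort manifest: uniform ages 0-18, balanced sexes, and
    the requested number of scans carrying each exclusion flag."""
    exclusion_counts = dict(exclusion_counts or {})
    bad = set(exclusion_counts) - (set(EXCLUSION_FLAGS) - {"none"})
    if bad:
        raise ValueError(f"unknown exclusion flags {sorted(bad)}")
    n_excluded = sum(exclusion_counts.values())
    if n_excluded > n_total:
        raise ValueError(f"exclusion counts ({n_excluded}) exceed n_total ({n_total})")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(0.0, 18.0, size=n_total)
    sexes = np.array(["M", "F"] * (n_total // 2 + 1))[:n_total]
    rng.shuffle(sexes)
    flags = np.array(["none"] * n_total, dtype=object)
    rows = rng.permutation(n_total)[:n_excluded]
    i = 0
    for flag, count in sorted(exclusion_counts.items()):
        flags[rows[i:i + count]] = flag
        i += count
    return pd.DataFrame({
        "scan_id": [f"scan_{i:04d}" for i in range(n_total)],
        "age_years": np.round(ages, 3),
        "sex": sexes,
        "exclusion_flag": flags,
    })
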