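"""Per-disk morphometry from binary masks.

All geometry is carried out in grid-millimetre space: voxel (i, j, k) sits
at ``(i, j, k) * spacing`` (voxel-centre convention, 0-based indices).

Each disk gets an anatomical coordinate frame derived from the inertia
(second-moment) axes of its annulus fibrosus: x left-right, y
anterior-posterior, z cranial-caudal.  To remove the influence of patient
rotation in the scanner, the frame is rotated about its z-axis until y lies
in the patient's own sagittal plane — the plane through the AF centroids of
the first thoracic level, the first lumbar level, and the most posteriorly
positioned AF.  Height, transverse cross-sectional area, slenderness
H/sqrt(A), compartment volumes and the nucleus-centroid offset are then
measured in that corrected frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import ScannerDirections

log = logging.getLogger(__name__)

__all__ = [
    "Plane", "DiscFrame", "PrincipalAxes", "MorphometryRecord",
    "mask_centroid", "mask_volume", "principal_axes", "orient_axes",
    "patient_sagittal_plane", "build_disc_frame", "disc_height",
    "cross_sectional_area", "slenderness", "nucleus_offset", "measure_disc",
]


@dataclass(frozen=True)
class Plane:
    """Plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValueError("degenerate plane normal")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, p) -> float:
        return float(np.dot(np.asarray(p) - self.point, self.normal))


@dataclass(frozen=True)
class DiscFrame:
    """Right-handed orthonormal triad anchored at the AF centroid.

    x points patient-left, y anterior, z cranial.
    """

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-9:
                raise ValueError(f"frame axes {a},{b} not orthogonal")
        for name in ("x", "y", "z"):
            if abs(np.linalg.norm(getattr(self, name)) - 1) > 1e-9:
                raise ValueError(f"frame axis {name} not unit length")
        if np.dot(np.cross(self.x, self.y), self.z) < 0:
            raise ValueError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns x, y, z (frame -> world)."""
        return np.column_stack([self.x, self.y, self.z])

    def to_local(self, points) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation


@dataclass(frozen=True)
class PrincipalAxes:
    """Inertia axes of a mask: rows of ``axes`` ordered by descending
    spatial extent (second moment); ``degenerate`` flags near-equal
    moments where the ordering is not meaningful."""

    axes: np.ndarray
    moments: np.ndarray
    centroid: np.ndarray
    degenerate: bool


@dataclass
class MorphometryRecord:
    """Complete per-disk measurement set.

    height_mm        chord length through the IVD centroid along frame z
    csa_mm2          area of the transverse (xy) section at the centroid
    slenderness      height / sqrt(csa)
    v_af/v_np/v_ivd  compartment volumes, v_ivd = v_af + v_np exactly
    np_ratio         v_np / v_ivd
    offset_mm        NP centroid minus IVD centroid, in frame axes
                     (+x left, +y anterior, +z cranial)
    """

    level_index: int
    height_mm: float
    csa_mm2: float
    slenderness: float
    v_af_mm3: float
    v_np_mm3: float
    v_ivd_mm3: float
    np_ratio: float
    offset_mm: tuple[float, float, float]
    flags: str = ""

    def __post_init__(self):
        if self.v_af_mm3 <= 0 or self.v_np_mm3 <= 0:
            raise ValueError("compartment volumes must be positive")
        if abs(self.v_ivd_mm3 - (self.v_af_mm3 + self.v_np_mm3)) > 1e-9:
            raise ValueError("V_IVD must equal V_AF + V_NP")
        if not (0 < self.np_ratio < 1):
            raise ValueError("NP:IVD ratio must lie in (0, 1)")
        if self.height_mm <= 0 or self.csa_mm2 <= 0:
            raise ValueError("height and CSA must be positive")
        if abs(self.slenderness - self.height_mm / np.sqrt(self.csa_mm2)) > 1e-12:
            raise ValueError("slenderness inconsistent with H/sqrt(A)")


# ---------------------------------------------------------------------------
# elementary measures


def _voxel_points(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx * np.asarray(spacing, dtype=float)


def mask_centroid(mask: np.ndarray, spacing) -> np.ndarray:
    """Centre of gravity: mean of voxel-centre coordinates (uniform weights)."""
    return _voxel_points(mask, spacing).mean(axis=0)


def mask_volume(mask: np.ndarray, spacing) -> float:
    """Voxel count times voxel volume, in mm^3."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * float(np.prod(np.asarray(spacing, dtype=float)))


def principal_axes(mask: np.ndarray, spacing, degeneracy_rtol: float = 0.05) -> PrincipalAxes:
    """Inertia axes: eigenvectors of the central second-moment tensor.

    The covariance of voxel-centre coordinates is used (eigenvectors agree
    with the physics inertia tensor; ordering here is by spatial extent).
    Rows of the result are ordered by descending moment, so ``axes[2]`` —
    the direction of smallest extent — is the candidate cranial-caudal
    axis of a disk.  Near-equal neighbouring moments (relative gap below
    ``degeneracy_rtol``) set the degenerate flag.
    """
    pts = _voxel_points(mask, spacing)
    if len(pts) < 4:
        raise ValueError(f"need at least 4 voxels for principal axes, got {len(pts)}")
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c) / len(pts)
    w, v = np.linalg.eigh(cov)           # ascending
    moments = w[::-1]
    axes = v[:, ::-1].T                  # rows, descending moment
    gaps = np.diff(moments[::-1])[::-1]  # moments[i] - moments[i+1]
    degenerate = bool(np.any(gaps < degeneracy_rtol * max(moments[0], 1e-300)))
    return PrincipalAxes(axes=axes, moments=moments, centroid=c, degenerate=degenerate)


# ---------------------------------------------------------------------------
# frame construction


_TILT_COS = np.cos(np.deg2rad(80.0))  # ~90 deg tilt guard


def orient_axes(axes: np.ndarray, directions: ScannerDirections) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve inertia axes into anatomically signed (x, y, z).

    ``axes`` rows are ordered by descending extent: the smallest-extent
    axis becomes z (flipped toward scanner cranial), the second in-plane
    axis becomes y (flipped toward scanner anterior), and x is recomputed
    as y x z so the triad is right-handed with x toward scanner left.
    """
    axes = np.asarray(axes, dtype=float)
    z = axes[2].copy()
    if abs(np.dot(z, directions.cranial)) < _TILT_COS:
        raise ValueError("candidate z-axis nearly orthogonal to scanner cranial "
                         "direction (disk tilted ~90 deg); cannot orient frame")
    if np.dot(z, directions.cranial) < 0:
        z = -z
    y = axes[1].copy()
    if abs(np.dot(y, directions.anterior)) < _TILT_COS:
        raise ValueError("candidate y-axis nearly orthogonal to scanner anterior "
                         "direction; cannot orient frame")
    if np.dot(y, directions.anterior) < 0:
        y = -y
    # re-orthogonalise defensively (eigh output is orthonormal already)
    y = y - np.dot(y, z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    return x, y, z


def patient_sagittal_plane(af_centroids: Mapping[int, np.ndarray],
                           directions: ScannerDirections,
                           l1_level: int = 13,
                           collinear_deg: float = 0.5) -> Plane:
    """Patient-specific sagittal plane from three AF centroids.

    The plane passes through the AF centroid of the first (most cranial)
    level, the first lumbar level, and the most posteriorly positioned AF
    regardless of level.  When the most posterior AF coincides with one of
    the first two anchors, the next most posterior one is used so three
    distinct points remain.  The returned normal points toward scanner
    left.
    """
    levels = sorted(af_centroids)
    if len(levels) < 3:
        raise ValueError("need AF centroids of at least three levels")
    first = levels[0]
    if l1_level not in af_centroids:
        raise ValueError(f"first lumbar level {l1_level} not among centroids")
    posterior = directions.posterior
    by_posterior = sorted(levels, key=lambda k: -float(np.dot(af_centroids[k], posterior)))
    third = next(k for k in by_posterior if k not in (first, l1_level))
    p1, p2, p3 = (np.asarray(af_centroids[k], dtype=float) for k in (first, l1_level, third))
    u, v = p2 - p1, p3 - p1
    n = np.cross(u, v)
    sin_angle = np.linalg.norm(n) / (np.linalg.norm(u) * np.linalg.norm(v))
    if sin_angle < np.sin(np.deg2rad(collinear_deg)):
        raise ValueError("the three defining AF centroids are collinear within "
                         f"{collinear_deg} deg; supply a sagittal plane manually")
    n = n / np.linalg.norm(n)
    if np.dot(n, directions.left) < 0:
        n = -n
    return Plane(point=p1, normal=n)


def build_disc_frame(af_mask: np.ndarray, spacing,
                     sagittal: Plane, directions: ScannerDirections) -> DiscFrame:
    """Anatomical frame of one disk, rotation-corrected about z.

    Starting from the oriented inertia axes of the AF, the frame is
    rotated about its z-axis by the unique angle in (-90, 90] degrees that
    brings y into the sagittal plane (y perpendicular to the plane
    normal); of the two in-plane solutions the one keeping y anterior is
    chosen.  The origin is the AF centroid.
    """
    pa = principal_axes(af_mask, spacing)
    if pa.degenerate:
        log.warning("AF inertia moments nearly degenerate; frame may be unstable")
    x, y, z = orient_axes(pa.axes, directions)
    n = sagittal.normal
    xn, yn = float(np.dot(x, n)), float(np.dot(y, n))
    if np.hypot(xn, yn) < 1e-9:
        raise ValueError("frame z-axis is parallel to the sagittal normal; "
                         "rotation about z cannot align y with the plane")
    theta = np.arctan2(yn, xn)  # makes (y cos - x sin) . n = 0
    candidates = []
    for t in (theta, theta - np.pi, theta + np.pi):
        if -np.pi <= t <= np.pi:
            yr = y * np.cos(t) - x * np.sin(t)
            xr = x * np.cos(t) + y * np.sin(t)
            candidates.append((t, xr, yr))
    # prefer the solution keeping y anterior; fall back to |t| smallest
    anterior = [c for c in candidates if np.dot(c[2], directions.anterior) > 0]
    pool = anterior if anterior else candidates
    t, xr, yr = min(pool, key=lambda c: abs(c[0]))
    xr /= np.linalg.norm(xr)
    yr = yr - np.dot(yr, z) * z
    yr /= np.linalg.norm(yr)
    xr = np.cross(yr, z)
    return DiscFrame(origin=pa.centroid, x=xr, y=yr, z=z)


# ---------------------------------------------------------------------------
# frame-dependent measures


def _points_in_mask(points: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """Nearest-voxel membership test for an array of mm-space points."""
    spacing = np.asarray(spacing, dtype=float)
    idx = np.rint(points / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=-1)
    out = np.zeros(len(points), dtype=bool)
    if ok.any():
        sel = idx[ok]
        out[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    return out


def _points_in_mask_interp(points: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """Sub-voxel membership: trilinear interpolation of the binary mask
    with the digitized surface placed at the 0.5 level.  Averages out the
    staircase of tilted surfaces, so chord measurements are not quantized
    to whole voxel layers."""
    from scipy.ndimage import map_coordinates
    spacing = np.asarray(spacing, dtype=float)
    coords = (points / spacing).T
    vals = map_coordinates(mask.astype(np.float32), coords, order=1,
                           mode="constant", cval=0.0)
    return vals >= 0.5


def _bounding_radius(mask: np.ndarray, spacing, center) -> float:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) * np.asarray(spacing, dtype=float)
    hi = idx.max(axis=0) * np.asarray(spacing, dtype=float)
    corners = np.array([[a, b, c] for a in (lo[0], hi[0])
                        for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
    return float(np.max(np.linalg.norm(corners - center, axis=1)))


def disc_height(ivd_mask: np.ndarray, spacing, frame: DiscFrame,
                step_mm: float | None = None, method: str = "centroid_chord") -> float:
    """Disk height at the centre of gravity, in mm.

    The default measures the chord: the line through the IVD centroid
    along frame z is supersampled (step = min spacing / 4) and the height
    is last crossing minus first crossing, so internal gaps that survived
    gap closing are included in the chord.  ``method='mean'`` instead
    averages chord lengths over the transverse footprint on a 1 mm grid
    (exposed for sensitivity checks, not used by default).
    """
    spacing = np.asarray(spacing, dtype=float)
    if step_mm is None:
        step_mm = float(spacing.min()) / 4.0
    c = mask_centroid(ivd_mask, spacing)
    R = _bounding_radius(ivd_mask, spacing, c) + step_mm
    t = np.arange(-R, R + step_mm, step_mm)
    if method == "centroid_chord":
        pts = c + t[:, None] * frame.z
        from scipy.ndimage import map_coordinates
        vals = map_coordinates(ivd_mask.astype(np.float32), (pts / spacing).T,
                               order=1, mode="constant", cval=0.0)
        inside = vals >= 0.5
        if not inside.any():
            raise ValueError("centroid line misses the mask")
        idx = np.flatnonzero(inside)
        i0, i1 = idx[0], idx[-1]
        t0, t1 = t[i0], t[i1]
        # sub-step refinement of the 0.5 crossings
        if i0 > 0 and vals[i0] > vals[i0 - 1]:
            t0 = t[i0 - 1] + step_mm * (0.5 - vals[i0 - 1]) / (vals[i0] - vals[i0 - 1])
        if i1 + 1 < len(t) and vals[i1] > vals[i1 + 1]:
            t1 = t[i1] + step_mm * (vals[i1] - 0.5) / (vals[i1] - vals[i1 + 1])
        return float(t1 - t0)
    elif method == "mean":
        cell = 1.0
        uu = np.arange(-R, R + cell, cell)
        heights = []
        for a in uu:
            for b in uu:
                base = c + a * frame.x + b * frame.y
                pts = base + t[:, None] * frame.z
                inside = _points_in_mask_interp(pts, ivd_mask, spacing)
                if inside.any():
                    ti = t[inside]
                    heights.append(ti.max() - ti.min())
        if not heights:
            raise ValueError("footprint grid misses the mask")
        return float(np.mean(heights))
    raise ValueError(f"unknown height method {method!r}")


def cross_sectional_area(ivd_mask: np.ndarray, spacing, frame: DiscFrame,
                         cell_mm: float = 0.2, margin_mm: float = 2.0) -> float:
    """Transverse cross-sectional area (mm^2) in the disk's xy-plane.

    The plane through the IVD centroid normal to frame z is resampled on
    a square grid (default 0.2 mm cells, bounding box + 2 mm margin);
    the area is the in-mask hit count times the cell area.
    """
    spacing = np.asarray(spacing, dtype=float)
    c = mask_centroid(ivd_mask, spacing)
    R = _bounding_radius(ivd_mask, spacing, c) + margin_mm
    g = np.arange(-R, R + cell_mm, cell_mm)
    A, B = np.meshgrid(g, g, indexing="ij")
    pts = (c[None, :] + A.reshape(-1, 1) * frame.x[None, :]
           + B.reshape(-1, 1) * frame.y[None, :])
    hits = _points_in_mask(pts, ivd_mask, spacing)
    n = int(hits.sum())
    if n == 0:
        raise ValueError("transverse plane misses the mask")
    return n * cell_mm ** 2


def slenderness(height_mm: float, csa_mm2: float) -> float:
    """S = H / sqrt(A); unitless proxy for mechanical (in)stability."""
    if height_mm <= 0 or csa_mm2 <= 0:
        raise ValueError("height and area must be positive")
    return height_mm / np.sqrt(csa_mm2)


def nucleus_offset(np_mask: np.ndarray, ivd_mask: np.ndarray, spacing,
                   frame: DiscFrame) -> tuple[float, float, float]:
    """NP centroid minus whole-IVD centroid, projected on the frame axes.

    Signs: +x patient-left, +y anterior, +z cranial.
    """
    d = mask_centroid(np_mask, spacing) - mask_centroid(ivd_mask, spacing)
    return (float(np.dot(d, frame.x)), float(np.dot(d, frame.y)), float(np.dot(d, frame.z)))


def measure_disc(af_mask: np.ndarray, np_mask: np.ndarray, spacing,
                 sagittal: Plane, directions: ScannerDirections,
                 level_index: int = 0,
                 step_mm: float | None = None, cell_mm: float = 0.2,
                 frame: DiscFrame | None = None) -> MorphometryRecord:
    """Run the full per-disk measurement chain and return one record."""
    if frame is None:
        frame = build_disc_frame(af_mask, spacing, sagittal, directions)
    ivd = af_mask | np_mask
    v_af = mask_volume(af_mask, spacing)
    v_np = mask_volume(np_mask, spacing)
    h = disc_height(ivd, spacing, frame, step_mm=step_mm)
    a = cross_sectional_area(ivd, spacing, frame, cell_mm=cell_mm)
    return MorphometryRecord(
        level_index=level_index,
        height_mm=h, csa_mm2=a, slenderness=slenderness(h, a),
        v_af_mm3=v_af, v_np_mm3=v_np, v_ivd_mm3=v_af + v_np,
        np_ratio=v_np / (v_af + v_np),
        offset_mm=nucleus_offset(np_mask, ivd, spacing, frame),
    )
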