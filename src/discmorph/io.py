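"""Labeled-volume I/O and cohort bookkeeping.

Segmentations arrive as 3D integer label maps (NIfTI), one label per
(disk level, structure) with structure one of AF (annulus fibrosus) or
NP (nucleus pulposus).  This module resolves a label schema into per-disk
binary mask pairs, reproduces the sub-millimetre gap-closing refinement
applied to wrapped segmentation models, and applies the cohort exclusion
filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

STRUCTURES = ("AF", "NP")

#: Closed enum of exclusion reasons (plus "none" for included scans).
EXCLUSION_FLAGS = (
    "none",
    "spine_not_fully_imaged",
    "no_sagittal",
    "poor_quality",
    "spinal_pathology",
    "malposition",
    "brain_mri",
    "improper_slice_thickness",
)


@dataclass(frozen=True)
class ScannerDirections:
    """Anatomical unit vectors expressed in grid-millimetre space.

    Grid-millimetre space puts voxel (i, j, k) at ``(i, j, k) * spacing``
    (voxel-centre convention); the three vectors say which way patient
    left, anterior and cranial point in that space.
    """

    left: np.ndarray
    anterior: np.ndarray
    cranial: np.ndarray

    def __post_init__(self):
        for v in (self.left, self.anterior, self.cranial):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("scanner direction vectors must be unit length")

    @property
    def posterior(self) -> np.ndarray:
        return -self.anterior


_AXCODE_VECTORS = {"L": ("left", +1), "R": ("left", -1),
                   "A": ("anterior", +1), "P": ("anterior", -1),
                   "S": ("cranial", +1), "I": ("cranial", -1)}


def directions_from_axcodes(axcodes: tuple[str, str, str]) -> ScannerDirections:
    """Build ScannerDirections from per-axis anatomical codes.

    ``axcodes[i]`` names the anatomical direction of *increasing* index
    along grid axis i, e.g. ``('L', 'A', 'S')`` for a left/anterior/
    superior-ordered grid.
    """
    vecs: dict[str, np.ndarray] = {}
    for axis, code in enumerate(axcodes):
        if code not in _AXCODE_VECTORS:
            raise ValueError(f"unknown axis code {code!r}")
        name, sign = _AXCODE_VECTORS[code]
        e = np.zeros(3)
        e[axis] = sign
        vecs[name] = e
    if set(vecs) != {"left", "anterior", "cranial"}:
        raise ValueError(f"axis codes {axcodes} do not span three distinct anatomical axes")
    return ScannerDirections(**vecs)


@dataclass
class LabeledVolume:
    """3D integer label grid with physical spacing and orientation.

    data : integer array, 0 = background
    spacing_mm : per-axis voxel size
    axcodes : anatomical direction of increasing index per grid axis
    affine : optional voxel-to-world affine kept for provenance
    """

    data: np.ndarray
    spacing_mm: np.ndarray
    axcodes: tuple[str, str, str]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integer labels")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be three positive values")
        directions_from_axcodes(self.axcodes)  # validates

    def directions(self) -> ScannerDirections:
        return directions_from_axcodes(self.axcodes)

    @property
    def labels_present(self) -> set[int]:
        return set(np.unique(self.data)) - {0}


@dataclass(frozen=True)
class LabelSchema:
    """Mapping (level_index, structure) -> nonzero label id."""

    labels: Mapping[tuple[int, str], int]

    def __post_init__(self):
        ids = list(self.labels.values())
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        if any(i == 0 for i in ids):
            raise ValueError("label ids must be nonzero")
        for (level, structure) in self.labels:
            if structure not in STRUCTURES:
                raise ValueError(f"unknown structure {structure!r}")
        for level in self.levels:
            for s in STRUCTURES:
                if (level, s) not in self.labels:
                    raise ValueError(f"level {level} lacks a label for {s}")

    @property
    def levels(self) -> list[int]:
        return sorted({lvl for (lvl, _) in self.labels})

    def label_of(self, level: int, structure: str) -> int:
        return self.labels[(level, structure)]

    @classmethod
    def default(cls, n_levels: int = 17) -> "LabelSchema":
        """AF of level k -> 2k-1, NP of level k -> 2k."""
        lab = {}
        for k in range(1, n_levels + 1):
            lab[(k, "AF")] = 2 * k - 1
            lab[(k, "NP")] = 2 * k
        return cls(lab)

    def to_json(self, path: str | Path) -> None:
        entries = [{"level_index": lvl, "structure": s, "label": lab}
                   for (lvl, s), lab in sorted(self.labels.items())]
        Path(path).write_text(json.dumps({"labels": entries}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSchema":
        raw = json.loads(Path(path).read_text())
        return cls({(e["level_index"], e["structure"]): e["label"] for e in raw["labels"]})


@dataclass
class DiscMaskPair:
    """Binary AF and NP masks of one disk on the parent grid."""

    level_index: int
    af_mask: np.ndarray
    np_mask: np.ndarray

    def __post_init__(self):
        if self.af_mask.shape != self.np_mask.shape:
            raise ValueError("AF and NP masks must share a grid")
        if np.any(self.af_mask & self.np_mask):
            raise ValueError(f"level {self.level_index}: AF and NP masks overlap "
                             "(input error; masks must be disjoint)")
        if not self.af_mask.any() or not self.np_mask.any():
            raise ValueError(f"level {self.level_index}: empty structure mask")

    @property
    def ivd_mask(self) -> np.ndarray:
        return self.af_mask | self.np_mask


def write_labeled_volume(vol: LabeledVolume, path: str | Path) -> None:
    """Write as NIfTI; affine is rebuilt from spacing and axis codes."""
    if vol.affine is not None:
        affine = vol.affine
    else:
        ras_vec = {"R": (1, 0, 0), "L": (-1, 0, 0), "A": (0, 1, 0),
                   "P": (0, -1, 0), "S": (0, 0, 1), "I": (0, 0, -1)}
        affine = np.eye(4)
        affine[:3, :3] = np.column_stack(
            [vol.spacing_mm[i] * np.array(ras_vec[c]) for i, c in enumerate(vol.axcodes)])
    img = nib.Nifti1Image(vol.data.astype(np.int16), affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_labeled_volume(path: str | Path, schema: LabelSchema | None = None) -> LabeledVolume:
    """Load a NIfTI label map and validate it against a schema.

    Labels present in the file but absent from the schema are reported via
    a warning and left in place (downstream mask extraction ignores them).
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {img.ndim}D")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: missing or invalid affine")
    rot = affine[:3, :3]
    # require an axis-aligned (permutation + flip) grid; oblique label maps
    # would need resampling, which we refuse to do silently
    col_norm = np.linalg.norm(rot, axis=0)
    if np.any(col_norm <= 0):
        raise ValueError(f"{path}: degenerate affine")
    if np.any(np.max(np.abs(rot), axis=0) / col_norm < 0.999):
        raise ValueError(f"{path}: oblique affine not supported for label volumes")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=0):
            raise ValueError(f"{path}: non-integer label data")
        data = rounded.astype(np.int32)
    axcodes = nib.orientations.aff2axcodes(affine)
    spacing = np.array(img.header.get_zooms()[:3], dtype=float)
    vol = LabeledVolume(data=data, spacing_mm=spacing, axcodes=axcodes, affine=affine)
    if schema is not None:
        unknown = vol.labels_present - set(schema.labels.values())
        if unknown:
            log.warning("%s: labels %s not in schema; ignored", path, sorted(unknown))
    return vol


def extract_disc_masks(vol: LabeledVolume, schema: LabelSchema) -> list[DiscMaskPair]:
    """Resolve the schema into one AF/NP mask pair per disk level.

    Levels missing either structure are skipped with a logged reason;
    if no level resolves, the volume is unusable and an error is raised.
    """
    present = vol.labels_present
    pairs = []
    for level in schema.levels:
        af_id = schema.label_of(level, "AF")
        np_id = schema.label_of(level, "NP")
        missing = [s for s, lab in (("AF", af_id), ("NP", np_id)) if lab not in present]
        if missing:
            log.info("level %d skipped: missing %s label(s)", level, "/".join(missing))
            continue
        pairs.append(DiscMaskPair(level_index=level,
                                  af_mask=vol.data == af_id,
                                  np_mask=vol.data == np_id))
    if not pairs:
        raise ValueError("no disk level could be resolved from the volume")
    return pairs


def close_small_gaps(mask: np.ndarray, spacing_mm, max_gap_mm: float = 1.0) -> np.ndarray:
    """Morphological closing with a metric ball of diameter ``max_gap_mm``.

    Mirrors the gap-filling behaviour of surface "wrap" post-processing:
    internal slits and channels narrower than ``max_gap_mm`` are filled.
    The ball radius is measured in millimetres, so anisotropic voxels are
    handled correctly (exact Euclidean distance transforms with per-axis
    sampling).  The result always contains the input.
    """
    if max_gap_mm < 0:
        raise ValueError("max_gap_mm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    r = max_gap_mm / 2.0
    spacing = np.asarray(spacing_mm, dtype=float)
    if r == 0 or not mask.any():
        return mask.copy()
    pad = tuple(int(np.ceil(r / s)) + 1 for s in spacing)
    padded = np.pad(mask, [(p, p) for p in pad])
    d_to_mask = ndimage.distance_transform_edt(~padded, sampling=spacing)
    dilated = d_to_mask <= r
    d_inside = ndimage.distance_transform_edt(dilated, sampling=spacing)
    closed = dilated & (d_inside > r)
    closed |= padded
    sl = tuple(slice(p, n + p) for p, n in zip(pad, mask.shape))
    return closed[sl]


# ---------------------------------------------------------------------------
# cohort manifest


MANIFEST_COLUMNS = ["scan_id", "age_years", "sex", "exclusion_flag"]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    if manifest["scan_id"].duplicated().any():
        raise ValueError("scan_id values must be unique")
    bad = set(manifest["exclusion_flag"]) - set(EXCLUSION_FLAGS)
    if bad:
        raise ValueError(f"unknown exclusion flags {sorted(bad)}")
    if not manifest["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be 'M' or 'F'")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)[MANIFEST_COLUMNS].to_csv(path, index=False)


def apply_exclusion_filters(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Split a cohort manifest into included scans and an exclusion report.

    Returns the rows whose flag is "none" and a {flag: count} report over
    the excluded rows.  |included| + sum(report) == |manifest| always.
    """
    validate_manifest(manifest)
    included = manifest[manifest["exclusion_flag"] == "none"].copy()
    excluded = manifest[manifest["exclusion_flag"] != "none"]
    report = excluded["exclusion_flag"].value_counts().to_dict()
    return included, {str(k): int(v) for k, v in report.items()}
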