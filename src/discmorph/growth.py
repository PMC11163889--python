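"""Reference growth curves for the pediatric disk phantom generator.

The default table encodes, as piecewise-linear anchors over age 0-18, the
published developmental trajectories of thoracolumbar disks: height rises
modestly and only in the first decade (low-thoracic roughly 4 to 7 mm,
lumbar 5 to 10 mm, upper/mid-thoracic plateauing near 5 mm), transverse
cross-sectional area grows steadily throughout growth and more in males
(birth-to-adulthood factors around x4.2/x2.5 upper-thoracic and x5.2/x3.9
lumbar for M/F), the nucleus:disk volume ratio stays near 10-12% in the
upper and mid-thoracic spine but climbs toward 20-25% caudally, and the
nucleus centroid drifts anteriorly in the lumbar spine and posteriorly
mid-thoracically during adolescence.

Mid-thoracic height and area anchors are jointly calibrated so that disk
slenderness H/sqrt(A) averaged over ages 9-13 is 0.23 for females and 0.27
for males, the most scrutinised sex difference in this body of work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

LEVEL_GROUPS = ("upper_thoracic", "mid_thoracic", "low_thoracic", "lumbar")
SEXES = ("M", "F")

#: level_index ranges (inclusive) mirroring T1-T4 / T5-T8 / T9-T12 / L1-L5
LEVEL_GROUP_RANGES = {
    "upper_thoracic": (1, 4),
    "mid_thoracic": (5, 8),
    "low_thoracic": (9, 12),
    "lumbar": (13, 17),
}

#: first lumbar analogue (start of the "lumbar" index range)
L1_LEVEL_INDEX = 13

AGE_RANGE = (0.0, 18.0)

Anchors = Sequence[tuple[float, float]]


def level_group_of(level_index: int) -> str:
    for name, (lo, hi) in LEVEL_GROUP_RANGES.items():
        if lo <= level_index <= hi:
            return name
    raise ValueError(f"level index {level_index} outside 1..17")


@dataclass(frozen=True)
class GrowthCurves:
    """Piecewise-linear anchor sets for one (level group, sex) cell."""

    height_mm: Anchors
    csa_mm2: Anchors
    np_ratio: Anchors
    np_offset_y_mm: Anchors

    def __post_init__(self):
        for name in ("height_mm", "csa_mm2", "np_ratio", "np_offset_y_mm"):
            anchors = getattr(self, name)
            ages = [a for a, _ in anchors]
            vals = [v for _, v in anchors]
            if ages != sorted(ages):
                raise ValueError(f"{name}: anchors must be sorted by age")
            if min(ages) < AGE_RANGE[0] or max(ages) > AGE_RANGE[1]:
                raise ValueError(f"{name}: anchor ages must lie in {AGE_RANGE}")
            if name != "np_offset_y_mm" and any(v <= 0 for v in vals):
                raise ValueError(f"{name}: anchor values must be strictly positive")
            if name == "np_ratio" and any(not (0 < v < 0.5) for v in vals):
                raise ValueError("np_ratio anchors must lie in (0, 0.5)")

    def _interp(self, anchors: Anchors, age: float) -> float:
        ages = np.array([a for a, _ in anchors])
        vals = np.array([v for _, v in anchors])
        return float(np.interp(age, ages, vals))

    def at(self, age: float) -> dict[str, float]:
        if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
            raise ValueError(f"age {age} outside {AGE_RANGE}")
        return {name: self._interp(getattr(self, name), age)
                for name in ("height_mm", "csa_mm2", "np_ratio", "np_offset_y_mm")}


@dataclass(frozen=True)
class GrowthCurveTable:
    """Growth curves keyed by (level_group, sex)."""

    entries: Mapping[tuple[str, str], GrowthCurves]

    def __post_init__(self):
        for group in LEVEL_GROUPS:
            for sex in SEXES:
                if (group, sex) not in self.entries:
                    raise ValueError(f"missing growth curves for ({group}, {sex})")

    def curves(self, level_group: str, sex: str) -> GrowthCurves:
        return self.entries[(level_group, sex)]

    def at(self, level_group: str, sex: str, age: float) -> dict[str, float]:
        return self.curves(level_group, sex).at(age)


def _csa_anchors(birth: float, factor: float, early_fraction: float = 0.45) -> Anchors:
    """CSA anchors with the steep early phase: ``early_fraction`` of the
    total birth-to-18 gain is realised by age 4, the rest linearly."""
    final = birth * factor
    at4 = birth + early_fraction * (final - birth)
    return ((0.0, birth), (4.0, at4), (18.0, final))


def default_growth_table() -> GrowthCurveTable:
    """The calibrated default table (see module docstring for anchors)."""
    e: dict[tuple[str, str], GrowthCurves] = {}

    # --- upper thoracic: height plateaus below 5 mm; CSA factors M x4.2, F x2.5
    e[("upper_thoracic", "M")] = GrowthCurves(
        height_mm=((0.0, 3.8), (8.0, 4.8), (18.0, 4.8)),
        csa_mm2=_csa_anchors(100.0, 4.2),
        np_ratio=((0.0, 0.10), (18.0, 0.12)),
        np_offset_y_mm=((0.0, 0.0), (18.0, 0.0)),
    )
    e[("upper_thoracic", "F")] = GrowthCurves(
        height_mm=((0.0, 3.4), (8.0, 4.2), (18.0, 4.2)),
        csa_mm2=_csa_anchors(100.0, 2.5),
        np_ratio=((0.0, 0.10), (18.0, 0.12)),
        np_offset_y_mm=((0.0, 0.0), (18.0, 0.0)),
    )

    # --- mid thoracic: calibrated so mean slenderness over ages 9-13 is
    #     0.27 (M) / 0.23 (F); heights flat from age 8, CSA through the
    #     calibration point A(11) = (H_plateau / S_target)^2
    e[("mid_thoracic", "M")] = GrowthCurves(
        height_mm=((0.0, 4.2), (8.0, 5.4), (18.0, 5.4)),
        csa_mm2=_csa_anchors(_csa_birth_from_midpoint(400.0, 4.4), 4.4),
        np_ratio=((0.0, 0.10), (18.0, 0.12)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, -1.2)),
    )
    e[("mid_thoracic", "F")] = GrowthCurves(
        height_mm=((0.0, 3.6), (8.0, 4.4), (18.0, 4.4)),
        csa_mm2=_csa_anchors(_csa_birth_from_midpoint(366.0, 3.0), 3.0),
        np_ratio=((0.0, 0.10), (18.0, 0.12)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, -1.2)),
    )

    # --- low thoracic: height 4 -> 7 mm in the first decade
    e[("low_thoracic", "M")] = GrowthCurves(
        height_mm=((0.0, 4.0), (10.0, 7.0), (18.0, 7.0)),
        csa_mm2=_csa_anchors(187.5, 4.8),
        np_ratio=((0.0, 0.14), (18.0, 0.19)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, 0.4)),
    )
    e[("low_thoracic", "F")] = GrowthCurves(
        height_mm=((0.0, 4.0), (10.0, 7.0), (18.0, 7.0)),
        csa_mm2=_csa_anchors(187.5, 3.4),
        np_ratio=((0.0, 0.12), (18.0, 0.20)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, 0.4)),
    )

    # --- lumbar: height 5 -> 10 mm (both sexes meet 10 mm at the adult
    #     anchor); CSA factors M x5.2, F x3.9; NP ratio up to 23 / 25 %
    e[("lumbar", "M")] = GrowthCurves(
        height_mm=((0.0, 5.2), (10.0, 10.0), (18.0, 10.0)),
        csa_mm2=_csa_anchors(269.23, 5.2),
        np_ratio=((0.0, 0.18), (18.0, 0.23)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, 1.5)),
    )
    e[("lumbar", "F")] = GrowthCurves(
        height_mm=((0.0, 4.8), (10.0, 10.0), (18.0, 10.0)),
        csa_mm2=_csa_anchors(269.23, 3.9),
        np_ratio=((0.0, 0.17), (18.0, 0.25)),
        np_offset_y_mm=((0.0, 0.0), (3.0, 0.0), (18.0, 1.5)),
    )
    return GrowthCurveTable(e)


def _csa_birth_from_midpoint(csa_at_11: float, factor: float,
                             early_fraction: float = 0.45) -> float:
    """Invert the CSA anchor shape for the birth value given A(11).

    With anchors (0, A0), (4, A0 + f*(F-1)*A0), (18, A0*F) and linearity
    between ages 4 and 18, A(11) is the mean of the age-4 and age-18
    values, i.e. A0 * (1 + (F-1) * (f + 1) / 2 * ...); solved exactly here.
    """
    # A(4) = A0 * (1 + ef*(F-1)); A(11) = (A(4) + A(18)) / 2
    scale = (1 + early_fraction * (factor - 1) + factor) / 2.0
    return csa_at_11 / scale
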