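"""End-to-end orchestration: per-scan measurement, cohort runs, validation.

A scan run resolves the label schema, applies sub-millimetre gap closing
to every structure mask, builds the patient sagittal plane from the AF
centroids, constructs each disk's rotation-corrected frame and emits one
morphometry row per resolvable level.  A cohort run applies the exclusion
filter, maps the scan runner over the included scans, stratifies the
records and produces the growth-curve summary tables.  Per-level failures
are recorded and never abort a cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from . import geometry as geo
from .growth import L1_LEVEL_INDEX, LEVEL_GROUPS, default_growth_table
from .io import (LabeledVolume, LabelSchema, apply_exclusion_filters,
                 close_small_gaps, extract_disc_masks, read_labeled_volume,
                 validate_manifest)
from .stats import loess_fit, percent_change, stratify, welch_t

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["scan_id", "level_index", "H_mm", "A_mm2", "S",
                  "V_AF_mm3", "V_NP_mm3", "V_IVD_mm3", "np_ratio",
                  "off_x_mm", "off_y_mm", "off_z_mm", "flags"]


@dataclass
class RunConfig:
    """Reproducible configuration of a measurement run."""

    input_dir: Path | None = None
    schema_path: Path | None = None
    manifest_path: Path | None = None
    output_dir: Path | None = None
    gap_close_mm: float = 1.0
    line_step_mm: float | None = None     # default: min spacing / 4
    csa_cell_mm: float = 0.2
    loess_span: float = 0.75
    l1_level: int = L1_LEVEL_INDEX
    seed: int = 0

    def __post_init__(self):
        if self.gap_close_mm < 0 or self.csa_cell_mm <= 0:
            raise ValueError("tolerances must be positive")
        if self.line_step_mm is not None and self.line_step_mm <= 0:
            raise ValueError("line step must be positive")
        for name in ("input_dir", "schema_path", "manifest_path", "output_dir"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def provenance(self) -> dict:
        cfg = {k: (str(v) if isinstance(v, Path) else v)
               for k, v in dataclasses.asdict(self).items()}
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest, "seed": self.seed,
                "discmorph_version": __version__,
                "numpy_version": np.__version__}


def run_scan(volume: LabeledVolume | str | Path, schema: LabelSchema,
             config: RunConfig | None = None, scan_id: str = "") -> pd.DataFrame:
    """Measure every resolvable disk of one labeled volume.

    Returns one row per level with the full morphometry record; levels
    whose measurement fails get a NaN row with the reason in ``flags``.
    """
    config = config or RunConfig()
    if not isinstance(volume, LabeledVolume):
        volume = read_labeled_volume(volume, schema)
    spacing = volume.spacing_mm
    directions = volume.directions()
    pairs = extract_disc_masks(volume, schema)

    # each disk is processed on its padded bounding box: gap closing and
    # the supersampled measures are local operations, so cropping changes
    # nothing but the run time
    pad_mm = config.gap_close_mm + 3.0
    cleaned = []
    for pair in pairs:
        union = pair.af_mask | pair.np_mask
        idx = np.argwhere(union)
        pad = np.ceil(pad_mm / spacing).astype(int) + 1
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + pad, np.array(union.shape))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        af = close_small_gaps(pair.af_mask[sl], spacing, config.gap_close_mm)
        npm = close_small_gaps(pair.np_mask[sl], spacing, config.gap_close_mm)
        af &= ~npm  # closing may brush the AF/NP interface; NP keeps priority
        cleaned.append((pair.level_index, af, npm, lo * spacing))

    flags_global = []
    try:
        centroids = {lvl: geo.mask_centroid(af, spacing) + off
                     for lvl, af, _, off in cleaned}
        sagittal = geo.patient_sagittal_plane(centroids, directions,
                                              l1_level=config.l1_level)
    except ValueError as exc:
        log.warning("scan %s: sagittal plane fell back to scanner-left (%s)", scan_id, exc)
        lvl0, af0, _, off0 = cleaned[0]
        sagittal = geo.Plane(point=geo.mask_centroid(af0, spacing) + off0,
                             normal=directions.left)
        flags_global.append("sagittal_fallback")

    rows = []
    for lvl, af, npm, off in cleaned:
        base = {"scan_id": scan_id, "level_index": lvl}
        try:
            local_plane = geo.Plane(point=sagittal.point - off, normal=sagittal.normal)
            rec = geo.measure_disc(af, npm, spacing, local_plane, directions,
                                   level_index=lvl,
                                   step_mm=config.line_step_mm,
                                   cell_mm=config.csa_cell_mm)
            rows.append({**base, "H_mm": rec.height_mm, "A_mm2": rec.csa_mm2,
                         "S": rec.slenderness, "V_AF_mm3": rec.v_af_mm3,
                         "V_NP_mm3": rec.v_np_mm3, "V_IVD_mm3": rec.v_ivd_mm3,
                         "np_ratio": rec.np_ratio,
                         "off_x_mm": rec.offset_mm[0], "off_y_mm": rec.offset_mm[1],
                         "off_z_mm": rec.offset_mm[2],
                         "flags": ";".join(flags_global)})
        except ValueError as exc:
            log.warning("scan %s level %d failed: %s", scan_id, lvl, exc)
            rows.append({**base, **{c: np.nan for c in RECORD_COLUMNS[2:-1]},
                         "flags": ";".join(flags_global + [f"failed:{exc}"])})
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def inventory(manifest: pd.DataFrame, n_levels: int = 17) -> dict:
    """Counting arithmetic of a cohort at the manifest level."""
    validate_manifest(manifest)
    included, report = apply_exclusion_filters(manifest)
    n_inc = len(included)
    return {"n_total": int(len(manifest)), "n_included": n_inc,
            "n_excluded": int(len(manifest) - n_inc),
            "exclusion_report": report,
            "n_disks": n_inc * n_levels,
            "n_structures": 2 * n_inc * n_levels}


def summarize_cohort(cohort: pd.DataFrame, span: float = 0.75,
                     age_grid=None) -> dict[str, pd.DataFrame]:
    """Growth-curve and comparison summaries of a stratified cohort table.

    Scatter points are per-subject means within each level group (one
    value per scan and group), LOESS-smoothed over age per group and sex.
    Also reports birth-to-18 percent changes per outcome and the
    mid-thoracic slenderness sex comparison at ages 9-13.
    """
    if age_grid is None:
        age_grid = np.arange(0.0, 18.5, 1.0)
    outcomes = ["H_mm", "A_mm2", "S", "V_AF_mm3", "V_NP_mm3", "np_ratio",
                "off_x_mm", "off_y_mm", "off_z_mm"]
    ok = cohort.dropna(subset=["H_mm"])
    per_subject = (ok.groupby(["scan_id", "level_group", "sex", "age_years"],
                              as_index=False)[outcomes].mean())

    loess_rows, pct_rows = [], []
    for group in LEVEL_GROUPS:
        for sex in ("M", "F"):
            sub = per_subject[(per_subject["level_group"] == group)
                              & (per_subject["sex"] == sex)]
            if len(sub) < 4:
                continue
            for outcome in outcomes:
                fit = loess_fit(sub["age_years"], sub[outcome], span=span,
                                query=age_grid)
                for a, v in zip(age_grid, fit.fitted):
                    loess_rows.append({"level_group": group, "sex": sex,
                                       "outcome": outcome, "age": a, "fit": v})
                if outcome in ("H_mm", "A_mm2", "V_AF_mm3", "V_NP_mm3"):
                    try:
                        pct = percent_change(fit, 0.0, 18.0)
                    except ValueError:
                        pct = np.nan
                    pct_rows.append({"level_group": group, "sex": sex,
                                     "outcome": outcome, "percent_0_to_18": pct})

    tests = []
    mid = ok[(ok["level_group"] == "mid_thoracic")
             & (ok["age_years"] >= 9) & (ok["age_years"] <= 13)]
    per_scan_s = mid.groupby(["scan_id", "sex"], as_index=False)["S"].mean()
    f = per_scan_s.loc[per_scan_s["sex"] == "F", "S"]
    m = per_scan_s.loc[per_scan_s["sex"] == "M", "S"]
    if len(f) >= 2 and len(m) >= 2:
        t, df, p = welch_t(f, m)
        tests.append({"test": "mid_thoracic_slenderness_F_vs_M_ages_9_13",
                      "mean_F": f.mean(), "mean_M": m.mean(),
                      "t": t, "df": df, "p": p})

    return {"loess": pd.DataFrame(loess_rows),
            "percent_change": pd.DataFrame(pct_rows),
            "tests": pd.DataFrame(tests)}


def run_cohort(manifest: pd.DataFrame, config: RunConfig,
               schema: LabelSchema | None = None,
               volume_provider: Callable[[pd.Series], LabeledVolume] | None = None,
               n_levels: int = 17) -> dict:
    """Measure a whole cohort and summarize it.

    Volumes come either from ``volume_provider(manifest_row)`` or from
    ``config.input_dir / f"{scan_id}.nii.gz"``.  Returns a dict with the
    inventory, the stratified per-disk cohort table, the summary tables
    and a provenance block; writes CSV/JSON outputs when
    ``config.output_dir`` is set.
    """
    validate_manifest(manifest)
    schema = schema or LabelSchema.default(n_levels)
    included, report = apply_exclusion_filters(manifest)
    if included.empty:
        raise ValueError("no scans remain after exclusion filtering")
    inv = inventory(manifest, n_levels)
    log.info("cohort: %d/%d scans included; %d disks, %d structures expected",
             inv["n_included"], inv["n_total"], inv["n_disks"], inv["n_structures"])

    frames = []
    for _, row in included.iterrows():
        if volume_provider is not None:
            vol = volume_provider(row)
        else:
            if config.input_dir is None:
                raise ValueError("config.input_dir required without a volume provider")
            vol = config.input_dir / f"{row['scan_id']}.nii.gz"
        frames.append(run_scan(vol, schema, config, scan_id=row["scan_id"]))
    records = pd.concat(frames, ignore_index=True)

    ages = included.set_index("scan_id")["age_years"]
    sexes = included.set_index("scan_id")["sex"]
    cohort = stratify(records, ages=ages, sexes=sexes)
    summaries = summarize_cohort(cohort, span=config.loess_span)

    out = {"inventory": inv, "cohort": cohort, **summaries,
           "provenance": config.provenance()}
    if config.output_dir is not None:
        config.output_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(config.output_dir / "cohort_morphometry.csv", index=False,
                      float_format="%.5g")
        for name in ("loess", "percent_change", "tests"):
            out[name].to_csv(config.output_dir / f"summary_{name}.csv",
                             index=False, float_format="%.6g")
        (config.output_dir / "provenance.json").write_text(
            json.dumps({"inventory": inv, **out["provenance"]}, indent=1))
    return out


def validate(config: RunConfig | None = None, n_recovery_disks: int = 30,
             spacing_mm=(0.5, 0.5, 0.5)) -> dict:
    """Run the analytic-oracle, rotation-invariance and phantom-recovery
    suites and report measured tolerances with pass/fail flags."""
    from . import validation as val

    config = config or RunConfig()
    report: dict = {"cases": n_recovery_disks}
    if n_recovery_disks <= 0:
        report["status"] = "inconclusive"
        report["reason"] = "no phantom cases requested"
        return report

    try:
        oracle = val.analytic_oracle_report(spacing_mm)
        report["analytic_oracle"] = {**oracle,
                                     "pass": all(v < 0.02 for v in oracle.values())}
    except ValueError as exc:
        report["analytic_oracle"] = {"pass": False, "error": str(exc)}

    try:
        rot = val.rotation_invariance_report(spacing_mm=spacing_mm)
        report["rotation_invariance"] = {
            **rot,
            "pass": (max(rot["height_rel"], rot["csa_rel"], rot["v_ivd_rel"]) < 0.02
                     and rot["offset_abs_mm"] < 0.2)}
    except ValueError as exc:
        report["rotation_invariance"] = {"pass": False, "error": str(exc)}

    try:
        sweep = val.recovery_sweep(default_growth_table(), n_disks=n_recovery_disks,
                                   seed=config.seed, spacing_mm=spacing_mm)
        rec = {}
        ok = True
        for name in ("H", "A", "V_AF", "V_NP", "ratio"):
            slope, r2 = val.regression_slope_r2(sweep[f"{name}_true"],
                                                sweep[f"{name}_meas"])
            rec[name] = {"slope": slope, "r2": r2}
            ok &= abs(slope - 1) <= 0.03 and r2 > 0.99
        report["phantom_recovery"] = {**rec, "pass": ok}
    except ValueError as exc:
        report["phantom_recovery"] = {"pass": False, "error": str(exc)}
    report["status"] = ("pass" if all(report[k]["pass"] for k in
                                      ("analytic_oracle", "rotation_invariance",
                                       "phantom_recovery")) else "fail")
    return report
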