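#!/usr/bin/env python
"""Growth-curve analysis of the measured cohort.

Reproduces the cohort-level statistics on the synthetic cohort: LOESS
growth curves per level group and sex, birth-to-adulthood percent
changes, age-trend regressions, the mid-thoracic slenderness sex
comparison at ages 9-13, and nucleus-offset patterns by age group.
Figures (scatter + LOESS, mirroring the usual height/CSA/slenderness and
volume/ratio panels) go to scratch/figures/."""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from discmorph.stats import loess_fit, percent_change, trend_fit, welch_t

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGDIR = ROOT / "scratch" / "figures"

OUTCOMES = {"H_mm": "disk height (mm)", "A_mm2": "CSA (mm$^2$)",
            "S": "slenderness", "V_AF_mm3": "AF volume (mm$^3$)",
            "V_NP_mm3": "NP volume (mm$^3$)", "np_ratio": "NP:IVD ratio"}
GROUPS = ["upper_thoracic", "mid_thoracic", "low_thoracic", "lumbar"]


def main() -> None:
    FIGDIR.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(RESULTS / "cohort_morphometry.csv").dropna(subset=["H_mm"])
    per_subject = cohort.groupby(
        ["scan_id", "level_group", "sex", "age_years"], as_index=False
    )[list(OUTCOMES) + ["off_x_mm", "off_y_mm", "off_z_mm"]].mean()

    # percent changes and age trends per level group and sex; the
    # percent-change reads use a narrower span (0.35) because growth is
    # steepest in the first years of life and a wide window smears the
    # birth value across that phase
    rows, trends = [], []
    grid = np.linspace(0, 18, 37)
    for outcome in OUTCOMES:
        for group in GROUPS:
            for sex in ("M", "F"):
                sub = per_subject.query("level_group == @group and sex == @sex")
                fit = loess_fit(sub["age_years"], sub[outcome], span=0.35,
                                query=grid)
                rows.append({"outcome": outcome, "level_group": group,
                             "sex": sex,
                             "pct_birth_to_18": percent_change(fit)})
                tr = trend_fit(sub, outcome)
                trends.append({"outcome": outcome, "level_group": group,
                               "sex": sex, "slope_per_year": tr.slope,
                               "p": tr.p_value})
    pct = pd.DataFrame(rows)
    pct.to_csv(RESULTS / "percent_change_birth_to_18.csv", index=False)
    pd.DataFrame(trends).to_csv(RESULTS / "age_trends.csv", index=False)

    csa = pct.query("outcome == 'A_mm2'").set_index(["level_group", "sex"])
    print("CSA increase birth->18 (final as % of initial):")
    for group in GROUPS:
        m = csa.loc[(group, "M"), "pct_birth_to_18"]
        f = csa.loc[(group, "F"), "pct_birth_to_18"]
        print(f"  {group:15s}  M {m:5.0f}%   F {f:5.0f}%")

    # mid-thoracic slenderness sex gap at early adolescence
    mid = cohort.query("level_group == 'mid_thoracic' and 9 <= age_years <= 13")
    per_scan = mid.groupby(["scan_id", "sex"], as_index=False)["S"].mean()
    f = per_scan.query("sex == 'F'")["S"]
    m = per_scan.query("sex == 'M'")["S"]
    t, df, p = welch_t(f, m)
    print(f"mid-thoracic slenderness ages 9-13: F {f.mean():.3f} vs M {m.mean():.3f}"
          f"  (Welch t={t:.2f}, df={df:.1f}, p={p:.2g})")

    # nucleus offsets by age group (anterior positive)
    off = cohort.groupby(["level_group", "age_group"])[
        ["off_x_mm", "off_y_mm", "off_z_mm"]].mean().round(2)
    off.to_csv(RESULTS / "nucleus_offsets_by_age_group.csv")
    print("mean nucleus AP offset (mm) by level group and age group:")
    print(off["off_y_mm"].unstack().to_string())

    # scatter + LOESS panels
    for outcome, label in OUTCOMES.items():
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, sex in zip(axes, ("M", "F")):
            for group in GROUPS:
                sub = per_subject.query("level_group == @group and sex == @sex")
                ax.scatter(sub["age_years"], sub[outcome], s=6, alpha=0.4)
                fit = loess_fit(sub["age_years"], sub[outcome], span=0.75,
                                query=grid)
                ax.plot(grid, fit.fitted, label=group.replace("_", " "))
            ax.set_title({"M": "males", "F": "females"}[sex])
            ax.set_xlabel("age (years)")
        axes[0].set_ylabel(label)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(FIGDIR / f"{outcome}_by_age.png", dpi=110)
        plt.close(fig)
    print(f"figures under {FIGDIR}")


if __name__ == "__main__":
    main()
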