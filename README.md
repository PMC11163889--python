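# discmorph

Morphometry of intervertebral disks (IVDs) from labeled segmentation
volumes, for studying how the annulus fibrosus (AF) and nucleus pulposus
(NP) develop during growth.

Pediatric spinal deformities such as idiopathic scoliosis emerge while
the disk is still maturing, and disk *slenderness* — height relative to
footprint size — is a candidate mechanical risk factor. Quantifying it
reproducibly from MRI segmentations requires a per-disk anatomical
coordinate frame that is independent of how the patient lay in the
scanner. `discmorph` implements that measurement chain and the cohort
statistics around it:

- per-disk frames from the AF's inertia axes (eigenvectors of the central
  second-moment tensor), rotated about the cranio-caudal axis into a
  patient-specific sagittal plane built from three AF centroids;
- disk height `H` (chord through the centre of gravity), transverse
  cross-sectional area `A`, slenderness `S = H/√A`, compartment volumes
  `V_AF`, `V_NP`, `V_IVD = V_AF + V_NP`, the hydration proxy
  `V_NP : V_IVD`, and the signed NP-centroid offset in the frame axes;
- cohort statistics: T1–L5 level groups and SRS age groups, LOESS growth
  curves, birth-to-adulthood percent changes, OLS age trends, Welch sex
  comparisons, and ICC(2,1) segmentation reliability;
- a calibrated spine-phantom generator (labeled NIfTI + ground-truth
  sidecar) that emulates the published growth trajectories of pediatric
  disks, used to validate the whole chain since no clinical cohort is
  distributable.

## Worked example

Measure one synthetic scan end to end:

```sh
discmorph phantom --out /tmp/ph --n-scans 1 --n-levels 17 --seed 3
discmorph measure /tmp/ph/scan_0000.nii.gz --schema /tmp/ph/schema.json \
    --out-csv /tmp/ph/morphometry.csv
```

or in Python:

```python
from discmorph import (default_growth_table, LabelSchema, RunConfig,
                       run_scan)
from discmorph.phantom import PhantomSpec, generate_phantom

table = default_growth_table()
spec = PhantomSpec(age_years=8.0, sex="F", pose_deg=(4, -6, 3),
                   jitter_sd=0.03, seed=42)
vol, truths = generate_phantom(table, spec)          # 17 labeled disks
df = run_scan(vol, LabelSchema.default(), RunConfig(), scan_id="demo")
print(df[["level_index", "H_mm", "A_mm2", "S", "np_ratio"]].round(3))
```

which prints one row per disk level (1 = most cranial, 13–17 = lumbar):

```
 level_index  H_mm  A_mm2     S  np_ratio
           1 4.262 178.44 0.319     0.113
           5 4.410 308.28 0.251     0.114
           9 6.447 458.24 0.301     0.156
          13 9.037 748.76 0.330     0.204
          17 9.111 764.24 0.330     0.199
```

Heights grow caudally (≈4 mm upper-thoracic to ≈9 mm lumbar at age 8),
the NP takes ~11% of disk volume in the thoracic spine rising to ~20%
in the lumbar spine, and slenderness is lowest mid-thoracic — the
patterns the growth table encodes, recovered here from the voxel masks
alone under a rotated patient pose.

The numbered scripts under `analysis/` run the full synthetic study:
`01_build_cohort.py` (180 candidate scans, exclusion filter → 126
included, 2142 disks / 4284 structures), `02_measure_cohort.py` (measures
all included scans; ~2 min), `03_growth_curves.py` (LOESS curves, percent
changes, the mid-thoracic slenderness sex gap at ages 9–13 — females
≈0.231 vs males ≈0.272, Welch p ≈ 1e-10 on the default cohort),
`04_reliability.py` (ICCs under simulated re-segmentation) and
`05_validation.py` (analytic oracles, rotation invariance, parameter
recovery). Tables land in `results/`.

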