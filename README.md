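# sulcalstrain

Head-impact kinematics → sulcal brain-strain analysis at desk scale.

Repeated head impacts in American football are linked to chronic traumatic
encephalopathy (CTE), a tauopathy whose hallmark lesions sit at the **depths of
cortical sulci** — exactly where finite-element head models predict mechanical
strain concentrates during impacts.  Player position shapes the impacts a
player receives: defensive backs and receivers take rarer, harder hits
(profile 1), linemen take frequent, milder ones (profile 3).  This package
rebuilds that analysis chain end to end with synthetic, calibrated inputs so
the mechanics and statistics can be run, inspected and tested in minutes on a
laptop: it is aimed at injury-biomechanics students and method developers, not
at clinical prediction.

The pipeline:

1. **Synthetic impact cohorts** — three exposure profiles (n = 49/69/30 by
   default) of 6-DOF half-sine impact pulses whose peak resultants are
   calibrated to published per-profile means (linear velocity 3.9/3.1/2.8 m/s,
   linear acceleration 428/329/273 m/s², rotational velocity 25/19/18 rad/s,
   rotational acceleration 3/2/2 krad/s²) via zero-truncated normals with a
   truncation-corrected mean.
2. **Idealized sulcated brain model** — a 2D plane-strain disc with 12
   sinusoidal cortical folds, a 2 mm CSF film and a rigid prescribed-motion
   skull boundary, advanced by an explicit central-difference FE solver
   (nearly incompressible neo-Hookean tissue, optional Prony viscoelasticity).
   Per element it records the peak **maximum principal Green-Lagrange strain**
   E = ½(FᵀF − I) and the peak maximum principal value of dE/dt.
3. **NIfTI fields and atlas ROIs** — peak fields are rasterized to single-slice
   NIfTI volumes with a matching sulcal/gyral atlas on the same grid; per
   impact the whole-brain 90th-percentile strain/strain-rate and the
   ROI-averaged sulcal and gyral means are tabulated.
4. **Cohort statistics** — paired sulci-vs-gyri test (t or Wilcoxon by a
   Shapiro-Wilk gate, paired Cohen's d), one-way ANOVA with Tukey HSD,
   two-way mixed ANOVA (profile × region), Pearson r² with Fisher-z CIs, and
   joint OLS of sulcal metrics on the four kinematic peaks.

See `docs/methods.md` for the model, its assumptions and its limitations —
in particular, absolute strain magnitudes in the 2D idealization run well
above whole-head values; the meaningful outputs are the *directional*
patterns (sulci > gyri, profile ordering, rotational dominance).

## Worked example

```python
from sulcalstrain.pipeline import RunConfig, run_pipeline
rundir = run_pipeline(RunConfig.smoke(outdir="results/smoke", seed=0))
```

This simulates the 27-impact smoke cohort (12/6/9 per profile, 3.5 mm mesh,
≈ 10 min) and writes `cohort.csv`, per-impact NIfTI volumes, `atlas.nii.gz`
and `stats_report.md`.  With seed 0 the report reads (abridged):

```
- Sulci vs gyri, strain: 0.595 ± 0.458 vs 0.326 ± 0.289, paired_t,
  stat = 7.74, p = 3.25e-08, d = 1.49
- Mixed ANOVA (strain, transform=sqrt): profile F = 2.73 (p = 0.0857),
  region F = 194 (p = 5.3e-13), interaction F = 2.7 (p = 0.0877)

| response           | predictor    | r²   | 95% CI      |
| sulcal_mean_strain | peak_lin_vel | 0.09 | (0.00–0.37) |
| sulcal_mean_strain | peak_rot_vel | 0.92 | (0.83–0.96) |
```

Reading: every impact strains the sulcal fundi more than the gyral crowns
(cohort means 0.595 vs 0.326, a large paired effect d = 1.49); the region
effect dominates the mixed ANOVA; and sulcal strain is driven by rotational,
not linear, head motion (r² = 0.92 vs 0.09) — in the joint regression only the
rotational peaks are significant predictors.  Per-profile means in the same
run order profile 1 > profile 2 > profile 3 in 90th-percentile strain
(0.93 / 0.80 / 0.40) and strain rate.  The same patterns at the published
scale are the study's central findings; the magnitudes here are desk-scale.

The numbered scripts under `analysis/` run the same stages as separate,
narrated steps (01 cohort generation, 02 FE smoke cohort, 03 smooth-control
contrast, 04 statistics, 05 validation battery), writing under `results/`.
A CLI wraps the same library: `sulcalstrain run-all --seed 0 --outdir out`,
plus `generate`, `simulate`, `analyze` and `validate` subcommands.

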