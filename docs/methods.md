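# Methods

`sulcalstrain` re-creates, at desk scale, an analysis chain that maps head-impact
kinematics to cortical-fold deformation: a synthetic cohort of American-football
head impacts in three player-position exposure profiles drives an idealized
finite-element brain cross-section; per-element peak Green-Lagrange strain and
strain-rate fields are rasterized to NIfTI volumes, summarized over sulcal and
gyral atlas regions, and compared statistically across profiles and against the
impact kinematics.  Everything below is the package's own account of what is
modelled, what is idealized away, and why.

## Synthetic impact kinematics

Each impact is a pair of smooth, compactly supported half-sine acceleration
pulses — one linear (m/s²), one rotational (rad/s²) — along independent random
unit directions fixed over the pulse, sampled at 0.05 ms.  Velocities are the
cumulative trapezoidal integrals from rest.  Peak *resultants* (max over time of
the Euclidean norm) are the summary quantities.

Per profile, the generator draws:

* **peak velocity** `V` from a normal truncated at zero.  The location
  parameter is solved (Brent) so that the *post-truncation* mean equals the
  profile target — without this correction a profile-1 linear velocity target
  of 3.9 m/s with SD 2.2 m/s would inflate to ≈ 4.09 m/s.
* **pulse duration** `T` uniformly from a per-channel range `[a, 3a]`.  A
  half-sine of duration `T` realizing peak velocity `V` has amplitude
  `A = πV/(2T)`, so `E[A] = (π/2)·E[V]·E[1/T]`; `a` is solved in closed form so
  that `E[A]` equals the profile's mean peak acceleration exactly.  The
  resulting durations are 7–27 ms, the typical range of helmeted-impact
  pulses.  With a degenerate (zero-SD) velocity spec the duration collapses to
  the harmonic-mean value so that every realized quantity is deterministic.

Calibration targets per profile (n = 49/69/30 impacts by default): linear
velocity 3.9/3.1/2.8 m/s, linear acceleration 428/329/273 m/s², rotational
velocity 25/19/18 rad/s, rotational acceleration 3000/2000/2000 rad/s².
Linear dispersions are the published per-profile SDs; rotational dispersions
re-use the coefficient of variation of the matching linear quantity because no
usable rotational dispersions are available.  All four *means* are calibrated
exactly in expectation; the realized acceleration *spread* is implied by the
velocity and duration draws (CoV ≈ 0.64 versus the target ≈ 0.69) — a known,
accepted approximation.

Impact-speed classes (`very_low` … `very_high`) follow the collision and fall
speed bands, applied to the peak linear velocity.

What the generator does **not** emulate: impact location/orientation taxonomy,
helmet and neck mechanics, biphasic (rebound) pulses, correlations between
linear and rotational severity within an impact, and any frequency/exposure
weighting.  Tests that pass on these cohorts therefore validate the pipeline's
mechanics and statistics, not the realism of any single reconstructed impact.

## Idealized sulcated brain model

The domain is a 2D plane-strain disc of radius ≤ 80 mm:

* a **butterfly core** (elliptic square-to-circle block, radius 40 mm) fills
  the centre — a free inner boundary would slosh under linear acceleration and
  dominate the strain field with a mesh artefact;
* a structured ring of quadrilaterals continues to the **cortical surface**
  `r(θ) = r̄ + (d/2)·cos(n_folds·θ)` with 12 folds and fold depth d = 12 mm
  (crests = gyri at 78 mm, troughs = sulcal fundi at 66 mm);
* a **uniform 2 mm CSF film** covers the folded surface; its outer face is the
  rigid skull boundary, whose nodes are prescribed.  The skull surface
  conforms to the folds.  This is a deliberate idealization: with a circular
  skull and CSF-filled sulcal wedges, rotational shear enters almost entirely
  through the thin crest film (stiffness ∝ 1/thickness), concentrating strain
  in gyral *crowns* — the opposite of the fundal concentration seen in folded
  cortex.  A conforming film loads the corrugated surface uniformly and
  restores the fold-root (fundus) concentration mechanism.
* interior brain/core nodes are Laplacian-smoothed (10 sweeps; surface, CSF
  and skull nodes fixed) to relax the skewed cells at the four core corners.

The matching ROI atlas labels the outermost cortical element layers
(`cortical_depth` = 4 mm worth) as one sulcal and one gyral region per fold:
elements whose local surface lies in the deeper half of the trough-to-crest
span are sulcal (fundus + lower walls), crest-adjacent elements gyral.  Deep
brain and CSF are "other" and excluded from the sulcal/gyral statistics.  The
smooth control mesh (fold depth 0) labels its whole cortical ribbon
"smooth_cortex".  Region counts are configurable and intentionally far below a
real surface parcellation's.

## Materials

Nearly incompressible neo-Hookean solids (plane strain,
`S = μ(I − C⁻¹) + λ ln J · C⁻¹`): brain μ = 2.5 kPa, K = 50 MPa, ρ = 1040 kg/m³;
CSF μ = 1 kPa, K = 50 MPa, ρ = 1000 kg/m³.  The CSF shear modulus is the soft-
solid convention of explicit head models rather than a fluid value: the film
must couple skull rotation into the cortex of the *smooth* control as well —
with a water-like modulus the smooth film slips freely and the smooth-vs-
sulcated comparison measures film slip instead of strain redistribution.  An
optional one-term Prony series relaxes the shear stress
(`μ(t) = μ(1 − g(1 − e^{−t/τ}))`, Simo recurrence update); the default is
purely elastic.  All constants are config-exposed.

## Explicit dynamics

Central-difference integration with lumped mass (ρA/4 per corner node).
Elements use single-point quadrature with Flanagan–Belytschko stiffness
hourglass control (coefficient 0.05); the hourglass shape vectors are
orthogonal to affine fields, so rigid motions produce neither strain nor
hourglass force.  The stable step is `0.5 · min(h/c)` with
`h = area / longest edge` (captures thin CSF cells) and `c` the dilatational
wave speed (≈ 219 m/s), giving dt ≈ 2–5 µs at the mesh sizes used.

Skull nodes follow the rigid motion obtained by twice integrating the trace:
planar rotation about the domain centroid from the resultant rotational
acceleration magnitude, plus the in-plane projection of linear acceleration.
Beyond the end of the recorded trace the skull coasts at its final velocities.
Every impact is observed for a **fixed 25 ms window** regardless of its pulse
length, so that cross-impact strain comparisons are not confounded by pulse
duration.  Per-element maximum-principal Green-Lagrange strain
(`E = ½(FᵀF − I)`, closed-form 2×2 eigenvalues) and the maximum principal
value of the finite-difference `dE/dt` are tracked at **every** step — the
tensor is differentiated first, then the principal value taken — and running
peaks are returned.  Mass-proportional damping is available (default 0) and
documented to bias strain-rate peaks when used.

Degenerate inputs: element inversion or non-finite displacement raises a
divergence error carrying the failure time; the offending trace is saved for
replay by the pipeline.

## Fields, atlas and summaries

Per-element peaks transfer to a regular voxel grid (2 mm default) by
point-in-element lookup at voxel centres — piecewise-constant, no smoothing,
so sulcal concentrations are not blurred; out-of-brain voxels carry the
background value.  Fields are single-slice NIfTI-1 volumes (float32, RAS+,
mm); the atlas rasterizes onto the identical grid, so registration is the
identity by construction.  Per impact: whole-brain 90th-percentile strain and
strain rate (linear-interpolation order statistics — the robust severity
scalar), per-ROI means, and sulcal/gyral means as the *unweighted average of
the per-ROI means* (each region counts once); the voxel-weighted alternative
is computed alongside.

## Statistics

* Sulci vs gyri: two-tailed paired t-test, with a Wilcoxon signed-rank
  fallback when Shapiro-Wilk rejects normality of the differences at 0.05;
  the reported `V` is the R convention (sum of positive ranks).  Cohen's d is
  the paired variant, mean(diff)/SD(diff).
* Profile effects: one-way ANOVA, dfs (k−1, N−k), Tukey HSD post-hocs via the
  studentized range (scipy), with unadjusted pooled-t p-values alongside.
* Profile × region: two-way mixed ANOVA (pingouin), between = profile,
  within = region on the two region-level values per impact.  Strain-like
  responses are square-root transformed first; if the transformed cell
  residuals still fail Shapiro-Wilk the log transform is used; the choice is
  recorded in the result.
* Kinematics relations: Pearson r per kinematics/metric pair, reported as r²
  with a 95% CI from the Fisher z-interval on r, endpoints squared and
  ordered (clipped at 0 when the r-interval straddles zero); joint OLS
  (statsmodels) of each sulcal metric on the four peaks with β, 95% CI and p;
  a design condition number above 1e8 sets a collinearity flag rather than
  failing.

## Problem sizes

The analysis scripts and the test suite run a smoke configuration chosen to
keep a complete run in minutes on one CPU: 12/6/9 impacts, 3.5 mm elements
(≈ 1 800 cells), 2 mm voxels, 25 ms windows.  The full-scale defaults
(49/69/30 impacts, 1 mm elements ≈ 17 000 cells) run the same code path
proportionally longer.  Generator-calibration checks use 10 000 draws per
profile; null-calibration checks use 300–400 replicates at n = 148.

## Known limitations

* 2D plane strain overdrives shear relative to a 3D head, and the monotone
  half-sine rotation never reverses, so strain accumulates for the whole
  window: absolute strain magnitudes run well above published whole-head
  values and only *directional* comparisons (sulci vs gyri, profile
  orderings, rotational vs linear coupling) are meaningful.
* The conforming rigid boundary is an idealized loading surface, not a skull
  shape; there is no brain-skull sliding interface, no falx/tentorium, no
  ventricles, and a single homogeneous brain material.
* The synthetic atlas is an analogue of a surface parcellation, not a
  replication; its sulcal/gyral split is a geometric rule on an idealized
  fold.
* Wilcoxon statistics reported on near-degenerate cohorts (every sulcal mean
  above its gyral partner) sit at the extreme of their range; effect sizes are
  more informative there than the statistic itself.
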