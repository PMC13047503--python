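# Methods

`oxymet` models a multimodal experiment in which broadband continuous-wave
near-infrared spectroscopy (NIRS) and arterial-spin-labeling (ASL) MRI are
acquired simultaneously from mouse cortex, and the combined measurements are
reduced to per-animal physiology: tissue hemoglobin saturation (StO₂),
cytochrome-c-oxidase (CCO) content and redox state, cerebral blood flow
(CBF), oxygen extraction fraction (OEF) and the cerebral metabolic rate of
oxygen (CMRO₂).  This note records the models, the defaults and why they
were chosen, and what the synthetic data generator does and does not
emulate.

## Spectroscopic forward model

Attenuation follows the modified Beer–Lambert law on a 1 nm grid over
705–960 nm:

    A(λ) = L · Σᵢ εᵢ(λ) cᵢ + a + b·λ

with mean optical pathlength `L` (cm), chromophore concentrations `cᵢ`
(µM; water as volume fraction × 55.5 M), and an affine scattering term
`a + b·λ` assumed constant over a recording.  The chromophore set is
{HbO₂, dHb, oxCCO, reCCO, water}.

The bundled extinction table (`oxymet/data/extinction_synthetic.csv`) is a
**synthetic surrogate**: smooth curves with the field's qualitative features
(a sharp deoxyhemoglobin band near 760 nm, a water feature in 800–850 nm
with the rising 970 nm shoulder, broad oxidized/reduced CCO bands near
830/790 nm, a smooth HbO₂ curve rising toward 900+ nm).  Because the
simulator and the fitter share this one table, recovery tests exercise the
estimation mathematics without requiring the non-redistributable reference
compilation; absolute concentrations are only as "real" as the surrogate
coefficients, which is the correct scope for a simulation-driven pipeline.

## Spectral inversion

The fitter assumes scattering and water content are constant and works in
Savitzky–Golay smoothed second-derivative space (default window 11 points,
polynomial order 3; edge handling by local polynomial interpolation so that
polynomial inputs are reproduced exactly).  The second derivative
annihilates the affine baseline identically; because the same linear
operator is applied to the measured spectrum and to the extinction
templates, smoothing distortion cancels and the noise-free inversion is
exact to machine precision.

1. **Pathlength.**  Over the 800–850 nm water window, the measured second
   derivative is regressed on the water template scaled by the known tissue
   water concentration (fraction 0.80 × 55.5 M), with the hemoglobin and
   CCO templates as nuisance regressors.  The fitted water scale is `L̂`; a
   non-positive scale raises a degenerate-spectrum error.  `L̂` is inversely
   proportional to the assumed water fraction by construction.
2. **Deoxyhemoglobin.**  Second-derivative regression over 720–800 nm
   (bracketing the 760 nm band) with HbO₂/oxCCO/reCCO as nuisance
   regressors and the known water term subtracted; concentrations scale by
   `1/L̂`.
3. **CCO.**  Second-derivative regression over 720–900 nm for oxCCO and
   reCCO with hemoglobin nuisance regressors.  An attenuation-space variant
   with (1, λ) baseline regressors was evaluated and rejected: the broad
   CCO bands are nearly collinear with an affine baseline, inflating the
   per-animal totCCO SD to ≈1 µM (a quarter of the EAE group mean) at the
   default noise level, versus ≈0.17 µM in derivative space.  Windows are
   configurable; all designs are column-normalized and a condition number
   above 1e10 raises a conditioning error naming the window.
4. **Total hemoglobin.**  During the terminal anoxia pulse all hemoglobin
   deoxygenates, so the dHb plateau equals tHb.  The estimator smooths the
   in-window frame-wise dHb trace with a 5 s moving average and returns the
   mean of the top quartile.  The smoothing matters: the top-quartile order
   statistic of an unsmoothed noisy trace is biased upward by ≈1.3 per-frame
   SDs; after smoothing the residual bias is ≈+0.6 % of tHb, which
   propagates to ≈+0.26 StO₂ points in the most affected (EAE) group.
5. **StO₂** = (1 − dHb/tHb)·100, clipped to [0, 100] with an audit flag.
   The baseline dHb is the mean over the ASL-aligned averaging window
   (default 0–840 s of a 25-minute recording), matching the practice of
   averaging NIRS over the ASL acquisition.

Time windows are half-open `[start, end)`, so a 14-minute window at 6 Hz
contains exactly 5040 frames and the 50 s anoxia window exactly 300.

## Oximetry

Tissue saturation is modeled as a fixed arterial/venous mixture
StO₂ = f·SaO₂ + (1−f)·SvO₂ with arterial fraction f = 0.25, giving
SvO₂ = (StO₂ − 0.25·SaO₂)/0.75; OEF = (SaO₂ − SvO₂)/SaO₂; and by the
modified Fick principle CMRO₂ = CBF · OEF · (SaO₂/100) · k_O₂.

Two constants are calibrations, not measurements, and are exposed in
`OximetryParams`:

* **SaO₂ = 98 %** — solving the partition/OEF equations against each
  group's reported (StO₂, OEF) pair independently implies SaO₂ ≈ 97.4–98.2 %,
  so a single 98 % preset is used for all groups.
* **k_O₂ = 0.107 ml O₂/ml blood** — chosen so the Fick product of the
  healthy-control group means reproduces their reported CMRO₂ (5.5).  Note
  the three groups' printed means are not jointly Fick-consistent under any
  single k_O₂ unless CBF and OEF are negatively correlated within animals;
  the per-animal joint distribution is unrecoverable from printed summaries,
  so the EAE CMRO₂ mean is not used as a recovery target.

A raw OEF outside [0, 1] (recovered StO₂ above SaO₂; ≈1 % of EAE draws) is
clamped and flagged (`OEF_clamped`), keeping the animal auditable in the
cohort.  Negative SvO₂ is likewise flagged, never silently clipped.
Hypoxia is classified per animal as StO₂ ≤ reference mean − 2 SD
(boundary inclusive), with the healthy-control group as reference.

## ASL quantification

A saturation-recovery variable-TR series (TR = 0.1, 0.5, 1, 3, 7.5 s) is
fitted voxelwise to M(TR) = M₀(1 − e^(−TR/T1)) by a coarse log-spaced T1
grid search with M₀ profiled out in closed form, refined by vectorized
Gauss–Newton (a per-voxel `curve_fit` over thousands of images is
computationally infeasible; the vectorized fit matches the closed form to
<0.1 % noise-free).  Voxels with non-positive signal or T1 outside
(0.1, 5] s are masked (NaN), never fatal.

Magnetization-transfer-corrected perfusion weighting uses two control and
two tag images: ΔM = mean(controls) − mean(tags), symmetric within pairs.
Flow uses the standard single-compartment CASL expression

    CBF = 6000 · λ · ΔM / (2α · T1 · M_ctrl)   [ml·100g⁻¹·min⁻¹]

with defaults λ = 0.90 ml/g and α = 0.70 (declared surrogates for the
sequence-specific values, configurable).  ROI statistics are sample
mean/SD (n−1) over in-mask, non-missing voxels; the dual-rater rule flags
ROI means differing by strictly more than 5 % of the primary rater's value.

## Synthetic data generator

Three cohort presets (healthy naive controls; CFA/PTX adjuvant-injected
controls; EAE) carry the group-level distributions of CBF, StO₂, totCCO
and oxidized fraction, sample sizes 15/14/13, a 25-minute 6 Hz NIRS
protocol whose last minute contains a 50 s anoxia pulse, and a 14-minute
ASL window.

* **Truncated normals are moment-matched.**  Preset (mean, SD) are the
  *observed* moments; the generator solves for parent normal parameters
  whose truncation to the physical bounds reproduces them (scipy truncnorm
  moments + root finding).  Naive truncation would, e.g., shift the widest
  group's saturation mean by −0.3 points and shrink its SD — the moment
  match keeps mean, SD and CV simultaneously faithful.
* **Joint structure.**  (CBF, StO₂) are drawn from a correlated bivariate
  normal: ρ = 0 in naive animals, +0.5 in the inflamed arms (low flow
  co-occurring with low oxygenation).  tHb (100 ± 10 µM), pathlength
  (1.8 ± 0.15 cm) and the scattering baseline are free presets at
  literature scale for anesthetized rodent cortex; the study being
  emulated does not print them.
* **NIRS recordings** hold CCO, water and scattering constant; during the
  anoxia pulse StO₂ decays exponentially (τ = 4 s, so the plateau occupies
  the last ~30 s); only the plateau level matters to the tHb estimator.
  Independent Gaussian OD noise (default SD 1e-3) is added per frame and
  wavelength.
* **ASL phantoms** are 128×128 single slices (FOV 25.6 mm, 1.5 mm slice): a
  brain disc with a dorsal cortical band at the animal's true CBF plus a
  zero-mean sinusoidal heterogeneity pattern (±10 %), background at 60 % of
  cortical flow, T1 = 1.9 s, M₀ = 1000, noise scaled by 1/√16 for the 16
  averages.  Control/tag/T1-series images are generated with exactly the
  equations the quantifier inverts.
* **Disease courses** are integer daily scores on the 15-point scale
  (tail 0–2 + four limbs 0–3; 15 reserved for death): zero until a
  per-animal onset day (uniform on days 10–12), linear rise, plateau over
  days 15–17 at a per-animal level drawn from 7.9 ± 0.7.  Control arms
  score zero throughout.  No attrition is simulated; the trajectory
  statistics accept missing values regardless.

What the generator does **not** emulate: instrument drift, motion,
wavelength miscalibration, HASTE blurring and B0/B1 inhomogeneity, transit
delays, melanin/lipid chromophores, or longitudinal sessions.  Passing
recovery tests therefore demonstrate correctness of the estimation
mathematics under the stated noise model, not robustness to real-world
artifacts.

All randomness flows from a single seed through `numpy` `SeedSequence`
spawns (group keys are CRC32 of the group name, so regeneration is
process-independent); identical seeds yield byte-identical manifests.

## Statistics

Shapiro–Wilk screening per group (constant groups reported as degenerate);
Kruskal–Wallis omnibus with tie correction; pairwise two-sided Mann–Whitney
post-hocs multiplied by the number of pairs and capped at 1 (Dunn's z-test
available behind `posthoc="dunn"`); Pearson correlation with the two-sided
t-transform p; sample CV = 100·SD(n−1)/mean; two-sample normal-approximation
sample size n = ⌈2(z₁₋α/₂ + z_power)²·SD²/δ²⌉.  Disease-trajectory
divergence defaults to per-day rank-sum tests Bonferroni-corrected across
days (first corrected p < α is the divergence day); a mixed-design
repeated-measures ANOVA omnibus on complete cases is available
(`method="rm_anova"`, via pingouin) since the exact mixed model under
attrition is underdetermined.  Sample SD and two-sided tests throughout;
missing values pairwise-dropped for correlations, listwise within a metric
for group tests.

The power example worth flagging: detecting a 20-unit flow difference at
α = 0.05 and 95 % power with n = 4 per group requires an assumed SD ≈ 7.5,
which is far below the healthy-control between-animal SD (24.6, which would
give n ≈ 40).  `sample_size_power` therefore takes the SD as an explicit
argument rather than hard-wiring either value.

## Acceptance protocol and problem sizes

`scripts/acceptance.py` regenerates 200 seeded cohorts per group, pushes
every animal through the complete raw-data pipeline (spectra → inversion →
anoxia tHb → StO₂ → oximetry; ASL stack → T1 → ΔM → CBF → ROI), and
reports grand means of the cohort means, plus a 100 000-draw Monte Carlo of
the hypoxia classifier and the disease-course plateau.  The spectral frame
grid is thinned 10× (0.6 Hz): every estimator averages within its time
window, so thinning adds variance but no bias, and keeps the full protocol
around seven minutes on one CPU.  Numerical tie-breaks and degenerate-input
policies (clipping flags, NaN masking, condition-number guards) are as
described above.

## Known limitations

* Absolute chromophore scales inherit the synthetic extinction surrogate.
* The anoxia tHb estimator retains a small positive bias (~0.6 %) by
  design of the robust plateau statistic.
* Single-slice, single-compartment ASL without transit-delay modeling.
* The CBF–StO₂ correlation of the inflamed presets (+0.5) is a modeling
  choice constrained only qualitatively by the emulated study.
* The mixed-design RM ANOVA is an omnibus contract on complete cases, not
  a full attrition-aware mixed model.
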