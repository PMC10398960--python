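# Methods

## Contact mechanics

Indentation of soft tissue by a rigid sphere is modelled with the Hertz
solution for a sphere on an elastic half-space,

F = (4/3) · E/(1 − ν²) · √R_c · δ^{3/2},

where E is the apparent Young's modulus (Pa), ν Poisson's ratio, R_c the
bead radius (μm) and δ the indentation depth (μm). Internally all lengths
are μm, forces nN and moduli Pa; the single conversion constant
(1 Pa·μm² = 10⁻³ nN) lives in `hippomech.units` so no stage can commit a
silent 10³ modulus error. Defaults: ν = 0.5 (hydrated, nearly
incompressible tissue), R_c = 12.5 μm, cantilever spring constant
k = 0.07 N/m, force setpoint 15 nN.

Assumptions and deliberate simplifications:

* purely elastic response — no viscoelasticity, adhesion (JKR/DMT) or
  hydrodynamic drag; only the approach segment is analysed;
* half-space geometry — valid because slices (~500 μm) are far thicker
  than the ≤7 μm fitted indentation, so no bottom-effect correction;
* the fit is restricted to δ ≤ 7 μm, keeping the contact radius
  α = √(R_c·δ) ≤ 9.35 μm below the bead radius, the applicability limit
  of the sphere solution.

## Curve processing

1. **Baseline**: a line fitted to the first 30% of samples (guaranteed
   pre-contact by the generator's pre-travel rule) is subtracted from the
   whole deflection record.
2. **Contact point**: candidate break points are scanned; each splits the
   curve into a flat-zero segment and a Hertz-shaped (δ^{3/2}) segment
   fitted by linear least squares, and the total squared residual is
   minimised. If the best candidate's post-contact deflection does not
   exceed 5× the baseline noise SD the curve is declared contact-free.
3. **Force-indentation**: F = k·d and δ = (z − z_c) − d for post-contact
   samples; δ clipped at zero.
4. **Hertz fit**: nonlinear least squares over (E, contact-point offset).
   The offset is a free nuisance parameter (±2 μm bounds) initialised by
   the piecewise detector; the δ ≤ 7 μm fit window is re-selected as the
   offset moves (up to three passes). Quality flags: `low_depth` below
   0.5 μm fitted depth, `poor_fit` when the RMS residual exceeds 10% of
   the maximum fitted force or the optimiser fails, `no_contact` from the
   detector. Non-`ok` curves become missing map cells.

On noiseless generated curves the full chain returns the generating
modulus to relative error below 10⁻⁶ (the generator produces exact
mechanical equilibria — see below — so this is a genuine round trip, not
a tolerance artifact).

## Map geometry

The acquisition grid covers 1,500 × 450 μm at 30 μm steps with inclusive
endpoints: 51 × 16 cells, cell-centred coordinates, x rightward and
y downward. Duplicate positions are an error (each site is indented
once), off-grid positions beyond step/4 are rejected, and no
interpolation or smoothing is applied. Region masks are inputs aligned to
the grid; labels 1–10 follow the anatomical scheme (CA1 SO/pyr/SR, SLM,
ML, DG granule, Hilus, CA3 SO/pyr/SR) and collapse onto seven analysis
groups: {1,3}, {2}, {4}, {5}, {6}, {7,8,10}, {9}. Rendering uses the
"hot" colormap on a 0–800 Pa scale with X markers for missing cells and
values above range.

## Statistics

**Outlier rule.** One pass per (cohort, analysis-group) stratum: points
strictly outside mean ± 2 sample SDs (n−1 denominator) are dropped.
Strata under 3 points are skipped with a warning. The removal report
records per-stratum counts and bounds; at the default generator settings
the rule removes ≈4.3–4.4% of points. Because moduli are right-skewed,
the rule trims the upper tail preferentially and depresses downstream
means by roughly 3–4% — an inherent property of ±2SD cleansing on
log-normal data that the report surfaces rather than hides.

**Mixed model.** `modulus ~ analysis_group × cohort + (1 | animal)`,
fitted by REML (statsmodels MixedLM). The fixed part uses cell-means
coding — one indicator per observed group × cohort cell — so each
coefficient *is* the estimated marginal mean of that cell with equal
weighting over the factorial grid, and EMM/contrast standard errors come
directly from the fixed-effect covariance. Fits that drive the animal
variance to the boundary are kept and flagged `singular`. Because the
default lbfgs optimiser can fail, or report convergence with corrupt
coefficients, at that boundary, every candidate fit is validated (finite
REML likelihood; each cell coefficient inside its own stratum's data
range) with fall-through to Powell and Nelder-Mead.

**Degrees of freedom** use a containment-style split: cross-cohort
contrasts draw on between-animal information and get
n_animals − n_cohorts df; within-cohort contrasts get the residual
within-animal df, n_obs − n_animals − (n_cells − n_cohorts).

**Tukey adjustment.** For a family of m contrasts with joint t-statistics
T and estimated correlation R, the adjusted p of contrast i is
P(max_j |T_j| ≥ |t_i|) under a multivariate t(df_i, R) — the exact
generalisation of Tukey's studentized-range method to an arbitrary
family. Rectangle probabilities are evaluated by scipy's seeded
quasi-Monte-Carlo, so outputs are reproducible; adjusted p-values are
floored at the unadjusted value to absorb QMC noise. The default family
is all cross-cohort pairs within each group (21 contrasts), oriented
later-minus-earlier cohort; family membership is configurable. Under a
simulated null the measured family-wise error at α = 0.05 is ≈0.01–0.03 —
conservative, as expected when a sub-family of all pairwise comparisons
is adjusted with estimated correlations.

**Diagnostics.** Normal Q-Q data of the marginal residuals with Blom
plotting positions; the Q-Q correlation is attached (NaN for constant
residuals).

## GFAP quantification

Mean raw 8-bit intensity in five 150 × 150 μm ROIs per subregion per
slice. Placement is seeded-random rejection sampling inside the region
mask — a reproducible stand-in for manual selection — requiring ≥80% of
ROI pixels inside the region and no overlap between ROIs; regions that
cannot host five ROIs are skipped with a warning. ROIs may contain plaque
pixels (as manually placed ROIs plausibly did); passing a plaque mask
switches to the exclusion mode for sensitivity analysis. No background
subtraction or normalisation is applied, matching quantification of raw
intensities under fixed acquisition settings. Aggregation: per-animal
mean per region, then cohort mean/median/SD across all ROI points. Note
that the 80%-inside rule lets up to a fifth of an ROI sample a
neighbouring region, which biases a region's mean toward its neighbours
by up to ~0.2× the intensity gap — visible with the synthetic band mask,
smaller with realistically wide anatomical regions.

## Reporting

Percent change is 100·(m_new − m_ref)/m_ref, computed on EMMs for
stiffness and on cohort ROI means for GFAP (each panel mirrors what its
source analysis estimates; whether a published heatmap used EMMs or raw
pooled means is generally ambiguous — EMMs are the package's choice and
are recorded here). Summaries round to whole percent; CSVs keep full
precision. Significance flags default to adjusted p < 0.001 and render as
directional arrows. The heatmap stage is a pure function of the stage
CSVs, so figures are exactly reproducible from saved artifacts.

## Synthetic data generator

**Force curves** are exact equilibria of the coupled system
F = a·δ^{3/2}, δ = (z − z_c) − F/k, solved per sample by fixed-point
iteration to 10⁻¹² relative tolerance; exactness is what makes round-trip
fitting tests meaningful at 10⁻⁶. Baseline tilt (nN/μm) and Gaussian
force noise (nN) are added through the spring constant; the ramp stops at
the 15 nN setpoint; pre-contact travel is at least 6 μm and at least 55%
of the post-contact travel so the 30% baseline window stays pre-contact.
Sampling is 0.05 μm per point (10 μm/s approach at ~200 Hz equivalent).

**Cohorts** follow the reference study design: 3-month wild type n = 12,
18-month wild type n = 11, 17-month APP knock-in n = 4; 200 points per
analysis group per animal by default (the order of per-region point
counts a 30 μm map yields). Each animal gets an additive normal intercept
(SD = 15% of the grand calibration mean ≈ 41 Pa); within animal × group,
moduli are log-normal — positive and right-skewed like measured tissue
moduli — with mean equal to calibration-plus-intercept (floored at 1% of
the calibration mean) and CV 0.35, a spread under which the ±2SD rule
removes ≲5% of points. The calibration table anchors the cells with
reference values (CA1 pyramidal 546/491/251 Pa, CA1 SO/SR 396/409/275,
DG granule 180/311/139, CA3 pyramidal 168 and Hilus/CA3 196 in young
wild types); cells without a reference value (SLM, ML, aged/APP CA3 and
Hilus) are package choices consistent with the qualitative pattern
(stable SLM/ML; slight, non-significant CA3/Hilus softening under
pathology). The CA1 SO/SR group mean is treated as a pooled-point mean
over both strata. No within-region variance or distribution family is
available from reference data: log-normal/CV 0.35/15% animal SD are
stated assumptions of this package, chosen once, not fitted.

**GFAP images** are per-region base intensities plus Gaussian detector
noise plus Poisson-placed bright disks (default 15 μm radius, +60 levels,
20 plaques/mm² in the APP cohort only), clamped to [0, 255]. The
intensity table is synthetic, emulating the qualitative pattern: stable
reactivity with aging except a dentate decrease, and broad elevation
under amyloid pathology. The band mask (ten vertical strips) is synthetic
anatomy: it gives every label contiguous territory but none of the
curved geometry, thickness variation or boundary uncertainty of real
hippocampal layers.

**What passing tests show — and don't.** Parameter-recovery results
demonstrate that the pipeline is unbiased (up to the documented trimming
effect) *under its own generating assumptions*: Hertzian contact, additive
animal effects, log-normal within-animal spread, exchangeable points. They
do not validate those assumptions against real tissue, which exhibits
viscoelasticity, spatial correlation along maps, slice-to-slice variation
(not modelled; animals are the only nesting level) and heavier tails.

## Problem sizes and determinism

Default verification runs use 20 replicate full-size cohorts (37,800
points each) for parameter recovery, 500 small-design replicates for null
calibration, 200 reduced cohorts (20 points per cell) for interval
coverage, and 500 noisy curves for fit-bias checks. Every random stage
takes an explicit seed (numpy Generator); pipeline stage seeds derive
from the single run seed, and two runs with the same configuration are
bitwise-identical in their CSV outputs.

## Known limitations

* Simple Hertz only; apparent moduli at large strain on soft tissue carry
  model error that cancels in percentage comparisons but not in absolute
  values.
* Contact-point detection assumes a monotonic approach with a flat(tened)
  baseline; strong interference fringes would need a richer baseline
  model.
* The Tukey adjustment treats the estimated contrast correlation and the
  containment df as known; both are approximations, biased conservative
  in the measured calibration.
* Region masks are inputs; no registration between the AFM field and
  histology is attempted, and plaque biology is reduced to intensity
  disks.
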