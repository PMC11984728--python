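# Methods

This note records the model, the numerical choices and their rationale, and
the known limitations of the `cardiopcct` measurement chain.

## Phantom and physics model

The dynamic phantom is an 8-structure voxelised mouse heart (LV, RV, LA, RA,
aorta, venae cavae, pulmonary artery, myocardium; label 0 is background) on
an isotropic grid (default 64³ at 0.125 mm). Ventricular and atrial
ellipsoids are rescaled per cardiac phase so the voxel-counted LV and RV
volume curves realise the prescribed ejection fractions (defaults 50% / 45%)
at the prescribed heart rate (default 480 beats/min, i.e. 8 Hz); vessels are
static. Truth volumes are voxel counts, so metric recovery can be assessed
without discretisation bias.

Blood is water plus iodinated contrast (default 10 mg/mL); myocardium is
soft tissue. Linear attenuation is evaluated at each energy bin's effective
energy:

* water and soft tissue use embedded mass-attenuation table excerpts
  (log–log interpolated); water tracks reference tabulations within 5% over
  20–80 keV, which is asserted in tests;
* iodine uses an effective analytic photoelectric + Compton model with the
  K-edge step at 33.2 keV. It is an *effective* model: it reproduces the
  K-edge contrast mechanism, not tabulated iodine values.

Bin effective energies are flat-spectrum midpoints of the threshold
intervals (for thresholds 25/34/50/60 keV at 80 kVp: 29.5, 42, 55, 70 keV);
the first two bins bracket the K-edge.

Acquisition simulates one exposure per time step (default 10 ms) along a
continuously rotating parallel-beam gantry (default 1260° total), with
Poisson counting noise at a per-pixel-per-exposure flux. Projections are
line integrals from a sparse slice-stacked 2D projector (bilinear footprint,
0.5° angle quantisation with block caching). The projector's forward/adjoint
pair passes a dot-product test at machine precision, which the iterative
solver relies on.

## Intrinsic gating

The cardiac surrogate is the total log-attenuation of each exposure (sum of
all detector pixels and bins). For parallel rays this is angle-invariant up
to discretisation, and it peaks at end-diastole when the iodinated blood
volume is largest. An alternative detector-row centre-of-mass surrogate with
naive local-maxima peak picking was evaluated and rejected: on simulated
streams its timing jitter (~0.07 cycles) reduced phase-bin accuracy to
38–53%, whereas the implemented detector reaches ≥ 92% at protocol dose.

Processing: (1) band-pass 5–12 Hz (300–720 beats/min, bracketing
anaesthetised mouse heart rates); (2) heart rate from the parabolic-refined
periodogram peak; signal presence is tested on the *raw* surrogate's
periodogram (in-band peak ≥ 50× the off-band median) so that band-pass
filtering cannot manufacture a "signal" out of noise; (3) re-filter in a
narrow band (0.8–1.25× the located rate); (4) peak times from the smoothed,
detrended analytic (Hilbert) phase's upward crossings of 2πk, which averages
timing noise over ~1 s while following slow drift; (5) each exposure gets
`floor(n_phases · fractional R–R position)`; exposures outside the first and
last peak are dropped and reported. A split-half frequency comparison warns
when the rate is non-stationary.

## Reconstruction

`iterative_reconstruct` minimises the surrogate objective
`||Ax − y||² + λ·R(x)` per phase/energy cell, where `R` couples cells: joint
bilateral smoothing shares one edge-weight field per phase across energy
bins, and patch-wise temporal singular-value soft-thresholding suppresses
incoherent phase-to-phase fluctuations.

* Data step: block-CGLS (a few conjugate-gradient least-squares inner
  iterations per outer pass). A SART-preconditioned gradient step was tried
  first and rejected: it converged far too slowly for the noiseless
  λ=0 contract (12% RMSE after 30 sweeps vs < 2% required; CGLS reaches
  1.8% in under a second on the 32² toy).
* Monotonicity contract: a damped line search never accepts an objective
  increase (candidate steps are blend-halved on failure); three consecutive
  failed outer iterations raise a divergence error carrying the objective
  log. On the strongly-undersampled gated problem (2400 exposures split
  into 10 phases) the regularised objective with λ=0.2 from an FBP start is
  not monotone and the solver raises per contract — the end-to-end protocol
  therefore runs λ=0 (pure CGLS), and the regulariser is exercised on
  problems where the surrogate descends.
* FBP (ramp-filtered back-projection) provides the initialiser and warns on
  < 180° angular coverage. Its interior bias on small disks is ~5% of peak
  regardless of view count, which is why it is an initialiser and not the
  estimator.

## Material decomposition

Per voxel, bin attenuations `X` are modelled as `X = M·C` with `M` the
sensitivity matrix (basis-material attenuation per unit concentration at
each bin energy) and `C ≥ 0` concentrations. `M` comes from the physics
model (`iodine_ca_water` for ≥ 3 bins, `iodine_water` for 2, `auto`
selects by bin count) or from calibration measurements. The solver is an
active-set non-negative least squares (most-negative-first removal plus
KKT-checked re-entry, Lawson–Hanson semantics); a vectorised
exhaustive-subset path handles large voxel batches. Tests pin it to an
independent brute-force constrained optimum to 1e−8 on random voxels; on
the noiseless phantom the blood-pool iodine concentration is recovered to
0.1% and the reported condition number flags ill-posed bases.

## Segmentation

Two engines behind one evaluation interface:

* Competitive seeded region growing on a min-heap: all structures grow
  simultaneously in order of intensity distance to their seed mean, each
  with a tolerance (absolute or a fraction of the robust 1–99 percentile
  intensity range). Morphological closing optionally fills noise holes.
* A compact NumPy 3D U-Net (hand-coded backprop, Adam, cross-entropy,
  random-crop/rotation/intensity augmentation). Gradients are verified
  against finite differences; a 2-volume toy overfits to Dice > 0.95 in
  ~3 s. It is a CPU-scale network for the full train/predict/evaluate
  contract, not a GPU-scale segmenter.

Evaluation reports per-structure Dice, Jaccard, precision, recall and
accuracy, with absent classes reported as NaN (not 0), and aggregates with
the *sample* (n−1) standard deviation — the convention that reproduces the
embedded reference score table exactly.

Segmentation of reconstructions uses the lowest-energy-bin CT volume, where
iodine contrast is strongest. The two-bin iodine map was evaluated as an
input and rejected: with bins 25–34/34–80 keV the decomposition condition
number is ≈ 227 and the per-voxel iodine estimates have within-class spread
comparable to their mean — consistent with the reference finding that
CT-input segmentation outperforms iodine-map input.

## Metrics

From the phase-resolved labels: ED/ES are the max/min of the LV volume
curve (indices logged); SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR,
CI = CO/mass; myocardial mass averages exactly the diastolic and systolic
myocardial volumes times 1.053 g/mL. RV metrics carry an `RV` prefix;
RVEF is stored as a fraction with an explicit unit flag and never silently
rescaled. Heart rate comes from the gating stage (single source of truth).
`percent_group_difference` evaluates group-mean percent differences on any
cohort table; narrative percent statements that contradict the embedded
group-mean table are catalogued in
`cardiopcct.metrics.INCONSISTENT_RESULTS_STATEMENTS`, not forced.

## Cohort and statistics

`generate_cohort` draws a 140-animal cohort from embedded per-cell
(genotype × sex × exercise) sample sizes and per-cell metric means/SDs,
with a per-genotype HN (humanized NOS2 factor) carrier probability.
Truncated-normal draws are the default (gamma optional for right-skewed
metrics); the embedded tables are population parameters, so cell means
converge to them with n.

The analysis cascade: Shapiro–Wilk (marginal) and median-centred Levene
tests route each metric to full-factorial ANOVA
(`genotype * exercise * sex * hn`), Gamma log-link GLM, or Kruskal–Wallis
with Dunn's post hoc. ANOVA uses Type II sums of squares by default
(`ss_type` exposed; the η² decomposition Ση² + residual = 1 holds exactly
for Type I / balanced designs, and is asserted there). Inestimable terms
(empty 4-way cells, which a random HN draw produces in roughly 1 cohort in
20) are dropped with a warning. Stratified exercised-vs-sedentary
comparisons use Mann–Whitney U — exact for ≤ 8 per arm without ties,
tie-corrected normal otherwise — with one BH-FDR family across all
stratified tests and pooled-SD Cohen's d. The BH step-up adjustment is
written out and cross-checked against statsmodels; the exact U test is
pinned to exhaustive enumeration. Null simulations show the BH
any-rejection rate and the Gamma-GLM per-term type-I error at 0.05 ± 0.01
over 1,000 replicates.

## Desk-scale parameter choices

* **Grid and protocol**: end-to-end runs use 64³ voxels, 10 phases, 2
  energy bins (thresholds 25/34 keV), 2400 exposures over 1260°. Measured:
  ~60 s on one CPU, EF error ≤ 0.5 percentage points, HR error ≤ 0.04%.
* **Dose**: protocol flux is 3×10⁵ counts/pixel/exposure. At 3×10⁴ the
  blood–myocardium contrast in the lowest bin (~0.001 per voxel step)
  is only ~2 reconstruction-noise SDs and region growing leaks or
  collapses; 3×10⁵ brings it to ~6 SDs, after which EF recovery is robust
  to the growing tolerance across 0.08–0.2 of the robust intensity range.
  `AcquisitionSpec` keeps the lower-dose 3×10⁴ default for study-like
  noise levels; the pipeline default is the protocol dose.
* **Iterations**: λ=0 CGLS with 2 outer × 6 inner iterations suffices at
  protocol dose; more iterations sharpen noise faster than edges.
* **Seeds**: every stochastic stage draws a sub-seed (< 2³¹) from a seed
  sequence spawned off the single configured seed; all sub-seeds are
  recorded in the run manifest, and identical seed + config reproduces
  bit-identical artifacts (asserted via output checksums).

## I/O conventions

Volumes are NIfTI-1 with an isotropic diagonal affine (mm); in-memory order
is (z, y, x), file order (x, y, z[, phase, energy]); round trips are
bit-exact. Label maps are uint8 with a JSON class sidecar. Files whose
affine is not canonical (RAS) are reoriented on load and the reorientation
logged; corrupt files fail early with the offending byte offset. Tables are
CSV with full float precision; projection streams are compressed `.npz`
plus a JSON sidecar.

## Limitations

* **APOE2 / cardiac-index regression**: cohorts generated from the embedded
  per-cell means cannot reproduce the qualitative claim that APOE2
  stratified exercise comparisons are non-significant for CI. The embedded
  APOE2-male cell means differ by ~27% in CI (0.484 vs 0.382, Cohen's
  d ≈ 0.9), so stratified tests detect the difference in roughly half of the
  seeds. This is an internal tension of the reference summary tables (the
  underlying raw data must differ from what the printed cell means imply);
  the corresponding acceptance sub-check is left failing rather than
  weakened. The EF and RVEF sub-claims pass (≥ 80% of seeds), as do all
  other qualitative regressions.
* The iodine attenuation model is effective, not tabulated; 2-bin
  decomposition is honest about its conditioning but not quantitative.
* The projector is parallel-beam; cone-beam effects, scatter, detector
  spectral distortion (charge sharing, pile-up) are not modelled.
* The U-Net is CPU-scale (small crops, few channels); it demonstrates the
  training/evaluation contract rather than state-of-the-art accuracy.
* Gating assumes a quasi-stationary heart rate inside the band; it warns on
  drift but does not re-gate adaptively.
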