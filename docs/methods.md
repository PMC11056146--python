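# Methods

`wmhtraj` reimplements, on synthetic cohorts with known ground truth, a
longitudinal analysis of white-matter-hyperintensity (WMH) tissue signatures
in cerebral small vessel disease: two-timepoint quantitative MRI is reduced to
within-mask means over four longitudinal tissue classes — stable
normal-appearing white matter (NAWM), stable WMH, progressing WMH (NAWM at
baseline, WMH at 1 year) and regressing WMH (the reverse) — and those means
feed a repeated-measures statistical battery. The scientific question the
design encodes is whether regressing WMHs follow a different microstructural
trajectory (FA rising, MD and T1 roughly flat) than progressing and stable
WMHs (FA falling, MD and T1 rising).

## The phantom and what it emulates

A subject is a pair of pre-aligned label volumes on a fine "structural" grid
(default 48³ at 1 mm; desk-scale stand-in for a whole head) and a coarse
"diffusion" grid (24³ at 2 mm) covering the same physical extent. The brain is
an ellipsoid with a concentric white-matter core; one spherical "stroke"
lesion and `n_lesions` spherical WMHs (radii 1.8–3.5 mm) are placed inside the
WM. Longitudinal change is rim-based, reflecting that incident WMH change
overwhelmingly appears at the edge of existing lesions: progressing lesions
gain a 1-voxel rim (a configurable fraction appears as de-novo lesions),
regressing lesions lose a 2-voxel shell. The deeper regression shell is
deliberate: it makes regression events span robustly detected interior tissue,
so the measured regression mask has the specificity the real analysis enforced
(strictly WMH at baseline and normal-appearing at 1 year), instead of
consisting solely of partial-volume edge voxels.

Quantitative parameters are assigned **per longitudinal class**: each subject
draws one value per class and parameter from Normal(population mean, SD)
(giving the repeated-measures model a true subject effect), every voxel of the
class shares it, and the 1-year value adds the class's programmed effect.
Within-mask variance in the fitted maps therefore comes from measurement
noise, which is the level the statistics operate on. Class means were chosen
so the cross-sectional orderings match the field's observations (NDI and FA
highest in stable NAWM and lowest in stable WMH; MD, T1 and FWF the reverse;
ODI separating NAWM from all lesional classes).

Signals:

* **Diffusion.** The baseline acquisition is multishell (b = 0×15, 200×3,
  600×6, 1000×64, 2000×64 s/mm²; quasi-uniform Fibonacci directions), the
  1-year acquisition single-shell (b = 0×8, 1000×64), matching the two-visit
  protocol asymmetry that makes NODDI a baseline-only analysis. Noise-free
  signals are the Watson-NODDI forward model evaluated at the voxel's
  (v_ic, ODI, v_iso); noise is Rician (magnitude of signal + complex Gaussian,
  SD = S0/SNR, default SNR 30). Because the generator is the NODDI model, the
  ground-truth FA/MD of a class is *defined* as the iterative-WLS tensor fit
  of its noise-free signal on the b ∈ {0, 1000} subset — a deterministic map —
  and the programmed 1-year effects are specified on the generating parameters
  (v_ic, ODI, v_iso), with the induced FA/MD changes recorded in the truth
  table. The defaults induce the qualitative 1-year pattern under study: FA
  rises only in regressing WMH; FA falls while MD and T1 rise in progressing
  and stable WMH; MD creeps up in stable NAWM.
* **Relaxometry.** SPGR (flips 2°/5°/12°, TR 8 ms — the TR and the IR readout
  flip of 5° are protocol assumptions, not published values) plus IR-SPGR at
  TI 600/1500 ms at baseline; the shortened 1-year protocol keeps flips 2°/12°
  and TI 600 ms. A smooth B1 ramp (0.9–1.1 across the volume) makes the flip
  angle scale a genuinely estimated quantity. Noise is Gaussian, the usual
  high-SNR magnitude approximation in relaxometry.
* **FLAIR.** Voxel noise SD is mean/SNR; non-WM brain tissue sits 4 noise-SDs
  above WM so the *brain-intensity* SD — the reference of the threshold rule —
  is dominated by tissue contrast, as on real images. WMH voxels sit at
  μ_brain + c·σ_brain with per-class contrast c (defaults ≈3 brain-SDs);
  the noise-free field is smoothed (σ = 0.5 voxel) within the brain to emulate
  partial-volume edges. Smoothing never crosses the brain/background edge,
  which would otherwise corrupt the brain statistics at desk scale.

What the phantom does **not** emulate: realistic anatomy, scanner artifacts,
motion, distortion, atrophy, registration error (volumes are generated
pre-aligned; only grid resampling is performed), and voxel-to-voxel biological
heterogeneity within a class. Passing tests therefore demonstrate that the
pipeline recovers programmed effects under idealized alignment and
class-homogeneous tissue — not that it would survive registration failure or
segmentation drift on clinical data.

## Fitting

* **DTI**: log-linear system ln S = ln S0 − b gᵀDg solved by OLS and then
  re-weighted with w = (predicted S)², iterated (default 2 passes, 1e-6
  convergence tolerance on the coefficients). Only the b ∈ {0, 1000} subset is
  used; the intermediate and high shells feed NODDI exclusively. Nonpositive
  signals are replaced by the voxel's smallest positive signal before the log;
  negative eigenvalues are clamped to 1e-12 so FA stays in [0, 1].
* **Watson-NODDI**: three compartments — Watson-dispersed sticks
  (d_par = 1.7e-3 mm²/s), a tortuosity-coupled extracellular tensor
  (d_perp = d_par(1 − v_ic), axial/radial mixing through the Watson alignment
  τ₁ = ⟨(n·μ)²⟩), and isotropic free water (d_iso = 3.0e-3 mm²/s) — the
  standard in-vivo diffusivity defaults. τ₁ uses the Dawson-function closed
  form with a power series below κ = 0.5 to avoid cancellation; the
  intracellular integral uses Gauss-Legendre × azimuthal-midpoint spherical
  quadrature (32 × 16 nodes, growing with κ so the sharpening Watson peak
  stays resolved). The fit is a grid search over (v_ic, v_iso, ODI) — one
  quadrature per ODI candidate, linear mixing for the rest — with μ
  initialized from the DTI principal eigenvector, followed by bounded
  nonlinear least squares on all five parameters.
* **DESPOT1-HIFI**: joint (T1, M0, B1) least squares of the SPGR equation and
  the ideal-inversion IR-SPGR equation |M0 sin(B1α)(1 − 2e^(−TI/T1))| — a
  simplification of the full segmented-readout recursion; generator and
  fitter share it, keeping the analysis self-consistent. For a fixed B1 the
  SPGR subproblem is the linear DESPOT1 regression (slope e^(−TR/T1)), so the
  volume fitter scans B1, picks among near-tied local minima the one closest
  to the nominal scale (the IR magnitude fold admits a second exact root when
  only one TI is acquired), and refines by ternary search. The shortened
  1-year protocol does not identify B1 at all under this model, so
  longitudinal runs fix the follow-up B1 at the baseline estimate — B1 is a
  coil/positioning property and is constant across visits in the phantom.

## Segmentation and change masks

WMH candidates are voxels above mean + 1.69·SD of brain tissue; a
lesion-distribution prior below 0.1 vetoes candidates; the candidate indicator
is Gaussian-smoothed (σ = 0.5 voxel) and re-binarized at 0.5 (removing
isolated speckle); candidates with intensity Z < 0.95 are dropped. The
reference statistics are refined once with first-pass hyperintensities
excluded: at realistic lesion loads (~1% of brain) this changes nothing, but
at desk scale (~4%) it stops the threshold from tracking the per-visit lesion
volume, which would otherwise carve spurious change rings off stable lesion
edges. The Z-score rule uses the same refined brain statistics (the natural
reading; the referent is not pinned down by the source description). Stroke
voxels are excluded from the WMH masks, and NAWM is the WM mask minus WMH and
stroke.

The four class masks are pure set intersections of the two visits' NAWM/WMH
masks; voxels in neither intersection (e.g. WMH→stroke) belong to no class.
Structural-space volumes (mL) are computed *before* cluster filtering;
clusters under 5 voxels (26-connectivity by default; 6 available) are removed
before nearest-neighbor resampling onto the quantitative grids. Resampling
maps each target voxel center to the nearest source center, ties toward the
lower index.

## Statistics

Per parameter and timepoint, a one-way repeated-measures ANOVA across the four
classes (complete cases only), with the Greenhouse-Geisser ε̂ =
(Σλ)²/((k−1)Σλ²) from the double-centered condition covariance, clipped to
[1/(k−1), 1]; corrected p from F at ε-scaled dfs. Tukey HSD contrasts use the
pooled within-subject MS_error (SE = √(2·MS_err/n), studentized range with
(k−1)(n−1) df); a per-pair paired-difference SE mode (df n−1) is available for
sensitivity analysis. Tukey CIs use the uncorrected error df. Longitudinal
change is assessed by classical paired t tests per class for FA, MD and T1,
Holm-adjusted over the joint 12-test family — the family size implied by the
published adjusted values. All tests are two-sided at α = 0.05 with 95% CIs.

A note on calibration: with the estimated ε the GG correction is slightly
conservative under mild non-sphericity (ε̂ is downward-biased at n = 20) and
essentially exact under strong non-sphericity, where the uncorrected F is
markedly anticonservative. The acceptance checks therefore probe the strongly
non-spherical regime (true ε ≈ 0.68, within the range implied by the study's
printed dfs), where both the nominal level and the necessity of the
correction are visible.

## Problem sizes and numerical choices

Default grids are 48³/24³ with 20 lesions and SNR 30; cohort runs use n = 20
subjects for the longitudinal battery. NODDI class means are estimated on a
deterministic per-class subsample of at most 60 voxels (the within-mask mean
of a class-homogeneous phantom is estimated, not exhaustively averaged),
keeping the baseline-only NODDI analysis at desk scale. Optimizer tolerances:
1e-6 (WLS coefficients), 1e-10/1e-12 (bounded least squares); B1 grid 51
points on [0.5, 1.5] with 40 ternary iterations. Degenerate inputs (all-zero
voxels, rank-deficient direction sets, empty masks, single-voxel brain masks,
zero within-subject covariance) are flagged or rejected rather than silently
fitted.

## Known limitations

Class-homogeneous tissue overstates the purity of within-mask means relative
to real data; segmentation-edge displacement still biases the small change
classes toward their neighbors (quantified in the tests at ≲0.02 FA / 0.07 MD
units noise-free) even though programmed *changes* are recovered cleanly; the
IR model omits the segmented readout; no registration or distortion is
simulated; and the probabilistic lesion prior is a dilated WM mask, not a
population template.
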