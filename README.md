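# wmhtraj

Longitudinal white-matter-hyperintensity (WMH) tissue-signature analysis on
synthetic quantitative-MRI cohorts.

WMHs — the bright FLAIR lesions of cerebral small vessel disease — do not only
grow: discrete areas can also regress back to normal-appearing white matter
(NAWM). Whether regression reflects genuine tissue improvement or measurement
error can be probed with quantitative MRI: within each subject, tissue is
classed as stable NAWM, stable WMH, progressing WMH (NAWM → WMH over a year)
or regressing WMH (WMH → NAWM), and fractional anisotropy (FA), mean
diffusivity (MD), quantitative T1 and NODDI indices (NDI, ODI, FWF; baseline
only) are compared across classes and over time. The expected signature of
genuine regression is FA rising in regressing WMHs while FA falls and MD/T1
rise in progressing and stable WMHs.

Because the underlying patient cohort is not public, `wmhtraj` rebuilds the
entire analysis as a tested pipeline over synthetic subjects with known ground
truth:

* `wmhtraj.phantom` — two-timepoint phantoms: label volumes with rim-based
  lesion progression/regression, Watson-NODDI diffusion signals (multishell at
  baseline, single-shell at 1 year) with Rician noise, SPGR/IR-SPGR volumes
  for T1 mapping, FLAIR-like volumes, masks and a ground-truth table.
* `wmhtraj.qmri` — fitters: iterative weighted-least-squares diffusion tensor
  (FA = √(½·Σ(λᵢ−λⱼ)²/Σλᵢ²), MD = mean eigenvalue), Watson-NODDI
  (A = (1−v_iso)[v_ic·A_ic + (1−v_ic)·A_ec] + v_iso·e^(−b·d_iso)) and
  DESPOT1-HIFI T1 with joint B1 estimation.
* `wmhtraj.segmentation` — hierarchical FLAIR thresholding
  (mean + 1.69 SD, probabilistic-prior veto, smoothing, Z ≥ 0.95) and NAWM by
  subtraction.
* `wmhtraj.change_masks` — four-class intersection logic, <5-voxel cluster
  exclusion, nearest-neighbor resampling, structural-space volumetrics.
* `wmhtraj.stats` — repeated-measures ANOVA with Greenhouse-Geisser
  correction, Tukey HSD post hocs, paired t tests with Holm adjustment.
* `wmhtraj.pipeline` — end-to-end orchestration with reproducible seeds.

## Worked example

```python
from wmhtraj.pipeline import RunConfig, run_cohort

cfg = RunConfig(n_subjects=8, master_seed=7)   # desk-scale synthetic cohort
cohort, res = run_cohort(cfg)

a = res["cross_sectional"]["fa_bl"]["anova"]
print(f"baseline FA ANOVA: F({a.df1:.1f}, {a.df2:.1f}) = {a.f:.1f}, "
      f"eps = {a.epsilon:.2f}, p = {a.p:.2e}")
for r in res["paired"]["fa"]:
    print(f"FA {r.label:<16} delta = {r.estimate:+.4f} "
          f"[{r.ci_low:+.4f}, {r.ci_high:+.4f}]  p_holm = {r.p_holm:.2e}")
v = res["sign_pattern"]
print(f"programmed effects recovered: {v['n_matching']}/{v['n_programmed']}")
```

prints

```
baseline FA ANOVA: F(2.3, 16.0) = 38.8, eps = 0.76, p = 4.18e-07
FA stable_nawm      delta = -0.0025 [-0.0030, -0.0020]  p_holm = 3.43e-05
FA stable_wmh       delta = -0.0224 [-0.0264, -0.0185]  p_holm = 1.72e-05
FA progressing_wmh  delta = -0.0333 [-0.0373, -0.0293]  p_holm = 1.84e-06
FA regressing_wmh   delta = +0.0198 [+0.0159, +0.0238]  p_holm = 3.43e-05
programmed effects recovered: 8/8
```

The cross-sectional ANOVA separates the four tissue classes
(Greenhouse-Geisser-corrected dfs), and the paired tests recover the
programmed 1-year pattern: FA falls in stable NAWM, stable WMH and progressing
WMH but *rises* in regressing WMH — the signature distinguishing genuine
regression from noise. With an output directory set
(`cfg.out_dir = Path("results")`), per-contrast Tukey tables, the paired-test
table, class volumes (mL) and a JSON run summary are written as CSV/JSON.

The same stages are scriptable from a shell:

```bash
wmhtraj run --seed 7 --n-subjects 8 --out results/
wmhtraj phantom make --out cohort/ --seed 1 --n-subjects 2
wmhtraj segment --flair cohort/sub-000/flair_bl.nii.gz \
    --brain-mask cohort/sub-000/brain_mask.nii.gz \
    --prior cohort/sub-000/template_prior.nii.gz --out wmh.nii.gz
```

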