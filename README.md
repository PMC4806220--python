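# lesionrate

Longitudinal morphometry of cerebral small vessel disease: white-matter
hyperintensity (WMH) segmentation, diffeomorphic per-voxel rate maps, and
voxel-wise statistics — exercised end to end on synthetic longitudinal brain
phantoms with analytic ground truth.

## The problem

In small vessel disease, confluent WMH grow year on year while the brain —
chiefly cortical grey matter — atrophies. Quantifying *where* and *how fast*
both processes run, and whether they are coupled, requires a longitudinal
pipeline that (a) segments lesioned brains correctly, (b) measures local
tissue change without conflating it with lesion-driven misclassification,
and (c) supports voxel-wise inference across a cohort. `lesionrate`
implements such a pipeline for researchers in neuroimaging methods:

1. **Phantom** — synthetic cohorts of two-channel (T1-like, FLAIR-like)
   longitudinal series on ~1 mm isotropic grids. Atrophy is a global
   exponential contraction `x -> c + exp(a t)(x - c)` about the brain
   centroid `c`, so the true stationary velocity field is `v(x) = a (x - c)`
   and its divergence is exactly `3a` — every downstream stage has a
   closed-form oracle. WMH grow radially from periventricular seeds at
   `g` mm/year; per-subject rates `(a_i, g_i)` follow a bivariate normal
   with configurable correlation `rho`.
2. **Segmentation** — EM on a multivariate Gaussian mixture with spatially
   varying class priors (population tissue probability maps, TPMs),
   bootstrapped from a first intensity-anchor pass. WMH is a fourth class,
   GM-like on T1 and bright on FLAIR.
3. **Repair** — WMH posterior and grey-matter mass reassigned to white
   matter inside the lesion mask; lacunes reclassified to their most likely
   healthy tissue via the TPMs, identically at all time points; brain-mask
   cleanup. Repaired {GM, WM, CSF} again partition the tissue mass.
4. **Registration** — stationary-velocity-field (SVF) demons with
   scaling-and-squaring: each subject's time points are registered to an
   individual mid-point average; the per-time-point velocity divergence,
   regressed voxel-wise against acquisition time, yields a **rate map** in
   1/year (negative = local tissue loss). Individual averages are then
   registered to a group template.
5. **Group maps** — warped tissue x rate products, a lesion-presence
   normalized WMH rate map (voxel average over lesioned subjects only), and
   voxel-based quantification (VBQ) weighted smoothing
   `G*(w p)/G*(w)` at 6 mm FWHM.
6. **Volumetrics** — threshold-count volumes, total cerebral / intracranial
   volume (probability threshold 0.2), per-subject annualized least-squares
   rates, percent change, inter-rater reliability metrics (SEM, percent
   variability, ICC(2,1)), and cohort statistics.
7. **Voxel statistics** — voxel-wise multiple regression of VBQ rate maps
   (effect of interest plus confounds: baseline age, sex, lacune volume,
   TIV, baseline WMH volume), one-sided contrasts, and family-wise-error
   control by Freedman-Lane max-statistic permutation.

## Worked example

Recover a known atrophy rate from a noise-free subject (three annual-ish
visits, true atrophy `a = -0.01`/year, so the true volumetric rate is
`3a = -0.03`/year everywhere in the brain):

```python
from lesionrate.experiments import rate_map_recovery
out = rate_map_recovery(seed=1, grid=64, atrophy_rate=-0.01)
print(f"mean rate  {out['mean_rate_per_year']:+.4f} /yr "
      f"(truth {out['true_rate_per_year']:+.4f})")
print(f"GM voxels with negative rate: "
      f"{100 * out['gm_negative_sign_fraction']:.1f}%")
```

prints

```
mean rate  -0.0352 /yr (truth -0.0300)
GM voxels with negative rate: 96.2%
```

i.e. the estimated rate map carries the right magnitude (registration
regularization biases it slightly) and the right sign in essentially all
interior grey matter. A cohort-level run ties WMH growth to atrophy:

```python
from lesionrate.experiments import cohort_rate_correlation
out = cohort_rate_correlation(seed=1, n_subjects=40, grid=64)
print(f"GM-rate vs WMH-rate Pearson r = {out['pearson_r']:+.2f}")
```

```
GM-rate vs WMH-rate Pearson r = -0.67
```

recovering (at desk scale) the negative coupling the generator imposed
(`rho = -0.7`): subjects whose lesions grow faster lose grey matter faster.

The file-based pipeline with resume and provenance is driven by a YAML
config:

```bash
lesionrate run --config run.yaml          # phantom ... vbm, resumable
lesionrate phantom --out cohort/ --seed 7 # cohort of NIfTI series + truth
lesionrate --version
```

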