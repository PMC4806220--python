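# Methods

This note documents the models, numerical choices and limitations behind
`lesionrate`. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic longitudinal phantom

**Geometry.** Baseline anatomy is a set of nested ellipsoids: ventricular
CSF inside white matter (WM) inside a grey-matter (GM) ribbon, all inside a
fixed intracranial (ICV) ellipsoid; the gap between brain surface and ICV is
sulcal/subarachnoid CSF several voxels thick. Semi-axes are fixed fractions
of the grid extent; generation errors out if the GM ribbon is thinner than
two voxels.

**Atrophy model.** A point at baseline position `p` sits at
`c + exp(a t)(p - c)` at time `t` years, with `c` the brain centroid and `a`
the per-subject atrophy rate (negative = contraction). This map was chosen
because its generating stationary velocity field `v(x) = a (x - c)` has the
closed-form divergence `3a`, giving exact oracles for the registration,
divergence and rate-fitting stages. All tissue labels (including the
ventricles) contract; vacated space inside the fixed ICV becomes CSF. Net
CSF volume therefore expands, emulating sulcal widening; the ventricles
themselves contract slightly, which real atrophic brains do not do — a
deliberate price for an exact analytic truth.

**Lesions.** WMH seeds are placed just outside the ventricular surface, in
deep WM. In baseline coordinates a voxel is lesioned at time `t` when its
distance to the nearest seed is at most `seed_radius + g t` (`g` mm/year),
clipped to WM; the per-time-point masks are accumulated as a running union
so growth is voxel-wise monotone even when atrophy moves the WM boundary
(lesions never heal). Balls live in baseline coordinates, so lesions
contract with their host tissue and the velocity-field truth stays exact.
Lacunes are small fixed spheres in deep WM. On T1 the WMH intensity equals
GM (reproducing the classic GM/WMH misclassification the repair stage
corrects) and lacunes are CSF-like; on FLAIR, WMH is the brightest class and
CSF the darkest.

**Cohort model.** Per-subject rates `(a_i, g_i)` are drawn from a bivariate
normal. Defaults: `a ~ N(-0.010, 0.004^2)` per year (about 1%/year linear,
3%/year volumetric tissue loss — the scale of symptomatic small vessel
disease), `g ~ N(0.5, 0.2^2)` mm/year radial growth on 2 mm seeds (lesion
volume growth of order 10%/year), correlation `rho = -0.7` (faster lesion
growth in subjects with faster atrophy). Visits default to annual
(0, 1, 2, 3 years); an optional dropout pattern truncates each subject's
series after visit `k` with configurable probabilities — the documented
example `(0.21, 0.06, 0.73)` mimics retention in a multi-year clinical
cohort. Channel noise defaults to SD 0.015 per channel, i.e. 5% of the
T1 GM-WM contrast. Everything is seeded; identical parameters and seed give
bit-identical cohorts.

**What the phantom does not emulate.** Cortical folding, bias fields,
motion, slice-thickness anisotropy, partial-volume intensities, scanner
drift, and within-tissue intensity texture. Tests passing on the phantom
therefore demonstrate correctness of the *computational machinery* (exact
oracles, conservation laws, error control) and ground-truth recovery under
idealized contrast — not robustness to real-scanner artefacts.

## Segmentation

Each time point's two-channel intensity vector is modelled as a mixture of
Gaussians with *spatially varying* class priors (the population TPMs),
fitted by EM. Posteriors are prior-weighted responsibilities, so a zero
prior annihilates a class at a voxel regardless of intensity. The
segmentation domain is wherever the prior sum reaches `mask_threshold`
(default 0.1, also the skull-strip threshold).

*Gaussians per class.* Default one per class. The phantom renders each
tissue at a single intensity, so a second component is unidentifiable and —
as observed empirically — drifts onto the neighbouring tissue's intensity
cluster, corrupting volumes. For real MRI with within-class variation,
`gaussians_per_class` accepts 2 (or more) per class; multi-Gaussian classes
are initialized by splitting the class moments ±0.5 SD along the principal
intensity axis.

*Initialization* is deterministic, from prior-weighted intensity moments.
When several classes receive (near-)identical moments — flat priors — the
duplicates are spread deterministically along the principal intensity axis
so EM can break the symmetry. No RNG is involved anywhere in segmentation.

*Bootstrap (first pass).* With no TPMs yet, crude priors are built from
data-driven intensity anchors within the supplied brain-inclusion (ICV)
mask: CSF at the dark T1 tail, GM mid, WM bright, WMH anchored at the mean
of the brightest 0.1% FLAIR voxels (robust to lesion loads below any fixed
quantile, provided lesions exceed ~0.1% of the intracranial volume). A
`background` class with unit prior fills a 6-voxel shell outside the mask so
that smoothing of the pooled TPMs cannot force out-of-brain voxels into a
tissue class. First-pass posteriors, pooled over subjects and time points
(identity alignment — phantom subjects share a grid; with real data this
pooling would happen in a group-average space), smoothed at 4 mm FWHM,
renormalized and floored at 1e-3 inside their support, become the
population TPMs for the second pass.

*WMH binarization* defaults to posterior ≥ 0.5 with connected components
under 5 voxels removed; an `otsu` mode estimates the threshold from the
posterior histogram. Both are stand-ins for per-subject manual
thresholding, not a reconstruction of any rater protocol.

*Convergence:* relative log-likelihood tolerance 1e-5, max 100 iterations
(60 in the pipeline defaults); the log-likelihood trace is recorded and is
non-decreasing. Singular covariances are ridge-regularized.

## Repair

Inside the binary WMH mask, grey-matter probability plus the WMH posterior
mass moves into white matter and GM is zeroed, so repaired {GM, WM, CSF}
remain a partition of the tissue mass — required for the warping stage to
treat them as a 3-class segmentation. CSF inside lesions is left untouched.
The union of lacune masks over time points is mapped into TPM space
(identity when no warp is supplied) and each voxel takes the argmax healthy
class, ties resolved WM > GM > CSF (lacunes live in WM territory), applied
identically at every time point. Brain-mask cleanup moves GM/WM mass within
a 2-voxel margin outside the inclusion mask into CSF and zeroes everything
beyond. Repair is idempotent, local, and mass-conserving (regression-tested
at 1e-4 relative).

Volumes are always computed from *unrepaired* posteriors — repair
redistributes mass between classes by design and would bias class volumes.

## Registration and rate maps

**Model.** A stationary velocity field (SVF) `v`, exponentiated by scaling
and squaring (at least 6 squarings; the number grows so each integration
step moves under 0.25 voxel). This replaces full geodesic shooting: the rate
construction only needs one velocity field per time point, and the SVF's
divergence is well defined and cheap. `register_pair(moving, fixed)` finds
`v` such that `fixed(exp(v)(x)) ~= moving(x)`; `exp(+v)` maps the moving
(reference/average) grid into the fixed image, so registering a template to
a time point contracted at rate `a` yields Jacobian `e^{3a}` and divergence
`3a` — tissue loss over time gives negative rates.

**Optimization.** Demons-style descent on multi-channel
sum-of-squared-differences over tissue probability maps (not raw
intensities): 3 pyramid levels, 30/20/10 iterations coarse-to-fine, force
smoothing (fluid) sigma 1 voxel, velocity smoothing (elastic) sigma 1.5
voxels, step size by backtracking with updates capped at 0.4 voxel; any
update producing a non-positive Jacobian is rejected and the step halved.
The velocity support is the dilated (4-voxel) union of the channel
supports. The elastic sigma of 1.5 was chosen so the boundary-driven
velocity decays *outside* the brain (in the sulcal CSF shell, where
expansion genuinely occurs) rather than bleeding a positive-divergence ring
into cortical GM.

**Subject average.** Initialize the template as the voxel-wise mean of the
time points; iterate (default 3 outer iterations): register every time
point to the template, subtract the mean velocity so the template stays at
the barycenter of the series, re-average the warped maps. Divergences of
the per-time-point velocities, regressed voxel-wise on acquisition time
(years from baseline, explicit input) by ordinary least squares, give the
subject's rate map in 1/year. The group template repeats the same
barycentric scheme across subjects' individual averages and supplies the
group-to-subject deformations used to warp rate maps, tissue templates and
lesion masks to group space.

**Numerical notes.** Divergence uses central differences in world mm
(one-sided at grid edges), computed from the stationary velocity (not the
full warp path — recorded here as the package's convention). Jacobians are
determinants of `I + grad(u)` with the same stencil. Template averaging is
order-invariant to 1e-6 (floating-point summation order only). Rate fitting
is the closed-form OLS slope; voxels with fewer than two valid time points
get rate 0.

**Accuracy envelope** (regression-tested, quantities recomputed by
`scripts/acceptance.py`): mean brain Jacobian recovered within 5% of
`e^{3a}` for a pure contraction; brain-interior mean rate within 30% of
`3a` with the correct sign at ≥95% of interior GM voxels. Registration
regularization biases rate magnitudes toward zero at sharp boundaries and
slightly overshoots inside; the bounds above are the honest envelope at
64^3 desk scale.

## Group maps

Warping to group space is pull-back trilinear interpolation through the
group-to-subject deformation, optionally Jacobian-modulated to preserve
integrated mass. The lesion-normalized WMH rate at a voxel averages only
over subjects whose lesion covers that voxel (minimum count 1 by default);
voxels lesioned in no subject are masked, which is distinct from a zero
rate. VBQ weighted smoothing is `G*(w p)/G*(w)` with a 6 mm FWHM Gaussian;
the weight is the warped tissue probability (GM weight for GM rate maps,
warped WMH template for WMH rate maps), and the output is masked where the
smoothed weight falls below 1e-3 of the mean positive weight. With unit
weight this reduces exactly to plain Gaussian smoothing.

## Volumetrics and cohort statistics

Class volumes count voxels at or above a probability threshold (mass
integration available behind a flag). Total cerebral volume is the region
where GM+WM+WMH ≥ 0.2; total intracranial volume adds CSF, constrained by
the brain inclusion mask. Annualized rates are per-subject OLS slopes over
all available time points; percent change is per subject from baseline,
then summarized (the mean of per-subject percent changes, not the percent
change of means). Reliability: SEM = SD(d)/sqrt(2) for paired differences
d; percent variability 100|d|/pair-mean (mean and SD); ICC(2,1) — two-way
random effects, absolute agreement, single measure — from its ANOVA
decomposition. Cohort tests: Pearson correlation, one-tailed two-sample t
between time points (volumes are expected to fall and lesions to grow),
ANOVA with t follow-up, Kruskal-Wallis; an automatic mode screens normality
with a Shapiro test at alpha 0.05.

## Voxel-wise inference

Rate-map stacks are regressed per voxel on a design of one effect of
interest plus confounds (baseline age, sex coded ±1/2, lacune volume, TIV;
plus baseline WMH volume for GM-rate models), continuous regressors
mean-centered, a single shared pseudo-inverse across voxels. One-sided
hypotheses are signed contrasts. Family-wise error is controlled by
max-statistic permutation under the Freedman-Lane scheme: permute the
residuals of the reduced (confound-only) model, refit the full model, take
the maximum t over the mask; corrected
`p = (1 + #{max-t >= t_obs}) / (n_perm + 1)`. This replaces random-field
theory because it is assumption-light and its error control is directly
verifiable by simulation (the test suite measures the family-wise rejection
fraction over 200 null simulations). Defaults: 1000 permutations (500 in
the batch experiments), mandatory seed, alpha 0.05, clusters by
26-connectivity. Contrasts are reported separately; no correction across
the contrast family is applied by default.

**Localization experiment.** The synthetic cohort for the voxel-wise
localization check draws global atrophy with near-zero variance
(`atrophy_rate_sd = 0.001`) and zero rate correlation, and injects an extra
GM contraction proportional to the subject's WMH growth z-score
(amplitude 0.005/year) inside one cortical patch. This isolates the
*regional* lesion-atrophy coupling as the only spatial association the
regression can find; with subject-level global atrophy variance at its
cohort default, the shared global term dominates voxel residuals and a
focal effect of plausible size is not separable at n = 40 — a realistic
power limitation worth knowing about, not a software artefact.

## Pipeline

Stages (phantom, segment, repair, longitudinal, groupmaps, volumes, vbm)
exchange data as NIfTI + TSV under one output directory; each stage records
a parameter hash in `provenance.json`, re-runs skip up-to-date stages, and
a single global seed is fanned out per stage by hashing the stage name
(every derived seed is below 2^31). The vbm stage skips itself (with a
marker file) when the cohort is too small for the design
(`n_subjects <= n_regressors`).

## Problem sizes

Unit tests run on 40^3 grids; ground-truth recovery and acceptance
experiments on 64^3 grids with 40-subject cohorts, 200 null simulations,
and 500 permutations. These sizes exercise every algorithmic path of the
method; larger grids change memory and wall time, not code paths.

## Known limitations

- The phantom's idealized contrast makes segmentation nearly perfect;
  segmentation accuracy numbers do not transfer to real MRI.
- Rate-map magnitudes are biased toward zero by registration
  regularization (documented envelope ±30% at desk scale).
- The demons SVF is a model substitution for geodesic shooting; velocity
  fields agree in divergence structure but are not geodesic momenta.
- Lacune repair approximates the expected healthy tissue from priors; it
  does not in-paint from neighbourhood context.
- Random-field-theory FWE, TFCE and cluster-extent inference are out of
  scope; only max-statistic voxel-level permutation is provided.
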