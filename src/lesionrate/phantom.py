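"""Synthetic longitudinal brain phantom with analytic ground truth.

The phantom emulates the structure of a longitudinal small-vessel-disease
cohort: per subject, 2-4 annual time points of co-registered T1-like and
FLAIR-like volumes on an isotropic ~1 mm grid, containing grey matter (GM),
white matter (WM), CSF, confluent periventricular white matter
hyperintensities (WMH) that grow over time, and optional lacunes.

Generative model
----------------
* Baseline anatomy: nested ellipsoids — ventricular CSF inside WM inside a GM
  ribbon, all inside a fixed intracranial (ICV) ellipsoid surrounded by
  background.
* Atrophy: global exponential contraction about the brain centroid ``c``;
  a point at baseline position ``p`` sits at ``c + exp(a*t)*(p - c)`` at time
  ``t`` (``a < 0`` = atrophy).  The corresponding stationary velocity field is
  ``v(x) = a*(x - c)`` with divergence exactly ``3a`` everywhere in the brain,
  which gives every downstream registration/divergence stage a closed-form
  oracle.  Space vacated at the brain surface fills with CSF (the ICV shell
  is fixed).
* WMH: spherical seeds on the ventricular margin; in baseline coordinates a
  voxel is lesioned at time ``t`` when its distance to the nearest seed is at
  most ``seed_radius + g*t`` (radial growth ``g`` in mm/year), clipped to
  white matter.  Masks are accumulated over time (lesions never heal), which
  guarantees voxel-wise monotone growth even under atrophy.
* Intensities: per-tissue channel means with additive Gaussian noise.  WMH is
  rendered GM-like on T1 (reproducing the classic GM/WMH misclassification
  that the repair stage must fix) and hyperintense on FLAIR; lacunes are
  CSF-like on both channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import VolumeImage

# integer label codes used in truth maps
BACKGROUND, CSF, GM, WM, WMH, LACUNE = 0, 1, 2, 3, 4, 5
LABEL_NAMES = {BACKGROUND: "background", CSF: "CSF", GM: "GM", WM: "WM",
               WMH: "WMH", LACUNE: "lacune"}
TISSUE_CLASSES = ("CSF", "GM", "WM", "WMH", "lacune")

#: default per-tissue (T1, FLAIR) channel means, arbitrary units in [0, 1].
#: Ordering constraints: T1 WM > GM > CSF with WMH == GM on T1; FLAIR WMH
#: bright, CSF dark; lacune == CSF on both channels.
DEFAULT_CHANNEL_MEANS = {
    "background": (0.02, 0.02),
    "CSF": (0.25, 0.15),
    "GM": (0.70, 0.60),
    "WM": (1.00, 0.55),
    "WMH": (0.70, 1.00),
    "lacune": (0.25, 0.15),
}

# ellipsoid semi-axes as fractions of the full grid extent per axis; the ICV
# pad leaves a sulcal/subarachnoid CSF shell several voxels thick so the
# expansion that balances brain contraction happens in CSF, not at the grid edge
_BRAIN_FRAC = np.array([0.40, 0.38, 0.34])
_WM_SCALE = 0.76       # WM ellipsoid relative to brain ellipsoid
_VENT_SCALE = 0.32     # ventricular CSF relative to brain ellipsoid
_ICV_PAD_FRAC = 0.06   # ICV ellipsoid = brain fractions + this


@dataclass
class PhantomParams:
    """Cohort-level generator parameters; defaults are the study conditions.

    Rates follow the bivariate-normal model ``(a, g) ~ N(mu, Sigma)`` with
    correlation ``rate_correlation_rho`` (negative: faster WMH growth in
    subjects with faster atrophy).  Default atrophy mean -0.010/year gives
    ~1%/year linear tissue loss (~3%/year volumetrically over the brain at
    the divergence level 3a = -0.03/year); default radial WMH growth
    0.5 mm/year on 2 mm seeds yields confluent lesion growth of order 10%
    volume per year, matching the scale of symptomatic small vessel disease.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    n_subjects: int = 10
    times_years: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    atrophy_rate_mean: float = -0.010
    atrophy_rate_sd: float = 0.004
    wmh_growth_mean: float = 0.5
    wmh_growth_sd: float = 0.2
    rate_correlation_rho: float = -0.7
    n_wmh_seeds: int = 6
    seed_radius_mm: float = 2.0
    n_lacunes: int = 2
    lacune_radius_mm: float = 1.5
    channel_means: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MEANS))
    noise_sd: tuple[float, float] = (0.015, 0.015)
    random_seed: int = 0
    #: optional probability that a subject's series *ends* after time point k
    #: (index >= 1); ``None`` keeps every subject complete.  A pattern that
    #: emulates annual-visit dropout over 4 visits is ``(0.21, 0.06, 0.73)``.
    dropout_probs: tuple[float, ...] | None = None

    def validate(self) -> None:
        if min(self.grid_shape) < 32:
            raise ValueError("grid_shape must be >= 32 voxels per axis")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if abs(self.rate_correlation_rho) > 1:
            raise ValueError("|rate_correlation_rho| must be <= 1")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times_years, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times_years must be strictly increasing with >= 2 entries")
        if self.atrophy_rate_sd < 0 or self.wmh_growth_sd < 0:
            raise ValueError("rate SDs must be non-negative")


@dataclass
class Timepoint:
    t1_image: VolumeImage
    flair_image: VolumeImage
    time_years: float
    lacune_mask: VolumeImage


@dataclass
class SubjectSeries:
    """One subject's ordered longitudinal acquisitions."""

    subject_id: str
    timepoints: list[Timepoint]
    covariates: dict = field(default_factory=dict)

    @property
    def times_years(self) -> np.ndarray:
        return np.array([tp.time_years for tp in self.timepoints])


@dataclass
class SubjectTruth:
    """Analytic ground truth accompanying one synthetic subject."""

    a: float                      # atrophy rate, 1/year
    g: float                      # WMH radial growth, mm/year
    labels: list[np.ndarray]      # per time point hard labels (codes above)
    brain_masks: list[np.ndarray]  # per time point contracted brain region
    icv_mask: np.ndarray          # static intracranial region (tissue + CSF)
    velocity: np.ndarray          # (3, X, Y, Z) stationary field a*(x-c), mm/yr
    divergence: np.ndarray        # 3a inside brain at baseline, else 0
    volumes: pd.DataFrame         # per time point per tissue, mm^3
    centroid_mm: np.ndarray


def _grid_coords_mm(shape, voxel_size):
    axes = [np.arange(n, dtype=float) * voxel_size for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_radius_sq(coords_rel, semi_axes):
    """Squared ellipsoid coordinate: <=1 inside the ellipsoid."""
    r = np.zeros_like(coords_rel[0])
    for x, s in zip(coords_rel, semi_axes):
        r += (x / s) ** 2
    return r


def _geometry(params: PhantomParams):
    shape = np.asarray(params.grid_shape)
    extent = shape * params.voxel_size_mm
    centre = (shape - 1) / 2.0 * params.voxel_size_mm
    brain = _BRAIN_FRAC * extent
    geo = {
        "centre": centre,
        "brain": brain,
        "wm": brain * _WM_SCALE,
        "vent": brain * _VENT_SCALE,
        "icv": brain + _ICV_PAD_FRAC * extent,
    }
    ribbon_mm = np.min(geo["brain"] - geo["wm"])
    if ribbon_mm < 2 * params.voxel_size_mm:
        raise ValueError(
            f"degenerate geometry: GM ribbon {ribbon_mm:.2f} mm thinner than 2 voxels")
    return geo


def _place_seeds(params: PhantomParams, geo, rng) -> np.ndarray:
    """WMH seed centres (baseline mm coordinates relative to centroid).

    Seeds sit just outside the ventricular surface, pushed radially into the
    deep white matter so the initial lesion caps the periventricular margin.
    """
    dirs = rng.normal(size=(params.n_wmh_seeds, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # scale each direction onto the ventricular ellipsoid surface
    scale = 1.0 / np.sqrt(np.sum((dirs / geo["vent"]) ** 2, axis=1))
    surface = dirs * scale[:, None]
    return surface + dirs * (params.seed_radius_mm + 1.0)


def _place_lacunes(params: PhantomParams, geo, rng) -> np.ndarray:
    """Lacune centres in deep WM (baseline mm coordinates, rel. centroid)."""
    centres = []
    guard = 0
    while len(centres) < params.n_lacunes and guard < 1000:
        guard += 1
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        rho = rng.uniform(0.55, 0.85)  # fractional position between vent and WM edge
        vent_s = 1.0 / np.sqrt(np.sum((d / geo["vent"]) ** 2))
        wm_s = 1.0 / np.sqrt(np.sum((d / geo["wm"]) ** 2))
        centres.append(d * (vent_s + rho * (wm_s - vent_s)))
    return np.array(centres) if centres else np.zeros((0, 3))


def generate_subject(
    params: PhantomParams,
    subject_index: int,
    rates: tuple[float, float],
    times_years=None,
    covariates: dict | None = None,
) -> tuple[SubjectSeries, SubjectTruth]:
    """Generate one subject's longitudinal series and its analytic truth.

    ``rates = (a, g)``: atrophy rate in 1/year and WMH radial growth in
    mm/year.  Randomness (seed/lacune placement, noise) is derived from
    ``(params.random_seed, subject_index)`` so cohorts are reproducible and
    subjects independent.
    """
    params.validate()
    a, g = float(rates[0]), float(rates[1])
    if not (np.isfinite(a) and np.isfinite(g)):
        raise ValueError("rates must be finite")
    times = np.asarray(params.times_years if times_years is None else times_years,
                       dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("times must be non-negative, strictly increasing, >= 2 points")

    geo = _geometry(params)
    rng = np.random.default_rng([params.random_seed, subject_index])
    seeds = _place_seeds(params, geo, rng)
    lacunes = _place_lacunes(params, geo, rng)

    shape = tuple(params.grid_shape)
    vox = params.voxel_size_mm
    coords = _grid_coords_mm(shape, vox)
    rel = [c - cc for c, cc in zip(coords, geo["centre"])]

    means = params.channel_means
    mean_lut = {
        BACKGROUND: means["background"], CSF: means["CSF"], GM: means["GM"],
        WM: means["WM"], WMH: means["WMH"], LACUNE: means["lacune"],
    }
    icv = _ellipsoid_radius_sq(rel, geo["icv"]) <= 1.0

    labels_t, brain_masks, tps, vol_rows = [], [], [], []
    wmh_acc = np.zeros(shape, dtype=bool)
    for t in times:
        shrink = np.exp(-a * t)  # maps current position back to baseline coords
        pre = [x * shrink for x in rel]
        in_brain = _ellipsoid_radius_sq(pre, geo["brain"]) <= 1.0
        in_wm = _ellipsoid_radius_sq(pre, geo["wm"]) <= 1.0
        in_vent = _ellipsoid_radius_sq(pre, geo["vent"]) <= 1.0

        lab = np.full(shape, BACKGROUND, dtype=np.uint8)
        lab[icv] = CSF                      # ICV shell: sulcal/outer CSF
        lab[in_brain] = GM
        lab[in_wm & in_brain] = WM
        lab[in_vent & in_brain] = CSF       # ventricles

        # lacunes: fixed spheres in baseline coordinates, inside WM
        lac = np.zeros(shape, dtype=bool)
        for c3 in lacunes:
            d2 = sum((p - ci) ** 2 for p, ci in zip(pre, c3))
            lac |= d2 <= params.lacune_radius_mm ** 2
        lac &= lab == WM

        # WMH: distance-to-nearest-seed balls in baseline coordinates
        if len(seeds):
            r_t = params.seed_radius_mm + g * t
            d2min = np.full(shape, np.inf)
            for s in seeds:
                d2 = sum((p - si) ** 2 for p, si in zip(pre, s))
                np.minimum(d2min, d2, out=d2min)
            ball = d2min <= r_t ** 2
            raw = ball & (lab == WM) & ~lac
            if t == times[-1]:
                ball_in_icv = ball & icv
                if ball_in_icv.sum() and raw.sum() < 0.5 * ball_in_icv.sum():
                    warnings.warn("WMH growth clipped by WM extent", stacklevel=2)
        else:
            raw = np.zeros(shape, dtype=bool)
        wmh_acc = wmh_acc | raw  # monotone: lesions never heal
        lab[wmh_acc & (lab != BACKGROUND)] = WMH
        lab[lac] = LACUNE

        labels_t.append(lab)
        brain_masks.append(in_brain)

        imgs = []
        for ch in range(2):
            img = np.empty(shape, dtype=float)
            for code, m in mean_lut.items():
                img[lab == code] = m[ch]
            if params.noise_sd[ch] > 0:
                img += rng.normal(0.0, params.noise_sd[ch], size=shape)
            imgs.append(img)
        tps.append(Timepoint(
            t1_image=VolumeImage(imgs[0], vox),
            flair_image=VolumeImage(imgs[1], vox),
            time_years=float(t),
            lacune_mask=VolumeImage(lac.astype(np.uint8), vox),
        ))
        vv = vox ** 3
        vol_rows.append({
            "time_years": float(t),
            **{name: float((lab == code).sum()) * vv
               for code, name in LABEL_NAMES.items() if code != BACKGROUND},
        })

    velocity = np.stack([a * x for x in rel])  # mm/year
    divergence = np.where(brain_masks[0], 3.0 * a, 0.0)
    truth = SubjectTruth(
        a=a, g=g, labels=labels_t, brain_masks=brain_masks, icv_mask=icv,
        velocity=velocity, divergence=divergence,
        volumes=pd.DataFrame(vol_rows), centroid_mm=geo["centre"].copy(),
    )
    series = SubjectSeries(
        subject_id=f"sub-{subject_index:03d}",
        timepoints=tps,
        covariates=dict(covariates or {}),
    )
    return series, truth


def draw_rates(params: PhantomParams, rng) -> np.ndarray:
    """Draw ``(a_i, g_i)`` pairs from the bivariate normal rate model."""
    sa, sg, rho = params.atrophy_rate_sd, params.wmh_growth_sd, params.rate_correlation_rho
    if abs(rho) > 1:
        raise ValueError("rate covariance is not positive semi-definite")
    cov = np.array([[sa ** 2, rho * sa * sg], [rho * sa * sg, sg ** 2]])
    if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
        raise ValueError("rate covariance is not positive semi-definite")
    mean = [params.atrophy_rate_mean, params.wmh_growth_mean]
    return rng.multivariate_normal(mean, cov, size=params.n_subjects,
                                   check_valid="ignore")


def generate_cohort(params: PhantomParams):
    """Generate a full cohort.

    Returns ``(series_list, truth_list, cohort_table)`` where the table holds
    subject id, baseline covariates and the true rates.
    """
    params.validate()
    if params.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng([params.random_seed, 987654321])
    rates = draw_rates(params, rng)
    n_t = len(params.times_years)

    last_idx = np.full(params.n_subjects, n_t - 1)
    if params.dropout_probs is not None:
        p = np.asarray(params.dropout_probs, dtype=float)
        if p.size != n_t - 1 or not np.isclose(p.sum(), 1.0):
            raise ValueError("dropout_probs must have len(times)-1 entries summing to 1")
        last_idx = rng.choice(np.arange(1, n_t), size=params.n_subjects, p=p)

    ages = rng.normal(69.0, 10.0, size=params.n_subjects)
    sexes = rng.choice(["F", "M"], size=params.n_subjects, p=[0.34, 0.66])

    series_list, truth_list, rows = [], [], []
    for i in range(params.n_subjects):
        times = np.asarray(params.times_years)[: last_idx[i] + 1]
        cov = {"age_baseline": float(ages[i]), "sex": str(sexes[i])}
        s, t = generate_subject(params, i, rates[i], times_years=times, covariates=cov)
        series_list.append(s)
        truth_list.append(t)
        rows.append({
            "subject_id": s.subject_id, "age_baseline": cov["age_baseline"],
            "sex": cov["sex"], "a_true": float(rates[i, 0]),
            "g_true": float(rates[i, 1]), "n_timepoints": len(times),
        })
    return series_list, truth_list, pd.DataFrame(rows)


def write_cohort(series_list, truth_list, cohort_table, out_dir) -> None:
    """Write a cohort as NIfTI volumes plus ``truth.json`` and ``cohort.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_doc, tsv_rows = {}, []
    for series, truth in zip(series_list, truth_list):
        sid = series.subject_id
        for k, tp in enumerate(series.timepoints, start=1):
            stem = f"{sid}_ses-{k}"
            tp.t1_image.save(out / f"{stem}_T1.nii.gz")
            tp.flair_image.save(out / f"{stem}_FLAIR.nii.gz")
            tp.lacune_mask.save(out / f"{stem}_lacune.nii.gz")
            tsv_rows.append({
                "subject_id": sid, "time_years": tp.time_years,
                "age_baseline": series.covariates.get("age_baseline", np.nan),
                "sex": series.covariates.get("sex", ""),
                "a_true": truth.a, "g_true": truth.g,
            })
        truth_doc[sid] = {
            "a": truth.a, "g": truth.g,
            "volumes": truth.volumes.to_dict(orient="list"),
        }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    pd.DataFrame(tsv_rows).to_csv(out / "cohort.tsv", sep="\t", index=False)


def synthetic_rate_map_cohort(
    params: PhantomParams,
    patch_radius_mm: float = 5.0,
    patch_amplitude: float = 0.005,
    map_noise_sd: float = 0.01,
    rho: float = 0.0,
):
    """Cohort of GM rate maps in which WMH growth drives extra focal atrophy.

    Builds, for ``params.n_subjects`` subjects sharing the phantom anatomy,
    per-subject GM contraction-rate maps ``y_i = 3*a_i`` inside the brain plus
    an extra contraction ``-patch_amplitude * z(g_i)`` confined to a cortical
    patch (a sphere centred in the GM ribbon), plus white voxel noise.  By
    default the global rates are drawn with ``rho = 0`` so the patch is the
    only spatial association between the maps and the WMH-growth covariate,
    isolating the regional coupling that voxel-wise regression must localize.

    Returns ``(stack, table, patch_mask, gm_mask)`` with ``stack`` of shape
    ``(n_subjects, *grid_shape)`` and a cohort table carrying the regression
    covariates (wmh_rate, age_baseline, sex, lacune_volume, tiv,
    wmh_baseline).
    """
    params.validate()
    geo = _geometry(params)
    rng = np.random.default_rng([params.random_seed, 271828182])
    p2 = PhantomParams(**{**params.__dict__, "rate_correlation_rho": rho})
    rates = draw_rates(p2, rng)
    a, gmm = rates[:, 0], rates[:, 1]

    shape = tuple(params.grid_shape)
    coords = _grid_coords_mm(shape, params.voxel_size_mm)
    rel = [c - cc for c, cc in zip(coords, geo["centre"])]
    brain = _ellipsoid_radius_sq(rel, geo["brain"]) <= 1.0
    wm = _ellipsoid_radius_sq(rel, geo["wm"]) <= 1.0
    gm_mask = brain & ~wm

    # patch centred mid-ribbon along +x
    centre = np.array([(geo["wm"][0] + geo["brain"][0]) / 2.0, 0.0, 0.0])
    d2 = sum((p - ci) ** 2 for p, ci in zip(rel, centre))
    patch = (d2 <= patch_radius_mm ** 2) & gm_mask

    z = (gmm - gmm.mean()) / (gmm.std() if gmm.std() > 0 else 1.0)
    stack = np.empty((params.n_subjects,) + shape)
    for i in range(params.n_subjects):
        y = np.where(brain, 3.0 * a[i], 0.0)
        y = y - patch_amplitude * z[i] * patch
        y += rng.normal(0.0, map_noise_sd, size=shape)
        stack[i] = y

    # analytic covariates: WMH volume rate from radial growth, nuisance draws
    r0, T = params.seed_radius_mm, float(np.asarray(params.times_years)[-1])
    wmh_rate = params.n_wmh_seeds * (4 / 3) * np.pi * ((r0 + gmm * T) ** 3 - r0 ** 3) / T
    table = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(params.n_subjects)],
        "gm_rate": 3.0 * a,
        "wmh_rate": wmh_rate,
        "age_baseline": rng.normal(69, 10, params.n_subjects),
        "sex": rng.choice(["F", "M"], params.n_subjects, p=[0.34, 0.66]),
        "lacune_volume": rng.gamma(2.0, 150.0, params.n_subjects),
        "tiv": rng.normal(1.4e6, 1e5, params.n_subjects),
        "wmh_baseline": params.n_wmh_seeds * (4 / 3) * np.pi * r0 ** 3
        + rng.normal(0, 50, params.n_subjects),
    })
    return stack, table, patch, gm_mask
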