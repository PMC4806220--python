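"""Tissue and WMH segmentation with population priors.

Each time point's two-channel intensity vector (T1, FLAIR) is segmented into
GM / WM / CSF / WMH posteriors by expectation-maximization on a multivariate
Gaussian mixture with *spatially varying* class priors — the population
tissue probability maps (TPMs).  WMH forms a fourth class driven chiefly by
its FLAIR hyperintensity; on T1 alone it is indistinguishable from grey
matter, which is precisely the misclassification the downstream repair stage
corrects.

The mixture uses a configurable number of Gaussians per class (default 2 for
GM and WM, 1 for CSF and WMH).  Initialization is deterministic, from
prior-weighted intensity moments (no k-means, no RNG), so segmentations are
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import VolumeImage, fwhm_to_sigma


@dataclass
class TissueProbMaps:
    """Per-class probability volumes on a common grid."""

    class_names: list[str]
    maps: dict[str, np.ndarray]
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        shapes = {self.maps[c].shape for c in self.class_names}
        if len(shapes) != 1:
            raise ValueError("all class maps must share one grid")
        for c in self.class_names:
            m = self.maps[c]
            if np.any(m < -1e-6) or np.any(m > 1 + 1e-6):
                raise ValueError(f"probabilities for {c!r} outside [0, 1]")

    @property
    def shape(self):
        return self.maps[self.class_names[0]].shape

    def stack(self) -> np.ndarray:
        return np.stack([self.maps[c] for c in self.class_names])

    @classmethod
    def from_stack(cls, class_names, arr, voxel_size=1.0) -> "TissueProbMaps":
        return cls(list(class_names), {c: arr[i] for i, c in enumerate(class_names)},
                   voxel_size)


@dataclass
class SegmentConfig:
    classes: tuple[str, ...] = ("GM", "WM", "CSF", "WMH", "background")
    #: one Gaussian per class by default: with piecewise-constant synthetic
    #: intensities a second component is unidentifiable and drifts onto the
    #: neighbouring tissue's intensity cluster, corrupting volumes.  Real MRI
    #: with within-class intensity variation warrants 2 for GM/WM.
    gaussians_per_class: dict = field(
        default_factory=lambda: {"GM": 1, "WM": 1, "CSF": 1, "WMH": 1})
    max_iter: int = 100
    tol: float = 1e-5               # relative log-likelihood change
    prior_floor: float = 1e-3       # smallest admissible class prior in-mask
    mask_threshold: float = 0.1     # prior-sum threshold defining the domain
    ridge: float = 1e-6             # covariance regularization (times mean var)
    wmh_threshold: float | str = 0.5
    min_component_voxels: int = 5


@dataclass
class MixtureModel:
    """Fitted prior-weighted Gaussian mixture with its convergence log."""

    class_names: list[str]
    means: list[np.ndarray]          # per Gaussian, (n_channels,)
    covariances: list[np.ndarray]    # per Gaussian, (n_channels, n_channels)
    weights: np.ndarray              # per Gaussian, within-class mixing
    gaussian_class: np.ndarray       # class index per Gaussian
    log_likelihood: list[float] = field(default_factory=list)


def build_population_tpms(label_maps: list[TissueProbMaps],
                          smoothing_fwhm_mm: float,
                          prior_floor: float = 1e-3,
                          brain_mask: np.ndarray | None = None) -> TissueProbMaps:
    """Average per-class probability maps over subjects into population TPMs.

    Maps are voxel-wise averaged, Gaussian-smoothed, renormalized so the class
    sum nowhere exceeds 1, and floored at ``prior_floor`` inside the brain
    mask so no class is ever impossible a priori.
    """
    if len(label_maps) < 2:
        raise ValueError("need >= 2 subjects' maps")
    names = label_maps[0].class_names
    shape = label_maps[0].shape
    vox = label_maps[0].voxel_size
    for lm in label_maps[1:]:
        if lm.class_names != names or lm.shape != shape:
            raise ValueError("mismatched class names or grids")
    mean = np.mean([lm.stack() for lm in label_maps], axis=0)
    if smoothing_fwhm_mm > 0:
        sig = fwhm_to_sigma(smoothing_fwhm_mm) / vox
        for i in range(mean.shape[0]):
            mean[i] = ndimage.gaussian_filter(mean[i], sig)
    total = mean.sum(axis=0)
    over = total > 1.0
    if np.any(over):
        mean[:, over] /= total[over]
    if brain_mask is None:
        # floor everywhere the pooled maps have any support, so no class is
        # impossible anywhere in the segmentation domain
        brain_mask = total > 0.05
    mean[:, brain_mask] = np.maximum(mean[:, brain_mask], prior_floor)
    total = mean.sum(axis=0)
    over = total > 1.0
    if np.any(over):
        mean[:, over] /= total[over]
    return TissueProbMaps.from_stack(names, mean, vox)


def quantile_anchor_tpms(t1: VolumeImage, flair: VolumeImage,
                         brain_mask: np.ndarray,
                         classes=("GM", "WM", "CSF", "WMH"),
                         sharpness: float = 40.0,
                         background_shell_voxels: int = 6) -> TissueProbMaps:
    """Crude first-pass priors from data-driven intensity anchors.

    Used to bootstrap population TPMs when none exist yet (the first
    segmentation pass).  Anchors each class at robust intensity quantiles
    within the brain mask — CSF dark / GM mid / WM bright on T1, WMH at the
    FLAIR high tail — and converts Mahalanobis-like distances to soft priors.
    No spatial information is used inside the mask; a ``background`` class
    with unit prior fills a shell just outside the mask so that, once the
    pooled TPMs are smoothed, out-of-brain voxels are not forced into a
    tissue class.
    """
    x1 = np.asarray(t1.data, dtype=float)[brain_mask]
    x2 = np.asarray(flair.data, dtype=float)[brain_mask]
    q = lambda v, p: float(np.percentile(v, p))
    # WMH anchor: mean of the brightest 0.1% FLAIR voxels — robust to lesion
    # loads below any fixed quantile, as long as lesions exceed ~0.1% of brain
    flair_top = float(np.mean(x2[x2 >= q(x2, 99.9)]))
    anchors = {
        "CSF": (q(x1, 8), q(x2, 8)),
        "GM": (q(x1, 45), q(x2, 55)),
        "WM": (q(x1, 85), q(x2, 35)),
        "WMH": (q(x1, 45), flair_top),
    }
    scale1 = max(q(x1, 85) - q(x1, 8), 1e-6)
    scale2 = max(flair_top - q(x2, 8), 1e-6)
    logits = []
    for c in classes:
        a1, a2 = anchors[c]
        d2 = (((t1.data - a1) / scale1) ** 2 + ((flair.data - a2) / scale2) ** 2)
        logits.append(-sharpness * d2)
    logits = np.stack(logits)
    logits -= logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    p *= brain_mask
    names = list(classes)
    if background_shell_voxels > 0:
        shell = ndimage.binary_dilation(
            brain_mask, iterations=background_shell_voxels) & ~brain_mask
        p = np.concatenate([p, shell[None].astype(float)])
        names.append("background")
    return TissueProbMaps.from_stack(names, p, t1.voxel_size)


def _init_mixture(intens: np.ndarray, priors: np.ndarray, cfg: SegmentConfig,
                  classes: list[str]) -> MixtureModel:
    """Deterministic initialization from prior-weighted moments.

    Multi-Gaussian classes are split along the principal axis of the weighted
    covariance at +/-0.5 sigma.  The WMH class is additionally restricted to
    the bright FLAIR tail: its pooled prior marks where *any* cohort member
    carries lesions, which in a given subject is mostly normal white matter —
    moments over that support would start (and often keep) the WMH Gaussian
    on the WM intensity cluster.  Anchoring on prior-weighted voxels in the
    top FLAIR percentile keeps the class on actual hyperintensities.
    """
    n_ch = intens.shape[1]
    class_mus = []
    means, covs, weights, gclass = [], [], [], []
    for ci, c in enumerate(classes):
        w = priors[ci]
        if c == "WMH" and n_ch >= 2:
            tail = intens[:, 1] >= np.quantile(intens[:, 1], 0.99)
            w_tail = w * tail
            if w_tail.sum() > 1e-6:
                w = w_tail
        wsum = float(w.sum())
        mu = (w[:, None] * intens).sum(axis=0) / wsum
        d = intens - mu
        cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / wsum
        cov += np.eye(n_ch) * (1e-4 * np.trace(cov) / n_ch + 1e-10)
        # flat or overlapping priors give several classes identical moments;
        # spread duplicates deterministically along the principal intensity
        # axis so EM can break the symmetry
        scale = np.sqrt(np.trace(cov) / n_ch)
        for prev in class_mus:
            if np.linalg.norm(mu - prev) < 1e-6 * max(scale, 1e-12):
                evals, evecs = np.linalg.eigh(cov)
                frac = (ci + 0.5) / len(classes) - 0.5
                mu = mu + 2.0 * frac * np.sqrt(max(evals[-1], 1e-12)) * evecs[:, -1]
                break
        class_mus.append(mu)
        k = cfg.gaussians_per_class.get(c, 1)
        if k == 1:
            means.append(mu); covs.append(cov); weights.append(1.0); gclass.append(ci)
        else:
            evals, evecs = np.linalg.eigh(cov)
            offset = 0.5 * np.sqrt(max(evals[-1], 1e-12)) * evecs[:, -1]
            for j in range(k):
                frac = (2 * j / (k - 1) - 1.0)  # -1 .. +1
                means.append(mu + frac * offset)
                covs.append(cov.copy())
                weights.append(1.0 / k)
                gclass.append(ci)
    return MixtureModel(list(classes), means, covs, np.asarray(weights, dtype=float),
                        np.asarray(gclass))


def _log_gauss(intens: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    n_ch = intens.shape[1]
    d = intens - mu
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + np.eye(n_ch) * (1e-6 * np.trace(cov) / n_ch + 1e-12)
        chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, d.T)
    maha = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (maha + logdet + n_ch * np.log(2 * np.pi))


def segment_tissues(t1: VolumeImage, flair: VolumeImage, tpms: TissueProbMaps,
                    config: SegmentConfig | None = None
                    ) -> tuple[TissueProbMaps, MixtureModel]:
    """EM segmentation of a two-channel image with spatially varying priors.

    Posteriors are prior-weighted Gaussian responsibilities normalized per
    voxel; a voxel with zero prior for a class keeps zero posterior for it
    regardless of intensity.  Runs to the relative log-likelihood tolerance
    or ``max_iter``; fully deterministic.
    """
    cfg = config or SegmentConfig()
    if t1.shape != flair.shape or t1.shape != tpms.shape:
        raise ValueError("channels and TPMs must share one grid")
    classes = [c for c in cfg.classes if c in tpms.class_names]
    dropped = [c for c in cfg.classes
               if c not in tpms.class_names and c != "background"]
    if dropped:
        warnings.warn(f"classes missing from TPMs dropped: {dropped}", stacklevel=2)

    prior_stack = np.stack([np.asarray(tpms.maps[c], dtype=float) for c in classes])
    mask = prior_stack.sum(axis=0) >= cfg.mask_threshold
    keep = []
    for ci, c in enumerate(classes):
        if np.any(prior_stack[ci][mask] > cfg.prior_floor / 10):
            keep.append(ci)
        else:
            warnings.warn(f"class {c!r} has no support in mask; dropped", stacklevel=2)
    classes = [classes[i] for i in keep]
    prior_stack = prior_stack[keep]

    intens = np.stack([np.asarray(t1.data, dtype=float)[mask],
                       np.asarray(flair.data, dtype=float)[mask]], axis=1)
    priors = prior_stack[:, mask]
    # renormalize priors over the retained classes (per-voxel)
    psum = priors.sum(axis=0)
    psum[psum <= 0] = 1.0
    priors = priors / psum

    model = _init_mixture(intens, priors, cfg, classes)
    n_g = len(model.means)
    n_vox = intens.shape[0]
    log_prior_g = np.empty((n_g, n_vox))
    resp = np.empty((n_g, n_vox))

    prev_ll = -np.inf
    mean_var = float(np.var(intens)) + 1e-12
    for _ in range(cfg.max_iter):
        for k in range(n_g):
            with np.errstate(divide="ignore"):
                log_prior_g[k] = (np.log(priors[model.gaussian_class[k]])
                                  + np.log(model.weights[k]))
            log_prior_g[k] += _log_gauss(intens, model.means[k], model.covariances[k])
        mx = log_prior_g.max(axis=0)
        np.exp(log_prior_g - mx, out=resp)
        tot = resp.sum(axis=0)
        ll = float(np.sum(mx + np.log(tot)))
        resp /= tot
        model.log_likelihood.append(ll)

        # M step
        for k in range(n_g):
            r = resp[k]
            rs = float(r.sum())
            if rs < 1e-8:
                continue
            mu = (r[:, None] * intens).sum(axis=0) / rs
            d = intens - mu
            cov = (r[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / rs
            cov += np.eye(2) * cfg.ridge * mean_var
            if np.linalg.det(cov) <= 0:
                warnings.warn("singular covariance ridge-regularized", stacklevel=2)
                cov += np.eye(2) * (1e-3 * mean_var)
            model.means[k] = mu
            model.covariances[k] = cov
        # within-class mixing weights
        for ci in range(len(classes)):
            sel = model.gaussian_class == ci
            csum = resp[sel].sum()
            if csum > 0:
                model.weights[sel] = resp[sel].sum(axis=1) / csum

        if prev_ll > -np.inf and abs(ll - prev_ll) <= cfg.tol * abs(prev_ll):
            break
        prev_ll = ll

    post = np.zeros((len(classes),) + t1.shape)
    for ci in range(len(classes)):
        sel = model.gaussian_class == ci
        post[ci][mask] = resp[sel].sum(axis=0)
    return TissueProbMaps.from_stack(classes, post, t1.voxel_size), model


def binarize_wmh(wmh_posterior: VolumeImage | np.ndarray,
                 threshold: float | str = 0.5,
                 exclusion_mask: np.ndarray | None = None,
                 min_component_voxels: int = 5) -> np.ndarray:
    """Threshold the WMH posterior into a binary lesion mask.

    ``threshold='otsu'`` picks the threshold from the in-mask posterior
    histogram (automatic stand-in for the per-subject manual thresholding
    protocol).  Voxels inside ``exclusion_mask`` (e.g. a corpus
    callosum/fornix analogue) are removed, then connected components smaller
    than ``min_component_voxels`` are discarded.
    """
    post = np.asarray(wmh_posterior.data if isinstance(wmh_posterior, VolumeImage)
                      else wmh_posterior, dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be a float in (0,1) or 'otsu'")
        from skimage.filters import threshold_otsu
        vals = post[post > 1e-3]
        threshold = float(threshold_otsu(vals)) if vals.size > 1 else 0.5
    if not 0.0 < float(threshold) < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = post >= float(threshold)
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    if min_component_voxels > 1 and mask.any():
        lab, n = ndimage.label(mask)
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_component_voxels)
        mask &= ~np.isin(lab, small[small > 0])
    if not mask.any():
        warnings.warn("WMH mask is empty", stacklevel=2)
    return mask


def skull_strip_mask(tpms: TissueProbMaps, threshold: float = 0.1) -> np.ndarray:
    """Brain mask from the GM+WM+CSF probability sum.

    Thresholds the tissue sum (default 0.1), keeps the largest connected
    component, and fills interior holes.
    """
    for c in ("GM", "WM", "CSF"):
        if c not in tpms.class_names:
            raise ValueError(f"class {c!r} required for skull stripping")
    total = sum(np.asarray(tpms.maps[c], dtype=float) for c in ("GM", "WM", "CSF"))
    mask = total >= threshold
    if not mask.any():
        return mask
    lab, n = ndimage.label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    if n > 1:
        second = np.sort(sizes)[-2]
        if second > 0.5 * sizes[largest]:
            warnings.warn("brain mask has a second component of similar size",
                          stacklevel=2)
    mask = lab == largest
    return ndimage.binary_fill_holes(mask)
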