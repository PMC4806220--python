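"""Group-space products: warped tissue x rate maps, lesion-normalized WMH
rates, and voxel-based-quantification (VBQ) weighted smoothing.

All operations here are deterministic voxel arithmetic on maps already
aligned to the group grid by the registration stage.  The lesion-normalized
WMH rate averages, at each voxel, only over the subjects whose lesion mask
covers that voxel — the average growth rate *given* a lesion is present —
rather than diluting the rate over the whole cohort.  VBQ smoothing
``G*(w.p) / G*(w)`` keeps smoothed parameter values from bleeding across
tissue boundaries by weighting with the warped tissue probability.
"""

from __future__ import annotations

import numpy as np

from .image import VolumeImage, smooth_gaussian
from .registration import Deformation, warp_image


def warp_to_group(image, deformation: Deformation, modulate: bool = False):
    """Pull a subject-space image onto the group grid.

    ``deformation`` maps group-grid coordinates into subject space (as
    returned by the group-template build).  With ``modulate`` the result is
    multiplied by the Jacobian determinant so integrated mass is preserved
    (tensor-based-morphometry convention).
    """
    arr = np.asarray(image.data if isinstance(image, VolumeImage) else image,
                     dtype=float)
    out = deformation.apply(arr)
    if modulate:
        out = out * deformation.jacobian()
    if isinstance(image, VolumeImage):
        return image.like(out)
    return out


def normalized_wmh_rate(warped_rates, warped_wmh_masks, min_count: int = 1):
    """Lesion-presence-normalized average WMH rate.

    Voxel value = sum_i(rate_i * mask_i) / sum_i(mask_i) wherever at least
    ``min_count`` subjects carry a lesion there; elsewhere the voxel is
    outside the returned support mask (masked, distinct from a zero rate).

    Returns ``(rate, support_mask)``.
    """
    if len(warped_rates) != len(warped_wmh_masks) or not warped_rates:
        raise ValueError("need equal-length, non-empty rate and mask lists")
    rates = np.stack([np.asarray(getattr(r, "data", r), dtype=float)
                      for r in warped_rates])
    masks = np.stack([np.asarray(getattr(m, "data", m), dtype=bool)
                      for m in warped_wmh_masks])
    count = masks.sum(axis=0)
    total = (rates * masks).sum(axis=0)
    support = count >= min_count
    out = np.zeros_like(total)
    np.divide(total, count, out=out, where=support)
    return out, support


def vbq_weighted_smooth(parameter_map, weight_map, fwhm_mm: float,
                        voxel_size: float = 1.0, eps: float | None = None):
    """Weighted Gaussian smoothing: ``G*(w.p) / G*(w)``.

    ``eps`` masks voxels whose smoothed weight is negligible; it defaults to
    1e-3 of the mean positive weight.  Returns ``(smoothed, support_mask)``.
    Reduces exactly to plain Gaussian smoothing when the weight is constant.
    """
    p = np.asarray(getattr(parameter_map, "data", parameter_map), dtype=float)
    w = np.asarray(getattr(weight_map, "data", weight_map), dtype=float)
    if isinstance(parameter_map, VolumeImage):
        voxel_size = parameter_map.voxel_size
    if p.shape != w.shape:
        raise ValueError("parameter and weight grids differ")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    num = smooth_gaussian(w * p, fwhm_mm, voxel_size)
    den = smooth_gaussian(w, fwhm_mm, voxel_size)
    if eps is None:
        pos = w[w > 0]
        eps = 1e-3 * float(pos.mean()) if pos.size else 1e-12
    support = den >= eps
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=support)
    return out, support


def cohort_average_rate(warped_tissue, warped_rate):
    """Voxel-wise mean over subjects of tissue_i * rate_i (unsmoothed)."""
    if len(warped_tissue) != len(warped_rate) or not warped_tissue:
        raise ValueError("lists must align by subject and be non-empty")
    acc = None
    for t, r in zip(warped_tissue, warped_rate):
        prod = (np.asarray(getattr(t, "data", t), dtype=float)
                * np.asarray(getattr(r, "data", r), dtype=float))
        acc = prod if acc is None else acc + prod
    return acc / len(warped_tissue)
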