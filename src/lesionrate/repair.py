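"""Segmentation repair: undo pathology-driven tissue misclassification.

Lesioned tissue confuses intensity-based segmentation: WMH is typically
assigned to grey matter (GM-like on T1), and the gliotic core of a lacune to
CSF.  Left uncorrected, those voxels would be dragged toward the wrong tissue
during template warping.  Repair therefore (1) moves WMH voxels' grey-matter
(and lesion) probability mass into white matter, (2) reassigns lacune voxels
to the most likely healthy tissue according to the population priors,
identically at every time point, and (3) enforces the brain mask, pushing
stray tissue mass at the margin into CSF.

After repair, {GM, WM, CSF} again form a per-voxel partition of the tissue
mass, so the warping stage can treat them as a 3-class segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .segmentation import TissueProbMaps


class RepairCode(IntEnum):
    UNTOUCHED = 0
    WMH_REPAIRED = 1
    LACUNE_REPAIRED = 2
    MASK_CLEANED = 3


@dataclass
class RepairedSegmentation:
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    provenance: np.ndarray  # RepairCode per voxel

    def as_tpms(self, voxel_size: float = 1.0) -> TissueProbMaps:
        return TissueProbMaps(["CSF", "GM", "WM"],
                              {"CSF": self.csf, "GM": self.gm, "WM": self.wm},
                              voxel_size)


def repair_wmh(gm: np.ndarray, wm: np.ndarray, wmh_mask: np.ndarray,
               wmh_prob: np.ndarray | None = None):
    """Reassign WMH voxels to white matter.

    Inside the lesion mask the grey-matter probability (plus the WMH posterior
    mass, when supplied) is added to white matter and grey matter zeroed;
    voxels outside the mask are untouched.  Conserves gm+wm(+wmh) mass.
    """
    gm = np.asarray(gm, dtype=float)
    wm = np.asarray(wm, dtype=float)
    m = np.asarray(wmh_mask, dtype=bool)
    if gm.shape != wm.shape or gm.shape != m.shape:
        raise ValueError("inputs must share one grid")
    gm2, wm2 = gm.copy(), wm.copy()
    add = gm[m]
    if wmh_prob is not None:
        add = add + np.asarray(wmh_prob, dtype=float)[m]
    wm2[m] = wm[m] + add
    gm2[m] = 0.0
    over = wm2 > 1 + 1e-6
    if np.any(over):
        # mass exceeding a full voxel is clipped; logged via the return path
        wm2[over] = 1.0
    return gm2, wm2


def repair_lacunes(series_segs: list[TissueProbMaps],
                   lacune_masks: list[np.ndarray],
                   tpms: TissueProbMaps,
                   subject_to_group_warp=None) -> list[np.ndarray]:
    """Assign each lacune voxel its most likely healthy tissue class.

    The union of the lacune masks over all time points is mapped into TPM
    space (through ``subject_to_group_warp`` when given, identity otherwise)
    and each voxel takes the argmax class over {GM, WM, CSF} of the TPM
    probability at the mapped location — ties resolved WM > GM > CSF, since
    lacunes live in white-matter territory.  The winning class is set to 1
    (others 0) identically at every time point.

    Returns the per-voxel class assignment; the segmentations in
    ``series_segs`` are modified in place.
    """
    if len(series_segs) != len(lacune_masks):
        raise ValueError("one lacune mask per time point required")
    union = np.zeros_like(np.asarray(lacune_masks[0], dtype=bool))
    for m in lacune_masks:
        union |= np.asarray(m, dtype=bool)
    if not union.any():
        return []
    idx = np.argwhere(union).astype(float).T  # (3, n)
    if subject_to_group_warp is not None:
        disp = subject_to_group_warp.disp_vox
        mapped = idx + np.stack([
            ndimage.map_coordinates(disp[i], idx, order=1, mode="nearest")
            for i in range(3)])
    else:
        mapped = idx
    shape = np.asarray(tpms.shape, dtype=float)
    if np.any(mapped < -0.5) or np.any(mapped > (shape[:, None] - 0.5)):
        import warnings
        warnings.warn("lacune voxels mapped outside the TPM grid; "
                      "nearest-voxel lookup used", stacklevel=2)
    order = ["WM", "GM", "CSF"]  # tie-break priority
    probs = np.stack([
        ndimage.map_coordinates(np.asarray(tpms.maps[c], dtype=float), mapped,
                                order=1, mode="nearest")
        for c in order])
    winner = np.argmax(probs, axis=0)  # argmax returns the first (priority) max
    assigned = [order[w] for w in winner]

    coords = np.argwhere(union)
    for seg in series_segs:
        for c in ("GM", "WM", "CSF"):
            if c not in seg.class_names:
                raise ValueError("series segmentations must contain GM/WM/CSF")
        for (i, j, k), cls in zip(coords, assigned):
            for c in ("GM", "WM", "CSF"):
                seg.maps[c][i, j, k] = 1.0 if c == cls else 0.0
    return assigned


def apply_brain_mask(segs: TissueProbMaps, brain_mask: np.ndarray,
                     margin_voxels: int = 2) -> TissueProbMaps:
    """Enforce the brain mask on a segmentation.

    Outside the mask but within a dilated margin, GM and WM mass is moved
    into CSF (misclassified dura/skull-edge voxels become CSF); strictly
    outside the margin all classes are zeroed.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != segs.shape:
        raise ValueError("mask grid mismatch")
    margin = ndimage.binary_dilation(mask, iterations=margin_voxels) & ~mask
    outside = ~mask & ~margin
    out = {c: np.asarray(segs.maps[c], dtype=float).copy() for c in segs.class_names}
    moved = np.zeros(segs.shape)
    for c in ("GM", "WM"):
        if c in out:
            moved[margin] += out[c][margin]
            out[c][margin] = 0.0
    if "CSF" in out:
        out["CSF"][margin] += moved[margin]
    for c in out:
        out[c][outside] = 0.0
    return TissueProbMaps(list(segs.class_names), out, segs.voxel_size)


def repair_segmentation(seg: TissueProbMaps, wmh_mask: np.ndarray,
                        brain_mask: np.ndarray | None = None,
                        margin_voxels: int = 2) -> RepairedSegmentation:
    """Full single-time-point repair: WMH -> WM, then brain-mask cleanup."""
    gm = np.asarray(seg.maps["GM"], dtype=float)
    wm = np.asarray(seg.maps["WM"], dtype=float)
    csf = np.asarray(seg.maps.get("CSF", np.zeros_like(gm)), dtype=float).copy()
    wmh = np.asarray(seg.maps["WMH"], dtype=float) if "WMH" in seg.maps else None

    prov = np.full(gm.shape, RepairCode.UNTOUCHED, dtype=np.int8)
    gm2, wm2 = repair_wmh(gm, wm, wmh_mask, wmh_prob=wmh)
    prov[np.asarray(wmh_mask, dtype=bool)] = RepairCode.WMH_REPAIRED

    if brain_mask is not None:
        tp = TissueProbMaps(["CSF", "GM", "WM"],
                            {"CSF": csf, "GM": gm2, "WM": wm2}, seg.voxel_size)
        cleaned = apply_brain_mask(tp, brain_mask, margin_voxels)
        changed = ((cleaned.maps["GM"] != gm2) | (cleaned.maps["WM"] != wm2)
                   | (cleaned.maps["CSF"] != csf))
        prov[changed & (prov == RepairCode.UNTOUCHED)] = RepairCode.MASK_CLEANED
        gm2, wm2, csf = cleaned.maps["GM"], cleaned.maps["WM"], cleaned.maps["CSF"]
    return RepairedSegmentation(gm2, wm2, csf, prov)
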