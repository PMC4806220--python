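"""Canonical end-to-end experiments at desk scale.

Each function wires several pipeline stages together under fixed study
conditions (the phantom defaults) and returns the headline quantities of the
analysis: ground-truth recovery of atrophy rate maps, the cohort-level
correlation between grey-matter and WMH volume rates, permutation-test
calibration, and voxel-wise localization of a lesion-driven atrophy focus.
They are used by the test suite and by ``scripts/acceptance.py``; problem
sizes (64^3 grids, 40 subjects, hundreds of permutations) are chosen so a
full run completes on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from . import phantom as ph
from . import registration as reg
from . import repair as rp
from . import segmentation as seg
from . import volumetrics as vol
from . import voxelstats as vs
from . import groupmaps as gm


def repaired_truth_channels(label_map: np.ndarray) -> list[np.ndarray]:
    """3-class (CSF, GM, WM) channels from a truth label map, with lesions
    folded into their host tissue (WMH -> WM, lacune -> CSF)."""
    return [
        ((label_map == ph.CSF) | (label_map == ph.LACUNE)).astype(float),
        (label_map == ph.GM).astype(float),
        ((label_map == ph.WM) | (label_map == ph.WMH)).astype(float),
    ]


def segment_subject(series, truth, cfg: seg.SegmentConfig | None = None,
                    tpms: seg.TissueProbMaps | None = None):
    """Two-pass segmentation of one subject's series.

    When no population TPMs are supplied they are bootstrapped from the
    subject's own first-pass (intensity-anchor) segmentations.  Returns
    ``(posteriors, wmh_masks, tpms)``.
    """
    cfg = cfg or seg.SegmentConfig(max_iter=60)
    if tpms is None:
        first = []
        for tp in series.timepoints:
            anchor = seg.quantile_anchor_tpms(tp.t1_image, tp.flair_image,
                                              truth.icv_mask)
            post, _ = seg.segment_tissues(tp.t1_image, tp.flair_image, anchor, cfg)
            first.append(post)
        if len(first) == 1:
            first = first * 2
        tpms = seg.build_population_tpms(first, smoothing_fwhm_mm=4.0)
    posteriors, masks = [], []
    for tp in series.timepoints:
        post, _ = seg.segment_tissues(tp.t1_image, tp.flair_image, tpms, cfg)
        m = seg.binarize_wmh(post.maps["WMH"], cfg.wmh_threshold
                             if not isinstance(cfg.wmh_threshold, str) else "otsu",
                             min_component_voxels=cfg.min_component_voxels)
        posteriors.append(post)
        masks.append(m)
    return posteriors, masks, tpms


def rate_map_recovery(seed: int = 0, grid: int = 64, atrophy_rate: float = -0.01,
                      n_outer_iters: int = 3) -> dict:
    """Recover the per-voxel atrophy rate of a noise-free phantom subject.

    Full path: phantom -> segmentation -> repair -> subject-average SVF
    registration -> divergence -> rate fit.  The analytic truth is a rate of
    ``3a`` per year everywhere in the brain.
    """
    params = ph.PhantomParams(grid_shape=(grid,) * 3, noise_sd=(0.0, 0.0),
                              times_years=(0.0, 1.5, 3.0), random_seed=seed)
    series, truth = ph.generate_subject(params, 0, (atrophy_rate, 0.5))
    posteriors, wmh_masks, tpms = segment_subject(series, truth)

    repaired = []
    for post, m in zip(posteriors, wmh_masks):
        r = rp.repair_segmentation(post, m, brain_mask=truth.icv_mask)
        repaired.append(r.as_tpms(params.voxel_size_mm))
    lac = [np.asarray(tp.lacune_mask.data, dtype=bool) for tp in series.timepoints]
    rp.repair_lacunes(repaired, lac, tpms)

    chans = [[np.asarray(s.maps[c], dtype=float) for c in ("CSF", "GM", "WM")]
             for s in repaired]
    _, vfs, _, jacs = reg.build_subject_average(chans, n_outer_iters=n_outer_iters)
    divs = [reg.divergence_map(v) for v in vfs]
    rate = reg.fit_rate_map(divs, series.times_years)

    mid = len(truth.labels) // 2
    brain_int = ndimage.binary_erosion(truth.brain_masks[mid], iterations=2)
    gm_int = ndimage.binary_erosion(truth.labels[mid] == ph.GM, iterations=1)
    return {
        "mean_rate_per_year": float(rate[brain_int].mean()),
        "true_rate_per_year": 3.0 * atrophy_rate,
        "relative_error": float(abs(rate[brain_int].mean() - 3 * atrophy_rate)
                                / abs(3 * atrophy_rate)),
        "gm_negative_sign_fraction": float((rate[gm_int] < 0).mean()),
        "min_jacobian": float(min(j.min() for j in jacs)),
        "rate_map": rate,
    }


def jacobian_recovery(seed: int = 0, grid: int = 64,
                      atrophy_rate: float = -0.02) -> dict:
    """Register a phantom to its analytically contracted copy (1 year)."""
    params = ph.PhantomParams(grid_shape=(grid,) * 3, noise_sd=(0.0, 0.0),
                              times_years=(0.0, 1.0), random_seed=seed)
    _, truth = ph.generate_subject(params, 0, (atrophy_rate, 0.0))
    moving = repaired_truth_channels(truth.labels[0])
    fixed = repaired_truth_channels(truth.labels[1])
    _, _, jac = reg.register_pair(moving, fixed)
    target = float(np.exp(3 * atrophy_rate))
    mean_jac = float(jac[truth.brain_masks[0]].mean())
    return {"mean_jacobian": mean_jac, "target": target,
            "relative_error": abs(mean_jac - target) / target,
            "min_jacobian": float(jac.min())}


def cohort_rate_correlation(seed: int = 0, n_subjects: int = 40,
                            grid: int = 64, rho: float = -0.7) -> dict:
    """Pipeline-estimated GM-volume vs WMH-volume annualized rates.

    Generates a cohort with correlated true rates (annual visits with a
    dropout pattern emulating a longitudinal clinical study), segments every
    time point with population TPMs pooled over the whole cohort's first
    pass, measures per-time-point volumes from the unrepaired posteriors,
    fits per-subject annualized rates, and correlates them across subjects.
    """
    params = ph.PhantomParams(
        grid_shape=(grid,) * 3, n_subjects=n_subjects,
        rate_correlation_rho=rho, random_seed=seed,
        dropout_probs=(0.21, 0.06, 0.73),
    )
    series_list, truth_list, table = ph.generate_cohort(params)
    cfg = seg.SegmentConfig(max_iter=60)

    # first pass pooled incrementally (running mean keeps memory flat)
    acc, n_acc = None, 0
    for series, truth in zip(series_list, truth_list):
        for tp in series.timepoints:
            anchor = seg.quantile_anchor_tpms(tp.t1_image, tp.flair_image,
                                              truth.icv_mask)
            post, _ = seg.segment_tissues(tp.t1_image, tp.flair_image, anchor, cfg)
            st = post.stack()
            acc = st if acc is None else acc + st
            n_acc += 1
    mean_tpms = seg.TissueProbMaps.from_stack(
        ("GM", "WM", "CSF", "WMH"), acc / n_acc, params.voxel_size_mm)
    tpms = seg.build_population_tpms([mean_tpms, mean_tpms],
                                     smoothing_fwhm_mm=4.0)

    gm_rates, wmh_rates, rows = [], [], []
    for series, truth in zip(series_list, truth_list):
        vols_gm, vols_wmh, times = [], [], []
        baseline = None
        for tp in series.timepoints:
            post, _ = seg.segment_tissues(tp.t1_image, tp.flair_image, tpms, cfg)
            m = seg.binarize_wmh(post.maps["WMH"], 0.5)
            v = vol.tissue_volumes(post, wmh_mask=m,
                                   lacune_mask=np.asarray(tp.lacune_mask.data,
                                                          dtype=bool),
                                   brain_mask=truth.icv_mask)
            vols_gm.append(v["gm_mm3"])
            vols_wmh.append(v["wmh_mm3"])
            times.append(tp.time_years)
            if baseline is None:
                baseline = v
        gm_rates.append(vol.annualized_rate(vols_gm, times))
        wmh_rates.append(vol.annualized_rate(vols_wmh, times))
        rows.append({
            "subject_id": series.subject_id,
            "gm_rate": gm_rates[-1], "wmh_rate": wmh_rates[-1],
            "age_baseline": series.covariates.get("age_baseline", np.nan),
            "sex": series.covariates.get("sex", "M"),
            "lacune_volume": baseline["lacune_mm3"],
            "tiv": baseline["tiv_mm3"], "wmh_baseline": baseline["wmh_mm3"],
            "gm_pct_change_total": vol.percent_change(vols_gm[0], vols_gm[-1]),
        })
    import pandas as pd

    df = pd.DataFrame(rows)
    r, p = stats.pearsonr(df["gm_rate"], df["wmh_rate"])
    true_r = float(np.corrcoef(table["a_true"], table["g_true"])[0, 1])
    return {
        "pearson_r": float(r), "p_value": float(p), "n": len(df),
        "true_rate_correlation": true_r,
        "median_wmh_rate_mm3_per_year": float(np.median(df["wmh_rate"])),
        "mean_gm_rate_mm3_per_year": float(np.mean(df["gm_rate"])),
        "table": df,
    }


def fwe_null_calibration(seed: int = 0, n_sims: int = 200, n_subjects: int = 40,
                         mask_shape=(16, 16, 16), n_perm: int = 500,
                         alpha: float = 0.05) -> dict:
    """Family-wise rejection fraction of the permutation test under the null.

    Pure-noise map stacks with a random effect regressor: the fraction of
    simulated datasets with any FWE-significant voxel should be ~alpha.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(mask_shape, dtype=bool)
    n_reject = 0
    for _ in range(n_sims):
        stack = rng.normal(size=(n_subjects,) + tuple(mask_shape))
        import pandas as pd

        table = pd.DataFrame({
            "wmh_rate": rng.normal(size=n_subjects),
            "age_baseline": rng.normal(70, 10, n_subjects),
            "sex": rng.choice(["F", "M"], n_subjects),
            "lacune_volume": rng.gamma(2, 100, n_subjects),
            "tiv": rng.normal(1.4e6, 1e5, n_subjects),
            "wmh_baseline": rng.gamma(2, 1e4, n_subjects),
        })
        design = vs.build_design(table, "gm_vs_wmhrate")
        contrast = np.zeros(design.X.shape[1])
        contrast[design.effect_index] = 1.0
        res = vs.permutation_fwe(stack, design, contrast, "positive", n_perm,
                                 int(rng.integers(2 ** 31)), alpha=alpha, mask=mask)
        if np.any(res.p_fwe <= alpha):
            n_reject += 1
    return {"rejection_fraction": n_reject / n_sims, "n_sims": n_sims,
            "alpha": alpha}


def fwe_power(seed: int = 0, n_runs: int = 50, n_subjects: int = 40,
              mask_shape=(16, 16, 16), n_perm: int = 500,
              effect_voxels: int = 5, effect_size_sd: float = 3.0) -> dict:
    """Detection rate for a small injected effect (amplitude in noise SDs)."""
    rng = np.random.default_rng(seed)
    mask = np.ones(mask_shape, dtype=bool)
    import pandas as pd

    detected = 0
    for _ in range(n_runs):
        x = rng.normal(size=n_subjects)
        stack = rng.normal(size=(n_subjects,) + tuple(mask_shape))
        flat = stack.reshape(n_subjects, -1)
        idx = rng.choice(flat.shape[1], size=effect_voxels, replace=False)
        flat[:, idx] += effect_size_sd * x[:, None] / x.std()
        table = pd.DataFrame({
            "wmh_rate": x,
            "age_baseline": rng.normal(70, 10, n_subjects),
            "sex": rng.choice(["F", "M"], n_subjects),
            "lacune_volume": rng.gamma(2, 100, n_subjects),
            "tiv": rng.normal(1.4e6, 1e5, n_subjects),
            "wmh_baseline": rng.gamma(2, 1e4, n_subjects),
        })
        design = vs.build_design(table, "gm_vs_wmhrate")
        contrast = np.zeros(design.X.shape[1])
        contrast[design.effect_index] = 1.0
        res = vs.permutation_fwe(stack, design, contrast, "positive", n_perm,
                                 int(rng.integers(2 ** 31)), mask=mask)
        sig = res.p_fwe <= res.alpha
        if sig.ravel()[idx].any():
            detected += 1
    return {"detection_rate": detected / n_runs, "n_runs": n_runs}


def patch_localization(seed: int = 0, n_subjects: int = 40, grid: int = 64,
                       n_perm: int = 500, fwhm_mm: float = 6.0,
                       alpha: float = 0.05) -> dict:
    """Localize a cortical patch whose atrophy rate is driven by WMH growth.

    The voxel-wise model-1 analogue: VBQ-smoothed GM rate maps regressed on
    the per-subject WMH growth rate (plus confounds), negative contrast,
    max-statistic permutation FWE.  Reports the Dice overlap between the
    FWE-significant region and the true patch.
    """
    # near-constant global atrophy across subjects: the lesion-coupled focal
    # excess inside the patch is the only association to find
    params = ph.PhantomParams(grid_shape=(grid,) * 3, n_subjects=n_subjects,
                              atrophy_rate_sd=0.001, random_seed=seed)
    stack, table, patch, gm_mask = ph.synthetic_rate_map_cohort(
        params, patch_radius_mm=6.0)
    smoothed = np.stack([
        gm.vbq_weighted_smooth(stack[i], gm_mask.astype(float), fwhm_mm,
                               params.voxel_size_mm)[0]
        for i in range(n_subjects)])
    design = vs.build_design(table, "gm_vs_wmhrate")
    contrast = np.zeros(design.X.shape[1])
    contrast[design.effect_index] = -1.0  # negative correlation with WMH rate
    res = vs.permutation_fwe(smoothed, design, contrast, "positive", n_perm,
                             seed=seed + 1, alpha=alpha, mask=gm_mask,
                             voxel_size=params.voxel_size_mm)
    sig = res.p_fwe <= alpha
    inter = float(np.sum(sig & patch))
    dice = 2 * inter / (sig.sum() + patch.sum()) if (sig.sum() + patch.sum()) else 0.0
    return {"dice": float(dice), "n_significant": int(sig.sum()),
            "patch_voxels": int(patch.sum()), "threshold_t": res.threshold,
            "result": res, "patch": patch}
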