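"""Voxel-wise multiple regression with permutation family-wise-error control.

Rate maps (one per subject, on the group grid) are regressed voxel-by-voxel
on an effect of interest plus confounds.  One-sided contrasts are tested with
max-statistic permutation under the Freedman-Lane scheme: residuals of the
reduced (confound-only) model are permuted, the full model refitted, and the
maximum t over the mask recorded per permutation.  The resulting corrected
p-value ``(1 + #{max-t >= t_obs}) / (n_perm + 1)`` controls family-wise error
without Gaussian-random-field assumptions and is exactly testable by
simulation.

Two canonical models mirror the study design:

* ``gm_vs_wmhrate`` (model 1): GM rate maps vs the subject-average WMH rate,
  confounds = baseline age, sex, lacune volume, TIV, baseline WMH volume.
* ``wmh_vs_gmrate`` (model 2): WMH rate maps vs the subject-average GM rate,
  confounds = baseline age, sex, lacune volume, TIV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

T_CAP = 1e6  # flag value for zero-residual voxels with a non-zero effect

MODELS = {
    "gm_vs_wmhrate": {
        "effect": "wmh_rate",
        "confounds": ["age_baseline", "sex", "lacune_volume", "tiv", "wmh_baseline"],
    },
    "wmh_vs_gmrate": {
        "effect": "gm_rate",
        "confounds": ["age_baseline", "sex", "lacune_volume", "tiv"],
    },
}


@dataclass
class DesignMatrix:
    X: np.ndarray                  # (n_subjects, n_regressors)
    names: list[str]
    roles: list[str]               # intercept | effect_of_interest | confound

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            corr = np.corrcoef(self.X.T + 1e-12 * np.random.default_rng(0).normal(
                size=self.X.T.shape))
            pairs = [(self.names[i], self.names[j])
                     for i in range(len(self.names)) for j in range(i)
                     if abs(corr[i, j]) > 0.999]
            raise ValueError(f"design matrix is rank deficient; collinear: {pairs}")

    @property
    def effect_index(self) -> int:
        return self.roles.index("effect_of_interest")


@dataclass
class VoxelStatResult:
    t_map: np.ndarray
    beta_maps: np.ndarray            # (n_regressors, *grid)
    max_null: np.ndarray             # (n_perm,) max statistic distribution
    p_fwe: np.ndarray                # corrected p per voxel (1 outside mask)
    threshold: float                 # (1 - alpha) quantile of the max-t null
    alpha: float
    side: str
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    uncorrected_mask: np.ndarray | None = None


def build_design(cohort_table: pd.DataFrame, model_id: str) -> DesignMatrix:
    """Design matrix for one of the canonical models.

    Continuous regressors are mean-centered; sex is coded F=-1/2, M=+1/2.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; choose from {list(MODELS)}")
    spec = MODELS[model_id]
    cols = [spec["effect"]] + spec["confounds"]
    missing = [c for c in cols if c not in cohort_table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    n = len(cohort_table)
    X = [np.ones(n)]
    names = ["intercept"]
    roles = ["intercept"]
    for c in cols:
        v = cohort_table[c]
        if c == "sex":
            x = v.map({"F": -0.5, "M": 0.5}).to_numpy(dtype=float) \
                if v.dtype == object else np.asarray(v, dtype=float)
        else:
            x = np.asarray(v, dtype=float)
        x = x - x.mean()
        x = x - x.mean()  # second pass removes the floating-point residue
        X.append(x)
        names.append(c)
        roles.append("effect_of_interest" if c == spec["effect"] else "confound")
    return DesignMatrix(np.column_stack(X), names, roles)


def _flatten_stack(map_stack, mask):
    stack = np.stack([np.asarray(getattr(m, "data", m), dtype=float)
                      for m in map_stack]) if not isinstance(map_stack, np.ndarray) \
        else np.asarray(map_stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    return stack.reshape(stack.shape[0], -1)[:, mask.ravel()], mask, stack.shape[1:]


def fit_voxelwise_glm(map_stack, design: DesignMatrix, mask):
    """Per-voxel OLS via one shared pseudo-inverse.

    Returns ``(betas, sigma2, Y, flat_mask_info)`` with ``betas`` of shape
    (n_regressors, n_voxels) and residual variance on n-p degrees of freedom.
    """
    Y, mask, grid = _flatten_stack(map_stack, mask)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("map stack and design rows misaligned")
    if n <= p:
        raise ValueError("need n_subjects > n_regressors")
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    sigma2 = np.sum(resid ** 2, axis=0) / (n - p)
    return betas, sigma2, Y, (mask, grid)


def t_contrast(betas, sigma2, design: DesignMatrix, contrast, side: str = "positive"):
    """t statistic per voxel for a contrast vector.

    ``side`` records the tested tail ('positive' or 'negative') for the
    permutation step; the returned t map is unsigned by side (negate the
    contrast for the opposite tail).  Zero-variance voxels get t=0 unless the
    contrast effect is non-zero there, in which case t is capped at +/-T_CAP.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (design.X.shape[1],):
        raise ValueError("contrast length must equal n_regressors")
    if not np.any(c):
        raise ValueError("contrast vector must be non-zero")
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    xtx_inv = np.linalg.pinv(design.X.T @ design.X)
    cvar = float(c @ xtx_inv @ c)
    eff = c @ betas
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(sigma2 * cvar)
    t[~np.isfinite(t) & (eff == 0)] = 0.0
    np.clip(t, -T_CAP, T_CAP, out=t)   # perfect-fit voxels flagged at the cap
    t[np.isnan(t)] = 0.0
    return t


def permutation_fwe(map_stack, design: DesignMatrix, contrast, side: str,
                    n_perm: int, seed: int, alpha: float = 0.05,
                    mask=None, voxel_size: float = 1.0,
                    uncorrected_p: float = 0.001) -> VoxelStatResult:
    """Freedman-Lane max-statistic permutation test for one contrast."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alpha < 1.0 / (n_perm + 1):
        raise ValueError(f"alpha={alpha} unattainable with n_perm={n_perm}")
    stack0 = np.stack([np.asarray(getattr(m, "data", m), dtype=float)
                       for m in map_stack]) if not isinstance(map_stack, np.ndarray) \
        else np.asarray(map_stack, dtype=float)
    if mask is None:
        mask = np.ones(stack0.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    betas, sigma2, Y, (mask, grid) = fit_voxelwise_glm(stack0, design, mask)
    sgn = 1.0 if side == "positive" else -1.0
    t_obs = sgn * t_contrast(betas, sigma2, design, contrast, side)

    # reduced model: everything the contrast does not touch
    X = design.X
    keep = np.flatnonzero(np.asarray(contrast, dtype=float) == 0)
    Xr = X[:, keep] if keep.size else np.ones((X.shape[0], 1))
    pinv_r = np.linalg.pinv(Xr)
    fit_r = Xr @ (pinv_r @ Y)
    resid_r = Y - fit_r

    n, p = X.shape
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cvar = float(np.asarray(contrast) @ xtx_inv @ np.asarray(contrast))
    c = np.asarray(contrast, dtype=float)

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(n)
        Yp = fit_r + resid_r[perm]
        b = pinv @ Yp
        r = Yp - X @ b
        s2 = np.sum(r ** 2, axis=0) / (n - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = sgn * (c @ b) / np.sqrt(s2 * cvar)
        tp[~np.isfinite(tp)] = 0.0
        max_null[j] = tp.max() if tp.size else 0.0

    p_fwe_flat = (1.0 + np.sum(max_null[None, :] >= t_obs[:, None], axis=1)) \
        / (n_perm + 1.0)
    threshold = float(np.quantile(max_null, 1.0 - alpha))

    t_map = np.zeros(grid)
    t_map[mask] = sgn * t_obs  # back to signed t
    p_map = np.ones(grid)
    p_map[mask] = p_fwe_flat
    beta_maps = np.zeros((betas.shape[0],) + grid)
    beta_maps[:, mask] = betas

    df = n - p
    t_unc = float(stats.t.ppf(1.0 - uncorrected_p, df))
    unc_mask = np.zeros(grid, dtype=bool)
    unc_mask[mask] = t_obs >= t_unc

    clusters = cluster_report(sgn * t_map, threshold, affine=None,
                              voxel_size=voxel_size, max_null=max_null)
    return VoxelStatResult(
        t_map=t_map, beta_maps=beta_maps, max_null=max_null, p_fwe=p_map,
        threshold=threshold, alpha=alpha, side=side, clusters=clusters,
        uncorrected_mask=unc_mask,
    )


def cluster_report(t_map, threshold: float, connectivity: int = 26,
                   affine: np.ndarray | None = None, voxel_size: float = 1.0,
                   max_null: np.ndarray | None = None) -> pd.DataFrame:
    """Connected suprathreshold clusters, sorted by peak statistic.

    ``connectivity`` in {6, 18, 26}; world peak coordinates come from the
    affine (or voxel scaling) for reporting.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    t = np.asarray(t_map, dtype=float)
    supra = t > threshold
    struct = {6: ndimage.generate_binary_structure(3, 1),
              18: ndimage.generate_binary_structure(3, 2),
              26: ndimage.generate_binary_structure(3, 3)}[connectivity]
    lab, n = ndimage.label(supra, structure=struct)
    rows = []
    for i in range(1, n + 1):
        sel = lab == i
        tv = t[sel]
        peak_flat = np.argmax(np.where(sel, t, -np.inf))
        ijk = np.unravel_index(peak_flat, t.shape)
        world = (affine @ np.r_[ijk, 1.0])[:3] if affine is not None \
            else np.asarray(ijk, dtype=float) * voxel_size
        row = {"cluster_id": i, "n_voxels": int(sel.sum()),
               "peak_t": float(tv.max()),
               "peak_i": int(ijk[0]), "peak_j": int(ijk[1]), "peak_k": int(ijk[2]),
               "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
               "peak_z_mm": float(world[2])}
        if max_null is not None:
            row["p_fwe_peak"] = float(
                (1 + np.sum(max_null >= tv.max())) / (len(max_null) + 1))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("peak_t", ascending=False).reset_index(drop=True)
    return df
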