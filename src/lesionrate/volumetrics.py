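"""Whole-brain volumetric measures and cohort statistics.

Volumes follow the threshold-count convention: a class contributes a voxel
when its probability is at or above the threshold.  Total cerebral volume
(TCV) is the volume where GM+WM+WMH probability reaches the threshold
(default 0.2); total intracranial volume (TIV) additionally includes CSF and
is constrained by the brain inclusion mask.  Annualized rates are per-subject
ordinary-least-squares slopes over all available time points (years from
baseline); percentage change is relative to baseline.  Unrepaired
segmentations are the intended input — repair redistributes mass between
classes and would bias class volumes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import TissueProbMaps

TCV_TIV_THRESHOLD = 0.2  # tissue probability threshold for TCV / TIV


def tissue_volumes(segs: TissueProbMaps,
                   wmh_mask: np.ndarray | None = None,
                   lacune_mask: np.ndarray | None = None,
                   brain_mask: np.ndarray | None = None,
                   threshold: float = 0.2,
                   mass_integration: bool = False) -> dict:
    """Volumes (mm^3) for one segmentation.

    ``mass_integration=True`` integrates probability mass instead of counting
    suprathreshold voxels (sensitivity-analysis mode; TCV/TIV stay
    threshold-based by definition).
    """
    for c in ("GM", "WM", "CSF"):
        if c not in segs.class_names:
            raise ValueError(f"class {c!r} missing from segmentation")
    vv = segs.voxel_size ** 3
    out = {}
    for c in segs.class_names:
        m = np.asarray(segs.maps[c], dtype=float)
        out[f"{c.lower()}_mm3"] = float(m.sum() * vv if mass_integration
                                        else (m >= threshold).sum() * vv)
    wmh_prob = np.asarray(segs.maps["WMH"], dtype=float) if "WMH" in segs.maps else 0.0
    if wmh_mask is not None:
        out["wmh_mm3"] = float(np.asarray(wmh_mask, dtype=bool).sum() * vv)
    elif "WMH" not in segs.maps:
        out["wmh_mm3"] = 0.0
    if lacune_mask is not None:
        out["lacune_mm3"] = float(np.asarray(lacune_mask, dtype=bool).sum() * vv)
    else:
        out.setdefault("lacune_mm3", 0.0)

    cerebral = (np.asarray(segs.maps["GM"], dtype=float)
                + np.asarray(segs.maps["WM"], dtype=float) + wmh_prob)
    tcv_vox = cerebral >= TCV_TIV_THRESHOLD
    intracranial = cerebral + np.asarray(segs.maps["CSF"], dtype=float)
    tiv_vox = intracranial >= TCV_TIV_THRESHOLD
    if brain_mask is not None:
        tiv_vox &= np.asarray(brain_mask, dtype=bool)
    out["tcv_mm3"] = float(tcv_vox.sum() * vv)
    out["tiv_mm3"] = float(tiv_vox.sum() * vv)
    return out


def annualized_rate(values, times_years) -> float:
    """Least-squares slope of a volumetric series, units per year."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_years, dtype=float)
    if v.size < 2 or v.size != t.size:
        raise ValueError("need >= 2 paired points")
    if np.unique(t).size < 2:
        raise ValueError("times must not be identical")
    tc = t - t.mean()
    return float(np.sum(tc * (v - v.mean())) / np.sum(tc ** 2))


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (followup - baseline) / baseline


def volume_table(per_subject_rows: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble per-(subject, time) volume rows into one tidy table.

    ``per_subject_rows`` maps subject_id to a frame with a ``time_years``
    column plus volume columns; adds per-subject annualized rates and percent
    change from baseline for every volume column.
    """
    frames = []
    for sid, df in per_subject_rows.items():
        df = df.sort_values("time_years").reset_index(drop=True)
        df.insert(0, "subject_id", sid)
        vol_cols = [c for c in df.columns if c.endswith("_mm3")]
        for c in vol_cols:
            base = df[c].iloc[0]
            df[c.replace("_mm3", "_pctchange")] = [
                np.nan if i == 0 else (percent_change(base, v) if base > 0 else np.nan)
                for i, v in enumerate(df[c])]
            df[c.replace("_mm3", "_rate")] = (
                annualized_rate(df[c], df["time_years"]) if len(df) >= 2 else np.nan)
        frames.append(df)
        if "tiv_mm3" in df and df["tiv_mm3"].iloc[0] > 0:
            rel = df["tiv_mm3"].max() / max(df["tiv_mm3"].min(), 1e-9) - 1
            if rel > 0.05:
                warnings.warn(f"TIV varies by {100*rel:.1f}% within {sid}",
                              stacklevel=2)
    return pd.concat(frames, ignore_index=True)


def reliability_metrics(v1, v2) -> dict:
    """Inter/intra-rater reliability for paired volume measurements.

    * ``sem_mm3``: standard error of measurement, SD(v1-v2)/sqrt(2).
    * ``mean_variability_pct`` (+SD): per-pair 100*|v1-v2|/mean(v1,v2).
    * ``icc``: two-way random-effects, absolute-agreement, single-measure
      intraclass correlation, from its ANOVA decomposition.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.size != v2.size or v1.size < 2:
        raise ValueError("need paired lists of length >= 2")
    pair_mean = (v1 + v2) / 2.0
    ok = pair_mean != 0
    if not np.all(ok):
        warnings.warn("zero-mean pairs dropped", stacklevel=2)
        v1, v2, pair_mean = v1[ok], v2[ok], pair_mean[ok]
    diff = v1 - v2
    sem = float(np.std(diff, ddof=1) / np.sqrt(2.0))
    variability = 100.0 * np.abs(diff) / pair_mean

    n = v1.size
    k = 2
    data = np.stack([v1, v2], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return {
        "sem_mm3": sem,
        "mean_variability_pct": float(variability.mean()),
        "variability_sd_pct": float(variability.std(ddof=1)) if n > 1 else 0.0,
        "icc": icc,
    }


def cohort_stats(table: pd.DataFrame, tests: list[dict]) -> pd.DataFrame:
    """Run a list of cohort-level tests and return a tidy results frame.

    Each test spec is a dict with a ``kind`` key:

    * ``{"kind": "pearson", "x": col, "y": col}``
    * ``{"kind": "ttest_1tailed", "value": col, "group": col, "alternative": "less"|"greater"}``
      one-tailed two-sample t between the two groups (sorted group labels).
    * ``{"kind": "anova", "value": col, "group": col}``
    * ``{"kind": "kruskal", "value": col, "group": col}``
    * ``{"kind": "auto_group", "value": col, "group": col}`` — Shapiro
      normality screen at alpha 0.05 choosing ANOVA vs Kruskal-Wallis.
    """
    rows = []
    for spec in tests:
        kind = spec["kind"]
        if kind == "pearson":
            x = table[spec["x"]].dropna()
            y = table[spec["y"]].dropna()
            common = x.index.intersection(y.index)
            if len(common) < 3:
                raise ValueError("Pearson correlation needs n >= 3")
            r, p = stats.pearsonr(table.loc[common, spec["x"]],
                                  table.loc[common, spec["y"]])
            rows.append({"test": "pearson", "variables": f"{spec['x']}~{spec['y']}",
                         "statistic": float(r), "p": float(p), "n": len(common)})
            continue
        vals = table[spec["value"]]
        groups = [vals[table[spec["group"]] == g].dropna().to_numpy()
                  for g in sorted(table[spec["group"]].unique())]
        label = f"{spec['value']}~{spec['group']}"
        n = int(sum(len(g) for g in groups))
        if kind == "ttest_1tailed":
            if len(groups) != 2:
                raise ValueError("one-tailed t-test needs exactly 2 groups")
            t, p = stats.ttest_ind(groups[0], groups[1],
                                   alternative=spec.get("alternative", "less"))
            rows.append({"test": "ttest_1tailed", "variables": label,
                         "statistic": float(t), "p": float(p), "n": n})
        elif kind in ("anova", "kruskal", "auto_group"):
            if kind == "auto_group":
                normal = all(len(g) >= 3 and stats.shapiro(g).pvalue >= 0.05
                             for g in groups)
                kind = "anova" if normal else "kruskal"
            fn = stats.f_oneway if kind == "anova" else stats.kruskal
            s, p = fn(*groups)
            rows.append({"test": kind, "variables": label,
                         "statistic": float(s), "p": float(p), "n": n})
        else:
            raise ValueError(f"unknown test kind {kind!r}")
    return pd.DataFrame(rows)
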