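"""Declarative, resumable pipeline: phantom -> segmentation -> repair ->
longitudinal warping -> group maps -> volumetrics -> voxel statistics.

The run is driven by a YAML config with one block per stage.  Every stage
writes its products under ``<out>/<stage>/`` together with a provenance
record (parameter hash + input hashes); re-running with an unchanged config
skips up-to-date stages, and deleting one stage's outputs regenerates only
that stage and its dependents.  A single global seed is fanned out to the
stages by hashing the stage name, so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import VolumeImage
from . import groupmaps, registration, repair, segmentation, volumetrics, voxelstats
from .phantom import PhantomParams, generate_cohort, write_cohort

STAGES = ["phantom", "segment", "repair", "longitudinal", "groupmaps",
          "volumes", "vbm"]
_DEPENDENTS = {s: STAGES[i + 1:] for i, s in enumerate(STAGES)}

DEFAULT_CONFIG = {
    "out_dir": "run",
    "seed": 0,
    "stages": list(STAGES),
    "phantom": {"grid_shape": [48, 48, 48], "n_subjects": 4,
                "times_years": [0.0, 1.0, 2.0]},
    "segment": {"wmh_threshold": 0.5, "max_iter": 60, "tol": 1e-5,
                "min_component_voxels": 5, "tpm_smoothing_fwhm_mm": 4.0},
    "repair": {},
    "longitudinal": {"n_outer_iters": 2, "iters": [20, 15, 8]},
    "groupmaps": {"fwhm_mm": 6.0, "min_count": 1},
    "volumes": {"threshold": 0.2},
    "vbm": {"model": "gm_vs_wmhrate", "side": "negative", "n_perm": 200,
            "alpha": 0.05},
    "limits": {"max_grid": 128, "max_subjects": 200},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("unreadable config: top level must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def validate_config(config: dict) -> list[str]:
    """Return a list of contract violations (empty when valid)."""
    v: list[str] = []
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        v.append(f"stages: unknown stage(s) {unknown}")
    ph = config.get("phantom", {})
    try:
        PhantomParams(**{k: tuple(val) if isinstance(val, list) else val
                         for k, val in ph.items()}).validate()
    except (TypeError, ValueError) as e:
        v.append(f"phantom: {e}")
    limits = config.get("limits", {})
    grid = ph.get("grid_shape", [64, 64, 64])
    if max(grid) > limits.get("max_grid", 128):
        v.append(f"phantom.grid_shape: exceeds limits.max_grid={limits.get('max_grid')}")
    if ph.get("n_subjects", 2) > limits.get("max_subjects", 200):
        v.append("phantom.n_subjects: exceeds limits.max_subjects")
    seg = config.get("segment", {})
    thr = seg.get("wmh_threshold", 0.5)
    if isinstance(thr, (int, float)) and not 0 < thr < 1:
        v.append("segment.wmh_threshold: must lie in the open interval (0, 1)")
    if seg.get("max_iter", 60) < 1:
        v.append("segment.max_iter: must be >= 1")
    vbm = config.get("vbm", {})
    if "vbm" in stages:
        if config.get("seed") is None:
            v.append("seed: required when the vbm (permutation) stage is enabled")
        if vbm.get("n_perm", 200) < 100:
            v.append("vbm.n_perm: must be >= 100")
        if vbm.get("model") not in voxelstats.MODELS:
            v.append(f"vbm.model: unknown (choose from {list(voxelstats.MODELS)})")
        alpha = vbm.get("alpha", 0.05)
        if not 0 < alpha < 1:
            v.append("vbm.alpha: must lie in (0, 1)")
    gm = config.get("groupmaps", {})
    if gm.get("fwhm_mm", 6.0) < 0:
        v.append("groupmaps.fwhm_mm: must be >= 0")
    if gm.get("min_count", 1) < 1:
        v.append("groupmaps.min_count: must be >= 1")
    return v


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


class _Provenance:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "provenance.json"
        self.records = {}
        if self.path.exists():
            self.records = json.loads(self.path.read_text())

    def stage_ok(self, stage: str, param_hash: str, outputs: list[Path]) -> bool:
        rec = self.records.get(stage)
        return (rec is not None and rec["param_hash"] == param_hash
                and all(Path(p).exists() for p in rec["outputs"])
                and bool(rec["outputs"]))

    def record(self, stage: str, param_hash: str, outputs: list[Path],
               inputs: list[str]) -> None:
        self.records[stage] = {
            "stage": stage, "param_hash": param_hash,
            "outputs": [str(p) for p in outputs],
            "input_hashes": inputs,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "version": __version__,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.records, indent=1))

    def invalidate(self, stage: str) -> None:
        for s in [stage] + _DEPENDENTS.get(stage, []):
            self.records.pop(s, None)


def run_pipeline(config: dict, dry_run: bool = False) -> dict:
    """Execute the configured stages in dependency order.

    Returns a machine-readable summary: per stage, whether it ran or was
    skipped (up to date), its outputs, and wall time.  Raises on the first
    stage failure after persisting partial provenance.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n" + "\n".join(violations))
    out = Path(config["out_dir"])
    prov = _Provenance(out)
    seed = int(config.get("seed", 0))
    requested = [s for s in STAGES if s in config.get("stages", STAGES)]

    summary = {"stages": [], "out_dir": str(out), "version": __version__}
    state: dict = {}
    for stage in STAGES:
        entry = {"name": stage, "requested": stage in requested,
                 "ran": False, "skipped_up_to_date": False,
                 "outputs": [], "seconds": 0.0}
        if stage not in requested:
            summary["stages"].append(entry)
            continue
        scfg = config.get(stage, {})
        ph = _params_hash({"stage": scfg, "seed": seed,
                           "phantom": config.get("phantom")})
        sdir = out / stage
        runner = _RUNNERS[stage]
        if prov.stage_ok(stage, ph, []) and not dry_run:
            entry["skipped_up_to_date"] = True
            entry["outputs"] = prov.records[stage]["outputs"]
            runner(config, state, sdir, seed, load_only=True)
            summary["stages"].append(entry)
            continue
        if dry_run:
            summary["stages"].append(entry)
            continue
        t0 = time.time()
        outputs = runner(config, state, sdir, seed, load_only=False)
        entry["seconds"] = round(time.time() - t0, 2)
        entry["ran"] = True
        entry["outputs"] = [str(p) for p in outputs]
        prov.record(stage, ph, outputs, inputs=[])
        summary["stages"].append(entry)
    (out / "summary.json").parent.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


# ---------------------------------------------------------------------------
# stage runners: each populates `state` for downstream stages and returns the
# files it wrote
# ---------------------------------------------------------------------------

def _phantom_params(config, seed) -> PhantomParams:
    ph = {k: tuple(v) if isinstance(v, list) else v
          for k, v in config.get("phantom", {}).items()}
    ph.setdefault("random_seed", stage_seed(seed, "phantom"))
    return PhantomParams(**ph)


def _run_phantom(config, state, sdir, seed, load_only=False):
    params = _phantom_params(config, seed)
    series, truths, table = generate_cohort(params)
    state.update(series=series, truths=truths, cohort_table=table, params=params)
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    write_cohort(series, truths, table, sdir)
    return sorted(sdir.glob("*"))


def _run_segment(config, state, sdir, seed, load_only=False):
    scfg = config.get("segment", {})
    params = state["params"]
    cfg = segmentation.SegmentConfig(
        max_iter=int(scfg.get("max_iter", 60)),
        tol=float(scfg.get("tol", 1e-5)),
        wmh_threshold=scfg.get("wmh_threshold", 0.5),
        min_component_voxels=int(scfg.get("min_component_voxels", 5)),
    )
    # first pass with intensity-anchor priors, pooled into population TPMs
    first = []
    for series, truth in zip(state["series"], state["truths"]):
        for tp in series.timepoints:
            anchor = segmentation.quantile_anchor_tpms(
                tp.t1_image, tp.flair_image, truth.icv_mask)
            post, _ = segmentation.segment_tissues(tp.t1_image, tp.flair_image,
                                                   anchor, cfg)
            first.append(post)
    tpms = segmentation.build_population_tpms(
        first, float(scfg.get("tpm_smoothing_fwhm_mm", 4.0)))
    posteriors, wmh_masks = [], []
    for series in state["series"]:
        subj_post, subj_masks = [], []
        for tp in series.timepoints:
            post, _ = segmentation.segment_tissues(tp.t1_image, tp.flair_image,
                                                   tpms, cfg)
            m = segmentation.binarize_wmh(post.maps["WMH"], cfg.wmh_threshold,
                                          min_component_voxels=cfg.min_component_voxels)
            subj_post.append(post)
            subj_masks.append(m)
        posteriors.append(subj_post)
        wmh_masks.append(subj_masks)
    state.update(tpms=tpms, posteriors=posteriors, wmh_masks=wmh_masks)
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    files = []
    vox = state["params"].voxel_size_mm
    for c in tpms.class_names:
        f = sdir / f"tpm_{c}.nii.gz"
        VolumeImage(tpms.maps[c], vox).save(f)
        files.append(f)
    for series, subj_post, subj_masks in zip(state["series"], posteriors, wmh_masks):
        for k, (post, m) in enumerate(zip(subj_post, subj_masks), start=1):
            for c in post.class_names:
                f = sdir / f"{series.subject_id}_ses-{k}_p{c}.nii.gz"
                VolumeImage(post.maps[c], vox).save(f)
                files.append(f)
            f = sdir / f"{series.subject_id}_ses-{k}_wmhmask.nii.gz"
            VolumeImage(m.astype(np.uint8), vox).save(f)
            files.append(f)
    return files


def _run_repair(config, state, sdir, seed, load_only=False):
    vox = state["params"].voxel_size_mm
    repaired_all = []
    for series, truth, subj_post, subj_masks in zip(
            state["series"], state["truths"], state["posteriors"],
            state["wmh_masks"]):
        reps = []
        for post, wmh_m in zip(subj_post, subj_masks):
            rep = repair.repair_segmentation(post, wmh_m,
                                             brain_mask=truth.icv_mask)
            reps.append(rep)
        lac = [np.asarray(tp.lacune_mask.data, dtype=bool)
               for tp in series.timepoints]
        segs = [r.as_tpms(vox) for r in reps]
        repair.repair_lacunes(segs, lac, state["tpms"])
        repaired_all.append(segs)
    state["repaired"] = repaired_all
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    files = []
    for series, segs in zip(state["series"], repaired_all):
        for k, seg in enumerate(segs, start=1):
            for c in seg.class_names:
                f = sdir / f"{series.subject_id}_ses-{k}_r{c}.nii.gz"
                VolumeImage(seg.maps[c], vox).save(f)
                files.append(f)
    return files


def _run_longitudinal(config, state, sdir, seed, load_only=False):
    lcfg = config.get("longitudinal", {})
    reg_cfg = registration.RegConfig(
        iters=tuple(lcfg.get("iters", [20, 15, 8])))
    vox = state["params"].voxel_size_mm
    n_outer = int(lcfg.get("n_outer_iters", 2))
    averages, rates, divs_all = [], [], []
    for series, segs in zip(state["series"], state["repaired"]):
        chans = [[np.asarray(s.maps[c], dtype=float)
                  for c in ("CSF", "GM", "WM")] for s in segs]
        tmpl, vfs, defs, jacs = registration.build_subject_average(
            chans, n_outer_iters=n_outer, config=reg_cfg)
        divs = [registration.divergence_map(v) for v in vfs]
        rate = registration.fit_rate_map(divs, series.times_years)
        averages.append(tmpl)
        rates.append(rate)
        divs_all.append(divs)
    state.update(subject_averages=averages, rate_maps=rates)
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    files = []
    for series, tmpl, rate in zip(state["series"], averages, rates):
        f = sdir / f"{series.subject_id}_ratemap.nii.gz"
        VolumeImage(rate, vox).save(f)
        files.append(f)
        for c, arr in zip(("CSF", "GM", "WM"), tmpl):
            f = sdir / f"{series.subject_id}_avg_{c}.nii.gz"
            VolumeImage(arr, vox).save(f)
            files.append(f)
    return files


def _run_groupmaps(config, state, sdir, seed, load_only=False):
    gcfg = config.get("groupmaps", {})
    vox = state["params"].voxel_size_mm
    tmpl, vfs, defs, jacs = registration.build_group_template(
        state["subject_averages"], n_outer_iters=2)
    warped_gm, warped_rate, warped_wmh = [], [], []
    for si, (series, rate, deform, truth, masks) in enumerate(zip(
            state["series"], state["rate_maps"], defs, state["truths"],
            state["wmh_masks"])):
        warped_rate.append(groupmaps.warp_to_group(rate, deform))
        gm_avg = state["subject_averages"][si][1]
        warped_gm.append(groupmaps.warp_to_group(gm_avg, deform))
        wmh_union = np.zeros(rate.shape, dtype=bool)
        for m in masks:
            wmh_union |= m
        warped_wmh.append(groupmaps.warp_to_group(
            wmh_union.astype(float), deform) > 0.5)
    avg_gm_rate = groupmaps.cohort_average_rate(warped_gm, warped_rate)
    norm_rate, norm_support = groupmaps.normalized_wmh_rate(
        warped_rate, warped_wmh, min_count=int(gcfg.get("min_count", 1)))
    fwhm = float(gcfg.get("fwhm_mm", 6.0))
    vbq_stack = []
    for g, r in zip(warped_gm, warped_rate):
        sm, _ = groupmaps.vbq_weighted_smooth(r, g, fwhm, vox)
        vbq_stack.append(sm)
    state.update(group_template=tmpl, avg_gm_rate=avg_gm_rate,
                 norm_wmh_rate=norm_rate, norm_support=norm_support,
                 vbq_gm_rate_stack=np.stack(vbq_stack),
                 group_gm=tmpl[1])
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, arr in [("avg_rate_GM", avg_gm_rate),
                      ("norm_wmh_rate", norm_rate),
                      ("norm_wmh_rate_mask", norm_support.astype(np.uint8))]:
        f = sdir / f"{name}.nii.gz"
        VolumeImage(np.asarray(arr, dtype=float), vox).save(f)
        files.append(f)
    for series, sm in zip(state["series"], state["vbq_gm_rate_stack"]):
        f = sdir / f"vbq_GM_rate_{series.subject_id}.nii.gz"
        VolumeImage(sm, vox).save(f)
        files.append(f)
    return files


def _run_volumes(config, state, sdir, seed, load_only=False):
    thr = float(config.get("volumes", {}).get("threshold", 0.2))
    rows = {}
    for series, truth, subj_post, subj_masks in zip(
            state["series"], state["truths"], state["posteriors"],
            state["wmh_masks"]):
        recs = []
        for tp, post, wmh_m in zip(series.timepoints, subj_post, subj_masks):
            vol = volumetrics.tissue_volumes(
                post, wmh_mask=wmh_m,
                lacune_mask=np.asarray(tp.lacune_mask.data, dtype=bool),
                brain_mask=truth.icv_mask, threshold=thr)
            vol["time_years"] = tp.time_years
            recs.append(vol)
        rows[series.subject_id] = pd.DataFrame(recs)
    table = volumetrics.volume_table(rows)
    state["volume_table"] = table

    # per-subject summary rates feed the vbm design
    summ = table.groupby("subject_id").first().reset_index()
    ct = state["cohort_table"].merge(
        summ[["subject_id", "gm_rate", "wmh_rate", "wmh_mm3", "lacune_mm3",
              "tiv_mm3"]], on="subject_id")
    ct = ct.rename(columns={"wmh_mm3": "wmh_baseline", "tiv_mm3": "tiv",
                            "lacune_mm3": "lacune_volume"})
    state["design_table"] = ct
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    f = sdir / "volumes.tsv"
    table.to_csv(f, sep="\t", index=False)
    f2 = sdir / "design.tsv"
    ct.to_csv(f2, sep="\t", index=False)
    return [f, f2]


def _run_vbm(config, state, sdir, seed, load_only=False):
    vcfg = config.get("vbm", {})
    table = state["design_table"]
    model = vcfg.get("model", "gm_vs_wmhrate")
    try:
        design = voxelstats.build_design(table, model)
    except ValueError:
        if load_only:
            return []
        sdir.mkdir(parents=True, exist_ok=True)
        f = sdir / "SKIPPED.txt"
        f.write_text("vbm skipped: design not estimable for this cohort size\n")
        return [f]
    if len(table) <= design.X.shape[1]:
        if load_only:
            return []
        sdir.mkdir(parents=True, exist_ok=True)
        f = sdir / "SKIPPED.txt"
        f.write_text("vbm skipped: n_subjects <= n_regressors\n")
        return [f]
    stack = state["vbq_gm_rate_stack"]
    mask = state["group_gm"] > 0.2
    contrast = np.zeros(design.X.shape[1])
    contrast[design.effect_index] = 1.0
    side = vcfg.get("side", "negative")
    if side == "negative":
        contrast = -contrast
    res = voxelstats.permutation_fwe(
        stack, design, contrast, "positive", int(vcfg.get("n_perm", 200)),
        stage_seed(seed, "vbm"), alpha=float(vcfg.get("alpha", 0.05)), mask=mask,
        voxel_size=state["params"].voxel_size_mm)
    state["vbm_result"] = res
    if load_only:
        return []
    sdir.mkdir(parents=True, exist_ok=True)
    vox = state["params"].voxel_size_mm
    files = []
    for name, arr in [("tmap", res.t_map), ("pfwe", res.p_fwe)]:
        f = sdir / f"{name}_{model}_{side}.nii.gz"
        VolumeImage(arr, vox).save(f)
        files.append(f)
    f = sdir / f"clusters_{model}_{side}.tsv"
    res.clusters.to_csv(f, sep="\t", index=False)
    files.append(f)
    return files


_RUNNERS = {
    "phantom": _run_phantom, "segment": _run_segment, "repair": _run_repair,
    "longitudinal": _run_longitudinal, "groupmaps": _run_groupmaps,
    "volumes": _run_volumes, "vbm": _run_vbm,
}
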