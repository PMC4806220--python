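"""Two-stage longitudinal warping: SVF registration, divergence and rate maps.

The deformation model is a stationary velocity field (SVF) ``v`` whose flow
``exp(v)`` (computed by scaling-and-squaring) is a diffeomorphism.  Pairwise
registration is a multi-resolution demons-style descent on multi-channel
sum-of-squared-differences over tissue probability maps, with Gaussian
(fluid + elastic) regularization and backtracking step control that rejects
any update producing a non-positive Jacobian.

Conventions
-----------
* ``register_pair(moving, fixed)`` returns ``v`` such that
  ``fixed(exp(v)(x)) ~= moving(x)``: exponentiating ``+v`` maps the moving
  (reference / individual-average) grid into the fixed (time-point) image.
* Velocity fields are stored in world millimetres, shape ``(3, X, Y, Z)``.
* Divergence is ``div v`` in 1/(unit warp): positive where the time point is
  locally expanded relative to the reference.  With time points registered to
  a mid-point average, tissue loss over time therefore yields negative
  rate-map values.
* A rate map is the per-voxel ordinary-least-squares slope of divergence
  against acquisition time in years from baseline (units 1/year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class RegConfig:
    """Registration hyper-parameters (units: voxels at the current level)."""

    n_levels: int = 3
    iters: tuple[int, ...] = (30, 20, 10)     # coarse -> fine
    sigma_fluid: float = 1.0                  # smoothing of the update force
    sigma_elastic: float = 1.5                # smoothing of the velocity field
    step0: float = 0.4                        # initial max update, voxels
    min_squarings: int = 6
    max_backtracks: int = 4
    pad_voxels: int = 4                       # velocity support margin around brain


@dataclass
class VelocityField:
    """Stationary velocity field in world mm, components-first."""

    v_mm: np.ndarray            # (3, X, Y, Z)
    voxel_size: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v_mm)):
            raise ValueError("velocity field contains non-finite values")


@dataclass
class Deformation:
    """Dense displacement (voxel units) of the flow of a velocity field."""

    disp_vox: np.ndarray        # (3, X, Y, Z), x -> x + disp(x)
    voxel_size: float
    velocity: VelocityField | None = field(default=None, repr=False)

    def apply(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Pull-back resampling: ``out(x) = image(x + disp(x))``."""
        return warp_image(image, self.disp_vox, order=order, cval=cval)

    def inverse(self) -> "Deformation":
        if self.velocity is None:
            raise ValueError("inverse requires the generating velocity field")
        neg = VelocityField(-self.velocity.v_mm, self.voxel_size)
        return exponentiate(neg)

    def jacobian(self) -> np.ndarray:
        return jacobian_determinant(self.disp_vox)


def _identity_grid(shape) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                indexing="ij"))


def warp_image(image: np.ndarray, disp_vox: np.ndarray, order: int = 1,
               cval: float = 0.0) -> np.ndarray:
    """Sample ``image`` at ``x + disp(x)`` (trilinear by default)."""
    grid = _identity_grid(image.shape)
    coords = grid + disp_vox
    return ndimage.map_coordinates(image, coords, order=order, mode="constant",
                                   cval=cval)


def _compose_disp(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Displacement of ``x -> x + w(x) + u(x + w(x))`` (i.e. u after w)."""
    grid = _identity_grid(u.shape[1:])
    coords = grid + w
    out = np.empty_like(u)
    for i in range(3):
        out[i] = w[i] + ndimage.map_coordinates(u[i], coords, order=1,
                                                mode="nearest")
    return out


def exponentiate(v: VelocityField, min_squarings: int = 6) -> Deformation:
    """Flow of a stationary velocity field by scaling and squaring."""
    u = v.v_mm / v.voxel_size  # displacement rate in voxels
    max_disp = float(np.max(np.sqrt(np.sum(u ** 2, axis=0)))) if u.size else 0.0
    n = min_squarings
    if max_disp > 0:
        n = max(min_squarings, int(np.ceil(np.log2(max(max_disp / 0.25, 1e-12)))))
    d = u / (2 ** n)
    for _ in range(n):
        d = _compose_disp(d, d)
    return Deformation(d, v.voxel_size, velocity=v)


def jacobian_determinant(disp_vox: np.ndarray) -> np.ndarray:
    """Determinant of ``I + grad(disp)`` by central differences (one-sided at
    the boundary); dimensionless local volume-change factor."""
    g = np.empty((3, 3) + disp_vox.shape[1:])
    for i in range(3):
        grads = np.gradient(disp_vox[i], axis=(0, 1, 2))
        for j in range(3):
            g[i, j] = grads[j]
    for i in range(3):
        g[i, i] += 1.0
    det = (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )
    return det


def divergence(v_mm: np.ndarray, voxel_size: float) -> np.ndarray:
    """``div v`` by central differences in world mm (one-sided at edges)."""
    out = np.zeros(v_mm.shape[1:], dtype=float)
    for i in range(3):
        out += np.gradient(v_mm[i], voxel_size, axis=i)
    return out


def divergence_map(v: VelocityField) -> np.ndarray:
    return divergence(v.v_mm, v.voxel_size)


def fit_rate_map(divergences, times_years) -> np.ndarray:
    """Per-voxel OLS slope of divergence against time (1/year).

    ``divergences`` is a sequence of same-shape maps; slope is the closed-form
    ``sum((t-tbar)(d-dbar)) / sum((t-tbar)^2)``; the intercept is discarded.
    """
    t = np.asarray(times_years, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 time points")
    if np.unique(t).size != t.size:
        raise ValueError("times must be distinct")
    stack = np.stack([np.asarray(d, dtype=float) for d in divergences])
    tc = t - t.mean()
    denom = float(np.sum(tc ** 2))
    dc = stack - stack.mean(axis=0)
    return np.tensordot(tc, dc, axes=(0, 0)) / denom


# ---------------------------------------------------------------------------
# pairwise SVF registration
# ---------------------------------------------------------------------------

def _downsample(img: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(img, 1.0)
    return sm[::2, ::2, ::2]


def _upsample_disp(u: np.ndarray, shape) -> np.ndarray:
    out = np.empty((3,) + tuple(shape))
    zoom = [s / c for s, c in zip(shape, u.shape[1:])]
    for i in range(3):
        out[i] = ndimage.zoom(u[i], zoom, order=1, mode="nearest") * zoom[i]
    return out


def _ssd(ref_chans, mov_chans, disp) -> float:
    s = 0.0
    for r, m in zip(ref_chans, mov_chans):
        s += float(np.sum((r - warp_image(m, disp)) ** 2))
    return s


def _support_mask(ref_chans, mov_chans, pad: int) -> np.ndarray:
    occ = np.zeros(ref_chans[0].shape, dtype=bool)
    for c in list(ref_chans) + list(mov_chans):
        occ |= np.abs(c) > 1e-3
    return ndimage.binary_dilation(occ, iterations=pad) if pad else occ


def _svf_level(ref_chans, mov_chans, v_vox, cfg: RegConfig, n_iters: int):
    """Demons iterations at one pyramid level; velocity in level-voxels."""
    support = _support_mask(ref_chans, mov_chans, cfg.pad_voxels)
    disp = exponentiate(VelocityField(v_vox, 1.0), cfg.min_squarings).disp_vox
    best = _ssd(ref_chans, mov_chans, disp)
    step = cfg.step0
    fails = 0
    for _ in range(n_iters):
        force = np.zeros_like(v_vox)
        for r, m in zip(ref_chans, mov_chans):
            w = warp_image(m, disp)
            diff = r - w
            gw = np.gradient(w)
            for i in range(3):
                force[i] += diff * gw[i]
        for i in range(3):
            force[i] = ndimage.gaussian_filter(force[i], cfg.sigma_fluid)
        fmax = float(np.max(np.sqrt(np.sum(force ** 2, axis=0))))
        if fmax < 1e-12:
            break
        force *= support
        accepted = False
        trial_step = step
        for _ in range(cfg.max_backtracks):
            v_new = v_vox + (trial_step / fmax) * force
            for i in range(3):
                v_new[i] = ndimage.gaussian_filter(v_new[i], cfg.sigma_elastic)
                v_new[i] *= support
            disp_new = exponentiate(VelocityField(v_new, 1.0),
                                    cfg.min_squarings).disp_vox
            ssd_new = _ssd(ref_chans, mov_chans, disp_new)
            if ssd_new < best and np.min(jacobian_determinant(disp_new)) > 0:
                v_vox, disp, best = v_new, disp_new, ssd_new
                step = min(trial_step * 1.2, 2.0)
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            fails += 1
            if fails >= 2:
                break
    return v_vox


def register_pair(moving, fixed, config: RegConfig | None = None):
    """Register ``fixed`` onto the grid of ``moving`` via an SVF.

    ``moving``/``fixed`` are sequences of same-grid channel arrays (tissue
    probability maps) or single arrays.  Returns
    ``(VelocityField, Deformation, jacobian)`` where the deformation is
    ``exp(+v)`` mapping moving-grid coordinates into the fixed image and the
    Jacobian is its determinant map (e.g. ``e^{3a}`` when the fixed image is
    the moving anatomy contracted at rate ``a`` for unit time).
    """
    cfg = config or RegConfig()
    mov_chans, vox = _as_channels(moving)
    fix_chans, vox_f = _as_channels(fixed)
    if vox_f != vox:
        raise ValueError("voxel size mismatch")
    if mov_chans[0].shape != fix_chans[0].shape:
        raise ValueError("grid shape mismatch")
    if len(mov_chans) != len(fix_chans) or not mov_chans:
        raise ValueError("need >= 1 common channel")

    # pyramids: ref = moving grid, mov = fixed image (pull-back direction)
    levels = [(list(mov_chans), list(fix_chans))]
    for _ in range(cfg.n_levels - 1):
        prev_r, prev_m = levels[-1]
        if min(prev_r[0].shape) < 16:
            break
        levels.append(([_downsample(c) for c in prev_r],
                       [_downsample(c) for c in prev_m]))
    levels = levels[::-1]  # coarse -> fine
    iters = list(cfg.iters[-len(levels):])

    v = np.zeros((3,) + levels[0][0][0].shape)
    for li, (ref_c, mov_c) in enumerate(levels):
        if v.shape[1:] != ref_c[0].shape:
            v = _upsample_disp(v, ref_c[0].shape)
        v = _svf_level(ref_c, mov_c, v, cfg, iters[li])

    vf = VelocityField(v * vox, vox)
    deform = exponentiate(vf, cfg.min_squarings)
    jac = deform.jacobian()
    if np.min(jac) <= 0:
        raise RuntimeError("registration produced a non-diffeomorphic deformation")
    return vf, deform, jac


def _as_channels(obj):
    """Accept a TissueProbMaps-like object, list of arrays, or one array."""
    vox = 1.0
    if hasattr(obj, "maps") and hasattr(obj, "class_names"):
        vox = float(getattr(obj, "voxel_size", 1.0))
        chans = [np.asarray(obj.maps[c], dtype=float) for c in obj.class_names]
    elif isinstance(obj, (list, tuple)):
        chans = [np.asarray(c, dtype=float) for c in obj]
    else:
        arr = np.asarray(obj, dtype=float)
        chans = [arr]
    return chans, vox


# ---------------------------------------------------------------------------
# barycentric template building
# ---------------------------------------------------------------------------

def _mean_channels(channel_stacks):
    """Voxel-wise mean over a list of channel lists."""
    n_ch = len(channel_stacks[0])
    return [np.mean([cs[i] for cs in channel_stacks], axis=0) for i in range(n_ch)]


def build_subject_average(series_maps, n_outer_iters: int = 3,
                          config: RegConfig | None = None):
    """Within-subject average template and per-time-point velocity fields.

    ``series_maps``: per-time-point channel lists (repaired or lesioned tissue
    probability maps on a common grid).  Iterates: register every time point
    to the current template, subtract the mean velocity (so the template stays
    at the barycenter of the series), re-average the warped maps.

    Returns ``(template_channels, velocities, deformations, jacobians)``,
    where ``exp(+v_k)`` maps the template grid to time point ``k``.
    """
    cfg = config or RegConfig()
    chans = [_as_channels(m)[0] for m in series_maps]
    vox = _as_channels(series_maps[0])[1]
    if not 2 <= len(chans) <= 4:
        raise ValueError("need 2-4 time points")
    template = _mean_channels(chans)

    velocities = [np.zeros((3,) + template[0].shape) for _ in chans]
    prev_rms = np.inf
    rises = 0
    for _ in range(n_outer_iters):
        new_v = []
        for tp in chans:
            vf, _, _ = register_pair(template, tp, cfg)
            new_v.append(vf.v_mm)
        vbar = np.mean(new_v, axis=0)
        new_v = [v - vbar for v in new_v]
        warped = []
        for tp, v in zip(chans, new_v):
            disp = exponentiate(VelocityField(v, vox)).disp_vox
            warped.append([warp_image(c, disp) for c in tp])
        new_template = _mean_channels(warped)
        rms = float(np.sqrt(np.mean(
            [(a - b) ** 2 for a, b in zip(new_template, template)])))
        velocities, template = new_v, new_template
        if rms > prev_rms:
            rises += 1
            if rises >= 2:
                warnings.warn("subject average did not converge; returning best",
                              stacklevel=2)
                break
        prev_rms = rms

    vfs = [VelocityField(v, vox) for v in velocities]
    deforms = [exponentiate(vf) for vf in vfs]
    jacs = [d.jacobian() for d in deforms]
    return template, vfs, deforms, jacs


def build_group_template(individual_averages, n_outer_iters: int = 3,
                         config: RegConfig | None = None):
    """Between-subject group template from individual average maps.

    Same barycentric scheme as :func:`build_subject_average`, across subjects.
    Returns ``(template_channels, velocities, deformations, jacobians)`` with
    ``exp(+v_s)`` mapping the group grid into subject ``s`` space (the
    deformation used to pull subject maps onto the group grid).
    """
    if len(individual_averages) < 2:
        raise ValueError("need >= 2 subjects")
    cfg = config or RegConfig()
    chans = [_as_channels(m)[0] for m in individual_averages]
    vox = _as_channels(individual_averages[0])[1]
    template = _mean_channels(chans)
    velocities = [np.zeros((3,) + template[0].shape) for _ in chans]
    prev_rms = np.inf
    rises = 0
    for _ in range(n_outer_iters):
        new_v = []
        for subj in chans:
            vf, _, _ = register_pair(template, subj, cfg)
            new_v.append(vf.v_mm)
        vbar = np.mean(new_v, axis=0)
        new_v = [v - vbar for v in new_v]
        warped = []
        for subj, v in zip(chans, new_v):
            disp = exponentiate(VelocityField(v, vox)).disp_vox
            warped.append([warp_image(c, disp) for c in subj])
        new_template = _mean_channels(warped)
        rms = float(np.sqrt(np.mean(
            [(a - b) ** 2 for a, b in zip(new_template, template)])))
        velocities, template = new_v, new_template
        if rms > prev_rms:
            rises += 1
            if rises >= 2:
                warnings.warn("group template did not converge; returning best",
                              stacklevel=2)
                break
        prev_rms = rms

    vfs = [VelocityField(v, vox) for v in velocities]
    deforms = [exponentiate(vf) for vf in vfs]
    jacs = [d.jacobian() for d in deforms]
    return template, vfs, deforms, jacs
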