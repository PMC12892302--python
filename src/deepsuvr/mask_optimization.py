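"""Data-driven derivation of reference and target Centiloid masks.

The trained correction network is a black box; to make its effect usable
in standard pipelines, new reference/target masks are optimized so that
the plain SUVRs they produce correlate maximally with the corrected
SUVRs.  Voxel weights are learnable parameters (sigmoid of unconstrained
logits, so always in [0, 1]); the loss is

    L = mean_tracers(1 - R^2(mask SUVR, corrected SUVR))
        + delta * (binarity(reference) + binarity(target))

with the binarity penalty sum(0.5 - |M - 0.5|)/B over the B brain
voxels.  After every gradient step the logits are smoothed with a 4 mm
FWHM kernel (spatial consistency) and averaged with their left-right
flip (symmetry).  delta starts small (5e-4) and is multiplied by 100
after 20 epochs, once the correlation term has taken shape.  A 3-level
multiresolution schedule (x4, x2, x1 downsampling) speeds up and
stabilizes convergence.  Because the resulting mask SUVRs are only
optimized for correlation, a per-tracer linear recalibration maps them
onto the corrected-SUVR scale before the Centiloid transform is applied.

Gradients are computed analytically (the SUVR of a weighted mask is a
ratio of linear functionals, so the chain rule is short) and stepped by
momentum gradient descent normalized by the global gradient RMS; the
per-voxel gradient magnitude encodes which voxels matter, so
per-parameter adaptive normalizers are deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .centiloid import MaskVolume
from .phantom import BrainGrid, fwhm_to_sigma_mm

__all__ = [
    "MaskOptConfig",
    "LearnableMaskPair",
    "binarity_loss",
    "pearson_loss",
    "optimize_masks",
    "recalibrate_masks",
    "binarize",
]


@dataclass
class MaskOptConfig:
    """Optimization schedule.

    ``delta`` is the binarity weight, multiplied by ``delta_ramp_factor``
    after ``delta_ramp_epochs`` epochs; one epoch is ``iters_per_epoch``
    gradient steps (the full-batch gradient makes "iteration" and "pass
    over the data" coincide, so the epoch length of the minibatch
    formulation is kept as an explicit knob).  Steps are plain gradient
    descent with momentum, normalized by the global gradient RMS — the
    per-voxel gradient *magnitude* carries the information about which
    voxels matter, so per-parameter normalizers (Adam-style) are
    deliberately avoided.  ``min_iters`` applies per multiresolution
    level; a level ends once the Pearson-loss improvement stays below
    ``tol`` and the minimum iteration count is reached.
    """

    delta: float = 5e-4
    delta_ramp_factor: float = 100.0
    delta_ramp_epochs: int = 20
    iters_per_epoch: int = 100
    smooth_fwhm_mm: float = 4.0
    tol: float = 1e-8
    level_factors: tuple[int, ...] = (4, 2, 1)
    min_iters: tuple[int, ...] = (1000, 3000, 8000)
    max_iters_per_level: int = 12000
    lr: float = 0.2
    momentum: float = 0.9
    init_clip: float = 0.2
    random_smoothing: bool = True
    max_smooth_fwhm_mm: float = 8.0

    def __post_init__(self):
        if self.delta <= 0 or self.tol <= 0:
            raise ValueError("delta and tol must be positive")


@dataclass
class LearnableMaskPair:
    reference: MaskVolume
    target: MaskVolume
    level: int = 3


def binarity_loss(mask: np.ndarray, brain_mask: np.ndarray) -> float:
    """Mean distance from binarity over brain voxels: sum(0.5-|M-0.5|)/B."""
    m = np.asarray(mask, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    b = int(brain.sum())
    if b == 0:
        raise ValueError("empty brain mask")
    vals = m[brain]
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    return float(np.sum(0.5 - np.abs(vals - 0.5)) / b)


def pearson_loss(mask_suvrs, corrected_suvrs) -> float:
    """1 - R^2 between mask-derived and corrected SUVRs (one tracer)."""
    x = np.asarray(mask_suvrs, dtype=float)
    y = np.asarray(corrected_suvrs, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need matched samples, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance SUVRs")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r**2


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _suvr_and_grads(x_flat, m_t, m_r):
    """SUVRs of all scans under masks plus the pieces needed for gradients."""
    st, sr = m_t.sum(), m_r.sum()
    t = x_flat @ m_t / st
    r = x_flat @ m_r / sr
    return t, r, t / r, st, sr


def _pearson_grad_s(s, c):
    """d(1 - r^2)/ds for one tracer group (returns loss too)."""
    u = s - s.mean()
    v = c - c.mean()
    uu = float(u @ u)
    vv = float(v @ v)
    uv = float(u @ v)
    if uu <= 0 or vv <= 0:
        raise ValueError("zero-variance SUVRs in a tracer group")
    r2 = uv**2 / (uu * vv)
    g = -(2 * uv * v * uu - 2 * uv**2 * u) / (uu**2 * vv)
    g -= g.mean()  # centering (d u/d s)
    return 1.0 - r2, g


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vol.astype(np.float64)
    return ndimage.zoom(vol.astype(np.float64), 1.0 / factor, order=1, grid_mode=True, mode="nearest")


def _upsample_to(z: np.ndarray, shape) -> np.ndarray:
    zoomf = [s / zs for s, zs in zip(shape, z.shape)]
    out = ndimage.zoom(z, zoomf, order=1, grid_mode=True, mode="nearest")
    # zoom can be off by one voxel on odd sizes; pad/crop to the exact shape
    pads = [(0, max(0, s - o)) for s, o in zip(shape, out.shape)]
    out = np.pad(out, pads, mode="edge")
    return out[tuple(slice(0, s) for s in shape)]


def optimize_masks(
    scans_by_tracer: Mapping[str, np.ndarray],
    corrected_suvrs: Mapping[str, np.ndarray],
    init_masks: tuple[MaskVolume, MaskVolume],
    config: MaskOptConfig = MaskOptConfig(),
    seed: int = 0,
) -> tuple[LearnableMaskPair, pd.DataFrame]:
    """Gradient optimization of a (reference, target) mask pair.

    ``scans_by_tracer`` maps tracer code to an (n_scans, D, H, W) stack of
    SUVR-scale volumes; ``corrected_suvrs`` holds the matching corrected
    SUVR per scan.  ``init_masks`` is (reference, target); their grid
    supplies shape, voxel size and brain mask.  Returns the optimized
    continuous masks (threshold with ``binarize`` for shipping) and a
    per-iteration history of the losses.
    """
    reference0, target0 = init_masks
    grid = reference0.grid
    if grid is None:
        raise ValueError("init masks must carry their BrainGrid")
    if len(scans_by_tracer) < 2:
        raise ValueError("need at least 2 tracers for the averaged Pearson loss")
    shape = grid.shape
    brain_full = grid.brain_mask
    rng = np.random.default_rng(seed)

    def to_logit(mask_values, sig_vox):
        sm = ndimage.gaussian_filter(mask_values.astype(np.float64), sigma=sig_vox)
        # soft clip keeps init logits unsaturated so excluded voxels stay recruitable
        sm = np.clip(sm, config.init_clip, 1 - config.init_clip)
        return np.log(sm / (1 - sm))

    sig0 = fwhm_to_sigma_mm(config.smooth_fwhm_mm) / grid.voxel_size_mm
    z_ref_full = to_logit(reference0.values, sig0)
    z_tgt_full = to_logit(target0.values, sig0)

    tracers = sorted(scans_by_tracer)
    history = []
    level_factors = config.level_factors
    z_ref = z_tgt = None
    it_global = 0
    for level, factor in enumerate(level_factors, start=1):
        lvl_shape = _downsample(np.zeros(shape), factor).shape
        brain = _downsample(brain_full.astype(np.float64), factor) > 0.25
        if z_ref is None:
            z_ref = _downsample(z_ref_full, factor)
            z_tgt = _downsample(z_tgt_full, factor)
        else:
            z_ref = _upsample_to(z_ref, lvl_shape)
            z_tgt = _upsample_to(z_tgt, lvl_shape)
        sig_vox = fwhm_to_sigma_mm(config.smooth_fwhm_mm) / (grid.voxel_size_mm * factor)

        xs, cs, groups = [], [], []
        for tr in tracers:
            stack = np.asarray(scans_by_tracer[tr], dtype=np.float64)
            for j in range(stack.shape[0]):
                vol = stack[j]
                if config.random_smoothing:
                    fw = rng.uniform(0.0, config.max_smooth_fwhm_mm)
                    if fw > 1e-6:
                        vol = ndimage.gaussian_filter(
                            vol, sigma=fwhm_to_sigma_mm(fw) / grid.voxel_size_mm
                        )
                xs.append(_downsample(vol, factor).ravel())
            cs.append(np.asarray(corrected_suvrs[tr], dtype=float))
            groups.append(stack.shape[0])
        x_flat = np.stack(xs)
        bounds = np.cumsum([0] + groups)
        b_count = max(int(brain.sum()), 1)
        bflat = brain.ravel()

        vel_ref = np.zeros_like(z_ref)
        vel_tgt = np.zeros_like(z_tgt)
        prev_lp = np.inf
        stall = 0
        min_it = config.min_iters[level - 1]
        ramp_iter = config.delta_ramp_epochs * config.iters_per_epoch
        for it in range(config.max_iters_per_level):
            delta = config.delta * (
                config.delta_ramp_factor if it_global >= ramp_iter else 1.0
            )
            mr = _sigmoid(z_ref.ravel()) * bflat
            mt = _sigmoid(z_tgt.ravel()) * bflat
            t_val, r_val, s_val, st, sr = _suvr_and_grads(x_flat, mt, mr)
            lp_sum = 0.0
            q = np.zeros_like(s_val)
            for gi, tr in enumerate(tracers):
                sl = slice(bounds[gi], bounds[gi + 1])
                lp, g = _pearson_grad_s(s_val[sl], cs[gi])
                lp_sum += lp
                q[sl] = g / len(tracers)
            lp_mean = lp_sum / len(tracers)

            # chain rule: s = t/r with t, r weighted means
            w_t = q / r_val
            grad_mt = (x_flat.T @ w_t - float(w_t @ t_val)) / st
            w_r = -q * t_val / r_val**2
            grad_mr = (x_flat.T @ w_r - float(w_r @ r_val)) / sr
            # binarity
            lb_r = float(np.sum(0.5 - np.abs(mr[bflat] - 0.5)) / b_count)
            lb_t = float(np.sum(0.5 - np.abs(mt[bflat] - 0.5)) / b_count)
            grad_mr += delta * (-np.sign(mr - 0.5)) / b_count * bflat
            grad_mt += delta * (-np.sign(mt - 0.5)) / b_count * bflat

            total = lp_mean + delta * (lb_r + lb_t)
            history.append(
                dict(level=level, iteration=it, L_p=lp_mean, L_b_ref=lb_r, L_b_tgt=lb_t, delta=delta, total=total)
            )
            if not np.isfinite(total):
                raise FloatingPointError("mask optimization diverged (non-finite loss)")

            sr_ = _sigmoid(z_ref.ravel())
            st_ = _sigmoid(z_tgt.ravel())
            gz_ref = (grad_mr * sr_ * (1 - sr_) * bflat).reshape(z_ref.shape)
            gz_tgt = (grad_mt * st_ * (1 - st_) * bflat).reshape(z_tgt.shape)

            rms = np.sqrt(
                np.mean(gz_ref.ravel()[bflat] ** 2 + gz_tgt.ravel()[bflat] ** 2)
            )
            vel_ref = config.momentum * vel_ref + gz_ref / (rms + 1e-12)
            vel_tgt = config.momentum * vel_tgt + gz_tgt / (rms + 1e-12)
            z_ref = z_ref - config.lr * vel_ref
            z_tgt = z_tgt - config.lr * vel_tgt

            # spatial consistency + symmetry, every iteration
            z_ref = ndimage.gaussian_filter(z_ref, sigma=sig_vox)
            z_tgt = ndimage.gaussian_filter(z_tgt, sigma=sig_vox)
            z_ref = 0.5 * (z_ref + z_ref[::-1, :, :])
            z_tgt = 0.5 * (z_tgt + z_tgt[::-1, :, :])

            it_global += 1
            if abs(prev_lp - lp_mean) < config.tol:
                stall += 1
            else:
                stall = 0
            prev_lp = lp_mean
            if it + 1 >= min_it and stall >= 5:
                break

    ref_vals = np.clip(_sigmoid(z_ref) * brain_full, 0.0, 1.0)
    tgt_vals = np.clip(_sigmoid(z_tgt) * brain_full, 0.0, 1.0)
    pair = LearnableMaskPair(
        reference=MaskVolume(ref_vals, grid=grid, name="optimized_reference"),
        target=MaskVolume(tgt_vals, grid=grid, name="optimized_target"),
        level=len(level_factors),
    )
    return pair, pd.DataFrame(history)


def binarize(mask: MaskVolume, threshold: float = 0.5) -> MaskVolume:
    """Hard-threshold a near-binary optimized mask for shipping."""
    return MaskVolume((mask.values >= threshold).astype(float), grid=mask.grid, name=mask.name + "_bin")


def recalibrate_masks(
    mask_suvrs: Mapping[str, np.ndarray],
    corrected_suvrs: Mapping[str, np.ndarray],
) -> dict[str, tuple[float, float]]:
    """Per-tracer linear map from mask SUVR to the corrected-SUVR scale.

    Ordinary least squares of corrected on mask SUVR; compose the result
    with the tracer's standard Centiloid transform to obtain Centiloids
    from the new masks.
    """
    out: dict[str, tuple[float, float]] = {}
    for tracer, ms in mask_suvrs.items():
        x = np.asarray(ms, dtype=float)
        y = np.asarray(corrected_suvrs[tracer], dtype=float)
        if x.size < 3:
            raise ValueError(f"tracer {tracer}: need >= 3 scans for recalibration")
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx <= 0:
            raise ValueError(f"tracer {tracer}: degenerate fit (zero variance)")
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        out[tracer] = (slope, float(y.mean() - slope * x.mean()))
    return out
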