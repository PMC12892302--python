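"""Longitudinal-consistency training penalties.

All four penalties act on corrected Centiloids of same-subject scan
pairs within a batch:

* ``L_d = max(0, CL_T0 - CL_T1)`` — amyloid burden must not decrease in
  an observational setting;
* ``L_c = |rate - f_c(mean)|`` — the pair's annual rate of change should
  match the natural-history curve at the pair's mean Centiloid;
* ``L_s = |s - 1|`` and ``L_i = |i|`` — the batch-level regression of
  corrected on uncorrected Centiloid should have unit slope and zero
  intercept, preventing scale drift and collapse.

The combined loss is ``mean(L_d) + alpha*mean(L_c) + beta*L_s +
gamma*L_i`` with defaults alpha=0.2, beta=1, gamma=0.01.  Per-pair terms
are averaged (not summed) so the effective weighting is independent of
batch size.  ``combined_loss_grad`` additionally returns the analytic
(sub)gradient with respect to every corrected Centiloid, which the
trainer chains through the Centiloid transform and the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import RateCurve

__all__ = [
    "LossWeights",
    "BatchPairs",
    "loss_decrease",
    "loss_curve",
    "loss_slope_intercept",
    "combined_loss",
    "combined_loss_grad",
]


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.2
    beta: float = 1.0
    gamma: float = 0.01

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class BatchPairs:
    """Corrected and standard Centiloids for a batch of scan pairs."""

    cl0_corrected: np.ndarray
    cl1_corrected: np.ndarray
    cl0_standard: np.ndarray
    cl1_standard: np.ndarray
    t0: np.ndarray
    t1: np.ndarray

    def __post_init__(self):
        for f in ("cl0_corrected", "cl1_corrected", "cl0_standard", "cl1_standard", "t0", "t1"):
            setattr(self, f, np.atleast_1d(np.asarray(getattr(self, f), dtype=float)))
        if np.any(self.t1 <= self.t0):
            raise ValueError("each pair must have T1 > T0")


def loss_decrease(cl0, cl1):
    """Hinge on Centiloid decrease: max(0, CL_T0 - CL_T1), elementwise."""
    out = np.maximum(0.0, np.asarray(cl0, dtype=float) - np.asarray(cl1, dtype=float))
    return float(out) if out.ndim == 0 else out


def loss_curve(cl0, cl1, t0, t1, curve: RateCurve):
    """Absolute deviation of the observed rate from the reference curve."""
    cl0, cl1 = np.asarray(cl0, dtype=float), np.asarray(cl1, dtype=float)
    t0, t1 = np.asarray(t0, dtype=float), np.asarray(t1, dtype=float)
    if np.any(t1 <= t0):
        raise ValueError("each pair must have T1 > T0")
    rate = (cl1 - cl0) / (t1 - t0)
    expected = curve((cl0 + cl1) / 2.0)
    out = np.abs(rate - expected)
    return float(out) if out.ndim == 0 else out


def loss_slope_intercept(corrected, standard) -> tuple[float, float]:
    """(|slope-1|, |intercept|) of the OLS fit of corrected on standard CL."""
    y = np.asarray(corrected, dtype=float)
    x = np.asarray(standard, dtype=float)
    if y.size < 3:
        raise ValueError("batch regression needs at least 3 scans")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 0:
        raise ValueError("standard Centiloids have zero variance in this batch")
    s = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    i = float(y.mean() - s * x.mean())
    return abs(s - 1.0), abs(i)


def combined_loss(
    batch: BatchPairs, curve: RateCurve, weights: LossWeights = LossWeights()
) -> tuple[float, dict[str, float]]:
    """Total training loss and its components for one batch."""
    ld = float(np.mean(loss_decrease(batch.cl0_corrected, batch.cl1_corrected)))
    lc = float(
        np.mean(loss_curve(batch.cl0_corrected, batch.cl1_corrected, batch.t0, batch.t1, curve))
    )
    corrected = np.concatenate([batch.cl0_corrected, batch.cl1_corrected])
    standard = np.concatenate([batch.cl0_standard, batch.cl1_standard])
    ls, li = loss_slope_intercept(corrected, standard)
    total = ld + weights.alpha * lc + weights.beta * ls + weights.gamma * li
    return total, {"L_d": ld, "L_c": lc, "L_s": ls, "L_i": li}


def combined_loss_grad(
    batch: BatchPairs, curve: RateCurve, weights: LossWeights = LossWeights()
) -> tuple[float, dict[str, float], np.ndarray, np.ndarray]:
    """Loss, components, and d(loss)/d(corrected CL) for both pair members.

    Returns ``(total, components, g0, g1)`` where ``g0[i]`` is the
    derivative with respect to the corrected baseline Centiloid of pair i.
    Absolute values and the hinge use sign subgradients (0 at kinks); the
    curve derivative is the piecewise-constant slope of the interpolant.
    """
    n = batch.cl0_corrected.size
    cl0, cl1 = batch.cl0_corrected, batch.cl1_corrected
    dt = batch.t1 - batch.t0

    g0 = np.zeros(n)
    g1 = np.zeros(n)
    # L_d
    dec = cl0 > cl1
    ld = float(np.mean(np.maximum(0.0, cl0 - cl1)))
    g0 += dec / n
    g1 += -dec.astype(float) / n
    # L_c
    mean_cl = (cl0 + cl1) / 2.0
    rate = (cl1 - cl0) / dt
    resid = rate - curve(mean_cl)
    lc = float(np.mean(np.abs(resid)))
    sgn = np.sign(resid)
    fslope = curve.slope(mean_cl)
    g0 += weights.alpha * sgn * (-1.0 / dt - fslope / 2.0) / n
    g1 += weights.alpha * sgn * (1.0 / dt - fslope / 2.0) / n
    # L_s / L_i over the pooled batch
    y = np.concatenate([cl0, cl1])
    x = np.concatenate([batch.cl0_standard, batch.cl1_standard])
    m = y.size
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx <= 0:
        raise ValueError("standard Centiloids have zero variance in this batch")
    s = float((xc * (y - y.mean())).sum() / sxx)
    i = float(y.mean() - s * x.mean())
    ls, li = abs(s - 1.0), abs(i)
    ds_dy = xc / sxx
    di_dy = 1.0 / m - x.mean() * ds_dy
    gy = weights.beta * np.sign(s - 1.0) * ds_dy + weights.gamma * np.sign(i) * di_dy
    g0 += gy[:n]
    g1 += gy[n:]

    total = ld + weights.alpha * lc + weights.beta * ls + weights.gamma * li
    return total, {"L_d": ld, "L_c": lc, "L_s": ls, "L_i": li}, g0, g1
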