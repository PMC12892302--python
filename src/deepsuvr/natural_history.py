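"""The natural-history rate curve f_c: expected CL/year given current CL.

Amyloid accumulation follows a population-level unimodal trajectory:
near-zero accumulation while amyloid-negative, a peak of a few CL/year in
the intermediate range, and slowing at high burden.  The curve is
estimated once, from standard-quantification scan pairs of a single
tracer, by lowess (tricube-weighted local linear regression, smoothing
fraction 0.2, two robustifying iterations), frozen on a fixed grid, and
then used as the static reference inside the longitudinal training loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = ["RateCurve", "compute_pair_stats", "fit_rate_curve", "evaluate_curve"]

DEFAULT_FRAC = 0.2
DEFAULT_GRID_SIZE = 201
ROBUSTIFYING_ITERS = 2


@dataclass(frozen=True)
class RateCurve:
    """A frozen lowess fit evaluated by linear interpolation, clamped
    to its endpoint values outside the fitted support."""

    support_CL: np.ndarray
    expected_rate: np.ndarray
    frac: float = DEFAULT_FRAC

    def __post_init__(self):
        s = np.asarray(self.support_CL, dtype=float)
        r = np.asarray(self.expected_rate, dtype=float)
        if s.ndim != 1 or s.shape != r.shape or s.size < 2:
            raise ValueError("support and rates must be 1-d arrays of equal length >= 2")
        if np.any(np.diff(s) <= 0):
            raise ValueError("support_CL must be strictly increasing")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(r))):
            raise ValueError("curve contains non-finite values")
        object.__setattr__(self, "support_CL", s)
        object.__setattr__(self, "expected_rate", r)

    def __call__(self, mean_CL):
        out = np.interp(np.asarray(mean_CL, dtype=float), self.support_CL, self.expected_rate)
        return float(out) if out.ndim == 0 else out

    def slope(self, mean_CL):
        """Piecewise-constant derivative of the interpolant (used by the
        analytic gradient of the curve loss)."""
        m = np.atleast_1d(np.asarray(mean_CL, dtype=float))
        seg = np.clip(np.searchsorted(self.support_CL, m) - 1, 0, self.support_CL.size - 2)
        ds = np.diff(self.support_CL)[seg]
        dr = np.diff(self.expected_rate)[seg]
        out = dr / ds
        out[(m < self.support_CL[0]) | (m > self.support_CL[-1])] = 0.0
        return float(out[0]) if np.isscalar(mean_CL) or np.ndim(mean_CL) == 0 else out

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        pd.DataFrame(
            {"mean_CL": self.support_CL, "expected_rate": self.expected_rate}
        ).to_csv(csv_path, index=False)
        csv_path.with_suffix(".json").write_text(json.dumps({"frac": self.frac}))

    @classmethod
    def load(cls, csv_path: str | Path) -> "RateCurve":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        frac = DEFAULT_FRAC
        sidecar = csv_path.with_suffix(".json")
        if sidecar.exists():
            frac = json.loads(sidecar.read_text())["frac"]
        return cls(df["mean_CL"].to_numpy(), df["expected_rate"].to_numpy(), frac=frac)


def compute_pair_stats(
    pairs: pd.DataFrame,
    cl0: str = "CL0",
    t0: str = "T0",
    cl1: str = "CL1",
    t1: str = "T1",
    subject: str | None = "subject_id",
) -> pd.DataFrame:
    """Per-pair mean Centiloid and annual rate of change.

    rate = (CL1 - CL0) / (T1 - T0),  mean = (CL1 + CL0) / 2.
    """
    df = pairs
    dt = df[t1].to_numpy(dtype=float) - df[t0].to_numpy(dtype=float)
    if np.any(dt <= 0):
        raise ValueError("each pair must have T1 > T0")
    out = pd.DataFrame(
        {
            "mean_CL": (df[cl1].to_numpy(dtype=float) + df[cl0].to_numpy(dtype=float)) / 2.0,
            "rate_CL_per_year": (df[cl1].to_numpy(dtype=float) - df[cl0].to_numpy(dtype=float)) / dt,
            "interval_years": dt,
        }
    )
    if subject is not None and subject in df.columns:
        out["subject_id"] = df[subject].to_numpy()
    return out


def fit_rate_curve(
    stats: pd.DataFrame,
    frac: float = DEFAULT_FRAC,
    grid_size: int = DEFAULT_GRID_SIZE,
    it: int = ROBUSTIFYING_ITERS,
) -> RateCurve:
    """Fit the static lowess reference curve on pair statistics.

    Requires at least 20 pairs spanning at least 30 CL so that the local
    windows are meaningful.  The fit is evaluated once on a fixed grid
    covering the observed mean-CL range and never refit during training.
    """
    mean = stats["mean_CL"].to_numpy(dtype=float)
    rate = stats["rate_CL_per_year"].to_numpy(dtype=float)
    if mean.size < 20:
        raise ValueError(f"need >= 20 pairs to fit the rate curve, got {mean.size}")
    if mean.max() - mean.min() < 30:
        raise ValueError("pairs must span at least 30 CL of mean Centiloid")
    grid = np.linspace(mean.min(), mean.max(), grid_size)
    fitted = _sm_lowess(rate, mean, frac=frac, it=it, xvals=grid)
    if not np.all(np.isfinite(fitted)):
        raise ValueError("lowess fit is degenerate (non-finite values)")
    return RateCurve(support_CL=grid, expected_rate=fitted, frac=frac)


def evaluate_curve(curve: RateCurve, mean_CL):
    """Expected CL/year at ``mean_CL`` (interpolated, endpoint-clamped)."""
    return curve(mean_CL)
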