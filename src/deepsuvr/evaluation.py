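"""Statistics for comparing Centiloid quantification methods.

Cross-sectional: the amyloid-negative peak of a cohort's Centiloid
distribution (lower-mean component of a two-Gaussian mixture), paired
bootstrap comparisons of peak stability across studies/tracers, Cohen's
d, and AUC against binary reads with the F1-optimal threshold.

Longitudinal: annual-rate outlier fractions against a reference range
(default [-5.8, 11.2] CL/year), the Hilbert-Schmidt Independence
Criterion and Spearman rho between mean Centiloid and rate of change,
emergent amyloid-positivity classification, and 5th-order polynomial
trajectory fits whose peak serves as a surrogate for the peak
accumulation rate.

``rate_scaling_simulation`` checks that correction training does not
erase genuine between-group differences in accumulation rate: a planted
rate scaling in 20% of subjects must survive retraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "PeakSummary",
    "OutlierThresholds",
    "EmergenceRule",
    "fit_negative_peak",
    "paired_bootstrap_stability",
    "hsic",
    "outlier_rates",
    "derive_thresholds",
    "cohens_d",
    "auc_and_f1_threshold",
    "classify_emergent",
    "fit_trajectory_polynomial",
    "rate_scaling_simulation",
]


@dataclass(frozen=True)
class PeakSummary:
    """Lower-mean component of a 2-Gaussian mixture fit ("negative peak")."""

    peak_mean: float
    peak_sd: float
    group: str = ""


@dataclass(frozen=True)
class OutlierThresholds:
    """Reference range for plausible annual Centiloid change.

    Defaults follow the published same-scanner, same-tracer reference
    range of [-5.8, 11.2] CL/year; ``derive_thresholds`` recomputes a
    range from a reference sample.
    """

    lower: float = -5.8
    upper: float = 11.2

    def __post_init__(self):
        if not self.lower < 0 < self.upper:
            raise ValueError("thresholds must satisfy lower < 0 < upper")


@dataclass(frozen=True)
class EmergenceRule:
    positivity_CL: float = 30.0
    min_followup_years: float = 4.5
    bracket_edges: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def fit_negative_peak(cl_values, seed: int = 0, group: str = "") -> PeakSummary:
    """EM fit of a two-component 1-d Gaussian mixture; return the first peak.

    The "first" peak is always the component with the lower mean, so the
    result is invariant to component label order.  k-means++ start, 10
    restarts, tolerance 1e-6.
    """
    x = np.asarray(cl_values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 values for a stable mixture fit")
    gm = GaussianMixture(
        n_components=2,
        n_init=10,
        init_params="k-means++",
        tol=1e-6,
        max_iter=500,
        random_state=seed,
    ).fit(x)
    if not gm.converged_:
        raise RuntimeError("EM did not converge")
    lower = int(np.argmin(gm.means_[:, 0]))
    return PeakSummary(
        peak_mean=float(gm.means_[lower, 0]),
        peak_sd=float(np.sqrt(gm.covariances_[lower, 0, 0])),
        group=group,
    )


def paired_bootstrap_stability(
    values: pd.DataFrame,
    reference: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired bootstrap of across-group spread, each method vs a reference.

    ``values`` has one row per group (study or tracer) and one column per
    method.  Groups are resampled with replacement identically for every
    method; the statistic is the standard deviation across groups.  The
    one-sided nonparametric p is the fraction of bootstrap differences
    whose sign is opposite to the mean difference; the 95% CI is the
    percentile interval.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 groups for a meaningful bootstrap")
    if reference not in values.columns:
        raise ValueError(f"reference method {reference!r} not in columns")
    rng = np.random.default_rng(seed)
    arr = values.to_numpy(dtype=float)
    n_groups = arr.shape[0]
    idx = rng.integers(0, n_groups, size=(n_boot, n_groups))
    boot_sd = arr[idx].std(axis=1, ddof=1)  # (n_boot, n_methods)
    ref_col = values.columns.get_loc(reference)
    diffs = boot_sd - boot_sd[:, [ref_col]]
    rows = []
    for j, method in enumerate(values.columns):
        d = diffs[:, j]
        mean_diff = float(d.mean())
        if method == reference:
            p = 0.5
        else:
            opposite = (d * np.sign(mean_diff) < 0) if mean_diff != 0 else np.full(n_boot, 0.5)
            p = float(np.mean(opposite))
        rows.append(
            dict(
                method=method,
                mean_difference=mean_diff,
                p_value=p,
                ci_low=float(np.quantile(d, 0.025)),
                ci_high=float(np.quantile(d, 0.975)),
            )
        )
    return pd.DataFrame(rows).set_index("method")


def _gram(x: np.ndarray) -> np.ndarray:
    d = squareform(pdist(x.reshape(-1, 1)))
    med = np.median(d[d > 0])
    if not np.isfinite(med) or med <= 0:
        raise ValueError("zero-variance input: kernel bandwidth undefined")
    return np.exp(-(d**2) / (2 * med**2))


def hsic(x, y) -> float:
    """Normalized Hilbert-Schmidt Independence Criterion in [0, 1].

    Gaussian kernels with the median-heuristic bandwidth, centered-Gram
    V-statistic, normalized by the geometric mean of the self-HSICs so
    that hsic(x, x) = 1.  Captures nonlinear, nonmonotone dependence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 for HSIC")
    k = _gram(x)
    l = _gram(y)
    h = np.eye(n) - np.ones((n, n)) / n
    kc = h @ k @ h
    lc = h @ l @ h
    xy = float((kc * lc).sum()) / n**2
    xx = float((kc * kc).sum()) / n**2
    yy = float((lc * lc).sum()) / n**2
    return xy / np.sqrt(xx * yy)


def outlier_rates(
    rates, thresholds: OutlierThresholds = OutlierThresholds()
) -> tuple[float, float]:
    """Percent of consecutive-visit pairs with implausible annual change:
    (decrease beyond lower, increase beyond upper)."""
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        return 0.0, 0.0
    neg = float(np.mean(r < thresholds.lower) * 100.0)
    pos = float(np.mean(r > thresholds.upper) * 100.0)
    return neg, pos


def derive_thresholds(reference_rates, coverage: float = 0.90) -> OutlierThresholds:
    """Central percentile bounds enclosing ``coverage`` of reference rates."""
    r = np.asarray(reference_rates, dtype=float)
    if r.size < 50:
        raise ValueError("need at least 50 reference rates")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = float(np.quantile(r, alpha)), float(np.quantile(r, 1.0 - alpha))
    if lo == hi:
        raise ValueError("degenerate reference distribution: equal bounds")
    return OutlierThresholds(lower=lo, upper=hi)


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def auc_and_f1_threshold(cl_values, binary_reads) -> tuple[float, float]:
    """Rank AUC and the Centiloid cut maximizing F1 against binary reads.

    Candidate cuts are midpoints between adjacent sorted values (plus
    outer sentinels); scans at or above the cut are called positive.
    Ties in F1 resolve to the lowest cut.
    """
    x = np.asarray(cl_values, dtype=float)
    y = np.asarray(binary_reads, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, x))
    xs = np.unique(x)
    cuts = np.concatenate([[xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0, [xs[-1] + 1.0]])
    best_f1, best_cut = -1.0, cuts[0]
    for c in cuts:
        pred = x >= c
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_cut = f1, float(c)
    return auc, best_cut


def classify_emergent(
    trajectories: pd.DataFrame,
    rule: EmergenceRule = EmergenceRule(),
    cl_column: str = "CL",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Label baseline-negative subjects as emergent amyloid-positive or stable.

    Eligibility: baseline CL below the positivity threshold and follow-up
    spanning at least ``min_followup_years``.  Returns (per-subject labels,
    per-bracket emergence proportions over baseline CL brackets, number of
    subjects excluded).
    """
    labels = []
    n_excluded = 0
    for sid, grp in trajectories.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_years")
        cl = grp[cl_column].to_numpy(dtype=float)
        t = grp["time_years"].to_numpy(dtype=float)
        baseline = cl[0]
        span = t[-1] - t[0]
        if baseline >= rule.positivity_CL or span < rule.min_followup_years:
            n_excluded += 1
            continue
        emergent = bool(np.any(cl[1:] >= rule.positivity_CL))
        labels.append(
            dict(subject_id=sid, baseline_CL=baseline, followup_years=span, emergent=emergent)
        )
    label_df = pd.DataFrame(labels, columns=["subject_id", "baseline_CL", "followup_years", "emergent"])
    edges = rule.bracket_edges
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = label_df[(label_df["baseline_CL"] >= lo) & (label_df["baseline_CL"] < hi)]
        rows.append(
            dict(
                bracket=f"[{lo:g},{hi:g})",
                n=len(sel),
                proportion_emergent=float(sel["emergent"].mean()) if len(sel) else np.nan,
            )
        )
    return label_df, pd.DataFrame(rows), n_excluded


def fit_trajectory_polynomial(
    pair_stats: pd.DataFrame,
    degree: int = 5,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Least-squares polynomial of annual rate on mean CL; peak within support.

    The peak (location, height) of the fitted curve over the observed
    mean-CL range serves as a surrogate for the peak accumulation rate;
    an optional bootstrap gives its confidence interval.
    """
    mean = pair_stats["mean_CL"].to_numpy(dtype=float)
    rate = pair_stats["rate_CL_per_year"].to_numpy(dtype=float)
    if mean.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} pairs for degree {degree}")
    def _fit(m, r):
        coefs = np.polynomial.polynomial.polyfit(m, r, degree)
        grid = np.linspace(m.min(), m.max(), 512)
        vals = np.polynomial.polynomial.polyval(grid, coefs)
        k = int(np.argmax(vals))
        return coefs, float(grid[k]), float(vals[k])
    coefs, loc, height = _fit(mean, rate)
    if not np.all(np.isfinite(coefs)):
        raise ValueError("ill-conditioned polynomial fit")
    out = {"coefficients": coefs, "peak_CL": loc, "peak_rate": height}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        peaks = []
        for _ in range(n_boot):
            idx = rng.integers(0, mean.size, mean.size)
            try:
                peaks.append(_fit(mean[idx], rate[idx])[2])
            except Exception:
                continue
        out["peak_rate_ci"] = (float(np.quantile(peaks, 0.025)), float(np.quantile(peaks, 0.975)))
    return out


def rate_scaling_simulation(
    cohort,
    transforms,
    factors=(0.9, 1.1, 1.2, 1.5, 2.0),
    split: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    train_cfg=None,
    net_config=None,
) -> pd.DataFrame:
    """Plant a rate scaling in 20% of subjects, retrain, test preservation.

    Visit times of the scaled subset are divided by ``factor`` (images are
    untouched), so the subset's apparent CL/year is multiplied by the
    factor.  For each factor a correction model is retrained on the
    manipulated cohort, and the ratio of the scaled subset's to the
    unscaled subset's polynomial peak rate is reported twice: evaluated
    with the manipulated timelines (expected approximately = factor) and
    with the original timelines (expected approximately 1: the model must
    not transfer the planted trajectory to subjects that do not have it).
    """
    from . import natural_history as nh
    from . import training as tr

    if train_cfg is None:
        train_cfg = tr.TrainConfig(seed=seed)
    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(cohort.table["subject_id"].unique()))
    rng.shuffle(subjects)
    n_scaled = int(round(split[0] * subjects.size))
    scaled_subjects = set(subjects[:n_scaled])

    base = tr.prepare_training_data(cohort, transforms)
    rows = []
    for factor in factors:
        table = base.table.copy()
        in_scaled = table["subject_id"].isin(scaled_subjects).to_numpy()
        table.loc[in_scaled, "time_years"] = table.loc[in_scaled, "time_years"] / factor
        data = tr.TrainingData(
            **{
                **{f: getattr(base, f) for f in base.__dataclass_fields__},
                "time_years": table["time_years"].to_numpy(dtype=float),
                "table": table,
            }
        )
        pairs = tr.select_pairs(table)
        a = pairs["idx_a"].to_numpy()
        b = pairs["idx_b"].to_numpy()
        trc = np.array(data.tracer)
        pib = (trc[a] == "PIB") & (trc[b] == "PIB")
        stats = nh.compute_pair_stats(
            pd.DataFrame(
                {
                    "CL0": data.cl_std[a][pib],
                    "T0": data.time_years[a][pib],
                    "CL1": data.cl_std[b][pib],
                    "T1": data.time_years[b][pib],
                }
            )
        )
        curve = nh.fit_rate_curve(stats)
        folds = tr.split_folds(table, n_folds=5, seed=seed)
        val = {s for s, f in folds.items() if f == 0}
        train = set(folds) - val
        res = tr.train_model(
            data, pairs, curve, train, val, net_config=net_config, train_cfg=train_cfg
        )
        cf = res.model.predict(data.volumes, data.one_hot)
        cl_corr = data.slope * cf * data.suvr_std + data.intercept

        def _peak_ratio(times):
            dt = times[b] - times[a]
            out = {}
            for name, cl in (("corrected", cl_corr), ("standard", data.cl_std)):
                peaks = {}
                for label, sel in (
                    ("scaled", np.isin(pairs["subject_id"], list(scaled_subjects))),
                    ("unscaled", ~np.isin(pairs["subject_id"], list(scaled_subjects))),
                ):
                    st = pd.DataFrame(
                        {
                            "mean_CL": (cl[a][sel] + cl[b][sel]) / 2.0,
                            "rate_CL_per_year": (cl[b][sel] - cl[a][sel]) / dt[sel],
                        }
                    )
                    peaks[label] = fit_trajectory_polynomial(st)["peak_rate"]
                out[name] = peaks["scaled"] / peaks["unscaled"]
            return out

        scaled_ratio = _peak_ratio(data.time_years)
        orig_ratio = _peak_ratio(base.time_years)
        rows.append(
            dict(
                factor=factor,
                peak_ratio_scaled_eval=scaled_ratio["corrected"],
                peak_ratio_original_eval=orig_ratio["corrected"],
                peak_ratio_scaled_eval_std=scaled_ratio["standard"],
                peak_ratio_original_eval_std=orig_ratio["standard"],
                val_spearman=res.val_spearman,
            )
        )
    return pd.DataFrame(rows)
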