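"""Training of the correction network and single-scan inference.

The unit of training is a same-subject scan pair acquired 0.25-3.5 years
apart (shorter gaps make annual rates unstable, longer ones break the
linear-rate approximation).  Subjects are split into balanced
cross-validation folds; each restart trains with early stopping on the
held-out fold's combined loss, and the restart with the highest
validation Spearman correlation between mean Centiloid and annual rate
is kept.  Inference needs only a single scan: the corrected SUVR is
CF * SUVR and the corrected Centiloid its tracer transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr

from .centiloid import CentiloidTransform, apply_centiloid, compute_suvr, standard_masks
from .losses import BatchPairs, LossWeights, combined_loss, combined_loss_grad
from .model import (
    Adam,
    CorrectionModel,
    NetworkConfig,
    build_network,
    desk_config,
    tracer_one_hot,
)
from .natural_history import RateCurve
from .phantom import MAX_INTERVAL_YEARS, MIN_INTERVAL_YEARS, Cohort, fwhm_to_sigma_mm

__all__ = [
    "AugmentationSpec",
    "desk_augmentation",
    "TrainConfig",
    "TrainingData",
    "TrainResult",
    "select_pairs",
    "split_folds",
    "augment",
    "prepare_training_data",
    "train_model",
    "infer_corrected_centiloid",
    "infer_cohort",
]


# --------------------------------------------------------------------------
# pair selection and fold splitting
# --------------------------------------------------------------------------

def select_pairs(
    table: pd.DataFrame,
    min_interval: float = MIN_INTERVAL_YEARS,
    max_interval: float = MAX_INTERVAL_YEARS,
) -> pd.DataFrame:
    """All within-subject ordered scan pairs with interval in bounds.

    For three eligible visits this yields the pairs (1,2), (2,3) and
    (1,3).  Row indices refer to positions in ``table`` (reset to
    0..n-1).  Subjects with no eligible pair contribute nothing.
    """
    table = table.reset_index(drop=True)
    rows = []
    for _, grp in table.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_years")
        idx = grp.index.to_numpy()
        times = grp["time_years"].to_numpy(dtype=float)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                dt = times[j] - times[i]
                if min_interval <= dt <= max_interval:
                    rows.append(
                        dict(
                            idx_a=int(idx[i]),
                            idx_b=int(idx[j]),
                            subject_id=grp["subject_id"].iloc[0],
                            interval_years=float(dt),
                        )
                    )
    return pd.DataFrame(rows, columns=["idx_a", "idx_b", "subject_id", "interval_years"])


def split_folds(
    table: pd.DataFrame, n_folds: int = 5, seed: int = 0, cl_column: str | None = None
) -> dict[str, int]:
    """Greedy balanced subject-level fold assignment.

    Subjects are stratified on (baseline tracer, visit count, baseline
    Centiloid tertile), shuffled within strata, and dealt round-robin so
    every fold sees a similar mix.  Each subject lands in exactly one fold.
    """
    if cl_column is None:
        cl_column = "CL_std" if "CL_std" in table.columns else "true_CL"
    subjects = (
        table.sort_values("time_years")
        .groupby("subject_id")
        .agg(
            tracer=("tracer", "first"),
            n_visits=("scan_id", "count"),
            baseline_cl=(cl_column, "first"),
        )
        .reset_index()
    )
    if len(subjects) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {len(subjects)}")
    try:
        subjects["cl_bin"] = pd.qcut(subjects["baseline_cl"], 3, labels=False, duplicates="drop")
    except ValueError:
        subjects["cl_bin"] = 0
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    counter = 0
    for _, grp in subjects.groupby(["tracer", "n_visits", "cl_bin"], sort=True, observed=True):
        ids = sorted(grp["subject_id"].tolist())
        rng.shuffle(ids)
        for sid in ids:
            assignment[sid] = counter % n_folds
            counter += 1
    return assignment


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Random rotation, smooth nonrigid warp, and incremental PSF blur.

    The blur target FWHM is drawn uniformly in [scanner PSF, ``max_fwhm_mm``]
    and applied as the incremental kernel sqrt(target^2 - psf^2), emulating
    resolution differences between scanners.
    """

    max_rotation_deg: float = 5.0
    nonrigid_sigma_vox: float = 20.0
    nonrigid_magnitude_vox: float = 50.0
    max_fwhm_mm: float = 8.0
    seed: int = 0


def desk_augmentation(voxel_size_mm: float, reference_voxel_mm: float = 2.0) -> AugmentationSpec:
    """Warp parameters rescaled from the 2 mm full-resolution defaults.

    The deformation-field smoothness and magnitude are stated in voxels of
    the 2 mm grid; on coarser desk grids both shrink by the voxel-size
    ratio so the physical displacement (a fraction of a centimetre) is
    preserved.
    """
    scale = reference_voxel_mm / voxel_size_mm
    return AugmentationSpec(
        nonrigid_sigma_vox=20.0 * scale, nonrigid_magnitude_vox=50.0 * scale
    )


def augment(
    volume: np.ndarray,
    spec: AugmentationSpec,
    seed: int,
    psf_fwhm_mm: float = 0.0,
    voxel_size_mm: float = 1.0,
) -> np.ndarray:
    """Apply one random augmentation draw; deterministic given ``seed``."""
    if psf_fwhm_mm > spec.max_fwhm_mm:
        raise ValueError(
            f"scanner PSF {psf_fwhm_mm} mm exceeds the augmentation cap {spec.max_fwhm_mm} mm"
        )
    rng = np.random.default_rng(seed)
    out = np.asarray(volume, dtype=np.float64)

    target_fwhm = float(rng.uniform(psf_fwhm_mm, spec.max_fwhm_mm))
    extra = np.sqrt(max(target_fwhm**2 - psf_fwhm_mm**2, 0.0))
    if extra > 1e-9:
        out = ndimage.gaussian_filter(out, sigma=fwhm_to_sigma_mm(extra) / voxel_size_mm)

    if spec.max_rotation_deg > 0:
        angles = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg, size=3)
        center = (np.array(out.shape) - 1) / 2.0
        rot = np.eye(3)
        for axis, ang in enumerate(np.deg2rad(angles)):
            c, s = np.cos(ang), np.sin(ang)
            r = np.eye(3)
            i, j = [a for a in range(3) if a != axis]
            r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
            rot = rot @ r
        offset = center - rot @ center
        out = ndimage.affine_transform(out, rot, offset=offset, order=1, mode="constant")

    if spec.nonrigid_magnitude_vox > 0 and spec.nonrigid_sigma_vox > 0:
        coords = np.indices(out.shape, dtype=np.float64)
        for ax in range(3):
            noise = rng.uniform(-1.0, 1.0, size=out.shape)
            disp = ndimage.gaussian_filter(noise, sigma=spec.nonrigid_sigma_vox)
            coords[ax] += disp * spec.nonrigid_magnitude_vox
        out = ndimage.map_coordinates(out, coords, order=1, mode="constant")
    return out.astype(np.float32)


# --------------------------------------------------------------------------
# training data preparation
# --------------------------------------------------------------------------

@dataclass
class TrainingData:
    """Pre-quantified cohort ready for network training/inference."""

    volumes: np.ndarray          # (N, D, H, W) cerebellum-normalized, brain-masked
    suvr_std: np.ndarray         # (N,) standard SUVR
    cl_std: np.ndarray           # (N,) standard Centiloid
    tracer: list[str]
    one_hot: np.ndarray          # (N, 5)
    subject_id: np.ndarray
    time_years: np.ndarray
    psf_fwhm_mm: np.ndarray
    slope: np.ndarray            # (N,) per-scan tracer transform slope
    intercept: np.ndarray
    table: pd.DataFrame
    voxel_size_mm: float = 1.0


def prepare_training_data(
    cohort: Cohort, transforms: dict[str, CentiloidTransform]
) -> TrainingData:
    """Quantify every scan with the standard masks and normalize volumes."""
    target, reference = standard_masks(cohort.grid)
    ref = reference.values
    brain = cohort.grid.brain_mask
    n = len(cohort.scans)
    shape = cohort.grid.shape
    vols = np.empty((n, *shape), dtype=np.float32)
    suvr = np.empty(n)
    tracers = []
    for i, scan in enumerate(cohort.scans):
        v = scan.load_volume().astype(np.float64)
        suvr[i] = compute_suvr(v, target, reference)
        ref_mean = (v * ref).sum() / ref.sum()
        nv = v / ref_mean
        nv[~brain] = 0.0
        vols[i] = nv.astype(np.float32)
        tracers.append(scan.acquisition.tracer)
    slope = np.array([transforms[t].slope for t in tracers])
    intercept = np.array([transforms[t].intercept for t in tracers])
    cl_std = slope * suvr + intercept
    table = cohort.table.copy().reset_index(drop=True)
    table["suvr_std"] = suvr
    table["CL_std"] = cl_std
    return TrainingData(
        volumes=vols,
        suvr_std=suvr,
        cl_std=cl_std,
        tracer=tracers,
        one_hot=tracer_one_hot(tracers),
        subject_id=table["subject_id"].to_numpy(),
        time_years=table["time_years"].to_numpy(dtype=float),
        psf_fwhm_mm=table["psf_fwhm_mm"].to_numpy(dtype=float)
        if "psf_fwhm_mm" in table
        else np.zeros(n),
        slope=slope,
        intercept=intercept,
        table=table,
        voxel_size_mm=cohort.grid.voxel_size_mm,
    )


# --------------------------------------------------------------------------
# the train loop
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Desk-scale defaults; the full-scale run uses batch 128 pairs and
    five restarts with an unbounded epoch budget under patience 20.

    Large batches matter here: the per-tracer gradient signal carried by
    tracer-switching pairs is high-variance, and small batches let the
    degenerate global-shrink direction win the optimization race.
    """

    batch_pairs: int = 128
    max_epochs: int = 200
    patience: int = 20
    restarts: int = 2
    lr: float = 3e-3
    seed: int = 0
    augment_spec: AugmentationSpec | None = None


@dataclass
class TrainResult:
    model: CorrectionModel
    log: pd.DataFrame
    val_spearman: float
    restart: int


def _pair_rates(cl: np.ndarray, times: np.ndarray, pairs: pd.DataFrame):
    a = pairs["idx_a"].to_numpy()
    b = pairs["idx_b"].to_numpy()
    dt = times[b] - times[a]
    return (cl[a] + cl[b]) / 2.0, (cl[b] - cl[a]) / dt


def _corrected_cl(data: TrainingData, cf: np.ndarray) -> np.ndarray:
    return data.slope * (cf * data.suvr_std) + data.intercept


def _validation_metrics(
    model: CorrectionModel,
    data: TrainingData,
    pairs: pd.DataFrame,
    curve: RateCurve,
    weights: LossWeights,
) -> tuple[float, float]:
    cf = model.predict(data.volumes, data.one_hot)
    cl = _corrected_cl(data, cf)
    a = pairs["idx_a"].to_numpy()
    b = pairs["idx_b"].to_numpy()
    batch = BatchPairs(
        cl0_corrected=cl[a],
        cl1_corrected=cl[b],
        cl0_standard=data.cl_std[a],
        cl1_standard=data.cl_std[b],
        t0=data.time_years[a],
        t1=data.time_years[b],
    )
    loss, _ = combined_loss(batch, curve, weights)
    mean_cl, rate = _pair_rates(cl, data.time_years, pairs)
    rho = spearmanr(mean_cl, rate).statistic if len(pairs) >= 3 else 0.0
    return loss, float(rho)


def train_model(
    data: TrainingData,
    pairs: pd.DataFrame,
    curve: RateCurve,
    train_subjects: set[str],
    val_subjects: set[str],
    net_config: NetworkConfig | None = None,
    weights: LossWeights = LossWeights(),
    train_cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Train with restarts + early stopping; select by validation Spearman.

    The natural-history ``curve`` must be fitted beforehand and is frozen.
    Training pairs are restricted to ``train_subjects``; the validation
    fold's subjects never contribute a training pair (checked).
    """
    if train_subjects & val_subjects:
        raise ValueError("train and validation subject sets overlap")
    if net_config is None:
        net_config = desk_config(data.volumes.shape[1:], seed=train_cfg.seed)
    pair_subj = pairs["subject_id"].to_numpy()
    train_pairs = pairs[np.isin(pair_subj, list(train_subjects))].reset_index(drop=True)
    val_pairs = pairs[np.isin(pair_subj, list(val_subjects))].reset_index(drop=True)
    if len(train_pairs) == 0:
        raise ValueError("no training pairs after subject filtering")

    best: TrainResult | None = None
    for restart in range(train_cfg.restarts):
        cfg_r = NetworkConfig(
            **{
                **{k: getattr(net_config, k) for k in net_config.__dataclass_fields__},
                "seed": net_config.seed + 1000 * restart,
            }
        )
        model = build_network(cfg_r)
        opt = Adam(model.parameters(), lr=train_cfg.lr)
        rng = np.random.default_rng(train_cfg.seed + 7919 * restart)
        best_val = np.inf
        best_state = None
        since_improve = 0
        log_rows = []
        for epoch in range(train_cfg.max_epochs):
            order = rng.permutation(len(train_pairs))
            comp_sums = {"L_d": 0.0, "L_c": 0.0, "L_s": 0.0, "L_i": 0.0}
            n_batches = 0
            for start in range(0, len(order), train_cfg.batch_pairs):
                sel = order[start : start + train_cfg.batch_pairs]
                if len(sel) < 2:
                    continue  # batch regression needs spread
                a = train_pairs["idx_a"].to_numpy()[sel]
                b = train_pairs["idx_b"].to_numpy()[sel]
                # randomized presentation order of the two pair members
                flip = rng.uniform(size=len(sel)) < 0.5
                first = np.where(flip, b, a)
                second = np.where(flip, a, b)
                stack = np.concatenate([first, second])
                vols = data.volumes[stack]
                if train_cfg.augment_spec is not None:
                    vols = np.stack(
                        [
                            augment(
                                v,
                                train_cfg.augment_spec,
                                seed=int(rng.integers(2**31 - 1)),
                                psf_fwhm_mm=float(data.psf_fwhm_mm[si]),
                                voxel_size_mm=data.voxel_size_mm,
                            )
                            for v, si in zip(vols, stack)
                        ]
                    )
                cf_stack = model.forward(
                    vols, data.one_hot[stack], train=True, rng=rng
                )
                cl_stack = data.slope[stack] * cf_stack * data.suvr_std[stack] + data.intercept[stack]
                pos = {int(s): k for k, s in enumerate(stack)}
                ia = np.array([pos[int(i)] for i in a])
                ib = np.array([pos[int(i)] for i in b])
                batch = BatchPairs(
                    cl0_corrected=cl_stack[ia],
                    cl1_corrected=cl_stack[ib],
                    cl0_standard=data.cl_std[a],
                    cl1_standard=data.cl_std[b],
                    t0=data.time_years[a],
                    t1=data.time_years[b],
                )
                _, comps, g0, g1 = combined_loss_grad(batch, curve, weights)
                dcl = np.zeros(len(stack))
                dcl[ia] += g0
                dcl[ib] += g1
                dcf = dcl * data.slope[stack] * data.suvr_std[stack]
                model.zero_grad()
                model.backward(dcf)
                opt.step()
                for k in comp_sums:
                    comp_sums[k] += comps[k]
                n_batches += 1
            val_loss, val_rho = (
                _validation_metrics(model, data, val_pairs, curve, weights)
                if len(val_pairs)
                else (np.nan, 0.0)
            )
            log_rows.append(
                dict(
                    restart=restart,
                    epoch=epoch,
                    **{k: v / max(n_batches, 1) for k, v in comp_sums.items()},
                    val_loss=val_loss,
                    val_spearman=val_rho,
                )
            )
            if len(val_pairs) and val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = model.get_state()
                since_improve = 0
            else:
                since_improve += 1
                if len(val_pairs) and since_improve >= train_cfg.patience:
                    break
        if best_state is not None:
            model.set_state(best_state)
        _, val_rho = (
            _validation_metrics(model, data, val_pairs, curve, weights)
            if len(val_pairs)
            else (np.nan, 0.0)
        )
        result = TrainResult(
            model=model, log=pd.DataFrame(log_rows), val_spearman=val_rho, restart=restart
        )
        if best is None or result.val_spearman > best.val_spearman:
            best = result
    return best


def infer_corrected_centiloid(
    model: CorrectionModel,
    volume: np.ndarray,
    tracer: str,
    target_mask,
    reference_mask,
    transform: CentiloidTransform,
) -> tuple[float, float, float]:
    """Single-scan inference: (CF, corrected SUVR, corrected CL)."""
    if transform.tracer != tracer:
        raise ValueError(f"transform is for {transform.tracer}, scan uses {tracer}")
    vol = np.asarray(volume, dtype=np.float64)
    suvr = compute_suvr(vol, target_mask, reference_mask)
    ref = np.asarray(
        reference_mask.values if hasattr(reference_mask, "values") else reference_mask,
        dtype=np.float64,
    )
    normalized = vol / ((vol * ref).sum() / ref.sum())
    cf = float(model.predict(normalized[None], tracer_one_hot(tracer))[0])
    suvr_corr = cf * suvr
    return cf, suvr_corr, float(apply_centiloid(suvr_corr, transform))


def infer_cohort(model: CorrectionModel, data: TrainingData) -> pd.DataFrame:
    """Batch inference over a prepared cohort; equals per-scan inference."""
    cf = model.predict(data.volumes, data.one_hot)
    suvr_corr = cf * data.suvr_std
    cl_corr = data.slope * suvr_corr + data.intercept
    out = data.table.copy()
    out["CF"] = cf
    out["suvr_corrected"] = suvr_corr
    out["CL_corrected"] = cl_corr
    return out
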