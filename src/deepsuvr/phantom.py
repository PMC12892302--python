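"""Synthetic amyloid-PET phantom cohorts with known ground truth.

Real amyloid-PET harmonization studies depend on restricted multi-cohort
data.  This module replaces them with brain-shaped label grids in a common
(template-like) space, per-subject amyloid trajectories driven by a
natural-history rate curve, and a forward acquisition model with
tracer-specific non-specific white-matter uptake, scanner point-spread
blur, a multiplicative SUVR bias, and voxel noise.  Because the true
Centiloid burden and the injected biases are known exactly, every
downstream stage (quantification, correction training, mask derivation,
statistics) can be validated by parameter recovery.

Geometry convention: axis 0 is left-right (the symmetry axis), axis 1
posterior-to-anterior, axis 2 inferior-to-superior.  The cerebellum sits
inferior-posterior to the cerebrum, as in template space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "TRACERS",
    "BACKGROUND",
    "CORTICAL_GREY",
    "SUBCORTICAL_WHITE",
    "CEREBELLUM_GREY",
    "CEREBELLUM_WHITE",
    "BRAINSTEM",
    "BrainGrid",
    "SubjectTrajectory",
    "AcquisitionSpec",
    "ScanRecord",
    "Cohort",
    "make_brain_grid",
    "simulate_trajectory",
    "render_volume",
    "render_scan",
    "generate_cohort",
    "default_rate_curve",
    "fwhm_to_sigma_mm",
]

TRACERS = ("PIB", "NAV", "FBB", "FBP", "FMM")

# Compartment labels.
BACKGROUND = 0
CORTICAL_GREY = 1
SUBCORTICAL_WHITE = 2
CEREBELLUM_GREY = 3
CEREBELLUM_WHITE = 4
BRAINSTEM = 5

# Forward-model tissue values, in cerebellum-relative (SUVR-like) units.
# Non-specific white-matter binding differs by tracer: the F18 tracers show
# markedly higher white-matter retention than PIB/NAV.  Under scanner blur
# this spills into the cortical ribbon and makes amyloid-negative scans of
# different tracers disagree by several Centiloids before any correction.
WM_NONSPECIFIC = {"PIB": 1.40, "NAV": 1.30, "FBB": 2.20, "FBP": 2.35, "FMM": 1.80}
GREY_BASE = 1.15          # non-specific cortical grey uptake
SPECIFIC_PER_CL = 0.008   # amyloid-specific cortical signal per Centiloid
CEREB_GREY_VALUE = 0.97
CEREB_WHITE_VALUE = 1.06
BRAINSTEM_VALUE = 1.20

MIN_INTERVAL_YEARS = 0.25   # 3 months
MAX_INTERVAL_YEARS = 3.5


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    """Gaussian FWHM to standard deviation (FWHM = 2 sqrt(2 ln 2) sigma)."""
    return fwhm_mm / 2.3548200450309493


@dataclass(frozen=True)
class BrainGrid:
    """A brain-shaped label volume standing in for template-space images."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    labels: np.ndarray

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def compartment(self, *label_values: int) -> np.ndarray:
        return np.isin(self.labels, label_values)

    @property
    def cerebellum_mask(self) -> np.ndarray:
        """Whole cerebellum (grey + white), the standard reference region."""
        return self.compartment(CEREBELLUM_GREY, CEREBELLUM_WHITE)

    @property
    def cortex_mask(self) -> np.ndarray:
        """Cortical grey, the standard target (neocortical) region."""
        return self.compartment(CORTICAL_GREY)

    @property
    def white_mask(self) -> np.ndarray:
        return self.compartment(SUBCORTICAL_WHITE)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def save_labels(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine()), str(path))


@dataclass(frozen=True)
class SubjectTrajectory:
    subject_id: str
    times_years: tuple[float, ...]
    true_CL: tuple[float, ...]

    def __post_init__(self):
        if len(self.times_years) != len(self.true_CL) or len(self.times_years) < 1:
            raise ValueError("times and CL values must have equal, nonzero length")


@dataclass(frozen=True)
class AcquisitionSpec:
    """One acquisition setup: tracer kinetics, scanner blur, bias, noise.

    ``bias_factor`` is a multiplicative SUVR distortion (scanner calibration
    and tracer quantification error combined) that the correction model is
    expected to invert; ``psf_fwhm_mm`` is the scanner point-spread function.
    """

    tracer: str
    scanner_id: str = "scanner0"
    psf_fwhm_mm: float = 0.0
    bias_factor: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        if not 0.0 <= self.psf_fwhm_mm <= 8.0:
            raise ValueError("psf_fwhm_mm must lie in [0, 8] mm")
        if not 0.5 < self.bias_factor < 2.0:
            raise ValueError("bias_factor must lie in (0.5, 2.0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ScanRecord:
    """One rendered PET acquisition.  ``true_CL`` is ground truth, test-only."""

    scan_id: str
    subject_id: str
    time_years: float
    acquisition: AcquisitionSpec
    true_CL: float
    volume: np.ndarray | None = None
    volume_path: Path | None = None

    def load_volume(self) -> np.ndarray:
        if self.volume is not None:
            return self.volume
        if self.volume_path is None:
            raise ValueError(f"scan {self.scan_id} has neither in-memory volume nor path")
        return np.asarray(nib.load(str(self.volume_path)).dataobj, dtype=np.float32)


def make_brain_grid(
    shape: Sequence[int] = (32, 36, 32),
    voxel_size_mm: float = 6.0,
    seed: int = 0,
) -> BrainGrid:
    """Build a left-right symmetric brain label grid.

    The cerebrum is an ellipsoid with a cortical-grey shell around a
    subcortical-white core; the cerebellum is a smaller ellipsoid
    (grey shell, white core) placed inferior-posterior; the brainstem is a
    cylinder anterior to the cerebellum.  The geometry is canonical, so the
    result is identical for any ``seed`` (kept for interface uniformity).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"grid shape {shape} too small: each dimension must be >= 16")
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # symmetric left-right coordinate about the exact grid centre
    x = (ix - (nx - 1) / 2.0) / nx
    y = iy / ny
    z = iz / nz

    labels = np.zeros(shape, dtype=np.int16)

    def ellipsoid_rho(cy, cz, ax, ay, az):
        return np.sqrt(
            (x / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        )

    # cerebrum
    rho_c = ellipsoid_rho(cy=0.55, cz=0.62, ax=0.40, ay=0.42, az=0.34)
    labels[rho_c <= 1.0] = CORTICAL_GREY
    labels[rho_c <= 0.85] = SUBCORTICAL_WHITE
    # brainstem: cylinder, anterior of the cerebellum, below the cerebrum
    r_bs = np.sqrt(x**2 + ((y - 0.42) / 1.0) ** 2)
    bs = (r_bs <= 0.075) & (z >= 0.06) & (z <= 0.40)
    labels[bs] = BRAINSTEM
    # cerebellum, inferior-posterior; overrides anything it touches
    rho_cb = ellipsoid_rho(cy=0.22, cz=0.22, ax=0.30, ay=0.17, az=0.17)
    labels[rho_cb <= 1.0] = CEREBELLUM_GREY
    labels[rho_cb <= 0.60] = CEREBELLUM_WHITE

    for lab in (CORTICAL_GREY, SUBCORTICAL_WHITE, CEREBELLUM_GREY, CEREBELLUM_WHITE, BRAINSTEM):
        if not np.any(labels == lab):
            raise ValueError(f"grid shape {shape} too small: compartment {lab} is empty")
    # enforce exact symmetry (construction is symmetric; this guards rounding)
    flipped = labels[::-1, :, :]
    if not np.array_equal(labels, flipped):  # pragma: no cover - construction is symmetric
        raise AssertionError("label construction lost left-right symmetry")
    return BrainGrid(shape=shape, voxel_size_mm=float(voxel_size_mm), labels=labels)


def default_rate_curve(cl: np.ndarray | float) -> np.ndarray | float:
    """Ground-truth natural-history rate curve used by the generator.

    A unimodal bell: accumulation is slow in amyloid-negative subjects,
    peaks around 40 CL at ~6 CL/year, and slows again at high burden.
    """
    cl = np.asarray(cl, dtype=float)
    out = 6.0 * np.exp(-(((cl - 40.0) / 25.0) ** 2))
    return out if out.ndim else float(out)


def simulate_trajectory(
    baseline_CL: float,
    times_years: Sequence[float],
    curve: Callable[[float], float] = default_rate_curve,
    seed: int = 0,
    steps_per_year: int = 120,
) -> SubjectTrajectory:
    """Evolve a subject's true Centiloid by integrating dCL/dt = f(CL).

    Integration is explicit Euler with ``steps_per_year`` sub-steps per
    year, which is ample for the smooth, bounded rate curves used here.
    The evolution is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic generators.
    """
    times = [float(t) for t in times_years]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("times_years must be strictly increasing")
    if not np.isfinite(baseline_CL):
        raise ValueError("baseline_CL must be finite")
    cl = float(baseline_CL)
    values = [cl]
    for t0, t1 in zip(times, times[1:]):
        n = max(1, int(np.ceil((t1 - t0) * steps_per_year)))
        dt = (t1 - t0) / n
        for _ in range(n):
            cl = cl + dt * float(curve(cl))
        values.append(cl)
    return SubjectTrajectory(
        subject_id="", times_years=tuple(times), true_CL=tuple(values)
    )


def render_volume(
    grid: BrainGrid,
    true_CL: float,
    acquisition: AcquisitionSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward model: tissue pattern -> blur -> multiplicative bias -> noise.

    Tissue values are cerebellum-relative: cortical grey carries
    ``GREY_BASE + SPECIFIC_PER_CL * true_CL``, white matter the tracer's
    non-specific coefficient.  The scanner PSF blur is applied to the tissue
    pattern; the SUVR bias then scales every non-cerebellar voxel, which
    makes the bias exactly multiplicative on any SUVR whose reference region
    is the cerebellum and whose target lies outside it.  Voxel noise is
    independent Gaussian, added last.
    """
    if true_CL < -60 or true_CL > 250:
        raise ValueError(f"true_CL={true_CL} outside the supported calibration range")
    labels = grid.labels
    vol = np.zeros(grid.shape, dtype=np.float64)
    vol[labels == CORTICAL_GREY] = GREY_BASE + SPECIFIC_PER_CL * true_CL
    vol[labels == SUBCORTICAL_WHITE] = WM_NONSPECIFIC[acquisition.tracer]
    vol[labels == CEREBELLUM_GREY] = CEREB_GREY_VALUE
    vol[labels == CEREBELLUM_WHITE] = CEREB_WHITE_VALUE
    vol[labels == BRAINSTEM] = BRAINSTEM_VALUE
    if acquisition.psf_fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma_mm(acquisition.psf_fwhm_mm) / grid.voxel_size_mm
        vol = gaussian_filter(vol, sigma=sigma_vox)
    scaled = ~grid.cerebellum_mask
    vol[scaled] *= acquisition.bias_factor
    if acquisition.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        vol = vol + rng.normal(0.0, acquisition.noise_sd, size=vol.shape)
    vol[~grid.brain_mask] = 0.0
    return np.maximum(vol, 0.0).astype(np.float32)


def render_scan(
    grid: BrainGrid,
    true_CL: float,
    acquisition: AcquisitionSpec,
    seed: int = 0,
    scan_id: str = "scan0",
    subject_id: str = "sub0",
    time_years: float = 0.0,
) -> ScanRecord:
    rng = np.random.default_rng(seed)
    vol = render_volume(grid, true_CL, acquisition, rng)
    return ScanRecord(
        scan_id=scan_id,
        subject_id=subject_id,
        time_years=float(time_years),
        acquisition=acquisition,
        true_CL=float(true_CL),
        volume=vol,
    )


# Cohort-level defaults: the study conditions the phantom emulates.
DEFAULT_TRACER_MIX = {"PIB": 0.4, "FBB": 0.3, "FBP": 0.3}
DEFAULT_TRACER_BIAS = {"PIB": 1.0, "NAV": 1.0, "FBB": 0.8, "FBP": 1.25, "FMM": 1.0}
DEFAULT_SCANNER_TABLE = {"scannerA": 4.0, "scannerB": 6.0}
DEFAULT_NOISE_SD = 0.01
DEFAULT_SWITCH_PROB = 0.3
DEFAULT_RATE_SCALE_SD = 0.15


@dataclass
class Cohort:
    """A rendered synthetic cohort: scans plus a tidy metadata table."""

    grid: BrainGrid
    scans: list[ScanRecord]
    table: pd.DataFrame

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        aff = self.grid.affine()
        for scan in self.scans:
            path = out_dir / f"{scan.scan_id}.nii"
            nib.save(nib.Nifti1Image(scan.load_volume(), aff), str(path))
            scan.volume_path = path
        self.grid.save_labels(out_dir / "labels.nii")
        self.table.to_csv(out_dir / "metadata.csv", index=False)
        return out_dir


def load_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :meth:`Cohort.save`."""
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "metadata.csv")
    img = nib.load(str(in_dir / "labels.nii"))
    labels = np.asarray(img.dataobj, dtype=np.int16)
    voxel = float(abs(img.affine[0, 0]))
    grid = BrainGrid(shape=labels.shape, voxel_size_mm=voxel, labels=labels)
    scans = []
    for _, row in table.iterrows():
        acq = AcquisitionSpec(
            tracer=row["tracer"],
            scanner_id=str(row.get("scanner_id", "scanner0")),
            psf_fwhm_mm=float(row.get("psf_fwhm_mm", 0.0)),
        )
        scans.append(
            ScanRecord(
                scan_id=row["scan_id"],
                subject_id=row["subject_id"],
                time_years=float(row["time_years"]),
                acquisition=acq,
                true_CL=float(row["true_CL"]) if "true_CL" in table.columns else np.nan,
                volume_path=in_dir / f"{row['scan_id']}.nii",
            )
        )
    return Cohort(grid=grid, scans=scans, table=table)


def generate_cohort(
    n_subjects: int,
    visits_per_subject: int | tuple[int, int] = (2, 3),
    tracer_mix: Mapping[str, float] | None = None,
    scanner_table: Mapping[str, float] | None = None,
    curve: Callable[[float], float] = default_rate_curve,
    seed: int = 0,
    grid: BrainGrid | None = None,
    tracer_bias: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    switch_tracer_prob: float = DEFAULT_SWITCH_PROB,
    rate_scale_sd: float = DEFAULT_RATE_SCALE_SD,
) -> Cohort:
    """Generate a longitudinal synthetic cohort.

    Baseline burden is a mixture of an amyloid-negative mode near 0 CL and
    a uniform accumulating tail; trajectories follow ``curve`` with mild
    per-subject lognormal rate heterogeneity.  Consecutive visit intervals
    are drawn within [0.25, 3.5] years.  A fraction of subjects switches
    tracer between visits (as happened historically when F18 tracers
    replaced PIB), which is what makes per-tracer biases longitudinally
    identifiable.  Fully deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    tracer_mix = dict(tracer_mix if tracer_mix is not None else DEFAULT_TRACER_MIX)
    if not tracer_mix:
        raise ValueError("tracer_mix must not be empty")
    for t in tracer_mix:
        if t not in TRACERS:
            raise ValueError(f"unknown tracer {t!r} in tracer_mix")
    scanner_table = dict(scanner_table if scanner_table is not None else DEFAULT_SCANNER_TABLE)
    tracer_bias = dict(DEFAULT_TRACER_BIAS, **(tracer_bias or {}))
    if grid is None:
        grid = make_brain_grid()
    rng = np.random.default_rng(seed)

    tracers = list(tracer_mix)
    probs = np.array([tracer_mix[t] for t in tracers], dtype=float)
    probs = probs / probs.sum()
    scanner_ids = list(scanner_table)

    scans: list[ScanRecord] = []
    rows = []
    for si in range(n_subjects):
        subject_id = f"sub{si:04d}"
        if isinstance(visits_per_subject, tuple):
            lo, hi = visits_per_subject
            n_visits = int(rng.integers(lo, hi + 1))
        else:
            n_visits = int(visits_per_subject)
        # visit schedule with intervals inside the pairing window
        times = [0.0]
        for _ in range(n_visits - 1):
            times.append(times[-1] + float(rng.uniform(0.6, 2.0)))
        if rng.uniform() < 0.55:
            baseline = float(np.clip(rng.normal(0.0, 4.0), -8.0, 12.0))
        else:
            baseline = float(rng.uniform(5.0, 90.0))
        rate_scale = float(np.exp(rng.normal(0.0, rate_scale_sd)))
        subj_curve = (lambda c, s=rate_scale: s * float(curve(c)))
        traj = simulate_trajectory(baseline, times, subj_curve)

        tracer = tracers[int(rng.choice(len(tracers), p=probs))]
        for vi, (t, cl) in enumerate(zip(traj.times_years, traj.true_CL)):
            if vi > 0 and len(tracers) > 1 and rng.uniform() < switch_tracer_prob:
                others = [tr for tr in tracers if tr != tracer]
                tracer = others[int(rng.choice(len(others)))]
            scanner = scanner_ids[int(rng.choice(len(scanner_ids)))]
            acq = AcquisitionSpec(
                tracer=tracer,
                scanner_id=scanner,
                psf_fwhm_mm=float(scanner_table[scanner]),
                bias_factor=float(tracer_bias[tracer]),
                noise_sd=noise_sd,
            )
            scan_id = f"{subject_id}_v{vi}"
            vol = render_volume(grid, cl, acq, rng)
            scans.append(
                ScanRecord(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    time_years=float(t),
                    acquisition=acq,
                    true_CL=float(cl),
                    volume=vol,
                )
            )
            rows.append(
                dict(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    tracer=tracer,
                    scanner_id=scanner,
                    psf_fwhm_mm=float(scanner_table[scanner]),
                    time_years=float(t),
                    true_CL=float(cl),
                )
            )
    table = pd.DataFrame(rows)
    return Cohort(grid=grid, scans=scans, table=table)
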