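"""Standard SUVR and Centiloid quantification.

SUVR is a mask-weighted mean-uptake ratio (target over reference); the
Centiloid scale is a per-tracer linear rescaling of SUVR anchored at 0 for
the young-control group mean and 100 for the typical-AD group mean.  Masks
are continuous weights in [0, 1] so the same code path serves the standard
binary masks and the learnable masks produced by mask optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import AcquisitionSpec, BrainGrid, fwhm_to_sigma_mm, render_volume

__all__ = [
    "MaskVolume",
    "CentiloidTransform",
    "compute_suvr",
    "make_composite_reference",
    "calibrate_centiloid_transform",
    "apply_centiloid",
    "standard_masks",
    "default_transforms",
    "quantify",
]

BRAIN_MASK_THRESHOLD = 0.5  # probabilistic brain masks are cut here before use


@dataclass
class MaskVolume:
    """A continuous-valued voxel mask bound to its grid."""

    values: np.ndarray
    grid: BrainGrid | None = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError(f"mask {self.name!r} has values outside [0, 1]")
        if self.grid is not None and self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match its grid")

    def save(self, path: str | Path) -> None:
        aff = self.grid.affine() if self.grid is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), aff), str(path))


@dataclass(frozen=True)
class CentiloidTransform:
    """CL = slope * SUVR + intercept, for one tracer."""

    tracer: str
    slope: float
    intercept: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("Centiloid transform slope must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"tracer": self.tracer, "slope": self.slope, "intercept": self.intercept}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CentiloidTransform":
        d = json.loads(Path(path).read_text())
        return cls(tracer=d["tracer"], slope=d["slope"], intercept=d["intercept"])


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, MaskVolume):
        return mask.values
    return np.asarray(mask, dtype=np.float64)


def compute_suvr(volume: np.ndarray, target_mask, reference_mask) -> float:
    """Mask-weighted mean over the target divided by the reference mean."""
    vol = np.asarray(volume, dtype=np.float64)
    tgt = _mask_array(target_mask)
    ref = _mask_array(reference_mask)
    if tgt.shape != vol.shape or ref.shape != vol.shape:
        raise ValueError("volume and mask shapes do not match")
    wt, wr = tgt.sum(), ref.sum()
    if wt <= 0 or wr <= 0:
        raise ValueError("mask is empty (all-zero weights)")
    return float(((vol * tgt).sum() / wt) / ((vol * ref).sum() / wr))


def make_composite_reference(
    wm_probability: np.ndarray,
    cerebellum_mask: np.ndarray,
    voxel_size_mm: float,
    fwhm_mm: float = 8.0,
    threshold_frac: float = 0.7,
) -> MaskVolume:
    """Whole cerebellum plus eroded subcortical white matter.

    The white-matter probability map is blurred (8 mm FWHM by default) and
    kept where it exceeds ``threshold_frac`` of its post-blur maximum,
    which erodes it away from grey-white boundaries affected by partial
    volume; the surviving core is unioned with the cerebellum mask.
    """
    wm = np.asarray(wm_probability, dtype=np.float64)
    if wm.min() < 0 or wm.max() > 1:
        raise ValueError("wm_probability must lie in [0, 1]")
    cereb = _mask_array(cerebellum_mask)
    if wm.max() > 0:
        blurred = gaussian_filter(wm, sigma=fwhm_to_sigma_mm(fwhm_mm) / voxel_size_mm)
        core = blurred > threshold_frac * blurred.max()
    else:
        core = np.zeros_like(wm, dtype=bool)
    values = np.maximum(core.astype(np.float64), cereb)
    if values.sum() == 0:
        raise ValueError("composite reference is empty")
    return MaskVolume(values=values, name="composite_reference")


def calibrate_centiloid_transform(yc_suvrs, ad_suvrs, tracer: str) -> CentiloidTransform:
    """Anchor calibration: 0 CL at the young-control mean, 100 at the AD mean."""
    yc = np.asarray(yc_suvrs, dtype=float)
    ad = np.asarray(ad_suvrs, dtype=float)
    if yc.size < 2 or ad.size < 2:
        raise ValueError("each calibration group needs n >= 2")
    if ad.mean() <= yc.mean():
        raise ValueError("AD group mean SUVR must exceed the young-control mean")
    slope = 100.0 / (ad.mean() - yc.mean())
    return CentiloidTransform(tracer=tracer, slope=slope, intercept=-slope * yc.mean())


def apply_centiloid(suvr, transform: CentiloidTransform):
    suvr = np.asarray(suvr, dtype=float)
    out = transform.slope * suvr + transform.intercept
    return float(out) if out.ndim == 0 else out


def standard_masks(grid: BrainGrid) -> tuple[MaskVolume, MaskVolume]:
    """The standard (target, reference) = (cortical grey, whole cerebellum)."""
    target = MaskVolume(grid.cortex_mask.astype(float), grid=grid, name="standard_target")
    reference = MaskVolume(
        grid.cerebellum_mask.astype(float), grid=grid, name="standard_reference"
    )
    return target, reference


def default_transforms(
    grid: BrainGrid, tracers=("PIB", "NAV", "FBB", "FBP", "FMM")
) -> dict[str, CentiloidTransform]:
    """Synthetic-world stand-in for the published per-tracer transforms.

    Each tracer is calibrated on idealized groups (true 0 CL and true
    100 CL, no blur, no bias, no noise) quantified with the standard masks.
    Calibration at zero PSF mirrors the idealized conditions of published
    transforms: cohort scans acquired with nonzero scanner PSF then show
    tracer-dependent white-matter spill-in that the transforms do not
    absorb, reproducing realistic inter-tracer disagreement.
    """
    target, reference = standard_masks(grid)
    out: dict[str, CentiloidTransform] = {}
    for tracer in tracers:
        acq = AcquisitionSpec(tracer=tracer, psf_fwhm_mm=0.0, bias_factor=1.0, noise_sd=0.0)
        yc = [compute_suvr(render_volume(grid, 0.0, acq), target, reference)] * 2
        ad = [compute_suvr(render_volume(grid, 100.0, acq), target, reference)] * 2
        out[tracer] = calibrate_centiloid_transform(yc, ad, tracer)
    return out


def quantify(
    volume: np.ndarray,
    target_mask,
    reference_mask,
    transform: CentiloidTransform,
) -> tuple[float, float]:
    """Convenience: (SUVR, CL) for one volume under one mask pair."""
    suvr = compute_suvr(volume, target_mask, reference_mask)
    return suvr, float(apply_centiloid(suvr, transform))
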