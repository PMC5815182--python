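"""Magnetization transfer ratio (MTR) mapping and ROI statistics.

Given paired gradient-echo acquisitions without (S0) and with (S_MT) an
off-resonance saturation pulse, the per-pixel ratio

    MTR = (S0 − S_MT) / S0

is sensitive to the macromolecular (myelin-bound) proton pool.  Pixels
whose S0 falls below a noise floor are flagged invalid and excluded from
all ROI statistics; the map itself is dimensionless (a fraction — multiply
by 100 for percentage-point units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask, GrayImage, RoiSet
from .errors import ValidationError

__all__ = ["MtrPair", "MtrResult", "compute_mtr", "estimate_noise_floor", "roi_report"]


@dataclass
class MtrPair:
    """Paired acquisitions: s0 (no saturation) and s_mt (with saturation).

    ``noise_floor`` is the S0 intensity below which a pixel is considered
    unreliable (background/air); see :func:`estimate_noise_floor`.
    """

    s0: GrayImage
    s_mt: GrayImage
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.s0.shape != self.s_mt.shape:
            raise ValidationError(
                f"MTR pair shapes differ: {self.s0.shape} vs {self.s_mt.shape}"
            )
        if self.s0.pixels.min() < 0 or self.s_mt.pixels.min() < 0:
            raise ValidationError("MR intensities must be non-negative")


@dataclass
class MtrResult:
    """MTR map with validity mask.

    ``mtr_map`` holds NaN at invalid pixels (S0 at or below the noise
    floor); ``valid`` marks the pixels that enter ROI statistics.
    """

    mtr_map: GrayImage
    valid: BinaryMask


def estimate_noise_floor(
    s0: GrayImage, background: np.ndarray, scale: float = 5.0
) -> float:
    """Robust noise floor from a user-named background (air) region.

    Returns ``scale × 1.4826 × MAD`` of the background intensities — the
    median absolute deviation rescaled to a Gaussian sigma — added to the
    background median, so pure-noise pixels fall below the floor.
    """
    bg = np.asarray(background, bool)
    if not bg.any():
        raise ValidationError("noise-floor background region is empty")
    vals = s0.pixels[bg]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med + scale * 1.4826 * mad


def compute_mtr(pair: MtrPair) -> MtrResult:
    """Per-pixel MTR = (S0 − S_MT)/S0 where S0 exceeds the noise floor.

    Invalid pixels carry NaN in the map (never a number), so they cannot
    silently enter downstream means.
    """
    s0 = pair.s0.pixels
    valid = s0 > pair.noise_floor
    mtr = np.full(s0.shape, np.nan)
    np.divide(s0 - pair.s_mt.pixels, s0, out=mtr, where=valid)
    return MtrResult(
        mtr_map=GrayImage(mtr, pair.s0.calibration, allow_nan=True),
        valid=BinaryMask(valid, pair.s0.calibration),
    )


def roi_report(
    result: MtrResult,
    s0: GrayImage,
    rois: RoiSet,
    control_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-ROI mean signal (from S0) and mean MTR over valid pixels.

    When ``control_means`` supplies ``{"signal": ..., "mtr": ...}`` from a
    control group, normalized columns (control mean ↦ 1.0) are appended.
    A ROI with no valid pixel is an error naming the ROI.
    """
    shape = s0.shape
    rows = []
    for name in rois.names:
        mask = rois.mask(name, shape) & result.valid.pixels
        if not mask.any():
            raise ValidationError(f"ROI {name!r} contains no valid MTR pixel")
        row = {
            "roi_name": name,
            "n_pixels": int(mask.sum()),
            "mean_signal": float(s0.pixels[mask].mean()),
            "mean_mtr": float(result.mtr_map.pixels[mask].mean()),
        }
        if control_means is not None:
            for key, col in (("signal", "mean_signal"), ("mtr", "mean_mtr")):
                if key in control_means:
                    denom = float(control_means[key])
                    if denom == 0:
                        raise ValidationError(f"control mean for {key!r} is zero")
                    row[f"norm_{col}"] = row[col] / denom
        rows.append(row)
    return pd.DataFrame(rows)
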