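"""Color deconvolution of brightfield chromogens.

Brightfield absorption follows Beer–Lambert: each stain s with unit
absorption vector v_s and local amount c_s contributes c_s · v_s to the
per-channel optical density OD_ch = −log10((I_ch + 1) / 256).  Unmixing
solves the per-pixel linear system OD = Vᵀ c for the stain amounts, which
yields e.g. a DAB ("brown") image free of the hematoxylin counterstain.

Default absorption vectors are the Ruifrok–Johnston calibrated values for
hematoxylin and DAB; both are configurable for other chromogen pairs
(GFAP/DAB, GST-π/DAB, MBP/DAB all use the same chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage, StainedSection
from .errors import ValidationError

# Ruifrok–Johnston absorption coefficients (R, G, B), pre-normalization
HEMATOXYLIN_VECTOR = (0.650, 0.704, 0.286)
DAB_VECTOR = (0.269, 0.568, 0.778)

__all__ = [
    "StainMatrix",
    "StainChannels",
    "rgb_to_od",
    "unmix_stains",
    "chromogen_gray",
    "HEMATOXYLIN_VECTOR",
    "DAB_VECTOR",
]


@dataclass
class StainMatrix:
    """Unit absorption vectors for two or three stains.

    Two-stain matrices are completed internally with the normalized cross
    product of the two vectors so that the per-pixel system is square; the
    residual channel is discarded after the solve.
    """

    vectors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] not in (2, 3):
            raise ValidationError("StainMatrix expects 2 or 3 RGB absorption vectors")
        if np.any(v < 0):
            raise ValidationError("stain absorption vectors must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValidationError("stain absorption vectors must be nonzero")
        self.vectors = v / norms[:, None]
        if len(self.names) != v.shape[0]:
            raise ValidationError("one name per stain vector required")
        if np.linalg.matrix_rank(self.vectors) < v.shape[0]:
            raise ValidationError("stain vectors are linearly dependent")

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """Hematoxylin + DAB with Ruifrok–Johnston defaults."""
        return cls(np.array([HEMATOXYLIN_VECTOR, DAB_VECTOR]), ("hematoxylin", "dab"))

    @property
    def n_stains(self) -> int:
        return self.vectors.shape[0]

    def completed(self) -> np.ndarray:
        """Square (3, 3) matrix with rows = stain vectors (+ residual)."""
        if self.n_stains == 3:
            m = self.vectors
        else:
            residual = np.cross(self.vectors[0], self.vectors[1])
            nrm = np.linalg.norm(residual)
            if nrm == 0:
                raise ValidationError("stain vectors are collinear; cannot complete matrix")
            m = np.vstack([self.vectors, residual / nrm])
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValidationError("stain matrix is singular")
        return m


@dataclass
class StainChannels:
    """Per-stain amount maps (non-negative optical-density units)."""

    channels: dict[str, GrayImage]

    def __getitem__(self, name: str) -> GrayImage:
        return self.channels[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.channels)


def rgb_to_od(section: StainedSection) -> np.ndarray:
    """Per-channel optical density, OD_ch = −log10((I_ch + 1)/256).

    White (255) maps to OD 0; black (0) to log10(256) ≈ 2.408.  The +1
    offset keeps the transform finite at zero intensity.
    """
    intensity = section.pixels.astype(np.float64)
    return -np.log10((intensity + 1.0) / 256.0)


def unmix_stains(
    od_image: np.ndarray, matrix: StainMatrix, calibration: float = 1.0
) -> StainChannels:
    """Solve OD = Vᵀ c per pixel and return per-stain amount maps.

    Negative solutions (noise pushing a pixel outside the stain simplex)
    are clipped to zero, the standard densitometry convention.
    """
    od = np.asarray(od_image, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValidationError("unmix_stains expects an (H, W, 3) optical-density image")
    m = matrix.completed()
    # od(pixel) = m.T @ c  =>  c = inv(m.T) @ od
    solve = np.linalg.inv(m.T)
    conc = od @ solve.T
    conc = np.clip(conc, 0.0, None)
    channels = {
        name: GrayImage(np.ascontiguousarray(conc[:, :, i]), calibration)
        for i, name in enumerate(matrix.names)
    }
    return StainChannels(channels)


def unmix_section(section: StainedSection, matrix: StainMatrix | None = None) -> StainChannels:
    """Convenience: rgb_to_od + unmix, propagating the section calibration."""
    matrix = matrix or StainMatrix.hdab()
    return unmix_stains(rgb_to_od(section), matrix, calibration=section.calibration)


def chromogen_gray(channels: StainChannels, chromogen: str = "dab") -> GrayImage:
    """8-bit-range gray rendering of the chromogen channel, stained = dark.

    g = 255 · 10^(−c), clipped to [0, 255]: zero stain renders white (255),
    and g is strictly decreasing in the stain amount.
    """
    if chromogen not in channels.channels:
        raise ValidationError(f"no chromogen channel named {chromogen!r}")
    c = channels[chromogen]
    g = np.clip(255.0 * np.power(10.0, -c.pixels), 0.0, 255.0)
    return GrayImage(g, c.calibration)
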