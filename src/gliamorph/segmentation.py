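"""Tissue, soma and process segmentation for DAB-stained glial cells.

The sequence is fixed: tissue masking on the raw-gray image, an adaptive
soma threshold anchored on the darkest in-tissue chromogen pixels, soma
labeling with size filtering, black top-hat extraction of thin processes,
soma subtraction, and homotopic thinning of the process mask to a
one-pixel-wide skeleton for length measurement.

All structuring-element radii and size filters are specified in µm (or
µm²) and converted to pixels through the image calibration, so the same
parameter set transfers across scan resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import BinaryMask, GrayImage, LabelMap
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "GliaSegmentation",
    "segment_tissue",
    "adaptive_soma_threshold",
    "segment_soma",
    "segment_processes",
    "skeletonize_processes",
    "segment_image",
]


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation sequence.

    tissue_threshold : gray cutoff separating tissue from the white slide
        background (pixels strictly darker are tissue seed pixels).
    closing_radius_um / opening_radius_um : disk radii for the smoothing
        steps of tissue masking.
    min_tissue_object_um2 : tissue fragments smaller than this are dropped.
    dark_seed_fraction : fraction of the darkest in-tissue chromogen pixels
        whose mean gray anchors the adaptive soma threshold.  Soma are the
        densest chromogen accumulations, so the seed must stay within the
        soma pixel population; the default suits sparse glial fields
        (tens of cells per 500 µm field).
    soma_threshold_factor : multiplier on the seed mean giving the soma
        binarization threshold.
    min_soma_area_um2 / max_soma_area_um2 : accepted soma size window.
    tophat_radius_um : structuring-element radius of the black top-hat;
        structures thinner than ~2× this radius respond, wider ones do not.
    process_threshold_factor : the top-hat response is kept where it
        exceeds factor × (255 − seed mean), reusing the soma seed gray as
        the contrast scale.
    min_process_object_px : speckle filter on the binarized top-hat.
    """

    tissue_threshold: float = 235.0
    closing_radius_um: float = 5.0
    opening_radius_um: float = 5.0
    min_tissue_object_um2: float = 10_000.0
    dark_seed_fraction: float = 0.005
    soma_threshold_factor: float = 1.4
    min_soma_area_um2: float = 20.0
    max_soma_area_um2: float = 400.0
    tophat_radius_um: float = 1.5
    process_threshold_factor: float = 0.15
    min_process_object_px: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.dark_seed_fraction < 1.0):
            raise ValidationError("dark_seed_fraction must lie strictly in (0, 1)")
        for name in (
            "closing_radius_um",
            "opening_radius_um",
            "min_tissue_object_um2",
            "soma_threshold_factor",
            "min_soma_area_um2",
            "max_soma_area_um2",
            "tophat_radius_um",
            "process_threshold_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.max_soma_area_um2 <= self.min_soma_area_um2:
            raise ValidationError("max_soma_area_um2 must exceed min_soma_area_um2")

    def for_stain(self, marker: str) -> "SegmentationParams":
        """Marker-specific soma size windows (astrocyte somata run larger)."""
        if marker.lower() in ("gfap", "astrocyte"):
            return replace(self, max_soma_area_um2=max(self.max_soma_area_um2, 800.0))
        return self


@dataclass
class GliaSegmentation:
    """Bundle of the segmentation products for one section.

    Invariants: soma ⊆ tissue; processes ∩ soma = ∅; skeleton ⊆ processes
    and one pixel wide.
    """

    tissue: BinaryMask
    soma: LabelMap
    soma_gray_mean: float
    processes: BinaryMask
    skeleton: BinaryMask
    seed_mean: float = field(default=float("nan"))
    soma_threshold: float = field(default=float("nan"))

    @property
    def calibration(self) -> float:
        return self.tissue.calibration


def _radius_px(radius_um: float, calibration: float) -> int:
    return max(1, int(round(radius_um / calibration)))


def segment_tissue(gray: GrayImage, params: SegmentationParams) -> BinaryMask:
    """Mask valid tissue against the white slide background.

    Threshold (darker than ``tissue_threshold``), then closing, hole
    filling, opening and removal of fragments below
    ``min_tissue_object_um2``, in exactly that order.  An empty result is
    allowed (blank field) and logged.
    """
    cal = gray.calibration
    mask = gray.pixels < params.tissue_threshold
    mask = morphology.closing(mask, morphology.disk(_radius_px(params.closing_radius_um, cal)))
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.opening(mask, morphology.disk(_radius_px(params.opening_radius_um, cal)))
    min_px = max(1, int(round(params.min_tissue_object_um2 / cal**2)))
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1, connectivity=2)
    if not mask.any():
        log.warning("tissue segmentation produced an empty mask")
    return BinaryMask(mask, cal)


def adaptive_soma_threshold(
    gray: GrayImage, tissue: BinaryMask, params: SegmentationParams
) -> tuple[float, float]:
    """Soma threshold anchored on the darkest in-tissue chromogen pixels.

    Returns ``(threshold, seed_mean)`` where ``seed_mean`` is the mean gray
    of the darkest ``dark_seed_fraction`` of in-tissue pixels and
    ``threshold = soma_threshold_factor × seed_mean`` clamped to [0, 255].
    The seed mean is reused downstream as the contrast anchor for process
    binarization.
    """
    if gray.shape != tissue.shape:
        raise ValidationError("gray image and tissue mask shapes differ")
    values = gray.pixels[tissue.pixels]
    if values.size == 0:
        raise ValidationError("tissue mask is empty; cannot compute soma threshold")
    k = max(1, int(round(params.dark_seed_fraction * values.size)))
    darkest = np.partition(values, k - 1)[:k]
    seed_mean = float(darkest.mean())
    threshold = float(np.clip(params.soma_threshold_factor * seed_mean, 0.0, 255.0))
    return threshold, seed_mean


def segment_soma(
    gray: GrayImage,
    tissue: BinaryMask,
    threshold: float,
    params: SegmentationParams,
) -> LabelMap:
    """Binarize at the adaptive threshold, label 8-connected, size-filter.

    Objects outside [min_soma_area_um2, max_soma_area_um2] are removed and
    surviving labels renumbered 1..n.  An empty map is a valid result.
    """
    cal = gray.calibration
    binary = tissue.pixels & (gray.pixels <= threshold)
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return LabelMap(labels)
    areas = np.bincount(labels.ravel())
    areas_um2 = areas * cal**2
    keep = (areas_um2 >= params.min_soma_area_um2) & (areas_um2 <= params.max_soma_area_um2)
    keep[0] = False
    remap = np.zeros(len(areas), dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabelMap(remap[labels])


def segment_processes(
    gray: GrayImage,
    tissue: BinaryMask,
    soma: LabelMap,
    seed_mean: float,
    params: SegmentationParams,
) -> BinaryMask:
    """Thin-process mask via black top-hat, binarization and soma subtraction.

    The black top-hat of the chromogen gray with a disk of
    ``tophat_radius_um`` responds to dark structures thinner than the disk
    (cell processes) and not to wide blobs (somata).  The response is kept
    where it exceeds ``process_threshold_factor × (255 − seed_mean)``,
    speckles below ``min_process_object_px`` are dropped, and soma pixels
    are subtracted to leave true processes only.
    """
    cal = gray.calibration
    if not (gray.shape == tissue.shape == soma.shape):
        raise ValidationError("gray, tissue and soma shapes differ")
    selem = morphology.disk(_radius_px(params.tophat_radius_um, cal))
    response = morphology.black_tophat(gray.pixels, selem)
    cutoff = params.process_threshold_factor * (255.0 - seed_mean)
    mask = tissue.pixels & (response > cutoff)
    mask = morphology.remove_small_objects(
        mask, max_size=max(1, params.min_process_object_px) - 1, connectivity=2
    )
    mask[soma.pixels > 0] = False
    return BinaryMask(mask, cal)


def skeletonize_processes(processes: BinaryMask) -> BinaryMask:
    """Homotopic ultimate thinning of the process mask to one-pixel width.

    Each 8-connected component reduces to a thin skeleton that is a subset
    of the input and preserves the component count.
    """
    skeleton = morphology.thin(processes.pixels)
    return BinaryMask(skeleton, processes.calibration)


def segment_image(
    tissue_gray: GrayImage,
    chromogen: GrayImage,
    params: SegmentationParams | None = None,
) -> GliaSegmentation:
    """Run the full segmentation sequence on one section.

    ``tissue_gray`` is the raw-image gray (counterstained tissue vs white
    background); ``chromogen`` is the stain-specific gray rendering in
    which labeled cells are dark.
    """
    params = params or SegmentationParams()
    tissue = segment_tissue(tissue_gray, params)
    if not tissue.pixels.any():
        empty = BinaryMask(np.zeros(tissue.shape, bool), tissue.calibration)
        return GliaSegmentation(
            tissue=tissue,
            soma=LabelMap(np.zeros(tissue.shape, np.int32)),
            soma_gray_mean=float("nan"),
            processes=empty,
            skeleton=BinaryMask(np.zeros(tissue.shape, bool), tissue.calibration),
        )
    threshold, seed_mean = adaptive_soma_threshold(chromogen, tissue, params)
    soma = segment_soma(chromogen, tissue, threshold, params)
    processes = segment_processes(chromogen, tissue, soma, seed_mean, params)
    skeleton = skeletonize_processes(processes)
    soma_pixels = chromogen.pixels[soma.pixels > 0]
    soma_gray_mean = float(soma_pixels.mean()) if soma_pixels.size else float("nan")
    log.info(
        "segmentation: tissue %d px, %d somata (threshold %.1f), %d process px",
        int(tissue.pixels.sum()), soma.object_count, threshold, int(processes.pixels.sum()),
    )
    return GliaSegmentation(
        tissue=tissue,
        soma=soma,
        soma_gray_mean=soma_gray_mean,
        processes=processes,
        skeleton=skeleton,
        seed_mean=seed_mean,
        soma_threshold=threshold,
    )
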