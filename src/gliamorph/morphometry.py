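"""Morphometric features, activation/size indices and bulk densitometry.

Per-cell features (area, perimeter, form factor, compartment areas and
skeleton lengths, optical densities) feed two region-level summary
indices used to read out glial activation state:

* activation index = (Σ soma area + Σ proximal area) / Σ distal area —
  activated (ameboid) cells retract their distal arbors, driving the
  ratio up;
* size index = (Σ soma area + Σ proximal area) / number of cells.

Bulk stains (e.g. myelin basic protein) are quantified as stained-area
fraction and integrated density over a region, and qPCR Ct tables are
transformed to fold changes via 2^−ΔΔCt.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage import measure

from .arborization import ArborDecomposition
from .core import BinaryMask, GrayImage, RoiSet
from .errors import ValidationError
from .segmentation import GliaSegmentation

__all__ = [
    "skeleton_length_um",
    "optical_density",
    "morphometric_features",
    "roi_features",
    "activation_index",
    "size_index",
    "stained_area_fraction",
    "normalize_to_control",
    "ddct_fold_change",
]

SQRT2 = math.sqrt(2.0)


def skeleton_length_um(mask: np.ndarray, calibration: float) -> float:
    """Length of a one-pixel-wide skeleton in µm.

    Counts each adjacent pixel pair once: orthogonal neighbors contribute
    one pixel step, diagonal neighbors √2 steps.  On a thinned skeleton no
    redundant corner adjacencies remain, so the pair count is the path
    length.
    """
    m = np.asarray(mask, bool)
    if not m.any():
        return 0.0
    orth = np.count_nonzero(m[:, :-1] & m[:, 1:]) + np.count_nonzero(m[:-1, :] & m[1:, :])
    diag = np.count_nonzero(m[:-1, :-1] & m[1:, 1:]) + np.count_nonzero(m[:-1, 1:] & m[1:, :-1])
    return (orth + SQRT2 * diag) * calibration


def optical_density(
    gray: GrayImage,
    objects: np.ndarray,
    exclusion: np.ndarray,
    tissue: BinaryMask | np.ndarray,
) -> float:
    """Mean optical density of an object set against local background.

    OD = log10(mean_gray(background) / mean_gray(objects)), where the
    background is every in-tissue pixel outside ``exclusion`` (normally
    the union of all visible-cell pixels).
    """
    t = tissue.pixels if isinstance(tissue, BinaryMask) else np.asarray(tissue, bool)
    obj = np.asarray(objects, bool)
    if not obj.any():
        raise ValidationError("optical_density: object set is empty")
    background = t & ~np.asarray(exclusion, bool)
    if not background.any():
        raise ValidationError("optical_density: background region is empty")
    bg_mean = float(gray.pixels[background].mean())
    obj_mean = float(gray.pixels[obj].mean())
    if obj_mean <= 0 or bg_mean <= 0:
        raise ValidationError("optical_density: non-positive mean gray")
    return math.log10(bg_mean / obj_mean)


def _object_perimeter_um(mask: np.ndarray, calibration: float) -> float:
    """Crofton 4-direction perimeter estimate of one object, in µm.

    Chosen over a raw chain-code walk because the latter overestimates
    smooth outlines by ~5%, which would systematically deflate form
    factors of round somata.
    """
    return float(measure.perimeter_crofton(mask, directions=4)) * calibration


def morphometric_features(
    decomp: ArborDecomposition,
    seg: GliaSegmentation,
    gray: GrayImage | None = None,
) -> pd.DataFrame:
    """Per-cell feature table.

    One row per segmented cell: soma area/perimeter/form factor (all
    µm-calibrated), proximal and distal areas, compartment skeleton
    lengths, and — when the chromogen gray is supplied — soma and
    visible-cell optical densities against the non-cell tissue background.
    """
    cal = decomp.calibration
    soma = decomp.soma.pixels
    skel = seg.skeleton.pixels
    rows = []
    visible_union = decomp.visible_mask()
    bg_available = gray is not None and bool((seg.tissue.pixels & ~visible_union).any())
    props = {p.label: p for p in measure.regionprops(soma)}
    for k in decomp.cell_ids:
        p = props[k]
        soma_mask = soma == k
        r0, c0, r1, c1 = p.bbox
        local = soma_mask[max(r0 - 1, 0) : r1 + 1, max(c0 - 1, 0) : c1 + 1]
        area = p.area * cal**2
        perim = _object_perimeter_um(local, cal)
        form_factor = 4.0 * math.pi * area / perim**2 if perim > 0 else float("nan")
        prox = decomp.proximal_mask(k)
        dist = decomp.distal_mask(k)
        row = {
            "soma_id": k,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "soma_area_um2": area,
            "soma_perimeter_um": perim,
            "soma_form_factor": form_factor,
            "proximal_area_um2": float(prox.sum()) * cal**2,
            "distal_area_um2": float(dist.sum()) * cal**2,
            "proximal_length_um": skeleton_length_um(skel & prox, cal),
            "distal_length_um": skeleton_length_um(skel & dist, cal),
            "soma_od": float("nan"),
            "visible_od": float("nan"),
        }
        if bg_available:
            row["soma_od"] = optical_density(gray, soma_mask, visible_union, seg.tissue)
            row["visible_od"] = optical_density(
                gray, decomp.visible_mask(k), visible_union, seg.tissue
            )
        rows.append(row)
    columns = [
        "soma_id", "centroid_row", "centroid_col", "soma_area_um2", "soma_perimeter_um",
        "soma_form_factor", "proximal_area_um2", "distal_area_um2",
        "proximal_length_um", "distal_length_um", "soma_od", "visible_od",
    ]
    return pd.DataFrame(rows, columns=columns)


def activation_index(cells: pd.DataFrame) -> float:
    """(Σ soma + Σ proximal area) / Σ distal area; NaN when no distal area.

    A vanishing distal compartment (fully retracted arbors) leaves the
    ratio undefined; callers receive NaN rather than infinity and should
    treat it as 'maximally activated / undefined'.
    """
    if len(cells) == 0:
        return float("nan")
    distal = cells["distal_area_um2"].sum()
    if distal <= 0:
        return float("nan")
    return float((cells["soma_area_um2"].sum() + cells["proximal_area_um2"].sum()) / distal)


def size_index(cells: pd.DataFrame) -> float:
    """(Σ soma + Σ proximal area) / cell count, in µm² per cell."""
    n = len(cells)
    if n == 0:
        return float("nan")
    return float((cells["soma_area_um2"].sum() + cells["proximal_area_um2"].sum()) / n)


def stained_area_fraction(
    gray: GrayImage,
    tissue: BinaryMask,
    roi: np.ndarray,
    threshold: float,
) -> tuple[float, float]:
    """Fraction of in-ROI tissue at or below the stain threshold, plus IntDen.

    Returns ``(fraction, integrated_density)`` where the integrated
    density sums (255 − gray) × calibration² over the suprathreshold-stain
    pixels (gray ≤ threshold) of the ROI's tissue.
    """
    region = np.asarray(roi, bool) & tissue.pixels
    if not region.any():
        raise ValidationError("stained_area_fraction: ROI contains no tissue")
    vals = gray.pixels[region]
    stained = vals <= threshold
    fraction = float(stained.mean())
    intden = float(np.sum(255.0 - vals[stained])) * gray.calibration**2
    return fraction, intden


def roi_features(
    cells: pd.DataFrame,
    seg: GliaSegmentation,
    gray: GrayImage,
    rois: RoiSet | None = None,
    stain_threshold: float = 200.0,
) -> pd.DataFrame:
    """Per-ROI summary table.

    Cells belong to a ROI when their soma centroid falls inside it; when
    ``rois`` is None a single whole-image region named ``full`` is used.
    Counts are normalized to the ROI's tissue area (per mm²).  The bulk
    stained-area fraction and integrated density use ``stain_threshold``
    on the chromogen gray.
    """
    shape = seg.tissue.shape
    cal = seg.calibration
    if rois is None or len(rois) == 0:
        masks = {"full": np.ones(shape, bool)}
    else:
        masks = rois.masks(shape)
    rows = []
    for name, mask in masks.items():
        tissue_px = int((mask & seg.tissue.pixels).sum())
        if tissue_px == 0:
            raise ValidationError(f"ROI {name!r} contains no tissue")
        if len(cells):
            rr = cells["centroid_row"].round().astype(int).clip(0, shape[0] - 1)
            cc = cells["centroid_col"].round().astype(int).clip(0, shape[1] - 1)
            inside = mask[rr.to_numpy(), cc.to_numpy()]
            sub = cells[inside]
        else:
            sub = cells
        tissue_mm2 = tissue_px * cal**2 / 1e6
        frac, intden = stained_area_fraction(gray, seg.tissue, mask, stain_threshold)
        rows.append(
            {
                "roi_name": name,
                "soma_count": len(sub),
                "soma_count_per_mm2": len(sub) / tissue_mm2,
                "activation_index": activation_index(sub),
                "size_index": size_index(sub),
                "stained_area_fraction": frac,
                "integrated_density": intden,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_control(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    control_group: str,
) -> pd.Series:
    """Divide every value by the mean of the control group's values.

    The control group mean maps to exactly 1.0; output order follows
    input order.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups))
    ctrl = values[groups.to_numpy() == control_group]
    if len(ctrl) == 0:
        raise ValidationError(f"control group {control_group!r} is empty")
    mean = float(ctrl.mean())
    if mean == 0:
        raise ValidationError("control group mean is zero; cannot normalize")
    return values / mean


def ddct_fold_change(table: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Relative qPCR quantification: fold change = 2^−ΔΔCt.

    ΔCt = target_ct − reference_ct per sample; ΔΔCt subtracts the mean ΔCt
    of the calibrator group; fold change is 2^−ΔΔCt (calibrator mean → 1).
    """
    required = {"sample", "group", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"qPCR table lacks columns: {sorted(missing)}")
    if not np.all(np.isfinite(table[["target_ct", "reference_ct"]].to_numpy(float))):
        raise ValidationError("Ct values must be finite")
    out = table.copy()
    out["delta_ct"] = out["target_ct"] - out["reference_ct"]
    cal = out.loc[out["group"] == calibrator_group, "delta_ct"]
    if len(cal) == 0:
        raise ValidationError(f"calibrator group {calibrator_group!r} not found in table")
    out["delta_delta_ct"] = out["delta_ct"] - float(cal.mean())
    out["fold_change"] = np.power(2.0, -out["delta_delta_ct"])
    return out
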