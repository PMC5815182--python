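"""Seeded generators for ground-truthed histology fields and MR pairs.

The histology generator emulates a DAB-stained (brown) glial field on a
hematoxylin-counterstained tissue background inside a white slide margin:
somata are rotated ellipses, processes are random walks (wrapped-normal
turning, optional branching), and the render follows Beer–Lambert optics
with the package's default stain vectors plus Gaussian pixel noise.  Two
morphotypes are modeled: *ramified* (resting) cells with long thin arbors
and *ameboid* (activated) cells with larger somata and short thick
processes.  Every image comes with full ground truth — per-cell specs,
soma label map, process polylines and proximal/distal skeleton lengths at
a stated influence radius — so segmentation and morphometry are testable
without external data.

The MR generator produces constant-plus-Gaussian-noise acquisition pairs
with a piecewise-constant true MTR field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from .core import BinaryMask, GrayImage, LabelMap, RoiSet, StainedSection
from .errors import ComputationError, ValidationError
from .mtr import MtrPair
from .stains import StainMatrix

__all__ = [
    "CellSpec",
    "CellTruth",
    "GroundTruth",
    "generate_histology",
    "generate_mr_pair",
    "roiset_from_layout",
]


@dataclass
class CellSpec:
    """Sampled geometry and staining parameters of one synthetic cell."""

    centroid: tuple[float, float]  # (row, col), pixels
    soma_radii_um: tuple[float, float]
    soma_angle: float
    n_primary_processes: int
    process_length_um: tuple[float, float]  # (mean, sd)
    branch_probability: float
    morphotype: str  # "ramified" | "ameboid"
    stain_amplitude: float  # peak chromogen OD of the soma

    def __post_init__(self) -> None:
        if min(self.soma_radii_um) <= 0:
            raise ValidationError("soma radii must be > 0")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValidationError("branch_probability must lie in [0, 1]")
        if self.process_length_um[0] < 0:
            raise ValidationError("process length mean must be >= 0")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    spec: CellSpec
    soma_area_px: int
    polylines: list[np.ndarray] = field(default_factory=list)
    total_length_um: float = 0.0
    proximal_length_um: float = 0.0
    distal_length_um: float = 0.0
    proximal_area_px: int = 0
    distal_area_px: int = 0


@dataclass
class GroundTruth:
    """Image-level ground truth of a generated histology field."""

    cells: list[CellTruth]
    soma_labels: LabelMap
    process_mask: BinaryMask
    tissue_mask: BinaryMask
    influence_radius_um: float
    stained_area_fraction: float

    @property
    def cell_count(self) -> int:
        return len(self.cells)


# Morphotype condition tables (units: µm unless stated).  Ramified cells are
# resting microglia-like (small soma, 4–6 long thin processes); ameboid cells
# are activated (enlarged soma, 2–4 short thick processes, arbors largely
# retracted inside the proximal influence zone).
_MORPHOTYPES = {
    "ramified": dict(
        radii=(2.5, 4.0), n_proc=(4, 6), length=(25.0, 5.0),
        branch_p=0.03, thickness_iter=0, process_od=0.30,
    ),
    "ameboid": dict(
        radii=(4.0, 6.0), n_proc=(2, 4), length=(10.0, 3.0),
        branch_p=0.01, thickness_iter=1, process_od=0.45,
    ),
}

# Soma chromogen OD: DAB accumulates densely and uniformly in glial somata,
# so the per-cell peak OD varies only slightly within a section.  The level
# (gray ≈ 40 at OD 0.8) keeps soma clearly darker than processes while
# leaving the adaptive threshold (factor × darkest-seed mean) enough
# headroom above the soma gray even when the dark seed lies entirely
# inside the soma population.
_SOMA_OD_RANGE = (0.79, 0.81)
_TURN_SD = 0.15  # radians per 1-px step
_HEMATOXYLIN_BASE = 0.12
_HEMATOXYLIN_VAR = 0.04


def _sample_cell(
    rng: np.random.Generator,
    centroid: tuple[float, float],
    morphotype: str,
    soma_od_range: tuple[float, float],
) -> CellSpec:
    p = _MORPHOTYPES[morphotype]
    return CellSpec(
        centroid=centroid,
        soma_radii_um=(rng.uniform(*p["radii"]), rng.uniform(*p["radii"])),
        soma_angle=rng.uniform(0, math.pi),
        n_primary_processes=int(rng.integers(p["n_proc"][0], p["n_proc"][1] + 1)),
        process_length_um=p["length"],
        branch_probability=p["branch_p"],
        morphotype=morphotype,
        stain_amplitude=rng.uniform(*soma_od_range),
    )


def _walk_process(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    n_steps: int,
    branch_p: float,
    inside: np.ndarray,
    depth: int = 0,
) -> list[np.ndarray]:
    """Random-walk polylines (1-px steps); terminates on leaving the field."""
    points = [start.copy()]
    pos = start.copy()
    polylines = []
    for step in range(n_steps):
        heading += rng.normal(0.0, _TURN_SD)
        pos = pos + np.array([math.sin(heading), math.cos(heading)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < inside.shape[0] and 0 <= c < inside.shape[1]) or not inside[r, c]:
            break
        points.append(pos.copy())
        if depth < 2 and n_steps - step > 4 and rng.random() < branch_p:
            side = 1.0 if rng.random() < 0.5 else -1.0
            branch_heading = heading + side * rng.uniform(0.3, 0.8)
            branch_steps = int((n_steps - step) * rng.uniform(0.4, 0.8))
            polylines.extend(
                _walk_process(rng, pos, branch_heading, branch_steps, branch_p, inside, depth + 1)
            )
    polylines.insert(0, np.array(points))
    return polylines


def generate_histology(
    n_cells: int,
    field_size_um: float = 500.0,
    morphotype_mix: float = 1.0,
    calibration: float = 0.5,
    seed: int = 0,
    noise_sd: float = 4.0,
    margin_um: float = 10.0,
    influence_radius_um: float = 12.0,
    min_separation_um: float = 15.0,
    soma_od_range: tuple[float, float] = _SOMA_OD_RANGE,
    stain_matrix: StainMatrix | None = None,
) -> tuple[StainedSection, GroundTruth]:
    """Render a ground-truthed DAB/hematoxylin glial field.

    Parameters
    ----------
    n_cells : number of cells to place (soma centers >= ``min_separation_um``
        apart; placement failure after retries raises).
    morphotype_mix : fraction of ramified cells (1.0 = all ramified,
        0.0 = all ameboid).
    noise_sd : Gaussian pixel-noise sigma on the rendered 8-bit channels.
    influence_radius_um : radius at which the ground-truth proximal/distal
        length split is reported.

    Identical arguments and seed give bitwise-identical outputs.
    """
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    if not (0.0 <= morphotype_mix <= 1.0):
        raise ValidationError("morphotype_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    size_px = int(round(field_size_um / calibration))
    margin_px = int(round(margin_um / calibration))
    shape = (size_px, size_px)

    tissue = np.zeros(shape, bool)
    tissue[margin_px : size_px - margin_px, margin_px : size_px - margin_px] = True

    # soma placement by rejection sampling
    max_radius_px = _MORPHOTYPES["ameboid"]["radii"][1] / calibration
    inner = margin_px + max_radius_px + 2
    if size_px - 2 * inner <= 0 and n_cells > 0:
        raise ValidationError("field too small for the requested margin and soma size")
    min_sep_px = min_separation_um / calibration
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 2000 * max(n_cells, 1):
            raise ComputationError(
                f"could not place {n_cells} somata {min_separation_um} µm apart; "
                "try fewer cells or a larger field"
            )
        cand = tuple(rng.uniform(inner, size_px - inner, size=2))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep_px**2 for r, c in centers):
            centers.append(cand)

    c_dab = np.zeros(shape)
    soma_labels = np.zeros(shape, np.int32)
    process_mask = np.zeros(shape, bool)
    cells: list[CellTruth] = []
    r_infl_px = influence_radius_um / calibration

    for idx, center in enumerate(centers, start=1):
        morphotype = "ramified" if rng.random() < morphotype_mix else "ameboid"
        spec = _sample_cell(rng, center, morphotype, soma_od_range)
        p = _MORPHOTYPES[morphotype]
        a_px = spec.soma_radii_um[0] / calibration
        b_px = spec.soma_radii_um[1] / calibration
        rr, cc = draw.ellipse(center[0], center[1], a_px, b_px,
                              shape=shape, rotation=spec.soma_angle)
        soma_labels[rr, cc] = idx
        c_dab[rr, cc] = np.maximum(c_dab[rr, cc], spec.stain_amplitude)
        truth = CellTruth(spec=spec, soma_area_px=len(rr))

        cell_proc = np.zeros(shape, bool)
        base_angles = np.linspace(0, 2 * math.pi, spec.n_primary_processes, endpoint=False)
        for angle in base_angles + rng.uniform(0, 2 * math.pi / max(spec.n_primary_processes, 1)):
            length_um = max(2.0, rng.normal(*spec.process_length_um))
            n_steps = int(round(length_um / calibration))
            # start just outside the soma boundary along the launch direction
            boundary_r = _ellipse_radius(a_px, b_px, spec.soma_angle, angle)
            start = np.array(center) + (boundary_r + 0.5) * np.array(
                [math.sin(angle), math.cos(angle)]
            )
            polylines = _walk_process(
                rng, start, angle, n_steps, spec.branch_probability, tissue
            )
            for line in polylines:
                if len(line) < 2:
                    continue
                steps = len(line) - 1
                truth.total_length_um += steps * calibration
                mid = (line[:-1] + line[1:]) / 2.0
                d = np.hypot(mid[:, 0] - center[0], mid[:, 1] - center[1])
                prox_steps = int(np.count_nonzero(d <= r_infl_px))
                truth.proximal_length_um += prox_steps * calibration
                truth.distal_length_um += (steps - prox_steps) * calibration
                pix = np.round(line).astype(int)
                cell_proc[pix[:, 0], pix[:, 1]] = True
                truth.polylines.append(line)
        if p["thickness_iter"]:
            cell_proc = ndimage.binary_dilation(
                cell_proc, np.ones((3, 3), bool), iterations=p["thickness_iter"]
            )
            cell_proc &= tissue
        cell_proc &= soma_labels != idx
        dist_to_center = None  # lazily computed only for area truth
        rr_p, cc_p = np.nonzero(cell_proc)
        if rr_p.size:
            dist_to_center = np.hypot(rr_p - center[0], cc_p - center[1])
            truth.proximal_area_px = int(np.count_nonzero(dist_to_center <= r_infl_px))
            truth.distal_area_px = int(rr_p.size - truth.proximal_area_px)
        process_mask |= cell_proc
        c_dab[cell_proc] = np.maximum(c_dab[cell_proc], p["process_od"])
        cells.append(truth)

    # soft edges: slight optical blur of the chromogen field
    c_dab = ndimage.gaussian_filter(c_dab, sigma=0.5)
    c_dab[~tissue] = 0.0

    # hematoxylin counterstain: smooth low-amplitude texture inside tissue
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=20.0)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd
    c_hem = np.clip(_HEMATOXYLIN_BASE + _HEMATOXYLIN_VAR * texture, 0.05, 0.25)
    c_hem[~tissue] = 0.0

    matrix = stain_matrix or StainMatrix.hdab()
    v_hem, v_dab = matrix.vectors[0], matrix.vectors[1]
    od = c_dab[:, :, None] * v_dab[None, None, :] + c_hem[:, :, None] * v_hem[None, None, :]
    intensity = 256.0 * np.power(10.0, -od) - 1.0
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    pixels = np.clip(np.round(intensity), 0, 255).astype(np.uint8)

    stained_px = int(((soma_labels > 0) | process_mask).sum())
    tissue_px = int(tissue.sum())
    section = StainedSection(
        pixels, calibration,
        label=f"synthetic-{seed}", stain_pair=(matrix.names[1], matrix.names[0]),
    )
    truth = GroundTruth(
        cells=cells,
        soma_labels=LabelMap(soma_labels) if soma_labels.max() == len(centers)
        else _relabel(soma_labels),
        process_mask=BinaryMask(process_mask, calibration),
        tissue_mask=BinaryMask(tissue, calibration),
        influence_radius_um=influence_radius_um,
        stained_area_fraction=stained_px / tissue_px if tissue_px else 0.0,
    )
    return section, truth


def _relabel(labels: np.ndarray) -> LabelMap:
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    remap = np.zeros(int(labels.max()) + 1, np.int32)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return LabelMap(remap[labels])


def _ellipse_radius(a: float, b: float, ellipse_angle: float, direction: float) -> float:
    """Radius of a rotated ellipse along a given direction."""
    t = direction - ellipse_angle
    return (a * b) / math.hypot(b * math.cos(t), a * math.sin(t))


# ---------------------------------------------------------------------------
# MR pairs
# ---------------------------------------------------------------------------

def generate_mr_pair(
    shape: tuple[int, int],
    roi_layout: dict[str, tuple[int, int, int, int]],
    mtr_by_region: dict[str, float],
    s0_level: float = 200.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    calibration: float = 1.0,
) -> tuple[MtrPair, GrayImage]:
    """Constant-plus-noise MR acquisition pair with a known MTR field.

    ``roi_layout`` maps region names to ``(r0, c0, r1, c1)`` half-open
    rectangles; ``mtr_by_region`` gives each region's true MTR in [0, 1).
    s0 = s0_level + N(0, noise_sd²); s_mt = s0_level·(1 − MTR) + independent
    noise.  Returns the pair and the noiseless true MTR field.
    """
    if s0_level <= 0:
        raise ValidationError("s0_level must be > 0")
    for name, value in mtr_by_region.items():
        if not (0.0 <= value < 1.0):
            raise ValidationError(f"region {name!r}: MTR must lie in [0, 1)")
        if name not in roi_layout:
            raise ValidationError(f"region {name!r} missing from roi_layout")
    rng = np.random.default_rng(seed)
    truth = np.zeros(shape)
    for name, (r0, c0, r1, c1) in roi_layout.items():
        truth[r0:r1, c0:c1] = mtr_by_region.get(name, 0.0)
    s0 = np.full(shape, float(s0_level))
    s_mt = s0_level * (1.0 - truth)
    if noise_sd > 0:
        s0 = s0 + rng.normal(0.0, noise_sd, shape)
        s_mt = s_mt + rng.normal(0.0, noise_sd, shape)
    s0 = np.clip(s0, 0.0, None)
    s_mt = np.clip(s_mt, 0.0, None)
    pair = MtrPair(GrayImage(s0, calibration), GrayImage(s_mt, calibration))
    return pair, GrayImage(truth, calibration)


def roiset_from_layout(roi_layout: dict[str, tuple[int, int, int, int]]) -> RoiSet:
    """Build a polygon RoiSet from rectangular (r0, c0, r1, c1) regions."""
    rois = RoiSet()
    for name, (r0, c0, r1, c1) in roi_layout.items():
        rois.add_polygon(name, [[r0, c0], [r0, c1], [r1, c1], [r1, c0]])
    return rois
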