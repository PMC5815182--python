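"""Per-cell decomposition of process arbors into proximal and distal parts.

For each soma the proximal marker is the soma dilated a fixed number of
times; skeleton pixels inside a circular influence zone around the soma
centroid that are reachable from the marker seed the "proximal thinned
processes"; morphological reconstruction (selection of whole 8-connected
components touching the markers) then recovers final proximal processes
inside the circle, the visible-cell set (soma + proximal), and distal
processes (the reconstructed arbor outside the circle).  Process
components touching no marker — staining from cells in another focal
plane — belong to neither compartment.

Pixels claimable by two neighboring cells are assigned to the nearer soma
centroid (ties to the lower label), so the compartment maps form a strict
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import BinaryMask, LabelMap
from .errors import ValidationError
from .segmentation import GliaSegmentation

__all__ = ["ArborParams", "ArborDecomposition", "reconstruct_from_markers", "decompose_arbors"]


@dataclass
class ArborParams:
    """soma_dilations: 3×3 dilation iterations defining the proximal marker;
    influence_radius_um: radius of the circular proximal zone around the
    soma centroid (µm)."""

    soma_dilations: int = 2
    influence_radius_um: float = 12.0

    def __post_init__(self) -> None:
        if self.soma_dilations < 1:
            raise ValidationError("soma_dilations must be >= 1")
        if self.influence_radius_um <= 0:
            raise ValidationError("influence_radius_um must be > 0")


@dataclass
class ArborDecomposition:
    """Partitioned arbor compartments for every segmented cell.

    ``proximal_owner`` / ``distal_owner`` are label images: value k > 0
    means the pixel is a proximal (resp. distal) process pixel of cell k;
    0 means unassigned.  Per-cell and whole-image masks derive from them.
    """

    soma: LabelMap
    centroids: np.ndarray  # (n_cells, 2) in pixel coordinates
    proximal_owner: np.ndarray
    distal_owner: np.ndarray
    calibration: float

    @property
    def cell_ids(self) -> range:
        return range(1, self.soma.object_count + 1)

    def proximal_mask(self, cell: int | None = None) -> np.ndarray:
        return self.proximal_owner > 0 if cell is None else self.proximal_owner == cell

    def distal_mask(self, cell: int | None = None) -> np.ndarray:
        return self.distal_owner > 0 if cell is None else self.distal_owner == cell

    def visible_mask(self, cell: int | None = None) -> np.ndarray:
        """Soma plus proximal processes ('visible' cell extent)."""
        if cell is None:
            return (self.soma.pixels > 0) | (self.proximal_owner > 0)
        return (self.soma.pixels == cell) | (self.proximal_owner == cell)

    def area_um2(self, owner: np.ndarray, cell: int) -> float:
        return float(np.count_nonzero(owner == cell)) * self.calibration**2


def reconstruct_from_markers(mask: BinaryMask | np.ndarray, markers: BinaryMask | np.ndarray) -> np.ndarray:
    """Union of 8-connected components of ``mask`` that intersect ``markers``.

    Equivalent to binary morphological reconstruction (geodesic dilation of
    ``markers ∩ mask`` inside ``mask`` to stability).
    """
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    mk = markers.pixels if isinstance(markers, BinaryMask) else np.asarray(markers, bool)
    if m.shape != mk.shape:
        raise ValidationError("mask and marker shapes differ")
    labels = measure.label(m, connectivity=2)
    hit = np.unique(labels[mk & m])
    hit = hit[hit > 0]
    if hit.size == 0:
        return np.zeros_like(m)
    return np.isin(labels, hit)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean disk by Euclidean distance to ``center``, built on its bbox."""
    h, w = shape
    r0 = max(int(np.floor(center[0] - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius_px)) + 2, h)
    c0 = max(int(np.floor(center[1] - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius_px)) + 2, w)
    out = np.zeros(shape, bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    out[r0:r1, c0:c1] = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
    return out


def decompose_arbors(seg: GliaSegmentation, params: ArborParams | None = None) -> ArborDecomposition:
    """Split each cell's processes into proximal and distal compartments.

    Per soma s with centroid c: marker = s dilated ``soma_dilations``
    times; proximal thinned = components of (skeleton ∩ disk(c, r))
    touching the marker; final proximal = components of the process mask
    touching the proximal thinned set, restricted to the disk; distal =
    the same reconstructed components outside the disk.  Contested pixels
    go to the nearer soma centroid, ties to the lower label.
    """
    params = params or ArborParams()
    if seg.skeleton is None:
        raise ValidationError("segmentation lacks a skeleton; run skeletonize_processes first")
    soma = seg.soma
    cal = seg.calibration
    shape = soma.shape
    n = soma.object_count
    proximal_owner = np.zeros(shape, np.int32)
    distal_owner = np.zeros(shape, np.int32)
    if n == 0:
        return ArborDecomposition(soma, np.zeros((0, 2)), proximal_owner, distal_owner, cal)

    centroids = np.array(ndimage.center_of_mass(soma.pixels > 0, soma.pixels, range(1, n + 1)))
    radius_px = params.influence_radius_um / cal
    proc = seg.processes.pixels
    skel = seg.skeleton.pixels
    proc_labels = measure.label(proc, connectivity=2)

    best_dist = np.full(shape, np.inf)
    structure = np.ones((3, 3), bool)

    for k in range(1, n + 1):
        center = tuple(centroids[k - 1])
        soma_k = soma.pixels == k
        marker = ndimage.binary_dilation(soma_k, structure, iterations=params.soma_dilations)
        disk = _disk_mask(shape, center, radius_px)
        proximal_thinned = reconstruct_from_markers(skel & disk, marker)
        hit = np.unique(proc_labels[proximal_thinned])
        hit = hit[hit > 0]
        if hit.size == 0:
            continue
        arbor = np.isin(proc_labels, hit)  # reconstruct(processes, proximal thinned)
        final_proximal = arbor & disk
        distal = arbor & ~disk
        claimed = final_proximal | distal
        rows, cols = np.nonzero(claimed)
        dist = np.hypot(rows - center[0], cols - center[1]) * cal
        win = dist < best_dist[rows, cols]
        wr, wc = rows[win], cols[win]
        best_dist[wr, wc] = dist[win]
        # reset any previous owner's claim at the pixels this cell wins
        proximal_owner[wr, wc] = 0
        distal_owner[wr, wc] = 0
        prox_win = final_proximal[wr, wc]
        proximal_owner[wr[prox_win], wc[prox_win]] = k
        distal_owner[wr[~prox_win], wc[~prox_win]] = k

    return ArborDecomposition(soma, centroids, proximal_owner, distal_owner, cal)
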