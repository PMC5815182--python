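"""End-to-end orchestration of the histology analysis sequence.

``analyze_section`` runs unmix → tissue → soma threshold → soma →
processes → skeleton → arbor decomposition → feature tables in memory;
``run_pipeline`` wraps it with file I/O, intermediate mask output, a
machine-readable manifest (config hash, versions, seed) and a log, and is
what the ``gliamorph run`` subcommand calls.  Re-running with identical
config and inputs reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arborization import ArborDecomposition, decompose_arbors
from .config import RunConfig
from .core import GrayImage, RoiSet, StainedSection, read_roiset, read_section, write_mask_png
from .errors import ComputationError, ValidationError
from .morphometry import morphometric_features, roi_features
from .segmentation import GliaSegmentation, segment_image
from .stains import chromogen_gray, unmix_section

log = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class SectionAnalysis:
    """All products of one analyzed section."""

    section: StainedSection
    chromogen: GrayImage
    seg: GliaSegmentation
    decomp: ArborDecomposition
    cells: pd.DataFrame
    rois: pd.DataFrame


def analyze_section(
    section: StainedSection,
    rois: RoiSet | None = None,
    config: RunConfig | None = None,
) -> SectionAnalysis:
    """Run the full analysis sequence on an in-memory section."""
    config = config or RunConfig()
    channels = unmix_section(section, config.stain.matrix())
    chromogen = chromogen_gray(channels, "dab")
    tissue_gray = section.mean_gray()
    seg_params = config.segmentation
    seg = segment_image(tissue_gray, chromogen, seg_params)
    decomp = decompose_arbors(seg, config.arbor)
    cells = morphometric_features(decomp, seg, chromogen)
    rois_df = roi_features(
        cells, seg, chromogen, rois, stain_threshold=config.morphometry.stain_threshold
    )
    return SectionAnalysis(section, chromogen, seg, decomp, cells, rois_df)


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_outputs(analysis: SectionAnalysis, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask_png(analysis.seg.tissue, out_dir / "tissue.png")
    write_mask_png(analysis.seg.processes, out_dir / "processes.png")
    write_mask_png(analysis.seg.skeleton, out_dir / "skeleton.png")
    import imageio.v3 as iio

    iio.imwrite(out_dir / "soma.png", analysis.seg.soma.pixels.astype(np.uint16))
    iio.imwrite(out_dir / "proximal.png", analysis.decomp.proximal_owner.astype(np.uint16))
    iio.imwrite(out_dir / "distal.png", analysis.decomp.distal_owner.astype(np.uint16))
    analysis.cells.to_csv(out_dir / "cells.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    analysis.rois.to_csv(out_dir / "rois.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    manifest = {
        "package": "gliamorph",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "section_label": analysis.section.label,
        "soma_count": int(analysis.decomp.soma.object_count),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """File-based pipeline: read inputs, analyze, write a run directory.

    Fails with the stage name on any stage error; partial outputs written
    before the failure are retained for debugging.
    """
    if config.image is None:
        raise ValidationError("run_pipeline: config.image is required")
    if config.calibration is None:
        raise ValidationError("run_pipeline: config.calibration (µm/pixel) is required")
    out = Path(out_dir or config.out_dir or "gliamorph-run")
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("gliamorph")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stage = "read"
        t0 = time.perf_counter()
        section = read_section(config.image, config.calibration)
        rois = read_roiset(config.roi, section.shape) if config.roi else None
        log.info("stage=read elapsed=%.2fs image=%s", time.perf_counter() - t0, config.image)
        stage = "analyze"
        t0 = time.perf_counter()
        analysis = analyze_section(section, rois, config)
        log.info(
            "stage=analyze elapsed=%.2fs somata=%d process_px=%d",
            time.perf_counter() - t0,
            analysis.decomp.soma.object_count,
            int(analysis.seg.processes.pixels.sum()),
        )
        stage = "write"
        write_outputs(analysis, out, config)
        log.info("stage=write out_dir=%s", out)
    except ValidationError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise ComputationError(f"pipeline stage {stage!r} failed for {config.image}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
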