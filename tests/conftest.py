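import numpy as np
import pytest

from gliamorph import analyze_section, generate_histology
from gliamorph.morphometry import activation_index, size_index, skeleton_length_um


@pytest.fixture(scope="session")
def small_analysis():
    """A 12-cell mixed-morphotype field at 250 µm, fully analyzed."""
    section, truth = generate_histology(
        12, field_size_um=250.0, morphotype_mix=0.6, calibration=0.5, seed=3
    )
    return section, truth, analyze_section(section)


@pytest.fixture(scope="session")
def field_summaries():
    """Pipeline summaries for paired ramified/ameboid 30-cell fields, seeds 1-5.

    These are the reference study conditions: 500 µm field, 0.5 µm/px,
    30 cells.  Only summary quantities are kept to bound memory.
    """
    out = {}
    for seed in range(1, 6):
        for morph, mix in (("ramified", 1.0), ("ameboid", 0.0)):
            section, truth = generate_histology(
                30, field_size_um=500.0, morphotype_mix=mix, calibration=0.5, seed=seed
            )
            analysis = analyze_section(section)
            cells = analysis.cells
            true_length = sum(c.total_length_um for c in truth.cells)
            measured_length = skeleton_length_um(analysis.seg.skeleton.pixels, 0.5)
            out[(seed, morph)] = {
                "true_count": truth.cell_count,
                "count": analysis.decomp.soma.object_count,
                "activation_index": activation_index(cells),
                "size_index": size_index(cells),
                "truth_size_index": sum(
                    (c.soma_area_px + c.proximal_area_px) * 0.25 for c in truth.cells
                )
                / truth.cell_count,
                "skeleton_length_ratio": measured_length / true_length,
            }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
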