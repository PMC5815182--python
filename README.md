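# gliamorph

Quantitative image analysis of glial cells in immunohistochemically
stained brain sections, plus magnetization-transfer-ratio (MTR) mapping
for paired MR acquisitions.

Neuroinflammation studies (e.g. cuprizone-induced demyelination and its
pharmacological modulation) read out microglia and astrocyte state from
brightfield sections stained with a brown DAB chromogen (Iba1, GFAP,
GST-π, MBP, MOG) on a hematoxylin counterstain. The biology lives in
*morphology*: resting microglia are ramified, with small somata and
long thin processes, while activated microglia turn ameboid — enlarged
somata, retracted arbors. `gliamorph` turns a calibrated RGB scan into
per-cell and per-region numbers that capture exactly that transition,
and computes MTR = (S₀ − S_MT)/S₀ maps as the companion in-vivo myelin
readout.

## What it computes

Starting from color deconvolution of the Beer–Lambert optical densities
(OD_ch = −log₁₀((I_ch + 1)/256), solved per pixel against hematoxylin
and DAB absorption vectors), the pipeline runs a fixed sequence:

1. tissue masking against the white slide background;
2. adaptive soma thresholding — the mean gray of the darkest in-tissue
   chromogen pixels, scaled by a factor;
3. soma labeling with a size window;
4. process extraction by black top-hat (structures thinner than the
   structuring disk), binarized against the soma-seed contrast, with
   soma subtraction;
5. homotopic thinning of processes for length measurement;
6. per-cell arbor decomposition: marker reconstruction from dilated
   somata within a circular influence zone splits each arbor into
   **proximal** and **distal** compartments;
7. morphometry: areas, Crofton perimeters, form factor 4πA/P²,
   compartment skeleton lengths (orthogonal steps 1 px, diagonal √2),
   optical densities against the local non-cell background, and the
   region indices

   * activation index = (Σ soma + Σ proximal area) / Σ distal area,
   * size index = (Σ soma + Σ proximal area) / cell count.

Bulk stains are quantified as stained-area fraction and integrated
density; qPCR Ct tables transform through 2^−ΔΔCt; any readout can be
normalized to a control group. A seeded generator renders
ground-truthed synthetic sections (ramified/ameboid morphotypes) and MR
pairs, so the whole pipeline is testable without slide data.

## Worked example

```python
from gliamorph import generate_histology, analyze_section

section, truth = generate_histology(
    n_cells=30, field_size_um=500, morphotype_mix=1.0,  # all ramified
    calibration=0.5, seed=1,
)
analysis = analyze_section(section)
print(analysis.rois.round(3).to_string(index=False))
```

```
roi_name  soma_count  soma_count_per_mm2  activation_index  size_index  stained_area_fraction  integrated_density
    full          30             130.412             0.982      76.592                  0.016          495023.617
```

All 30 generated cells are recovered (130 cells/mm² of tissue). The
activation index ≈ 1.0 says proximal mass roughly balances distal mass
— the ramified signature; the same field rendered ameboid
(`morphotype_mix=0.0`) yields ≈ 6, because distal arbors have retracted.
The size index is µm² of soma+proximal area per cell. Per-cell rows
carry the underlying features:

```
soma_id  soma_area_um2  soma_form_factor  proximal_area_um2  distal_area_um2  proximal_length_um  distal_length_um  soma_od
      1          34.25             1.026              33.50           109.00              48.835           163.146    0.768
      2          30.00             0.960              45.75            90.75              69.477           131.453    0.761
```

The MTR side, on a synthetic two-region phantom (S₀ = 200, noise σ = 4):

```python
from gliamorph import generate_mr_pair, compute_mtr, roi_report, roiset_from_layout

layout = {"cortex": (0, 0, 60, 100), "callosum": (60, 0, 120, 100)}
pair, _ = generate_mr_pair((120, 100), layout, {"cortex": 0.25, "callosum": 0.40},
                           s0_level=200, noise_sd=4, seed=1)
print(roi_report(compute_mtr(pair), pair.s0, roiset_from_layout(layout)).round(4).to_string(index=False))
```

```
roi_name  n_pixels  mean_signal  mean_mtr
  cortex      6000     199.9688    0.2498
callosum      6000     199.9363    0.3997
```

Both ROI means land on the true MTR (0.25, 0.40) to within the noise.

The same workflows are scriptable from the shell: `gliamorph run`
(full pipeline to cells.csv/rois.csv + masks + manifest), `segment`,
`arborize`, `quantify`, `mtr`, `qpcr`, and `synth histology|mr`.
See `gliamorph --help`.

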