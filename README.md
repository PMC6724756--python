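# fociquant

Per-cell quantification of multiplex fluorescent in situ hybridization
(RNAscope) images.

In an RNAscope assay every target mRNA molecule appears as a discrete
fluorescent punctum ("focus" or "dot"). Studies of transcript co-expression
— for example mapping HCN channel subunit mRNAs (HCN1/2/4) together with
excitatory/inhibitory neuron markers (VGlut1/2, VGat) across brain regions —
need those puncta counted *per cell*, with a cell anchored to its
DAPI-stained nucleus. `fociquant` implements that workflow as a tested,
reusable Python library and CLI:

1. **Nuclei segmentation** — Otsu threshold on the lightly smoothed DAPI
   channel, watershed on the negated Euclidean distance transform to split
   touching nuclei.
2. **Cell territories** — each nucleus mask is expanded by 3 px
   (nearest-label Euclidean assignment, so territories never overlap).
3. **Spot detection** — per probe channel: Gaussian prefilter (σ = 1 px),
   then *tolerance maxima*: a local maximum of height v survives iff no
   walk over pixels of value > v − tolerance reaches a strictly higher
   pixel (prominence ≥ tolerance).
4. **Per-cell counting and positivity** — each focus belongs to the
   territory owning its pixel; a cell is *positive* for a probe iff it
   holds ≥ 3 foci.
5. **Region summaries** — % of all DAPI-defined cells positive per probe
   (the heatmap quantity), conditional co-expression percentages
   (e.g. % of VGlut2⁺ cells that are HCN4⁺), and the partition of cells
   into co-expression classes (2³ classes for a triple assay).
   Quantification is marked *not applicable* for regions averaging fewer
   than 4 dots per DAPI-defined cell or where cell bodies cannot be
   separated.

Two companions make the pipeline testable end to end:

- a **synthetic tissue simulator** (`fociquant.simulate`) that renders
  DAPI nuclei and per-cell puncta with a zero-inflated Poisson count law,
  plus background, noise, stray spots and autofluorescent patches — and
  records the full ground truth;
- an **I_h sag metric** (`fociquant.ephys`) for current-clamp recordings:
  sweeps are averaged and sag = V_steady − V_min, the steady-state voltage
  of the stimulus epoch minus the most hyperpolarized point within the
  first second.

## Worked example

```python
from fociquant import (
    ChannelImage, ChannelSpec, DetectionParams, SimulationConfig,
    simulate_image, segment_nuclei, dilate_labels, detect_foci,
    build_cell_table, summarize_region, classify_cells,
)

specs = (
    ChannelSpec("HCN4", zero_inflation=0.5, mean_count=6.0),
    ChannelSpec("HCN2", zero_inflation=0.4, mean_count=5.0),
    ChannelSpec("VGlut2", zero_inflation=0.2, mean_count=7.0),
)
scene = simulate_image(SimulationConfig(n_nuclei=50, channels=specs, seed=12))

nuclei = segment_nuclei(ChannelImage(scene.stack[0], "DAPI"))
cells = dilate_labels(nuclei, radius=3)
focus_sets = [
    detect_foci(
        ChannelImage(scene.stack[i + 1], spec.name),
        DetectionParams(tolerance=0.5 * spec.effective_amplitude(), sigma=1.0),
    )
    for i, spec in enumerate(specs)
]
table = build_cell_table(cells, focus_sets, threshold=3)
summary = summarize_region(table)

print(f"{nuclei.n_nuclei} nuclei segmented")
for name in ("HCN4", "HCN2", "VGlut2"):
    print(f"{name}: {summary.percent_positive[name]:.1f}% of {summary.n_cells} cells positive")
print(f"HCN4|VGlut2: {summary.conditional[('HCN4', 'VGlut2')]:.1f}% of VGlut2+ cells co-express HCN4")
print(classify_cells(table).value_counts().to_string())
```

prints

```
50 nuclei segmented
HCN4: 48.0% of 50 cells positive
HCN2: 56.0% of 50 cells positive
VGlut2: 74.0% of 50 cells positive
HCN4|VGlut2: 43.2% of VGlut2+ cells co-express HCN4
class
VGlut2               12
triple expression    11
HCN2+VGlut2           9
HCN4+HCN2             6
HCN4+VGlut2           5
none                  3
HCN4                  2
HCN2                  2
```

The percent-positive numbers are fractions of *all* DAPI-defined cells;
the conditional percentage uses VGlut2-positive cells as its denominator;
the class table partitions the 50 cells into the eight possible
co-expression classes. With `seed=12` the planted truth is recovered
exactly — the point of the simulator is that every one of these numbers
can be checked against what was planted.

The same workflow is available from the shell:

```sh
fociquant simulate --out fixture/ --seed 12 --n-nuclei 50
fociquant run-all --config run.yaml      # segment → detect → count → summarise
fociquant sag --sweeps sweeps.csv --onset 0.5
```

## Scope

Single 2D optical planes only (multi-Z input is rejected, not projected);
anatomical regions arrive as user-supplied masks; detection tolerances are
per-channel user inputs, as in the assay itself. Subpixel spot
localization, intensity-based expression levels and 3D segmentation are
out of scope. See `docs/methods.md` for the model, parameter and design
details.
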