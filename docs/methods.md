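# Methods

## The quantification model

`fociquant` treats a multiplex FISH field as a single 2D optical plane with
one DAPI (nuclear) channel and up to three probe channels, each probe
rendering one mRNA species as diffraction-limited puncta. The analysis
chain is deterministic: identical inputs and parameters give byte-identical
outputs, and every stage is exposed as a library function so each can be
validated in isolation.

### Nuclei segmentation

Foreground is obtained by Otsu's global threshold on the DAPI image after
Gaussian smoothing (`smoothing_sigma`, default 1 px). Touching nuclei are
split by watershed on the negated Euclidean distance transform, seeded at
distance-map maxima (`min_seed_distance`, default 7 px ≈ one expected
nucleus radius; the distance map is smoothed with σ = 1 for seed finding
only, because EDT plateaus otherwise spawn several equal maxima inside one
nucleus). Components below `min_area` (default 50 px², roughly a quarter of
a 9-px-radius nucleus) are dropped and labels are relabelled contiguously.

Blank images are recognised by Otsu's own effectiveness measure
(between-class variance / total variance): a pure Gaussian-noise image
scores ≈ 0.64 *independently of its scale*, while any image with real
stained nuclei scores ≳ 0.8. Below `min_otsu_separability` (default 0.75)
the threshold is judged to be splitting noise and the result is an empty
label map rather than a speckle field.

Nuclei touching the image border are kept but flagged (`border` column) so
downstream analyses can exclude them.

### Cell territories: "dilated by three pixels"

Territories are built by nearest-label expansion: every background pixel
within Euclidean distance ≤ `radius` (default 3 px) of a nucleus joins the
*nearest* nucleus, ties going to the lower label id. This is deliberately
not per-label morphological dilation, which can overlap; disjoint
territories are what make per-cell counting unambiguous. The implementation
enumerates integer offsets with d² ≤ r² in ascending d² and takes the
minimum donor label per shell, which reproduces a per-pixel brute-force
nearest-nucleus scan exactly (tested on ≤ 64×64 geometries).

### Spot detection: tolerance maxima

Each probe channel is prefiltered with a Gaussian (σ = 1 px, reflective
boundaries; σ = 0 is the identity). Maxima are then accepted by a noise
tolerance (prominence) criterion, stated self-containedly:

> a maximal plateau of height v is accepted iff no path from it along
> pixels of value > v − tolerance reaches a pixel of value > v.

Equivalently, a maximum is accepted iff its topographic prominence — its
height above the saddle where its superlevel component merges into higher
ground — is at least the tolerance. The production code computes this with
one descending union-find sweep over the pixels (O(n log n)); the test
suite holds it to exact agreement with a literal per-maximum flood search
on random images.

Conventions the criterion itself leaves open:

- **Global maximum.** A summit from which no higher pixel is reachable is
  measured against the image minimum (the standard topographic convention
  for the highest peak). A constant image therefore has no maxima, and a
  tolerance above the total dynamic range yields an empty result.
- **Plateaus.** One focus per accepted plateau, at its centroid, rounded
  half-up. Equal-valued maxima that are mutually reachable within the
  tolerance collapse to a single focus at their joint centroid. Chains of
  exactly equal-valued peaks with mixed saddle depths follow the
  elder/merge rule of the union-find sweep; exact ties are measure-zero in
  real (noisy) data.
- **No intensity floor.** Dim but prominent maxima count; the assay leaves
  absolute brightness uncalibrated, so tolerance is the only dial, set per
  channel by the user.
- **Aberrations.** A uniform autofluorescent patch is flat: its interior
  noise maxima are all below a spot-scale tolerance, so it contributes at
  most its single overall summit and never fragments into spot-like
  detections. Masking such regions out remains the user's responsibility,
  as in practice.

### Counting, positivity, applicability

A focus belongs to the territory owning its pixel; foci on background
pixels are *strays*, counted but assigned to no cell, so per channel
`Σ cell counts + strays = detected foci` holds identically. A cell is
positive for a probe iff it holds ≥ `threshold` foci (default 3, the same
rule for every probe). Region membership is decided by the nucleus
centroid, not fractional overlap.

Quantification is declared *not applicable* for a (region, channel) pair
when the mean focus count per DAPI-defined cell is below 4.0 — the mean is
taken over **all** cells of the region, not only positive ones — or when
the separability diagnostic fails. That diagnostic flags fused clusters:
labels whose area exceeds a ceiling (default 4× the median label area)
count as fused, and the scene is separable iff the fused fraction of
foreground area is ≤ 0.1.

### Summaries

Percent-positive uses all DAPI-defined cells of the region as denominator.
Conditional co-expression (A|B) uses B-positive cells and is reported as
*missing* — never 0 — when there are no B-positive cells. Co-expression
classes are the exact power set of the probes (≤ 3 probes, 8 classes).
Percentages are carried at full precision; `pool_summaries` averages
per-slice percentages across images and reports mean ± SEM, i.e. slices
are summarised first and pooled after.

## The simulator

The generator emulates the data regime the pipeline targets: single-plane
fields at roughly 3 px/µm with DAPI nuclei and per-cell puncta.

| parameter | default | meaning |
|---|---|---|
| image | 320 × 320 px | one field |
| n_nuclei | 50 | rejection-sampled centres |
| nucleus radius | 9 ± 1 px (clipped ± 3 σ) | logistic-edge shaded disks |
| min_center_spacing | 28 px | < 2 r forces touching nuclei |
| count law | zero-inflated Poisson (π, λ); `fixed_count` for degenerate | per cell, per channel |
| spot amplitude / σ | 40 / 1.0 px | 2D Gaussian kernels |
| spot placement | uniform in nucleus disk + 1.5 px margin, pairwise ≥ 6 px | see below |
| background / noise | 10 / 2 (additive Gaussian, clipped at 0) | SNR 20 by default |
| strays | Poisson(`stray_rate`) per image, outside every territory | tests the stray path |
| aberrations | uniform rectangles on probe channels | the flat-patch failure mode |

Two geometric choices are load-bearing. First, the σ = 1 prefilter keeps
s²/(s²+1) of a σ = s spot's amplitude, so tolerances are naturally phrased
against `ChannelSpec.effective_amplitude()` — the height the detector
actually sees (half that value is the "easy regime" tolerance used in the
tests). Second, two filtered σ_eff-wide spots merge under a half-amplitude
tolerance when closer than ≈ 3.3 σ_eff ≈ 6 px, so in-cell spots are planted
pairwise ≥ 6 px apart (with a farthest-point fallback that preserves the
planted count when a crowded cell cannot satisfy the spacing), and nuclei
are given enough area that a Poisson(5) load packs at that spacing.

What the simulator does **not** model: Poisson shot noise (additive
Gaussian is used because tolerance semantics are easiest to reason about
under additive noise), realistic chromatin texture, point-spread-function
anisotropy, optical sectioning, photobleaching, or 3D. Passing recovery
tests therefore demonstrate the pipeline's correctness under resolvable,
well-exposed conditions — they do not certify performance on crowded or
low-SNR real tissue, where the tolerance and the applicability rules exist
precisely to flag trouble.

Determinism: a `(config, seed)` pair fully determines the scene, the
ground-truth tables and the fixture bytes on disk.

## The sag metric

Sweeps (5–10 in practice) are averaged pointwise. For the averaged trace,
`sag = V_steady − V_min`, with V_min the minimum within the first
`trough_window` (1 s) after stimulus onset and V_steady the mean over the
final `steady_window` (default 0.5 s — the protocol's "final steady state"
is not otherwise specified) of the stimulus epoch (5 s, −70 pA from −50 mV
in the motivating protocol). No smoothing is applied before the minimum
search. The metric is invariant to additive offsets, non-negative for
traces that relax upward after the trough, and exactly 0 for flat traces.

## Numerical and interface conventions

- Pixel coordinates are 0-based `(row, col)` everywhere, including CSVs.
- Focus centroids round half-up; two accepted maxima can in principle round
  to the same pixel, in which case the higher peak is kept (FocusSet
  forbids duplicate coordinates).
- Label maps are written as 16-bit TIFF (32-bit when > 65535 labels);
  image stacks as multi-page TIFF with channel names in the metadata.
- Multi-Z input is rejected with a message, never silently projected.
- The QC report (`qc.json`) records every parameter of a run; reruns on
  identical inputs are byte-identical.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run entirely on simulated data:
recovery on 320 × 320 fields with 50 nuclei (pooled over three fields in
the acceptance script), conservation on one hundred 140 × 140 two-channel
scenes, detector-vs-oracle equivalence on two hundred random 32 × 32
images, dilation-vs-brute-force on 64 × 64 geometries, and sag on 5 s
traces at 1 kHz. These sizes give the distributional checks ≥ 1000
simulated cells while keeping a full run in the tens of seconds.
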