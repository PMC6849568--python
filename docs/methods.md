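# Methods

## The counting problem

Adherent epithelial cultures are traditionally counted by dissociating the
monolayer and loading a haemocytometer — a destructive measurement that
cannot follow one culture through time. Phase-contrast (PC) microscopy
images the same culture non-invasively, but the phase halo (a bright ring
at every cell edge) defeats direct intensity thresholding: cells are
neither uniformly brighter nor darker than the background.

`pccount` implements a counting pipeline that works around the halo with
two mean filters. In a focused PC image the cell interior is darker than
its edge. A mean filter whose disk kernel is large enough to span a cell
averages the bright halo into the interior, so the heavily smoothed
interior becomes *brighter* than the lightly smoothed one. The difference

    D = mean_filter(I, r_large) - mean_filter(I, r_small)

is therefore positive inside cells and near zero in the background. After
clipping negative values (the halo ring itself, see below), a global Otsu
threshold separates the cell class; components smaller than `min_area`
(default 8 px) are discarded; the number of remaining 8-connected
components is the per-image cell count.

## Segmentation details and numerical choices

* **Kernel**: discrete disk `{(dx,dy): dx² + dy² ≤ r²}`, matching the
  round-kernel convention of standard particle-analysis software. The
  filter is computed by decomposing the disk into horizontal runs and
  sliding cumulative sums — O(N·r) per image, exact to float rounding
  (verified against brute-force convolution to 1e-9).
* **Borders**: edge replication, so a constant image is a fixed point of
  the filter at every radius and no artificial dark rim enters the
  threshold statistics.
* **Subtraction order**: large minus small, making interiors positive.
* **Negative clipping**: the halo ring is brighter in the lightly smoothed
  copy, so it comes out strongly *negative* in D. On 8-bit platforms the
  subtraction saturates at zero, and we reproduce that behaviour
  deliberately: without it the difference histogram is trimodal
  (halo / background / interior) and Otsu's bimodal split flips to the
  halo-versus-rest cut on a substantial fraction of images, merging the
  whole background into one foreground region. `dual_filter_subtract`
  still exposes the signed intermediate; the clipping happens inside
  `segment_cells`.
* **Otsu**: 256-bin histogram of the (min, max)-rescaled image; threshold
  maximises between-class variance, ties broken toward the lowest
  threshold; foreground is strictly above the threshold. A constant image
  raises a degenerate-input error, which callers report as a blank field
  (count 0).
* **Minimum area**: strict comparison — a 7 px component is removed, an
  8 px component kept.

Default radii are `r_small = 7`, `r_large = 22` pixels, the optimum for
H400 oral keratinocytes at a ×10 objective (0.74375 µm/px); they must be
re-derived for any new cell line, objective or camera, which is what the
optimisation module is for.

## Parameter selection with region relations

Radii are chosen by exhaustive search against a nuclear ground truth:
nuclei are stained (Hoechst), imaged in a paired epifluorescence channel
and segmented; a segmented PC region then "correctly detects" a cell when
it stands in an exclusive one-to-one RCC5 relation PP, PO or EQ with
exactly one nucleus (the nucleus is a proper part of, partially overlaps,
or equals the region). The five-relation calculus over pixel sets is:

    DR  X ∩ Y = ∅          disconnected
    PO  otherwise           partial overlap
    PP  X ⊂ Y               proper part
    PPi X ⊃ Y               proper part, inverted
    EQ  X = Y               equal

Violations define the misdetection taxonomy: a region with no nucleus is
**noise**; with ≥2 nuclei, **merged**; a nucleus with no region is
**missed**; with ≥2 regions its regions are **split**; a one-to-one pair
in PPi (region strictly inside its nucleus) is flagged but kept — it still
satisfies the one-to-one condition, so it is not a counting error.
Entangled configurations are resolved by fixed precedence (region-level
labels, then nucleus-level, then one-to-one pairs), making every label
deterministic and the category counts exact partitions. A fifth
nucleus-side label (`in_ppi`) keeps the partitions exact for PPi pairs.

`grid_search` scores every admissible pair (r_small < r_large), pooling
correct detections over all supplied images (total correct / total
nuclei — denser images weigh more); ties break toward the smaller
r_large, then the smaller r_small (cheaper filters, sharper
segmentations).

Count-error bookkeeping (`error_contributions`) expresses each category's
signed effect on the final count as a percentage of the correctly
detected cells: each noise region adds one; a merged region replaces its
k nuclei by one region (−(k−1)); a split nucleus contributes +(k−1); a
missed nucleus −1.

## Nuclei segmentation

The ground-truth channel is segmented with a deliberately conservative
recipe: 3×3 mean smooth → linear histogram normalisation to [0, 255] →
local mean threshold (disk radius 20 px, zero offset, strictly above; a
1e-6 guard absorbs float jitter on flat backgrounds) → marker-based
watershed on the distance transform (markers = regional maxima ≥5 px
apart; the watershed line stays background so touching nuclei come
apart) → two binary erosions with a 3×3 square → labelling. A blank field
yields zero regions. Overlays are provided for visual review; corrections
are applied by editing the exported mask and re-loading it. The offset
and watershed variant are unstated in common practice and would be
recalibrated on real data.

## Noise rejection

Spurious regions (debris, texture fragments) inflate the count — in the
reference H400 training composition, 280 noise regions against 1175
correct cells, a +24% error. A two-class Fisher discriminant (cell vs
noise) is trained on the taxonomy labels: merged and split regions are
relabelled as cells (they resemble cells morphologically and their count
effects roughly cancel), PPi regions are excluded and are never removal
candidates. Features per region: area, perimeter, circularity 4πA/P²
(clamped to ≤1), maximum/minimum Feret diameters (caliper over the convex
hull + 1 px for the pixel footprint), aspect ratio, solidity, and the
grey statistics of the region on the original PC image (mean, sd, min,
max, median, skewness, kurtosis). Features are standardised and the
discriminant is fitted with scikit-learn's SVD-based LDA, which tolerates
the collinearity this feature set inevitably has; the model serialises to
plain JSON (means, scales, weights, intercept, priors) so applying it
needs no fitted library state. Greyscale features are measured on the raw
PC image rather than the difference image; the alternative reading is
noted as open.

Evaluation uses precision p = TP/(TP+FP), recall r = TP/(TP+FN),
F1 = 2pr/(p+r) with "cell" positive. The published worked example
(96.3% of 1286 cells retained, 78.9% of 280 noise removed) implies
TP = 1238, FN = 48, TN = 221, FP = 59 and F1 = 0.959, which the package
reproduces by computing the metrics on that confusion matrix. The
resubstitution accuracy of that matrix is 93.2%; the separately printed
96.4% overall rate is not recoverable from the other printed figures by
simple arithmetic, so both numbers are reported where relevant.

## From fields of view to cultures

A whole-culture count extrapolates the mean per-image count by the area
ratio: `N_total = (A_total / A_image) × mean(N_image)`; for a 35 mm dish
(962.11 mm²) and a 1.19 × 0.89 mm field (1.06 mm²) the multiplier is
907.65. The number of fields to image is chosen from the running-mean
convergence: ΔC(n) = |mean(first n) − mean(first n−1)| / mean(first n) ×
100, with the recommendation being the smallest n from which ΔC stays at
or below the threshold (default 1.5%) for every later observed n — a
first crossing is not enough. The denominator (mean at n) is one of three
defensible readings and is recorded as a package decision. Validation
against a reference count uses a through-origin least-squares fit
`count_image = gradient × count_reference`, with R² computed against the
through-origin model. Growth curves apply the extrapolation per replicate
and time point; a log2-linear fit of the mean curve gives the doubling
time.

## The synthetic scene generator

No public micrographs accompany the method, so the package generates
ground-truthed PC/fluorescence pairs with the optical structure the
method relies on — and only that structure; there is no physical optics
simulation. Defaults (frozen before the validation studies were finalised)
emulate H400-scale cells at ×10:

| parameter | default | rationale |
|---|---|---|
| field | 800×600 px | quarter-scale acquisition frame |
| cell radius | 13 ± 1.5 px (~10 µm) | H400 at 0.74 µm/px |
| halo | exponential glow, scale 3 px, truncated at 9 px | smooth PC glow, not a hard ring |
| halo coverage | 50–90% of the circumference | halos vanish where cells touch |
| interior | −25 grey, fading 50% toward the edge | darkest perinuclear centre |
| per-cell contrast | uniform 0.5–1.0 | faint and strong cells coexist |
| cytoplasm texture | sd 15, correlation 2.5 px | organelle-scale mottle |
| PSF | Gaussian σ = 1 px | optical blur before the sensor |
| sensor noise | sd 8 | CCD noise |
| noise blobs | 15 per field, 20–150 px², half bright / half dark | debris-sized artefacts |
| nuclei | discs at 0.5× cell radius, jittered strictly inside | PP(N, C) by construction |
| placement | ≥ 2R + 4 px between centres; jittered hexagonal lattice above 45% of the packing bound | bodies disjoint, halos may touch; dense sheets are quasi-ordered |

The glow, coverage, texture and contrast terms are what make the
parameter search identifiable: with hard-edged complete rings every
radius pair segments perfectly and the detection-rate landscape is flat.
With the realistic rendering, kernels smaller than the cell cannot
integrate the glow (fragmented, faint responses → splits and misses) and
the landscape has an interior optimum near r_large ≈ R + 2×halo, which
is what the recovery study measures.

What the generator does **not** emulate: elongated or irregular cell
shapes, multinucleated cells, mitotic rounding, confluent contact sheets
(cell bodies never overlap), focus drift and illumination gradients.
Passing the synthetic studies therefore demonstrates the pipeline's
internal correctness and its behaviour under the stated optical
assumptions, not performance on any particular real cell line.

The experiment scheduler models exponential growth: the expected count
per field at time t is `n₀ · 2^(t/doubling)`, with per-field counts
Poisson-distributed around the expectation (random field placement in a
nonuniform culture) and a feasibility guard against over-packing.

## Validation studies and problem sizes

`pccount.validation` fixes the scaled-down study conditions run by both
the test suite and `scripts/acceptance.py`:

* filter exactness on twenty random 32×32 images (brute-force oracle);
* RCC5 against direct set logic on all 511² subset pairs of a 3×3 grid;
* parameter recovery on 20 replicates of four pooled 256² fields at
  densities 15/30/45/60 (cells R = 10 px, halo 3 px), searching
  r_small ∈ [2,8], r_large ∈ [8,20];
* noise-filter transfer: per replicate, train on three 400² scenes and
  score two held-out scenes, ten replicates;
* growth recovery: doubling 24 h, imaged 48–96 h, 2 replicates × 11
  fields of 360², averaged over five independent experiments (a single
  run carries several percent of Poisson sampling noise);
* ΔC trend over 1000 Monte-Carlo count series;
* bit-level determinism of the full pipeline under a fixed seed.

## Known limitations

* Counts are only as good as the segmentation regime: near confluence,
  touching cells merge and the count biases low; the method is intended
  for subconfluent monolayers.
* The Otsu threshold needs both classes present; a nearly empty field
  (or a blank one) is unreliable territory, and blank fields are reported
  as zero by convention.
* Parameters and the noise model are apparatus- and cell-line-specific;
  both must be re-derived when anything in the imaging chain changes.
* The nuclei recipe is empirical and expects a clean fluorescence
  background; noisy channels need manual mask review.
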