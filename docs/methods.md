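# Methods

## The measurement model

A colony-array screen plates every strain of an arrayed library in
quadruplicate on 1536-position plates and photographs the plates under
fixed acquisition settings. Two quantities are read per colony:

* **size** — the number of pixels assigned to the colony, a fitness proxy;
* **yellowness** — the mean of `sqrt(S · V)` (HSV saturation × value,
  geometric mean) over the colony's retained pixels. Under the fixed-hue
  assumption (a colony can only be a variant of yellow), `sqrt(S·V)` is a
  monotone proxy for pigment concentration that is insensitive to hue and
  bounded in [0, 1].

Segmentation is deliberately simple because the grid is known: global Otsu
thresholding on grayscale separates colonies from the darker background,
and each foreground pixel is assigned to the nearest grid-cell center,
capped at one cell pitch so an overgrown colony cannot annex a neighbor's
cell. The **pixel filter** retains the brighter half of each colony's
pixels (configurable quantile) before averaging yellowness; this removes
dim rim pixels and background bleed. Size is the unfiltered mask count —
the filter choice affects color, not area. Both the filter quantile and the
foreground threshold are configurable; the defaults are the package's own
interpretive choices where the procedure is otherwise underdetermined.

## Spatial correction and normalization

Colony size and color in high-density arrays are inflated near plate
borders. Two mechanisms address this:

1. **Position randomization** (at the layout level): each of the four
   replicate arrays of a library plate is pinned to a *different* screening
   plate, with the 2×2 interleave offset rotated by a seeded 4×4 Latin
   square, so plate- and neighbor-effects are decorrelated across
   replicates. Row/column positions within an array are never altered, so
   edge effects remain systematic.
2. **Edge correction** (per plate): for each frame ring r (ring 0
   outermost, default `n_frames = 2` rings), every value in the ring is
   multiplied by `median(center) / median(ring r)`. The correction is
   multiplicative — it preserves non-negativity and makes the operation
   idempotent — and applied independently to yellowness and size. Rings
   without valid colonies, or with a zero median, are left uncorrected with
   a logged warning.

Each screen is then z-normalized over **all** of its non-missing colonies
(plates pooled, sample sd with n−1), independently for yellowness and size.
The state machine raw → edge_corrected → normalized enforces the order;
renormalizing a normalized screen is the identity.

## Replicate filtering and gene scores

After derandomization each gene has up to 4 replicates per screen (16 when
four screens are pooled). Outliers within a gene's replicate set are
removed with the two-sided single-outlier **Grubbs test**
(`G = max|x−x̄|/s`, critical value `((n−1)/√n)·√(t²/(n−2+t²))` with
`t = t_{1−α/(2n), n−2}`), applied **iteratively** (remove, retest) because
pooled sets reach n = 16; default α = 0.05. The test is skipped for n < 3
or zero variance. The filter runs on the yellowness z-scores; a flagged
replicate is dropped for both metrics so the two gene scores always
average the same colonies. Genes with fewer than 3 surviving replicates
are dropped. The gene score is the plain mean of surviving z-scores.

Hit groups are threshold-based, not test-based: yellow above +1.2 screen
SD, white below −1.2. The **cyan** sub-group (high yellowness with little
or no fitness penalty) has no canonical numeric definition; the default
rule — `mean_yellow > 1.2` and `mean_size > 0` — is configurable, and cyan
is always reported alongside the yellow/white call, never instead of it.

Cross-screen reproducibility uses Pearson correlation on the common genes
and an upper-tail hypergeometric test on the overlap of the two screens'
top-k (or bottom-k) lists, with M = genes scored in both screens and ties
at the list boundary broken lexicographically (and logged).

## Enrichment and the term graph

Over-representation of a hit group within the scored-gene population is a
one-sided hypergeometric test per annotation term, BH-corrected across all
tested terms, with enrichment at q < 0.05. The population is the set of
genes that survived scoring (not the whole library), since the hit group is
itself a subset of the scored genes; a full-library population is a one-line
switch. Annotations are used exactly as given — genes are **not**
propagated to ancestor terms; the optional acyclic parent mapping is
consulted only when coloring nodes (first keyword matching the term's own
description, then breadth-first through ancestors, else "other"). Node size
is `s_min + s_scale·(−log10 q)` (defaults 10 and 5 display units) and edge
opacity is `shared/max_shared` — both purely presentational stand-ins for
qualitative drawing rules, and both configurable.

## The synthetic generator

`crispa.synthgen` emulates the statistical structure the analysis assumes,
not the optics of a real imager:

* **Effects**: a three-part mixture per gene — 90% bulk N(0, 0.3) on the
  pigment z scale, 5% yellow tail planted at +3, 5% white tail at −3
  (counts and magnitudes configurable; planted values are echoed exactly
  into the truth table). Yellow-tail genes carry a mean fitness penalty of
  −1.5 (sd 0.3); white-tail fitness is broad, N(0, 1).
* **Color model**: fixed yellow hue; saturation = logistic(pigment), value
  0.9; quantized to 8-bit RGB. The quantization is part of the model —
  `colony_sv()`/`planted_yellowness()` expose the exact rendered values, to
  which noise-free scoring recovery is exact (the continuous closed form
  agrees within ~1e−3 at mid saturations, but 8-bit RGB cannot represent
  arbitrary saturations better than ~1/255).
* **Size model**: disc area `π r0² · exp(0.15·(fitness + noise)) ·
  plate_bias · edge_bias(ring)`, radius clipped at half the cell pitch
  (clips recorded).
* **Nuisance structure**: per-plate lognormal bias (σ = 0.05) and a 1.25×
  multiplicative bias on the two outer rings, both applied to saturation
  (capped at 1) and area; 1% missing colonies; 1% contaminated colonies
  mixing in white-cell pixels at a Beta(1, 9) fraction.
* **Noise**: per-colony Gaussian noise (sd 0.3, equal to the bulk effect
  sd) added to pigment and fitness before rendering.

Everything is seeded; per-stage and per-plate sub-seeds are derived by
stable hashing so identical seeds give byte-identical layouts, images and
TSV outputs.

With these defaults the pooled four-screen study keeps a median of 16 of
the 16 possible replicates per gene (the ~1% missing rate plus Grubbs
removals rarely touch more than one replicate of the same gene); real
screens report medians nearer 15 because library strains also fail for
biological reasons the generator does not model.

### What passing tests do and do not show

The synthetic study demonstrates that the pipeline recovers planted effects
through the full image path — rendering, segmentation, scoring, correction,
pooling — under the stated noise and bias structure, and that independently
noised screens of the same truth reproduce each other (Pearson ≈ 0.95 at
these settings; real repeat screens report ≈ 0.77, because biological
replicate variation far exceeds the generator's measurement noise). It does
not validate behavior under non-uniform lighting, irregular colony
morphology, agar artifacts beyond a single multiplicative plate factor, or
camera noise — all deliberately out of scope for the renderer.

## Numerical and design choices

* Problem sizes: tests and the acceptance script use a 384-gene library
  across four screens (sixteen 1536-format plates at 16 px cell pitch) —
  one library plate's worth of genes, which exercises every code path
  (padding plates, Latin-square rotation, ring statistics) at a size
  comfortable for routine re-runs.
* Grubbs α = 0.05 two-sided, iterative with an n = 3 floor.
* Hit-list ranking ties broken lexicographically by gene id, logged.
* Edge correction: ratio-of-medians per ring (not pooled over the outer
  zone; a pooled mode is available), two rings by default.
* Degenerate inputs: constant screens raise on normalization; empty masks
  yield size 0 + missing flag; Otsu is skipped on featureless images
  (no foreground); zero-median rings are left uncorrected.
* Floats in TSV outputs are written at 6 significant digits; determinism is
  asserted at the checksum level.

## Known limitations

* The renderer's colonies are uniform discs; mask-shape statistics beyond
  pixel count are meaningless on synthetic data.
* Grubbs assumes approximate normality of replicate sets; with n = 4 its
  power is limited and two same-side outliers can mask each other.
* The hypergeometric overlap test treats hit lists as simple random draws,
  ignoring the correlation structure of gene scores; its p-values are
  comparative, not calibrated error rates.
* Enrichment uses annotations as given; without ancestor propagation,
  sparse specific terms can fall below detectable counts.
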