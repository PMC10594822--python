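# Methods

This note records the models, conventions and design choices behind
`neuromorph`, in the spirit of a methods section: what is computed, under
which assumptions, and where the open choices were made.

## Segmentation

Global histogram thresholding assumes a roughly bimodal intensity
distribution — cells against background — which holds for idealized or
well-contrasted phase-contrast frames. Six standard algorithms are
provided (`otsu`, `mean`, `isodata`, `triangle`, `li`, `yen`); they are
interchangeable options rather than competing contributions, and `otsu` is
the default. Low-contrast cultures should be segmented externally (e.g. a
trainable pixel classifier) and fed in as binary masks via the
pre-segmented path, which skips thresholding and, by default, the
watershed.

Pinned conventions:

* Object polarity is always explicit. `bright` foreground is strictly
  `intensity > T`; `dark` is the exact complement (`<= T`). The strict
  inequality fixes tie behavior once and for all.
* The returned `T` always leaves both classes non-empty
  (`min <= T < max` over the image's intensities).
* 16-bit images are histogrammed at native resolution (65 536 bins); no
  rescaling, hence no quantization drift.
* Otsu is evaluated in exact integer arithmetic: the between-class
  variance `w0 w1 (mu0 - mu1)^2` is, up to a constant factor, the integer
  ratio `(S0*N - S*N0)^2 / (N0*(N - N0))`, and candidates are compared by
  cross-multiplied Python integers. The argmax is therefore exact and ties
  resolve deterministically to the lowest threshold. `isodata` iterates
  the Ridler–Calvard fixed point `T = (mean(<=T) + mean(>T))/2` to within
  half an intensity unit; `triangle`, `li` and `yen` delegate to
  scikit-image and are clamped into the valid interval.

## Watershed

The binary watershed splits touching objects along valleys of the
Euclidean distance transform (EDT). Seeds are local maxima of the EDT
(minimum peak distance 2 px), merged within a 2 px radius to suppress
plateau oversegmentation; basins are flooded on the negated EDT
(8-connected flood) constrained to the mask. The separating line is carved
explicitly: every pixel whose 8-neighborhood contains a basin with a
smaller label is removed, which yields a one-pixel line, guarantees the
remaining sides are never 8-adjacent, and is deterministic.

Carving a line lowers the EDT next to it, which can expose new maxima on
thin structures; a single pass is therefore not idempotent in general. The
implementation iterates the carve to a fixpoint (pixel removal is
monotone, so this terminates quickly — two passes on typical scenes),
making `watershed_split` idempotent by construction. Consequences kept
deliberately:

* objects whose EDT has one (merged) maximum are returned unchanged;
* the output is a pixelwise subset of the input, and the pixel deficit
  equals the separating-line count;
* thin neurites attached to a soma are carved off at the junction (the
  soma's central maximum and the neurite's ridge plateau are distinct
  seeds) and may be further fragmented along their length. The pipeline's
  neurite pass is designed around this (below).

## Two-pass classification

Thresholding an idealized culture image yields soma+neurite blobs as
single connected components, which neither a cell-body nor a neurite
filter can accept whole. The pipeline therefore runs two passes:

1. **Cell-body pass** on the watershed-split mask: somata emerge as
   compact components and pass the area/circularity windows; carved
   neurite fragments fail them and are recorded as rejected.
2. **Neurite pass** on the *residual* mask: original foreground minus the
   accepted cell-body pixels. Because the residual is taken from the
   un-carved mask, watershed lines through neurites are restored and each
   neurite is again one component, measured at full length. The watershed
   line at the soma junction remains part of the neurite component, which
   keeps the neurite within one pixel of its soma — exactly what the
   attachment operator needs.

Classification is a pure filter: descriptors are never modified, order is
preserved, and every rejected record carries the first window it failed
(`area`, `circularity` or `aspect_ratio`), so filter behavior is fully
auditable from the per-motif CSVs.

The per-cell-type windows ship as editable presets. The `synthetic` preset
is exact for the generator's geometry and is the tested default; the named
cell-line presets are plausible starting points only — pixel-area bounds
depend on optics and binning, so any real study must calibrate them
against a manual consensus count (the tool deliberately performs no
uncertainty assessment).

## Shape descriptors

* **Area**: pixel count.
* **Perimeter**: length of the closed Moore-neighbor chain through the
  centers of the outer boundary pixels, axis steps 1 and diagonal steps
  √2; a single pixel is 4 by convention, and a 10×10 square measures
  exactly 36. Inner boundaries of holes are not traced (holes are rare and
  small in thresholded cultures).
* **Circularity**: 4πA/P², capped at 1.0. Under the chain convention the
  circularity of a digitized disk does not tend to 1: the chain length of
  a digitized circle exceeds 2πr by the mean digital-straightness factor
  (4/π)(2√2−2) ≈ 1.0548, so disk circularity converges to ≈ 0.90 from
  above as the radius grows. The classification presets account for this
  calibration (cell-body windows reach down to ≈ 0.55) rather than
  adopting a corrected perimeter estimator, which would break the exact
  chain values pinned above. The chain also carries a fixed ≈ 1 px/side
  finite-size bias, so circularity comparisons across scales are only
  meaningful for objects tens of pixels across.
* **Axes / aspect ratio**: major and minor axis of the moments-equivalent
  ellipse (rotation invariant — required for an orientation-fair
  aspect-ratio filter); each axis floored at 1 px so one-pixel-wide bars
  get a finite, large ratio.
* **Length**: maximum Feret diameter — the largest distance between
  boundary-pixel centers, computed on the convex hull. For curved
  neurites the alternative skeleton length is the longest geodesic through
  the morphological skeleton (unit/√2 edge weights, double-sweep shortest
  paths; exact on tree-shaped skeletons). Feret underestimates arc length
  with curvature; the skeleton loses roughly half a width at each end.
  Measured on the generator's scenes, both stay well inside 10% (straight)
  and 15% (curved) mean absolute relative error.

## Attachment points

Attachment points — the loci where neurites meet cell bodies, i.e. neurite
trunks and terminal ends collectively — are computed as: 1-px inner
outlines of both classes; 3×3 Sobel pair over the neurite outlines in
integer arithmetic, keeping every nonzero-gradient pixel (the edge band
hugging the outline); 8-connected dilation of both operands by
`dilation_px` (default 1); pixelwise AND; one point per 8-connected
overlap component. The AND of binary masks is the arithmetic overlap of
inverted 0/255 images without the bit-depth bookkeeping. The 1 px dilation
is an explicit tolerance: a soma outline and a neurite edge band can be
8-adjacent without sharing a pixel (the watershed line sits between
them). Overlap components, not pixels, are counted: one junction produces
one multi-pixel blob. Trunks and terminal ends are not distinguished in
the output. With the default tolerance, the operator's spatial reach is
three pixels; structures farther from every soma outline can never
register.

## Summaries and time courses

Per image: counts of accepted cell bodies, neurites and attachment points,
and arithmetic means of the per-motif descriptors. A metric whose class is
empty is *absent* (empty CSV cell), never zero — zeros would bias
time-course means. Aggregation is two-stage by default, matching a design
of several imaged areas per well: area summaries are averaged within each
well, then mean and sample standard deviation (n−1 denominator, reported
only for n ≥ 2) are computed over wells per (condition, time, metric);
`group_by="area"` pools every image as its own replicate instead. Time
points come verbatim from the manifest — filenames are never parsed.
Inputs are canonically ordered before any floating-point accumulation, so
results are invariant to input permutation, and the whole pipeline is
deterministic: identical config and inputs give byte-identical CSV trees.

## Synthetic scenes

The generator emulates the features the pipeline must discriminate:
somata as disks (radius 8–15 px by default), neurites as 1–3 px wide
Bresenham polylines grown from the soma boundary outward with bounded
per-step heading changes (`curvature`, default 0.15 rad per ~3 px step;
0 gives straight bars), detached "free" neurites, round debris specks
sized below the cell-body area minimum, two intensity levels (200/30 on
8-bit by default, either polarity) and additive Gaussian noise (sd 3 by
default; count-recovery tests use sd 5, ≈ 3% of contrast). Placement is
rejection sampling with gaps of at least 4 px between somata; any object
other than a neurite's own parent soma keeps a clearance larger than the
attachment operator's reach, so ground-truth junction counts are exact by
construction. A neurite's true length is its polyline arc length. All
randomness flows from one seed: equal specs give bitwise-identical images.
Infeasible packings fail loudly with a capacity error after bounded
retries.

Deliberately **not** modeled: phase-contrast halos, intensity gradients,
fasciculated neurite bundles, cell-density extremes, out-of-focus blur.
Passing on these scenes therefore demonstrates the correctness of the
operators and the pipeline's bookkeeping, not robustness to difficult real
imagery — on real data, threshold choice, pre-segmentation quality and
criteria calibration dominate.

## Problem sizes

The test-suite and the acceptance script size their simulations as: 200
random 16×16 images for the threshold oracle; 20 scenes of 10–40 somata
(512×512) for count recovery; 20 touching pairs (radius 10, center
distance 14–18 px); ≥ 50 straight and 42 curved neurites (640×640) for
length accuracy; 20 junction scenes with 1–8 junctions; a 12-scene fixture
corpus run twice for determinism. These sizes give exact-recovery
statistics with comfortable margin while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* Population-level morphometry only: no per-cell neurite assignment, no
  branch counting or Sholl analysis, no tracking across frames.
* The aspect-ratio filter is a global threshold; strongly curved neurites
  can have moderate ellipse aspect ratios and thresholds above ~3 may
  reject them.
* Neurite-pass measurements assume neurites do not cross each other;
  crossing structures merge into one motif and are measured jointly
  (the length of the identified oblong object, regardless of topology).
* Multi-page TIFFs contribute only their first plane (with a warning);
  z-stacks and multi-channel fluorescence are out of scope.
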