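# Methods

## The analysis problem

The porcine glottis carries two vocal folds per side: a cranial fold
(CraF), which lacks a vocal muscle and whose connective tissue is roughly
twice as deep, and a caudal fold (CauF), topographically similar to the
human vocal fold.  The mechanical layering of the folds' lamina propria —
a dense fibro-elastic subepithelial band (SEL, on the order of 20 um), a
loose superficial layer (SL), and elastic- or collagen-dominated
intermediate and deep layers (IL, DL) — underlies the phoniatric
body-cover model, and it changes with age.  `foldstrat` implements the
semi-automated histomorphometric workflow used to quantify that
stratigraphy in two stain renderings of coronal sections: collagen
structures in a Masson's-trichrome-like image (green), elastic fibres in a
resorcin-fuchsin-like image (dark violet).

Because no real slide images are distributed, the package includes a
first-class synthetic section generator with pixel-exact ground truth;
every downstream stage is developed and tested against it.

## Pipeline

1. **Object definition** (`segmentation`).  Pixels are classified in HSV
   space by stain-specific colour rules (hue interval — possibly wrapping
   the hue circle — plus saturation and value bounds).  Thresholds are
   configuration, defaulting to boxes matched to the rendering palette
   with margin for its +/-10% channel jitter.  The green collagen rule
   intentionally rejects the reddish anomalous trichrome reaction of the
   aged cranial fold's superficial zones, reproducing the false-negative
   collagen readings that anomaly causes in practice (near 0% measured
   against >=10% true content).
2. **ROI sampling** (`roi`).  The fold midline is the per-depth-row ridge
   of the Euclidean distance transform of the fold mask (the image border
   counts as boundary), clipped to start at the epithelium boundary and
   extended to the exact depth extent; it is monotone in depth.  Paired
   circular ROIs (35 um for measurement, 70 um for scoring) are placed at
   stations spaced one diameter apart, the two circles flanking the
   midline at one radius's perpendicular offset (configurable).  Pairs
   that would leave the fold or touch the epithelium are dropped and
   surface downstream as missing values, as happens in small young folds.
   A pixel belongs to an ROI iff its centre lies strictly inside the
   circle.
3. **Stratigraphy** (`stratigraphy`).  Depth is standardised into
   proportional subunits — 10 equal bins of the CauF's own depth, 20 of
   the CraF's — with half-open bins `[(k-1)/n, k/n)`.  A station's pair
   value is the mean of its two ROI area fractions; a subunit's value the
   mean of its stations; unsampled subunits stay missing (never imputed).
   Zones group subunits for statistics: CauF Z1={1}, Z2-Z4 consecutive
   triples; CraF Z1={1}, Z2-Z7 triples, Z8={20}.
4. **Scoring** (`scoring`).  Collagen objects in 70-um ROIs are counted in
   three diameter categories (2-4, >4-10, >10 um; boundary diameters fall
   to the lower category) and mapped to scores 0-3 by the category
   thresholds given in the module docstring.  An object's diameter is
   twice the median distance-transform value along its skeleton — an
   automated, reproducible proxy for an observer's visual judgement; the
   repeat-run equality of this deterministic pass stands in for
   intra-observer reliability.  An object counts toward an ROI when at
   least half of its skeleton lies inside (deterministic border
   tie-break).  The two ROIs of a pair have their per-category counts
   averaged (rounded) before scoring.
5. **Demarcation statistics** (`stats`).  Within an age group, three
   Wilcoxon signed-rank bars (neighbouring subunits; 2-subunit blocks,
   with subunit 1 isolated when significantly higher than subunit 2;
   consecutive zones) are summarised per subunit boundary: *distinct* when
   every bar testing the boundary is significant, *continuous* when bars
   disagree, *none* otherwise.  Between age groups, zones are compared
   with the tie-corrected Kruskal-Wallis test (chi-square, 1 df).  All
   tests are two-sided at alpha = 0.05 on raw p-values; no multiplicity
   adjustment is applied (comparison-wise error control is accepted by
   design).  A one-sample Kolmogorov-Smirnov test against a
   moment-matched normal is provided to document why nonparametric tests
   are used.

### Exact signed-rank p-values

Zero differences are dropped, absolute differences are midranked, and for
up to 25 informative pairs the null distribution of W+ is enumerated
exactly by dynamic programming over doubled ranks (two-sided p =
2 x min tail, capped at 1); beyond that a tie-corrected normal
approximation is used.  With n = 6 pairs the smallest attainable
two-sided p is 2/64 = 0.03125: significance at 0.05 requires all six
animals concordant, which bounds the attainable type-I level at 0.03125.

## The synthetic generator

A section is a rectangle: an epithelial band (default 50 um) over a
lamina propria of 700 um (CauF) or 1400 um (CraF), at 0.5 um/pixel
(resolving the 2-um minimum fibre diameter) and 240 um width.  Each
proportional subunit band carries a composition: collagen and elastic
area fractions, a weight mix over the three collagen diameter categories,
an elastic clump share, and the trichrome rendering (green/reddish).

Fibres are curvilinear strokes — random walks of bounded curvature
(heading increment U(-0.25, 0.25) per step), 10-25 um long, stamped as
overlapping discs of the sampled diameter — clipped to their band.  Start
positions are padded beyond the band and the image edges so clipping does
not deplete density near any border.  Stamping is budget-limited: a band
stops adding pixels once its target fraction is reached, so rendered
fractions match requested ones to within one disc stamp (well under the
2-percentage-point contract at default geometry).  Aged elastic material
is partly rendered as 5-10 um filled discs ("clumps"); the clump share
defaults to 0.2, reflecting that clumps are focal aggregations of a
minority of the elastic material.  Fibroblast nuclei are a neutral,
desaturated speckle texture (denser in young sections) that no colour
rule accepts; their density is cosmetic only.

Colour anchors (collagen green, anomalous reddish, elastic violet, pale
background, pink epithelium) are fixed RGB values with independent
+/-10% per-channel jitter.  All randomness flows through one
`numpy.random.Generator` seeded per section; identical (spec, zones,
seed) give bit-identical images.

Ground truth is computed by direct pixel counting of the pre-rendering
fibre masks per subunit band, plus per-band object counts by diameter
category.

### Default depth profiles

`default_profiles` encodes the study conditions per fold/age: the zone-1
elastic fractions equal the observed group means (CauF 9.72%/25.62%,
CraF 5.55%/31.51% for young/old), and the remaining subunits follow the
qualitative stratigraphy — subepithelial collagen peak and a deep
caudal-fold maximum in subunit 10; an elastic-rich intermediate layer in
zones 3-4 of the young cranial fold; a graded, demarcation-free aged
caudal collagen profile; reddish rendering of the aged cranial fold's
zones 1-3.

### Profile-level simulator

`simulate_profiles` is a cheap statistical counterpart of the image
pipeline used for the large-replicate property studies (type-I error,
demarcation recovery): per animal, the mean profile is scaled by a
lognormal factor (sigma 0.15, between-animal variation) plus independent
per-subunit noise (2 percentage points), truncated at zero.  It does not
model spatial texture, ROI geometry or segmentation error — those are
exercised by the image pipeline itself at smaller replicate counts.

## What the synthetic data does not show

The generator emulates area fractions, object diameters and the staining
anomaly, not real histology: no staining chemistry or fixation artefacts,
no 3-D structure, no anisotropic fibre orientation fields, no
out-of-focus blur, and rectangular fold geometry (the midline code
handles curved masks, but the generator does not produce them).  Passing
recovery tests therefore demonstrates the pipeline's correctness under
known ground truth, not segmentation accuracy on real slides, where
colour thresholds would need calibration (they are configuration for
exactly that reason).

## Numerical choices and problem sizes

* Pixel membership, bin edges and category boundaries all use half-open
  conventions stated at their definition sites; tie-breaks are
  deterministic.
* High band densities (>= ~50%) make strokes merge; object counting and
  diameter estimation are then conservative (fewer, thicker objects) —
  a known limitation shared with any connected-component approach.
* Recovery experiments use n = 6 sections per group, matching the group
  size of the study design; statistical property suites use 200-1000
  profile-level replicates at n = 6 animals.  These sizes are the
  package's standard experiment configuration.
* Degenerate inputs: empty or disconnected fold masks, midlines shorter
  than one ROI, all-tied samples and all-missing pairs are rejected or
  flagged untestable rather than silently processed.

## Open design points resolved

* "Pairs" of ROIs straddle the midline symmetrically at one radius's
  offset; the offset factor is configurable because the original layout
  is not specified beyond paired circles along a midline.
* The CraF's 20 proportional bins are bins of the CraF's own depth; with
  the 2:1 depth pairing this is numerically identical to sizing bins at
  10% of the CauF depth.
* The bar-2 conditional isolation of subunit 1 reads the bar-1 result for
  (1 vs 2) rather than re-testing, keeping one evidence source; with an
  odd number of remaining subunits the final block holds one subunit.
* Whether to report exact or asymptotic Wilcoxon p-values at n = 6 is
  resolved in favour of exact by default; the asymptotic path remains
  available (`method="approx"`).
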