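# Methods

## Scope and model

The package quantifies the tubulointerstitial compartment of renal cortex
from per-structure segmentation masks. It does not segment tissue itself:
the inputs are binary rasters produced by independent per-class models
(one-vs-all), which may disagree, and an optional RGB render of the
stained section. The analysis chain is

masks → compilation → morphometry → z-scores → PCA indices → K-means
phenotypes → clinical associations.

### Mask compilation

Independent per-class masks are reconciled in a fixed order. Connected
components (8-connectivity, configurable) below a per-class minimum area
are dropped first; the defaults mirror the object-size floors used when
the structures are segmented: glomeruli 500 μm², PTC 40 μm², tubules
200 μm², arteries/veins and cortex/medulla 1000 μm². The comparison is
inclusive (an object of exactly the minimum area is retained) — strictness
is not dictated by anything upstream, and the inclusive reading makes the
threshold a property of the retained set.

Pairwise intersection areas between all class masks are reported for QA
before any resolution. The dominant real-world error — capillaries
"detected" inside glomeruli — is corrected at object level: a PTC
component with more than 50% of its area inside the glomerular mask is
removed entirely rather than clipped, because a mostly-intraglomerular
detection is a false object, not a mis-outlined true one. The threshold
and a pixel-clipping alternative are configurable. Remaining contested
pixels go to the higher-priority class; the default total order is
glomeruli > arteries/veins > tubules > PTC. Only the relative priority of
glomeruli over the rest is externally constrained; the rest of the order
is a package choice and configurable. Pixels claimed by both cortex and
medulla count as cortex (conservative inclusion); medulla and
extra-cortical pixels are excluded from every downstream area.

### Morphometry

After removing glomeruli, tubules, PTC and vessels from the cortex, the
residual tissue is the interstitium. Sub-compartments are quantified
either from ground-truth labels (label mode, used with the synthetic
generator) or from the RGB render by nearest-reference-color
classification (color mode), with nuclei counted as connected components
of at least 4 px to suppress single-pixel color noise.

CTA is defined **additively** as the sum of the five compartment areas.
An alternative subtractive definition (cortex − glomeruli − vessels) is
computed only as a QA cross-check: the additive identity is authoritative
because it guarantees that the five CTA-relative percentages partition
100% exactly, which downstream tests assert at machine precision. Veins
are grouped with arteries in the subtractive form.

`tSize` is the mean area per tubule instance in μm² and `tCellDen` the
number of tubular nuclei per mm² of tubular area. Published variants of
both formulas written as ×100 ratios are inconsistent with their stated
definitions and with the magnitudes these indicators are reported at
(thousands of μm², thousands per mm²); the package implements the
definitions and exposes the ×100 forms behind a
`compat_printed_formulas` flag for cross-tool comparison. Unit
conversions use 1 mm² = 10⁶ μm²; CTA is reported in mm² to 3 decimals.

Biopsy adequacy requires ≥ 5 glomeruli and ≥ 4 mm² CTA (≥ 3 mm² in the
external-section preset). Excluded cases carry explicit reasons.

### Indices and phenotypes

The seven indicators are z-scored against the **training** cohort
(ddof = 1) and the eigenvectors of their correlation matrix define the
components; the retention rule is Kaiser (eigenvalue > 1), overridable to
a fixed count. At least two components are always kept so both indices
exist; if the rule alone keeps fewer, the model carries an explicit
warning. Orientation is fixed by convention: fibrillary collagen loads
positively on component 1 (**Chronicity Index**) and tubular cell
fraction positively on component 2 (**Inverted Acute Index**). Test
cohorts are standardized with the training scaler and projected through
the training loadings — never refitted — so scores are comparable across
cohorts; projecting the training set reproduces its fit scores exactly.

K-means runs in the frozen z-space with ≥ 10 restarts and a fixed seed;
K is selected by mean silhouette over K ∈ {2..8} or pinned (typically 4).
Because raw K-means cluster numbers are arbitrary, centroids receive
deterministic semantic labels: highest fibrillary collagen →
`chronic_severe`; of the rest, highest tubular lumen → `acute`; then
highest tCell% + tSize → `intact`; remainder → `intermediate`. Cluster
profiles are reported on the un-rescaled z-scale; within-cluster feature
correlations default to Pearson (Spearman available) and clusters with
fewer than 3 members yield an explicit absence rather than a matrix.

### Clinical associations

Group comparisons of an index across an ordinal grade use Kruskal–Wallis
with Dunn's pairwise rank tests (tie-corrected z from rank sums);
normality is reported per group via Shapiro–Wilk. The Dunn multiplicity
adjustment defaults to Holm (none/Bonferroni/Benjamini–Hochberg
selectable) — the adjustment method is a package choice. The tertile
analysis places cases into thirds of the Inverted-Acute score by
percentile (33.3/66.7) with stable rank-based tie handling; an
equal-range-thirds mode is available since "tertile of the score range"
admits both readings. Frequencies are the distribution of rejection
cases across tertiles (summing to 100%), with a chi-square test on the
tertile × rejection table.

Reciprocal serum creatinine rSC = 1/SC (dL/mg) is taken at the biopsy
(first measurement); its slope rSCs is ordinary least squares of 1/SC on
time, in months after biopsy (the time unit is a package choice, recorded
in output metadata). Fewer than 4 measurements yield an explicit
"insufficient follow-up" state and exclusion from the renal-function PCA.
That PCA z-scores {Inverted Acute, Chronicity, rSC, rSCs} on complete
cases (≥ 8 required), keeps two components, and reports the
orientation-invariant sign structure: acute morphology pairs with low rSC
at biopsy but with relatively better later slope (recovery), chronic
damage with steeper functional decline. Creatinine is mg/dL; a μmol/L
helper converts by 88.42.

## Synthetic cohort generator

No generative model for this tissue exists upstream; every distribution
below is a package design choice, chosen once to be histologically
plausible, and the tests measure the pipeline *under these conditions*.

Geometry is analytic and rasterized on an integer grid at a configurable
pixel size (default 0.5 μm/px, the resolution of a 20× whole-slide scan).
Tubules are lumen discs wrapped in an epithelial annulus with separated
nuclear dots, packed on a jittered hexagonal lattice; glomeruli and
arteries are large discs placed by rejection sampling (infeasible packing
raises an error rather than silently truncating); PTC are small blobs
squeezed into the interstitium, each committed only if its clipped area
stays above the downstream minimum-object floor. The interstitium is
split into fibrillary collagen vs non-fibrillary matrix by thresholding a
Gaussian-smoothed noise field at the quantile matching the target
collagen share — a spatially patchy two-phase field with exact fraction
control.

Two latent factors drive each case:

* chronicity *c* ∈ [0,1]: collagen share of interstitium 0.30 + 0.60c,
  tubule radius ×(1 − 0.40c), interstitial widening, PTC keep-probability
  ×(1 − 0.55c), nuclear density ×(1 + 0.5c);
* acuity *a* ∈ [0,1]: lumen-radius fraction 0.30 + 0.40a (epithelial
  flattening), interstitial widening with reduced collagen share
  (−0.15a, edema). A per-case flattening jitter (SD 0.03, shared across a
  case's tubules) reproduces the within-phenotype lumen/cell trade-off.

Ground truth is the generator's own sub-compartment raster; truth areas
are pixel counts on it, so they sum exactly to the generated CTA and
label-mode extraction can be checked for exact equality. Analytic disc
areas would differ from any rasterization by O(perimeter) and are not
used as truth. Clinical metadata couple to the latents: Banff ci ~
Binomial(3, 0.08 + 0.80c); acute rejection ~ Bernoulli(0.05 + 0.75a);
reciprocal creatinine starts near 1.0 dL/mg, declines with c over a 5–8
point, 0–24 month series, and in acute cases dips at biopsy with partial
recovery — which yields the expected sign structure in the renal-function
PCA. A configurable fraction of PTC objects is deliberately misplaced
inside glomeruli (mask only, never ground truth) to exercise the overlap
QA; at rate 1 every capillary is an error and the truth PTC area is zero.

Archetype cohorts plant four phenotypes at (c,a) = intact (0.08, 0.12),
intermediate (0.48, 0.28), chronic-severe (0.88, 0.18), acute
(0.15, 0.85), SD 0.045, with balanced group sizes in shuffled order. The
intermediate center carries mildly elevated acuity so the four phenotypes
are not collinear in feature space, matching its "average values of all
indicators" character.

What the generator does **not** emulate: nuclear texture and chromatin,
scanner artifacts and stain variation, irregular (non-disc) structure
shapes, interstitial inflammatory infiltrates, intra-biopsy heterogeneity,
and real segmentation-model error beyond the injected PTC class. Passing
tests therefore demonstrate correctness of the *computational pipeline*
under a controlled tissue model — not segmentation accuracy or clinical
performance on real slides.

## Problem sizes and numerics

Cohort-scale analyses run on a reduced field (600×600 μm at 2 μm/px, two
glomeruli) chosen because the five percentage features are scale-free —
the package's scale-invariance tests verify this — so cohort statistics
are unaffected while a 680-case cohort generates in well under a minute.
The 2.5×2.5 mm default field remains for single-case work and is the size
at which the 4 mm² adequacy criterion is meaningful; on the reduced field
the analysis drivers run with adequacy filtering off and say so.

Determinism: one integer seed drives everything; the same parameters and
seed give bit-identical rasters and metadata. K-means uses a fixed seed
with 10 restarts; identical refits return identical centroids. Eigen
decompositions use symmetric solvers; component sign indeterminacy is
removed by the orientation conventions above. Degenerate inputs fail
loudly: zero CTA, constant features (named in the error), missing cortex
mask, k > n, fewer than 2 groups, empty creatinine series. Zero-tubule
cases flag tSize/tCellDen as undefined instead of fabricating values.

Nucleus placement keeps a separation of 2r + 3·(pixel size) and a rim
margin of 1.5 px so rasterized nuclei remain distinct 8-connected
components at coarse test resolutions; nucleus radius should be at least
~1.2× the pixel size for counting fidelity.

## Known limitations

* Only the seven headline indicators are implemented; the broader
  per-compartment feature family is out of scope.
* Semantic cluster labels are heuristics over centroid profiles; for
  K ≠ 4 the extra or missing centroids degrade to numbered
  `intermediate` labels.
* Color-mode quantification assumes a palette whose reference colors are
  separated by clearly more than twice the noise amplitude; it is exact
  at zero noise by construction and degrades gracefully, not robustly,
  beyond that.
* The clinical metadata model is a sign-structure emulator, not a
  calibrated epidemiological model; absolute effect sizes in the clinical
  analyses are not meaningful beyond their direction.
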