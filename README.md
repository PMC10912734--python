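# nephromorph

Quantification of **acute and chronic transformations of the renal
tubulointerstitium** from multi-class segmentation masks of kidney biopsy
tissue.

Renal allograft management relies on biopsy assessment of rejection and of
acute/chronic parenchymal damage, but conventional semiquantitative grading
(Banff scores) is poorly reproducible. This package implements a
computational alternative for the tubulointerstitial compartment: starting
from per-structure segmentation masks of a modified Picrosirius-red-stained
cortical section (cortex/medulla, glomeruli, tubules, peritubular
capillaries, arteries/veins), it

1. **compiles** the independent one-vs-all masks into one consistent
   labeled raster — overlap QA, priority resolution, per-class minimum-area
   filtering, and removal of peritubular capillaries (PTC) spuriously
   detected inside glomeruli;
2. **extracts morphometry**: the residual cortex after removing all
   structures is the interstitium, which is split into fibrillary collagen
   and non-fibrillary matrix; tubules are split into lumen, epithelial cell
   mass, and nuclei. The cortical tubulointerstitial area is the additive
   sum

   CTA = tubular lumen + tubular cell + PTC + fibrillary collagen + non-fibrillary matrix,

   and the seven indicators are the five CTA-relative fractions
   `tLumen%`, `tCell%`, `ptc%`, `iColl%`, `iMatrix%` (they sum to 100 by
   construction) plus mean tubule area `tSize` (μm²) and tubular nuclear
   density `tCellDen` (nuclei per mm² of tubular area). Biopsy adequacy
   criteria (≥ 5 glomeruli, ≥ 4 mm² CTA, or ≥ 3 mm² for small external
   sections) gate the analysis;
3. **derives two indices** by PCA of the z-scored indicators on a training
   cohort: the **Chronicity Index** (fibrillary collagen loads positively;
   tracks interstitial fibrosis with tubular atrophy) and the **Inverted
   Acute Index** (tubular cell fraction loads positively; *low* values mean
   acute tubular injury — dilated lumens, flattened epithelium, interstitial
   edema). Scaler and loadings are frozen on training and applied unchanged
   to test cohorts;
4. **phenotypes biopsies** by K-means in the frozen z-space (silhouette-
   selected K, or pinned), with deterministic semantic labels
   (intact / intermediate / chronic-severe / acute) from the centroid
   profiles, plus per-cluster radar profiles and within-cluster feature
   correlations;
5. **associates with clinical data**: Kruskal–Wallis + Dunn tests of the
   Chronicity Index across Banff ci grades, tertile analysis of the
   Inverted Acute Index against acute-rejection diagnoses, reciprocal serum
   creatinine rSC = 1/SC (dL/mg) and its follow-up slope rSCs (per month,
   ordinary least squares over ≥ 4 measurements), and a joint
   renal-function PCA of {Inverted Acute, Chronicity, rSC, rSCs}.

Because no public dataset ships masks of this kind, the package includes a
first-class **synthetic cohort generator**: virtual cortical fields with
analytic disc/annulus geometry, pixel-level ground truth, two latent
factors (chronicity *c*, acuity *a*) driving the histology, injectable
intra-glomerular PTC errors, and linked clinical metadata. Every stage of
the pipeline is validated end to end against this ground truth.

## Worked example

```python
from nephromorph import (
    generate_cohort, fast_params, run_pipeline, PipelineConfig,
)

cases = generate_cohort(420, design="continuous", seed=2026,
                        base_params=fast_params(),
                        splits={"training": 300/420, "internal_test": 70/420,
                                "external_test": 50/420})
report = run_pipeline(cases, PipelineConfig(sampling="none", k=4, seed=0))
print(report["index_model"].component_labels)
print(report["scores"].head())
```

Running the numbered drivers in `analysis/` over this cohort prints, among
other things:

```
retained components: ['ChronicityIndex', 'InvertedAcuteIndex'] (eigenvalues [3.51 2.78], 90% of variance)
      training: Spearman(Chronicity, c) = +0.97, Spearman(InvertedAcute, a) = -0.96
Chronicity Index vs Banff ci: Kruskal–Wallis H = 198.8, p = 7.48e-43
per-grade medians: {'0': -1.85, '1': -0.72, '2': 0.95, '3': 2.07}
acute-rejection distribution over Inverted-Acute tertiles (lower/middle/upper): 50.3/36.6/13.1 %
```

Reading: the Kaiser rule keeps exactly two components; the first recovers
the latent chronic-injury factor almost perfectly (rank correlation +0.97),
the second anti-tracks the acute factor (−0.96, the "inverted" convention);
the Chronicity Index rises monotonically across Banff ci fibrosis grades;
and acute-rejection cases concentrate in the lowest Inverted-Acute tertile.
`analysis/04_cluster_phenotypes.py` additionally recovers the four planted
tissue phenotypes (silhouette-selected K = 4, adjusted Rand index 1.00 on
the archetype cohort).

## Command line

```bash
nephromorph simulate --n 20 --design archetypes --seed 1 --outdir cohort/
nephromorph run --manifest cohort/manifest.yaml --outdir out/ --k 4
nephromorph extract --masks cohort/case_0000 --out features.json
```

## Layout

```
src/nephromorph/     library: synthetic, maskops, morphometry,
                     multivariate, clinical, pipeline, io, cli
analysis/01..05_*.py narrative drivers writing tables to results/
tests/               pytest suite incl. end-to-end acceptance checks
docs/methods.md      model, generator, and design notes
```
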