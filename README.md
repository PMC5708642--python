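# hevcells

Unsupervised segmentation of tissue compartments — epithelium versus
connective stroma — in haematoxylin-and-eosin (H&E) stained brightfield
microscopy images, for digital-pathology researchers who need
compartment maps without hand-annotated training data.

The pipeline:

1. **Stain separation.** RGB transmittance is unmixed through the
   Beer–Lambert model (`OD = −log((v + ε)/255)`, solved against the H&E
   absorbance basis) into haematoxylin, eosin and residual channels.
2. **Virtual cells.** The stained-tissue mask (Huang fuzzy threshold of
   `min(H, E)`) is partitioned by a marker-controlled watershed around
   nuclear seeds — regional minima of depth ≥ h in the haematoxylin
   channel (h-minima transform), cleaned by an opening by reconstruction
   with e erosions.  Each resulting *v-cell* encloses one nucleus.
3. **Features.** 63 descriptors per v-cell: 11 intensity statistics ×
   3 stain channels, 22 v-cell shape measures (circularity
   `4πA/P²`, roundness `4A/(π·feret²)`, solidity `A/A_hull`,
   sphericity `MinR/MaxR`, rectangularity `A/(feret·breadth)`, …) and
   8 nucleus shape measures (concavity `A_hull − A`, convexity
   `P_hull/P`, …).
4. **Consensus clustering.** A 31-member ensemble (k-means ×10, EM ×10,
   LVQ ×4, MDB ×1, agglomerative ×6; k = 2 throughout) is pruned to a
   moderate-diversity subset (mean pairwise Rand index within
   [D1, D2] = [0.5, 0.9]) and combined by either **evidence
   accumulation** (hierarchical clustering of the co-association matrix
   `M_ij = m_ij/Ċ`) or **majority voting** after aligning cluster labels
   across members by maximal Jaccard overlap of their rendered pixel
   sets.
5. **Evaluation.** Against a pixel gold standard: Rand index over
   v-cell pairs, pixel-wise precision/recall/F1 (epithelium positive)
   and the Jaccard index of the epithelium maps.

A synthetic-tissue generator (two compartments differing in nuclear
density/shape and dye uptake, with exact gold standards) makes the whole
pipeline testable end to end.

## Worked example

```python
from hevcells import (SyntheticSpec, generate_tissue_image,
                      PipelineConfig, run_pipeline)

spec = SyntheticSpec(rng_seed=3)               # 512x512 core, 2 compartments
rgb, gold, centres = generate_tissue_image(spec)
print(len(centres))                            # 227 planted nuclei

cfg = PipelineConfig(consensus_method="both", rng_seed=1)
result = run_pipeline(rgb, cfg, gold=gold)
print(result.vcells.n_cells)                   # 227 v-cells, one per nucleus
print(len(result.ensemble), len(result.selected))   # 31 31
print(round(result.evaluation["voting"].f1, 3))     # 0.978
print(round(result.evaluation["eac"].f1, 3))        # 0.978
```

The run partitions the core into 227 v-cells (one per planted nucleus),
clusters them with the full 31-member ensemble, and both consensus
functions recover the epithelium/stroma split with F1 ≈ 0.98 against the
generated gold standard.  `result.features` is the 227 × 63 feature
table; `hevcells.write_artefacts(result, outdir)` saves the label TIFFs,
feature/consensus CSVs, the rendered magenta/green compartment map and
the evaluation JSON.

The same workflow is available from the shell:

```sh
hevcells simulate --size 512 --seed 3 --out sim/
hevcells run sim/image.tif --gold sim/gold.png --seed 1 --out out/
```

plus per-stage subcommands (`segment`, `features`, `cluster`,
`consensus`, `evaluate`) that exchange label TIFFs and CSV tables, so
any stage can be re-run alone.

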