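# imcspatial

Single-cell spatial analysis for imaging mass cytometry (IMC) cohorts:
per-cell feature extraction from segmentation masks, PhenoGraph-style
phenotyping, and the **pairwise distance rank (PDR)** — a symmetric,
rank-based statistic of phenotype–phenotype co-localization in tissue.

IMC ablates stained tissue in 1 µm steps and reads ~35 metal-tagged
antibodies per pixel, yielding multiplexed images of ~700 × 700 µm regions
of interest (ROIs). After segmentation, each cell carries a position, an
area, and a mean intensity per marker. This package answers the questions a
tissue-immunology study asks of such data: *which phenotypes exist*
(data-driven clustering), *how abundant is each phenotype per ROI and
condition* (unpaired t-tests with Holm correction), and *which phenotypes
sit next to each other* (PDR, per-ROI neighbor-distance summaries with
Welch's ANOVA, and RGB interaction-zone renderings). A synthetic-tissue
module generates cohorts with planted phenotype signatures and spatial
attraction so every stage is testable against known ground truth.

## The PDR statistic

For each cell, take its K = 50 nearest neighbors within the same ROI and
record the mean distance to the neighbors of each phenotype. Averaging over
all cells of a source phenotype A (in the selected ROIs) gives an asymmetric
mean-distance matrix **D**[A][B] in µm. All defined ordered off-diagonal
entries of D are ranked (fractional ranks on ties) and scaled affinely to
[0, 1], and the symmetric rank is the geometric mean

    PDR[A][B] = sqrt( r(A, B) · r(B, A) ),

so 0 marks the closest interacting pair and 1 the furthest. Because PDR
depends on D only through ranks, it is invariant to uniform coordinate
rescaling and to any strictly increasing transform of the distances.

Phenotyping follows the standard cytometry recipe: arcsinh(x/5) transform,
per-marker standardization (winsorized at ±3 sd), a k-nearest-neighbor graph
(k = 30) in expression space reweighted by the Jaccard similarity of
neighbor sets, and Louvain modularity maximization.

## Worked example

```python
import imcspatial as ims

# study-shaped synthetic cohort: 5 control + 12 treated ROIs, 32 markers
cfg = ims.default_config(seed=1)
table, truth = ims.generate_cohort(cfg)
print(len(table), table.roi_id.nunique())        # 77612 17

panel = ims.default_panel()
assign = ims.phenotype(table, panel, k=30, seed=1)
print(assign.n_clusters)                          # 10

labels = table["true_phenotype"].to_numpy(object)
treated = sorted(table.loc[table.condition == "treated", "roi_id"].unique())
neighbors = ims.knn(table, k=50)
profiles = ims.phenotype_profiles(neighbors, labels)
D, n = ims.mean_distance_matrix(profiles, labels,
                                table["roi_id"].to_numpy(object), rois=treated)
P = ims.pdr(D)
print(round(P.loc["cC3_hepatocyte", "macrophage"], 3))   # 0.0
print(round(P.loc["cC3_hepatocyte", "B_cell"], 3))       # 0.438
```

The cohort totals 77,612 cells over 17 ROIs. The default configuration
plants macrophage and Kupffer-cell attraction around apoptotic
(cC3+) hepatocytes in the treated condition; the PDR matrix recovers it —
the planted pair scores 0.0 (the closest pair in the cohort) while an inert
phenotype such as B cells ranks far higher (0.438).

The same pipeline runs from the shell:

```bash
imcspatial --seed 1 --out-dir run run-all      # simulate→cluster→spatial→zones→report
imcspatial --config my.yaml spatial            # one stage, resuming from CSVs
```

`run-all` writes the cell table, cluster signatures and abundance tests, the
mean-distance and PDR matrices with their heatmaps, the PDR feature map, the
interaction-zone rendering, and a JSON run report; identical seeds reproduce
identical numeric artifacts byte for byte.

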