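# Methods

## Overview

`imcspatial` implements the single-cell spatial analysis pipeline for
imaging-mass-cytometry (IMC) cohorts: featurization of segmentation masks
into per-cell marker tables, graph-based phenotyping, abundance comparisons
between conditions, and neighborhood statistics built around the symmetric
pairwise distance rank (PDR). Because real IMC acquisitions are large,
proprietary in format, and rarely deposited, the package ships a
synthetic-tissue generator whose cohorts have known phenotype identities
and planted spatial structure; every stage is validated against that ground
truth and against independent oracles.

## Synthetic tissue

Each ROI is a rectangle (default 700 × 700 µm, matching a typical IMC
ablation). Cell counts per phenotype are independent Poisson draws around
`cells_per_roi × proportion × shift(condition)`, so condition effects are
abundance shifts; phenotype signatures never change between conditions —
the contrast a treated-vs-control IMC study presents is different
composition and different spatial structure, not different biology per
marker.

Placement: unattracted phenotypes are complete spatial randomness (CSR)
over the rectangle. A planted attraction turns a declared fraction of one
phenotype's cells into offspring placed uniformly within a disk of radius
`r` around a uniformly chosen parent cell — a Matérn-style cluster process,
chosen over a Gaussian (Thomas-style) kernel because its bounded support
makes "within radius r" assertions exact. Offspring falling outside the ROI
are re-drawn up to 100 times, then placed at the parent; this preserves the
declared radius rather than silently inflating it. Chained attractions
(a parent that is itself an offspring) are rejected at validation.

Intensities are zero-truncated normal per marker with the phenotype's
signature mean/sd (detectors do not report negative counts); cell areas are
gamma-distributed (shape 16, ~25% CV) around the phenotype's mean area. All
randomness in one ROI flows through a single `numpy` generator seeded by
`(seed, condition index, roi_index)`, so any ROI regenerates independently
and bit-identically.

The default cohort emulates a 17-ROI two-condition study: 5 control + 12
treated ROIs, ~4,570 cells/ROI, 32 markers, ten liver-flavored phenotypes
(hepatocytes, an apoptotic cC3+ hepatocyte subset, LSECs, Kupffer cells,
macrophages, T/B/Treg lymphocytes, neutrophils). In the treated condition
the cC3+ subset triples, myeloid phenotypes expand, hepatocytes shrink
(shift 0.6, keeping the treated per-ROI expectation near `cells_per_roi` and
the cohort total near 77,700 cells), and macrophages/Kupffer cells are
attracted to cC3+ hepatocytes within 20 µm. The per-ROI count is a default
derived from cohort-scale arithmetic, not a constraint.

Mask rendering draws each cell as the `round(area)` in-bounds pixels nearest
its centroid (a digital disk whose pixel count equals the area exactly, with
deterministic tie-breaks), later cells overwriting earlier ones where disks
overlap. The channel stack carries the owning cell's marker vector per pixel
plus optional truncated Gaussian noise. What the generator does *not*
emulate: spillover between isotope channels, hot pixels, ablation artifacts,
segmentation errors, or tissue-scale anatomy such as zonation. Passing tests
therefore demonstrate correctness of the statistics under the stated point-
process model, not robustness to IMC acquisition noise.

## Featurization

Pixel (0, 0) is the center of the top-left pixel; x runs along columns, y
along rows; distances are in µm with a default pixel size of 1 µm (IMC's
ablation step). Per positive label: centroid = unweighted mean of member
pixel centers, area = pixel count × pixel_size², intensity = mean channel
value over member pixels (mean rather than sum, the common IMC convention;
whether a study uses mean or summed signal is usually unstated). Cells
touching the border are retained. No spillover or hot-pixel correction is
applied. scikit-image's regionprops provides the accumulation; tests pin it
to an explicit per-pixel loop oracle exactly.

## Phenotyping

The chain is the PhenoGraph recipe: `arcsinh(x / cofactor)` with cofactor 5
(the cytometry convention), per-marker standardization to mean 0 / sd 1
over all cells, winsorized at ±3 sd to blunt hot pixels; a k-nearest-
neighbor graph (k = 30 by default; the emergent cluster count is
data-driven, not forced) in expression space over the phenotyping markers
(nuclear/segmentation channels excluded); edges weighted by the Jaccard
index of the two cells' neighbor sets, each set including the cell itself
(so two coincident cells at k = 1 share weight 1); and Louvain modularity
maximization.

Louvain is implemented in-package: weighted Newman–Girvan modularity,
greedy local moves (gain tolerance 1e-9, ties to the lower community id),
aggregation with self-loops counted twice on the diagonal, a final
refinement sweep at the cell level, and a seeded node-order shuffle making
the result deterministic per (graph, seed). On graphs of ≤ 64 nodes, 64
seeded restarts are taken and the best-modularity partition kept — tiny
graphs are where the greedy heuristic can lodge in local optima and where
exhaustive verification is possible; large graphs use a single pass (8
restarts up to 2,000 nodes). The sweep is JIT-compiled with numba when
available and falls back to the identical pure-Python code otherwise.
Clustering pools all analysis ROIs; no batch correction is applied. Manual
cluster annotation (naming a cluster "Kupffer") is a user-supplied label
map, never an algorithmic step.

Cluster signatures are per-cluster means of the transformed expression,
z-scaled per marker across clusters; a single cluster or a zero-variance
marker scales to 0. Abundance is cells per (ROI, cluster); condition
comparisons use the unpaired pooled-variance t-test per cluster with raw
p-values and Holm-adjusted p-values reported side by side (the correction
choice is conservative and stated explicitly because "multiple t-tests"
alone underdetermines it).

## Spatial statistics

Neighborhoods are the K = 50 nearest cells by Euclidean centroid distance,
computed within each ROI only (ROIs are physically separate tissue cores),
self excluded, ties broken by (distance, lower row index), K truncated to
n−1 in small ROIs. Per cell, the phenotype distance profile is the mean
distance to the neighbors of each phenotype, missing when the phenotype is
absent from the neighborhood. Missing entries are dropped, not imputed:
imputing a worst-case distance would fabricate interaction evidence.

D[A][B] pools profiles over all phenotype-A cells in the selected ROIs
(pooled rather than per-ROI-ranked; a per-ROI path is available through the
`rois` argument). PDR ranks all defined ordered off-diagonal entries with
fractional ranks, maps them affinely so the extremes hit exactly 0 and 1,
and symmetrizes by the geometric mean of the two ordered ranks. The
diagonal is reported missing — self-pairs carry no interaction meaning.
Degenerate cases: fewer than two defined entries is an error; all entries
tied yields the single common value 0.5.

A consequence worth stating: PDR is a *rank* statistic and carries no
absolute scale. Its defined entries always span [0, 1] however large the
cohort, so under a CSR null the dispersion of PDR entries does not shrink
with sample size — the concentration appears in D (whose entries converge
to a common value), and the tests check exactly that. Interpretation of an
individual PDR value should always be relative to the other pairs in the
same matrix.

The feature map embeds PDR row vectors in 2-D (UMAP, seeded, n_neighbors
adapted to the handful of nodes; any callable embedder can be substituted;
< 3 phenotypes falls back to a deterministic circular layout). Node size
tracks phenotype frequency, node color the row-mean PDR, edge weight
1 − PDR. Missing PDR entries are imputed as 1 (maximally distant) for the
embedding only, with a warning.

Per-ROI neighbor-distance summaries recompute the A→B means without
pooling and compare neighbor phenotypes by Welch's ANOVA (unequal-variance
F with Welch–Satterthwaite degrees of freedom, implemented from the closed
form; scipy's and pingouin's implementations serve as oracles in tests).
All-equal group means return F = 0, p = 1 exactly.

Interaction zones pseudocolor each cell by proximity to three reference
phenotypes: channel c = exp(−d_c / τ) with d_c the distance to the nearest
reference-c cell in the ROI (a reference cell's own channel is 1). The
exponential kernel and its decay length τ = 25 µm (one to two cell
diameters) are declared choices — proximity-based coloring admits many
kernels, and the exponential gives a smooth, monotone, parameter-light map
whose white region marks three-way co-proximity. A reference phenotype
absent from a ROI zeroes that channel with a warning.

## Reporting and orchestration

Every figure (cluster heatmap, PDR heatmap with the yellow→black 0→1
colormap and hatched missing cells, feature map, zone rendering) has a CSV
twin; figures are views, CSVs the record. The JSON run report (schema
version 1) snapshots the configuration and its hash, the global and
per-stage seeds, headline counts, and every artifact path; emitting a
report with a missing artifact fails naming it.

The CLI composes the stages (`simulate`, `featurize`, `cluster`, `spatial`,
`zones`, `report`, `run-all`) over one run directory, resuming from
intermediate CSVs. A single `--seed` is split into per-stage seeds via
`numpy.random.SeedSequence(entropy=[seed, stage_index])`, so stages are
independently reproducible; identical seeds reproduce identical numeric
artifacts byte for byte. Usage errors exit 2, validation failures exit 1
with the offending field or file named.

## Problem sizes and numerical choices

Tests validate kNN and featurization against exhaustive oracles at n ≤ 200;
PDR against a rank-enumeration oracle on 100 random matrices; Louvain
against brute-force partition enumeration on graphs of ≤ 8 nodes and
against igraph's independent implementation on planted partitions;
phenotype recovery (ARI ≥ 0.9) on 12,000-cell cohorts of 8 phenotypes
separated by ≥ 3 sd; planted-interaction recovery on 20 cohorts of 12 ROIs
× ~1,500 cells; statistical calibration on 2,000-replicate Poisson nulls;
and the full pipeline at the study shape (17 ROIs, ~77,700 cells) with a
byte-identical rerun. The acceptance script reuses these problem sizes at
10 cohorts for interaction recovery. Tie-breaks are deterministic
everywhere (lower index wins); distances are exact Euclidean; rank ties are
fractional; all tolerances in tests are stated per assertion.

## Known limitations

- The generator's CSR/Matérn model omits spatial inhomogeneity (zonation,
  vessels), so recovery rates on real tissue with structured backgrounds
  may differ.
- PDR conflates abundance with proximity when a phenotype is very common:
  abundant phenotypes appear in many neighborhoods, including distant ones,
  inflating their mean distances. The per-ROI summaries partially expose
  this; a permutation-based enrichment test is out of scope.
- No spillover compensation, hot-pixel removal, or segmentation-error
  modeling; the mask is accepted as ground truth from the upstream
  segmentation model.
- Louvain optimality is only guaranteed-checked at small graph sizes; at
  cohort scale the heuristic's usual caveats apply.
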