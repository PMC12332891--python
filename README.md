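# fatestrat

Malignant-cell-fate stratification of breast cancer, as a tested,
reusable Python library.

Breast tumours are mixtures of malignant cells at different points along
differentiation trajectories, and where a tumour's cells sit along those
trajectories carries prognostic and therapeutic information that
standard receptor-based subtyping misses.  `fatestrat` implements the
full analysis chain that turns raw spot/cell expression into a
maturity-based patient stratification and a prognostic risk model:

1. **Spot annotation** — library-size normalisation, vst-style highly
   variable gene selection, PCA → kNN → Leiden clustering, one-vs-rest
   Wilcoxon markers (|log₂FC| > 0.5, BH FDR < 0.05), marker-panel typing
   of clusters into immune / stromal / malignant, and the hypergeometric
   **multimodal intersection analysis (MIA)**: for gene sets A, B in a
   universe of N genes with overlap k, the enrichment p is
   P(X ≥ k) with X ~ Hypergeom(N, |A|, |B|).
2. **Branching pseudotime** — a centroid-MST trajectory (PCA → k-means →
   minimum spanning tree → edge projection) giving a rooted pseudotime
   and branch labels; natural-cubic-spline likelihood-ratio tests for
   pseudotime- and branch-dependent expression; and the fate-gene
   cascade: (trajectory-DE ∩ ordering genes) ∩ KM-significant ∩
   uniCox-significant.
3. **Consensus subtypes** — resampled agglomerative consensus clustering
   (1 − Pearson distance), k chosen by the relative delta-area elbow of
   the consensus CDF, a PC1+PC2 fate-gene score per sample, and
   maturity labels I–IV anchored on SLIT3, ITGAX, PKIB, MCAM.
4. **Prognostic risk model** — per-gene KM/uniCox screens, an
   L1-penalised Cox path with cross-validated partial likelihood and an
   unpenalised multivariate refit, and the linear risk score
   `risk = Σᵢ βᵢ · exprᵢ`.  The packaged default is the printed 15-gene
   signature (RNASE1 0.1134, SLIT3 0.1126, GBP1 −0.2472, …,
   NDUFB1 −0.2030).  Evaluation: median-split log-rank, IPCW
   cumulative/dynamic AUC(t), covariate Cox tables.
5. **Drug matching** — cell lines assigned to the subtype centroid they
   best correlate with over the fate genes; per-drug Kruskal–Wallis
   across subtypes with BH control; direction-aware per-subtype drug
   rankings; centroid-stability cross-validation.
6. **Chromatin accessibility** — each chromosome tiled into 92 evenly
   spaced segments, peaks binned by midpoint, density = count/length,
   and a gene-location permutation test (uniform random re-placement,
   add-one empirical p) for accessibility enrichment at fate-gene loci.
7. **Gene-set scoring** — per-sample ssGSEA (symmetrised weighted-ECDF
   running sum, α = 0.25), pre-ranked GSEA with a gene-permutation null,
   and Pearson co-expression networks.

A first-class synthetic-data module generates every input with planted
ground truth — negative-binomial spot counts with type programmes, a
Y-shaped trajectory, Gaussian-centroid cohorts with exponential
survival and tuned censoring, subtype-shifted drug panels, and enriched
peak tracks — so the whole pipeline is testable end to end without any
download.

## Worked example

```bash
python examples/03_consensus_subtypes.py
```

prints, among other lines:

```
chosen k by delta-area elbow: 4
relative delta-area per k: {2: 0.407, 3: 0.536, 4: 0.199, 5: 0.007, 6: 0.008, 7: 0.01, 8: 0.008, 9: 0.008}
subtype label counts: {'II': 112, 'I': 99, 'III': 99, 'IV': 90}
```

The cohort was simulated with four planted subtypes; the delta-area
curve gains area up to k = 4 and flattens after (relative gains < 1%),
so the elbow criterion selects k = 4, and the four consensus clusters
are labelled I–IV by their maturity markers.  Similarly,
`examples/04_risk_model.py` scores a cohort with the packaged 15-gene
signature (coefficient sum −0.4154 at unit expression) and prints the
median-split log-rank test and AUC(1/2/3):

```
median-split log-rank chi2 = 265.03, p = 1.37e-59
AUC(t): {1.0: 0.801, 2.0: 0.846, 3.0: 0.85}
```

Each `examples/*.py` script is a short narrative for one capability
(spot annotation and MIA, trajectory and fate genes, subtypes, risk,
drugs, ATAC enrichment, gene sets) and states what its numbers mean.

## Command line

A thin CLI mirrors the library for scripted runs; outputs are
byte-identical when rerun with the same inputs and seed:

```bash
fatestrat simulate --what cohort --seed 1 --out data/
fatestrat subtype --expr data/expression.tsv --k 2:9 --out out/
fatestrat atac --peaks p.bed --sizes sizes.tsv --genes loci.tsv --out out/
```

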