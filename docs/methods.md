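# Methods

This note documents the models, conventions and numerical choices behind
`fatestrat`, in the order the pipeline runs them.

## Synthetic data model

The generators exist to exercise every stage against planted truth, and
their defaults define the conditions under which the package's
recovery claims hold.

**Counts.** Spot and trajectory counts are negative-binomial with a
shared dispersion (size) parameter on log-normal latent means:
`x ~ NB(mean = exp(μ), size = r)` with `r = nb_dispersion` (default 2, a
strongly overdispersed droplet-like regime; `r = inf` gives the Poisson
limit).  Baseline log-means are Normal(log 5, 0.5).

**Spot programmes.** Three spot types (immune 20%, stromal 30%,
malignant 50%) each over-express a programme of genes by `effect_size`
(default 2) on the log scale.  A programme is the type's canonical
3-gene marker panel (CD44/FTL/LGALS1, ALDH18A1/CD24/MIR205HG,
HLA-DRA/HLA-DRB1/HSPE1) plus 20 additional programme genes — cell types
differ broadly in expression, not only in their surface markers, and a
3-gene signal alone would make per-spot typing information-theoretically
marginal at droplet-like noise.  Annotation still uses only the 3-gene
panels.

**Trajectory.** Pseudotime is Uniform(0,1); spots past `branch_time`
(0.5) split equally onto two arms.  Genes form four equal modules:
early-decreasing, late-increasing, branch-specific (opposite linear
ramps on the two arms past the bifurcation, amplitude 2 in log units)
and flat nulls.

**Cohort.** Log-expression is Gaussian with unit within-subtype SD;
each of the four subtypes shifts its own gene block by `effect_size`
SDs.  Survival is exponential with
`log hazard = subtype offset + Σ β_g · x_g` over the informative genes
(shared β = 0.5 by default, or an explicit per-gene vector), baseline
median 5 years.  Subtype offsets rise 0.4 log-HR per subtype so planted
prognosis worsens from subtype 1 to 4.  Censoring is an independent
exponential whose rate is solved by bisection so that
`E[ρ/(ρ+λ_i)]` equals `censor_target` (default 0.3).  Weibull shape is
not modelled; constant hazard suffices for Cox-recovery testing.

**Cell lines and drugs.** Lines sit at the cohort subtype centroids
plus Normal(0, 0.5) noise; each drug is sensitive in one subtype
(round-robin) with its response shifted by 2 SD there.  The response
convention (larger = more sensitive) is recorded on the table; it is
never assumed.

**Peaks.** Background peak midpoints are uniform per chromosome with
counts multinomial in chromosome length (23 chromosomes, desk-scale
lengths ~1 Mb).  Gene loci are uniform over chromosomes and positions —
deliberately the same law as the permutation null, so null p-values are
exactly exchangeable.  Segments containing gene loci receive
Poisson((fold−1) × background-per-segment) extra peaks.

**Randomness.** All draws flow from one root seed through named
substreams (`SeedSequence(seed, spawn_key=(stream,))`), so adding a
generator never perturbs another's output.

What the generators do **not** emulate: spatial autocorrelation,
doublets/ambient RNA, batch effects, non-proportional hazards, dose-
response curve shape, and peak width/overlap structure.  Passing tests
demonstrate correctness of the algorithms under the stated model, not
performance on real tissue.

## Spot processing

Normalisation is counts-per-10k + log1p.  HVG selection ranks genes by
the residual of log1p-variance around a global quadratic trend in
log1p-mean — a vst-flavoured detrending that is robust when variable
genes cluster at one end of the mean axis.  Clustering is PCA (20 PCs)
→ symmetric kNN graph (k = 20) → Leiden at resolution 0.5, with labels
renumbered by community size for determinism.  QC filters (total-count
ceiling 100 000, mitochondrial fraction 0.10, gene detected in > 2
spots) are exposed as configuration and applied before normalisation.

Marker tests are one-vs-rest two-sided Wilcoxon rank-sum: exact when
both groups have ≤ 8 observations and no ties (verified against full
enumeration in the tests), normal approximation with tie correction
otherwise.  log₂FC is computed on the de-logged normalised scale with a
+1 stabiliser.  Cluster typing scores each panel by the mean log₂FC of
its genes in the cluster's marker rows (absent genes contribute 0) and
assigns the argmax if positive; exact ties stay `unassigned` — a
deliberate refusal to break biological ties arbitrarily.

MIA reports the upper-tail hypergeometric probability as the
enrichment p and the lower tail as depletion, separately, since
"intersection significance" alone does not fix a tail.

## Trajectory

The trajectory is intentionally simple: PCA to 2 components on the
ordering genes, k-means (10 centroids, deterministic quantile-based
initialisation so results are invariant to spot order), minimum
spanning tree over centroids, projection of each spot onto its nearest
tree edge, pseudotime = geodesic distance from the root.  Spots
projecting beyond a *leaf* endpoint keep their graded (unclamped)
ordering; spots beyond an interior junction are clamped onto the tree.
States are maximal chains between nodes of degree ≠ 2; a branch point
is any node of degree ≥ 3, and arm labels come from the connected
components left after removing it (0 = the root side).  This captures
what downstream selection needs — a rooted ordering plus branch labels
— without re-implementing a probabilistic graph-embedding method.

The root is the leaf whose member spots minimise mean expression of a
configurable maturity panel (default SLIT3 + ITGAX, the most/second-most
mature subtype markers), overridable by an explicit node id; with no
panel available the leaf with the lowest mean PC1 is a deterministic
fallback.  Only the *sign* of pseudotime depends on this choice.

Expression tests use a Gaussian working likelihood on log-normalised
values: LRT of a natural cubic spline (df = 3, boundary knots at the
data range, internal knots at quantiles) against intercept-only, with a
χ²(df) reference; the branch test adds a branch main effect and
per-branch spline terms (χ²(df+1)).  The statistic `n·log(RSS₀/RSS₁)`
is invariant to affine rescaling of expression.  A negative-binomial
GLM variant is a possible extension, not implemented.

## Consensus subtyping

Per resample (100 by default), 80% of samples and 80% of features are
drawn, samples are hierarchically clustered (average linkage on
1 − Pearson correlation) and cut at each k in 2..9; consensus(i,j) is
the co-clustering count over the co-sampling count.  Nine resamples —
a printed value in the method this follows — cannot stabilise a
consensus matrix, so 100 is the default and 9 remains available as
configuration.  Undefined entries (a pair never co-sampled) raise with
guidance to increase reps.  The final partition at each k is a
hierarchical cut of 1 − consensus.

k is selected by the relative delta-area of the consensus-CDF area:
Δ(k) = (A(k) − A(k−1))/A(k−1), with the smallest k as baseline, and the
chosen k is the largest whose Δ exceeds 0.05 — a numerical reading of
the "no appreciable variation after the elbow" criterion, which is
otherwise visual.  Degenerate flat CDFs fall back to k_min with a
warning.

The per-sample fate-gene score is the PC1 + PC2 coordinate of
standardised fate genes.  No formula for this score is fixed by the
method's source, so the convention is: each component's sign is
anchored so it correlates non-negatively with mean fate-gene
expression, and the summed score is flipped as a final guard.  Score
magnitudes are not comparable across cohorts, and the score's hazard
direction should be read from the survival analysis rather than
assumed: the analysis reports both.

Maturity labels I–IV attach to the four clusters by maximising total
cluster-mean marker expression (SLIT3, ITGAX, PKIB, MCAM) over
one-to-one assignments (Hungarian algorithm) — deterministic even under
ties.

## Prognosis

Cox fits use Efron tie handling throughout (synthetic times are
continuous, real inputs tie).  The univariate screen defaults to
p < 0.001, with the permissive p < 0.05 variant exposed — both
thresholds appear in the source method and the contradiction is
externalised as configuration.  The L1 path is coxnet
(30 alphas, ratio 0.01); the penalty is chosen by 10-fold
cross-validated partial likelihood (held-out contribution computed as
full-data minus training-fold log-likelihood at the training-fold
coefficients), at λ_min rather than 1-SE because the source optimises
fit; surviving genes are refit by unpenalised multivariate Cox and the
refit coefficients form the signature.  At a forced λ → 0 this
reproduces the direct multivariate fit to 1e-4, which the tests verify
against an independent grid-search maximiser of the written partial
likelihood.

The packaged 15-gene signature ships as a versioned JSON data file and
is never refit silently; `risk_score` errors on missing genes, listing
them.  Time-dependent AUC is the IPCW cumulative/dynamic estimator
(censoring weights from the Kaplan–Meier censoring curve); horizons
with no prior events are reported missing.  Perfect separation in a
univariate fit is flagged and reported at the boundary with a warning
rather than failing.

## Gene sets

ssGSEA scores one sample at a time from expression ranks alone.  The
implemented statistic is a *symmetrised* weighted-ECDF difference:
genes sorted by decreasing expression get rank weights (N−j)^α
(α = 0.25); both the in-set and out-set ECDFs carry the weights, and
the summed difference is divided by N.  The common hit-weighted-only
running sum has a structurally positive null mean (≈ +0.05·N at
α = 0.25), which breaks null-calibration; the symmetrised form keeps
random sets centred at zero (|mean| < 0.003 measured) while remaining
invariant to monotone transforms of expression.  Sets overlapping
fewer than 2 genes, or all genes, are skipped with warnings.

Pre-ranked GSEA uses the weighted KS running sum (weight exponent 1) on
a signed ranking statistic — signed rather than absolute ranking,
because two-tailed enrichment is only meaningful on a signed order — with
a gene-permutation null (the module receives a pre-ranked list, so
phenotype permutation is unavailable by construction).
NES = ES / mean(|null ES| of the same sign); p uses the same-sign null
with the add-one rule; BH across sets.

Correlation networks are all-pairs Pearson with two-sided t-based
p-values, BH-adjusted before the |R| and adjusted-p filters.

## Drugs

Lines are **hard-assigned** to the argmax-PCC cluster centroid
(z-standardised profiles within each cohort separately, PCC over shared
fate genes): a k-group rank test requires group membership, so a
correlation-weighted soft assignment is not meaningful here.  A
`min_pcc` guard and an explicit unmatched state handle weakly
correlated or constant lines.  Kruskal–Wallis H uses tie correction
with a χ²(groups−1) reference and BH across drugs.  Rankings order
FDR-significant drugs by the direction-corrected difference of medians
(in-subtype vs elsewhere).  Because public response measures disagree
about whether larger values mean sensitive or resistant, the direction
flag is mandatory on every response table — there is no silent default.
The 10-fold cross-validation is implemented as centroid-stability CV
(recompute centroids with each fold of cohort samples held out,
re-assign lines, report per-line agreement with the full-data
assignment): the minimal defensible reading of an otherwise unspecified
validation target.

## Chromatin accessibility

Segment boundaries are bᵢ = ⌊i·L/n⌋ (n = 92), giving an exact half-open
tiling with lengths differing by at most 1.  A peak belongs to the
unique segment containing its midpoint ⌊(start+end)/2⌋ — peaks are
short relative to segments, and midpoint assignment conserves total
counts exactly.  Density is count/length.

The permutation test re-places each gene uniformly at random on a
uniformly random declared chromosome (position uniform within it),
n_perm times (a within-chromosome-only variant is available);
both the per-gene densities and the gene-set mean are reported, with
add-one empirical p-values, which are therefore never 0 and lie in
[1/(n_perm+1), 1].  A split-half agreement check (both halves of a
randomly split peak set agreeing on set-level significance) is provided
as the package's interpretation of a cross-validated stability check of
this procedure.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by
design: cohorts of 200–1000 samples over 12–120 genes, 300–400 spots,
45 cell lines × 40 drugs, ~5000 peaks over 23 ~1 Mb chromosomes,
permutation depths of 150–1000, and 20–500 replicate calibration runs.
These sizes are the package's own defaults for reproducible examples;
all of them are configuration, not limits.

## Known limitations

- The centroid-MST trajectory assumes the branching structure is
  visible in two principal components; deeply nested or high-dimensional
  branching needs a different embedding.
- Gaussian spline LRTs are calibrated on log-normalised values, not raw
  counts.
- The consensus delta-area threshold (0.05) is a convention; data with
  genuinely gradual structure have no sharp elbow.
- The exponential survival generator cannot probe proportional-hazards
  violations.
- ssGSEA normalisation across samples (min–max) is optional and off by
  default; raw ES magnitudes depend on N and |S|.
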