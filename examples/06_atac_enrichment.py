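"""Test chromatin-accessibility enrichment at fate-gene loci.

Simulates an ATAC-like peak track over 23 chromosomes with a 5-fold
peak-rate excess in the segments containing 15 planted gene loci, tiles
each chromosome into 92 evenly spaced segments, and compares the
observed gene-segment densities against a random-placement permutation
null.
"""

from fatestrat import atac
from fatestrat.synth import SimulationConfig, simulate_peaks

cfg = SimulationConfig(seed=1, enrichment_fold=5.0, n_background_peaks=5000)
peaks, gene_loci, truth = simulate_peaks(cfg)

grid = atac.segment_genome(cfg.chrom_sizes, n_segments=92)
filled = atac.peak_density(peaks, grid)
print(f"{len(peaks)} peaks over {len(cfg.chrom_sizes)} chromosomes, "
      f"{grid.n_segments} segments each")
print(f"count conservation: {filled.segments['count'].sum()} peaks binned")

result = atac.gene_segment_permutation(
    gene_loci, peaks, filled, n_perm=1000, seed=1
)
print(f"observed mean density at gene segments: {result['observed_mean']:.2e}")
print(f"null mean +/- sd: {result['null_mean']:.2e} +/- {result['null_sd']:.2e}")
print(f"gene-set permutation p: {result['p_set']:.4g}")
# p is the add-one empirical tail probability that randomly re-placed
# genes see densities as high as the observed loci; with 5-fold planted
# enrichment it sits at the 1/(n_perm+1) floor.
print("per-gene p < 0.05 for",
      int((result["per_gene"]["pvalue"] < 0.05).sum()), "of",
      len(result["per_gene"]), "genes")
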