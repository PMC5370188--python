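# blastoseq

Single-cell RNA-seq analysis of the first lineage decision in the mouse
embryo: the segregation of the trophectoderm (TE) from the inner cell mass
(ICM) between the 16-cell and 64-cell stages. The package is a tested,
reusable implementation of the full analysis chain used to chart this
process from plate-based (Smart-seq2 style) single-cell transcriptomes with
ERCC spike-ins and a per-cell Cdx2-eGFP reporter measurement — together with
a synthetic-data generator that reproduces the statistical structure the
analysis assumes, so every step can be validated against known ground truth.

It is aimed at computational biologists who want either (a) the individual
building blocks (RPKM quantification, spike-in noise calibration, a
dropout-aware DE test, rank-correlation lineage classification,
hypergeometric gene-set overlap) as library functions, or (b) the end-to-end
pipeline on their own count matrices via the `blastoseq` CLI.

## What it computes

**Quantification and QC.** Expression is quantified as reads per kilobase of
exon model per million mapped reads, RPKM_gc = n_gc / (L_g/10³) / (N_c/10⁶).
Genes are kept when RPKM > 1 in ≥ 2 cells; cells are kept by expressed-gene
count (default ≥ 3500), mapping rate (≥ 40%) and median pairwise Spearman
correlation (≥ 0.8); per-stage PCA outliers are flagged.

**Technical noise and variable genes.** Spike-in counts are modelled as
negative binomial with variance v = m + m²/r, i.e. cv²(m) = 1/m + 1/r. The
overdispersion r is fitted to the spike-ins by weighted least squares, and
each gene's variability statistic is log₂(cv²_obs / cv²_tech(m)) — its excess
variability conditional on its mean. PCA runs on log10(RPKM+1) of the top-N
(default 100) variable genes with a deterministic sign convention.

**Differential expression.** A two-group test on raw integer counts:
per-gene negative-binomial model with trend-moderated dispersion, zeros
down-weighted by the posterior probability that they are counting zeros
rather than dropout, Wald Z on the log-fold difference,
Benjamini–Hochberg-corrected two-sided normal p-values, and a signed
corrected Z-score (cZ). Significance is called at adjusted p ≤ 0.05.

**Lineage classification.** Early-32-cell cells are split at the 500-unit
reporter cutoff into low (putative ICM) and high (putative TE) groups; the
top 50 DE genes per direction define the ICM and TE signatures; all cells
are then assigned ICM/TE/CO identities by hierarchical clustering on
1 − Spearman ρ over the signature genes, with clusters labelled by their
mean signature scores. Stage-wise DEG dynamics (16-cell stages pooled) and
exact hypergeometric overlap with peak-associated gene sets (genes
overlapping a peak plus each peak's nearest 5′ and 3′ neighbours) complete
the downstream analysis.

## Worked example

```python
import numpy as np
import blastoseq as bs

counts, genes, cells = bs.generate_dataset(bs.SimConfig(seed=0))
expr = bs.rpkm(counts, genes)

fit = bs.fit_technical_noise(counts.subset_genes(genes.index[genes.is_spikein]))
scores = bs.variability_statistic(counts.subset_genes(genes.index[~genes.is_spikein]), fit)
top = bs.top_variable_genes(scores, 100)

low, high = bs.reference_split(cells)                      # 500-unit eGFP cutoff at E32
de = bs.de_test(counts.subset_cells(low), counts.subset_cells(high))
signatures = bs.derive_signatures(de, n_top=50)
assignment = bs.assign_lineage(expr, signatures)

reporter = genes.index[genes.is_reporter][0]
r, p = bs.correlate(cells.egfp_intensity, np.log10(1 + counts.counts.loc[reporter]))
```

Output on this seed:

```
technical overdispersion r_tech = 10.62
early-32-cell reporter split: 22 low / 27 high
significant DEGs low vs high: 186
lineage assignment: {'TE': 106, 'ICM': 101, 'CO': 55}
post-bifurcation agreement with simulation truth: 1.000
protein-mRNA Pearson r = 0.6600 (p = 3.79e-34)
```

The fitted overdispersion recovers the simulated r = 10; the early-32-cell
reporter split defines the two reference groups; the derived signatures
classify all 262 cells into TE, ICM and a co-expressing (CO) population that
is concentrated at the 16-cell stages; and the reporter protein channel
correlates with its own log mRNA at the configured 0.66.

Gene-set overlap against, e.g., a set of 8190 TF-bound genes in a universe
of 18388:

```python
t = bs.hypergeom_overlap(k=162, n=404, K=8190, N=18388)
# expected 179.9, P(X<=k) = 0.0384, P(X>=k) = 0.9694
```

Both one-sided exact tails are reported; choosing the relevant one
(enrichment vs depletion) is deliberately left to the caller.

The same steps are available from the shell:

```bash
blastoseq simulate --seed 0 --out sim/
blastoseq qc --data sim/ --min-genes 500 --min-corr 0.5 --out qc/
blastoseq hvg --data sim/ --n 100 --out hvg.tsv
blastoseq classify --data sim/ --out assignment.csv
```

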