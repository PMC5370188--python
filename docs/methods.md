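# Methods

## Scope and model overview

blastoseq implements the analysis chain for charting ICM/TE lineage
segregation from single-cell RNA-seq of staged mouse embryos (early/late
16-cell, early/late 32-cell, 64-cell), where each cell additionally carries a
quantitative Cdx2-eGFP reporter intensity measured before sequencing.
Upstream steps (read alignment, exon-model construction) are out of scope:
the pipeline starts from a gene × cell matrix of raw integer counts, exon
model lengths, per-cell mapped-read totals, spike-in flags and per-cell
annotations.

## Synthetic data generator

The generator produces the study conditions the analysis assumes, plus
ground truth for recovery tests.

**Population structure.** Five stages with 70/43/49/39/61 cells (262 total)
from 36 embryos. At the two 16-cell stages the 113 cells are ICM/TE/CO in
proportions 33/24/56 — CO ("co-expressing") cells sit at the arithmetic
midpoint of the two lineage log-mean profiles, the minimal model of a state
that has not resolved. After the bifurcation every cell is ICM or TE; the
late-32 (18 ICM / 21 TE) and 64-cell (33 ICM / 28 TE) compositions follow
the observed study compositions, the early-32 split (22/27) interpolates
between them.

**Expression model.** Baseline mean counts are log-normal
(ln-mean 1.0, ln-sd 1.5) over 2000 genes; 100 genes are truly TE-specific
and 100 ICM-specific. TE effects are at full strength (2 log₂ units, i.e.
4-fold) from the 16-cell stage on; ICM effects ramp from 1.0 to 2.0 log₂
units across the five stages. This asymmetry mirrors the early
stabilisation of the TE profile versus the prolonged maturation of the ICM
profile, and it is what makes the within-TE stage-to-stage DEG counts lower
than the within-ICM counts in the dynamics analysis. The defaults are
calibrated only to make classification recovery non-trivial: no quantitative
per-gene effect sizes are available to emulate, so 4-fold was chosen as a
typical strong lineage-marker effect. Counts are negative binomial
(dispersion 0.1) with per-cell log-normal library scaling (ln-sd 0.3) and
logistic dropout whose probability decreases with the log expected count
(midpoint at ln m = 0, slope 1): dropout concentrates at low expression, as
both the DE model here and established single-cell error models assume.
An optional per-embryo random effect defaults to zero variance, since no
embryo batch effects are modelled by default; it is configurable.

**Spike-ins.** 92 species with constant expected input per cell (log-uniform
means between 2 and 500 counts) and purely technical overdispersion
r_tech = 10, i.e. cv²(m) = 1/m + 1/10. No dropout and no library scaling are
applied: the spike-in mix is added at fixed input per cell.

**Reporter channel.** One TE-signature gene (high baseline, mean 50 counts —
an abundant TE transcription factor) is designated the reporter. The protein
intensity is affine in the cell's *latent* log₁₀ expected transcript count
(lineage effect included; library scaling, counting noise and dropout
excluded, since those arise in sequencing after the protein was measured):
500 intensity units at the midpoint between the post-bifurcation ICM and TE
latent means, spanning 700 units across the gap. Gaussian noise is then
added with its scale solved numerically (Brent root-finding on the realized
draws) so that the population Pearson correlation between the protein
channel and the *observed* log₁₀(count+1) equals the configured target of
0.66. Coupling through the latent mean is what lets the channel separate
lineages sharply (TE/ICM cells straddle the 500-unit cutoff) while its
correlation with instantaneous mRNA stays moderate — the behaviour of a
stable protein integrating over transcriptional noise. If a realized draw's
latent–observed correlation falls below the target the channel is emitted
noise-free with a warning; the achieved correlation then equals that
realized value.

**What the generator does not emulate.** No embryo geometry, cell position,
division history or signalling dynamics; no transcript-length biases within
a gene; no gene–gene correlation beyond the two lineage programmes; no
EPI/PE substructure by default (the marker-panel classifier accepts planted
substructure constructed by the caller). Passing recovery tests on this
generator therefore demonstrates the statistical machinery under the
assumed noise model, not performance on any real dataset.

## Quantification and QC

RPKM_gc = n_gc / (L_g/10³) / (N_c/10⁶) with exon-model length L_g (bp) and
per-cell mapped-read total N_c. The identity
Σ_g RPKM_gc·L_g/10³ = 10⁶·(assigned/mapped) holds exactly and is tested.

The gene filter keeps genes with RPKM strictly > 1 in ≥ 2 cells ("expression
cutoff of 1" is read as a strict inequality; the boundary case RPKM = 1.0 is
removed). The cell filter is a single pass over all input cells (no
iterative re-filtering): expressed genes (RPKM > 1) ≥ 3500, mapping rate
≥ 0.40, and a pairwise-correlation score ≥ 0.8. The score is the **median**
Spearman correlation of the cell's log₁₀(RPKM+1) profile against every
other cell — median chosen for robustness where max or mean were equally
defensible; it is a parameter. Each removed cell records exactly one primary
reason, the first failed check in the order min_genes → mapping →
correlation. The mapping-rate threshold is approximate in origin and
exposed as a parameter.

Per-stage PCA outlier flagging is a concretization of an otherwise
unquantified step: within each stage (≥ 5 cells), cells whose Euclidean
distance from the componentwise median in the first two PCs exceeds
median + 5 × 1.4826·MAD of those distances are flagged. Flag-only; removal
is a caller decision. Degenerate (zero-variance) stages flag nothing, with a
warning.

## Technical noise fit and variable genes

Spike-in counts are size-factor normalized (per-cell spike-in totals scaled
to their geometric mean — the model says input is constant, so size factors
absorb capture efficiency). With per-spike-in mean mᵢ and squared
coefficient of variation cv²ᵢ, the model cv²(m) = 1/m + 1/r implies
cv²ᵢ − 1/mᵢ = 1/r for every spike-in; 1/r is estimated by weighted least
squares on a constant with weights ∝ mᵢ (abundant spike-ins pin down the
plateau). Negative estimates are clamped to the Poisson limit 1/r = 0 with a
warning. Preconditions: ≥ 3 spike-ins with nonzero mean, ≥ 10 cells.

The per-gene variability statistic is log₂(cv²_obs / cv²_tech(m)) at the
gene's own mean — a ratio at matched mean is the minimal reading of
"adjusting for technical variability conditional on the mean"; a difference
form is available via a flag. Genes with zero mean or expressed in < 2 cells
are excluded. Top-N selection (default N = 100; 100/250/500/1000 are the
conventional choices) sorts by the statistic with lexicographic gene-id
tie-breaks for determinism. No per-gene chi-square significance call is
made: selection is top-N, not significant-N.

## PCA

Log₁₀(RPKM+1), per-gene centering, no unit-variance scaling by default (gene
admission is already variance-controlled by the variability statistic;
scaling is a flag). SVD-based, with each component oriented so its
largest-magnitude gene loading is positive — output is then independent of
the numerical backend. The pseudocount 1 inside the log is a convention
choice for zero handling. PC1 ordering cells by developmental time is an
interpretation, not a code-level label.

## Differential expression

The test is an interface-compatible stand-in for a full Bayesian single-cell
error model: raw integer counts in, genes with zero reads across both groups
discarded, BH-corrected two-sided normal p-values and signed corrected
Z-scores (cZ) out, significance at adjusted p ≤ 0.05. It is **not** a
reimplementation of that model's per-cell error posterior, so DEG counts on
any real dataset will not match number-for-number.

Mechanics: joint size factors (total counts scaled to geometric mean);
per-gene NB dispersion by pooled within-group method of moments, clipped to
[10⁻⁶, 5] and shrunk halfway toward a fitted a + b/m trend (shrinkage weight
configurable) — moderation keeps 3-cell groups, which occur at stage
extremes, from producing degenerate dispersion estimates. Dropout handling:
the per-gene excess-zero fraction beyond the NB expectation is fitted with a
logistic curve decreasing in log mean; each observed zero is down-weighted
by the posterior probability that it came from the counting process. Group
means are weighted ratios with a half-count continuity term (keeps
all-zero-in-one-group genes finite and is symmetric between groups); the
Wald Z is the log-mean difference over its delta-method standard error.
cZ = sign(Z)·Φ⁻¹(1 − p_adj/2): correction is applied on the p scale and
mapped back to the Z scale, one of the two defensible readings of
"BH-corrected Z-score"; it guarantees |cZ| ≤ |Z|.

Under the null (identical NB groups, 50 cells each, 2000 genes) the mean
fraction of genes flagged is far below the 0.05 level (BH on a full null is
conservative); planted 4-fold changes are recovered with ≥ 80% power at 50
cells per group. Both are exercised in the acceptance suite.

## Lineage classification

The early-32-cell reference split uses the printed 500-unit reporter cutoff
(boundary to "high"); a PCA-based 2-means split is available via
`method="pca"` for data without a trusted cutoff. Signatures are the top 50
significant genes per direction ranked by |cZ| (gene-id tie-break); low-side
genes form the ICM signature, high-side the TE signature; they are disjoint
by construction.

All cells are clustered jointly (16-cell cells are classified against the
32-cell-derived signatures in the same clustering) on 1 − Spearman ρ over
log₁₀(RPKM+1) of the signature-gene union, hierarchically, cut at k = 3.
**Ward linkage is the default**, a deliberate departure from the more common
average linkage: on correlation-distance matrices average linkage chains,
and at k = 3 it tends to split off a singleton while merging the CO
population into a lineage cluster; Ward produces balanced clusters that
recover the three planted populations across seeds (post-bifurcation
accuracy ≥ 0.98, 16-cell CO fraction within 4 points of the configured
49.6%). Linkage and k remain parameters. Clusters are labelled by mean
TE-minus-ICM signature score (max → TE, min → ICM, rest → CO), where each
score is the mean per-gene-standardized log expression over the signature —
standardization makes the two signatures commensurate. Cells with constant
expression over the signature genes (rank correlation undefined) are
assigned by their own scores with a warning. The same machinery backs
`marker_panel_classify` for user-supplied two-panel classifications (e.g.
EPI/PE markers within the ICM).

## DEG dynamics and overlap enrichment

The two 16-cell stages are pooled (lineage-resolved groups are otherwise too
small), giving stages 16 → E32 → L32 → C64. Between-lineage tests run per
stage for ICM–TE, ICM–CO and TE–CO; within-lineage tests run for consecutive
stages within ICM and TE and for the CO→ICM and CO→TE transitions out of the
pooled 16-cell stage. Groups under 3 cells are skipped with a warning.

Overlap significance is the exact hypergeometric test with universe N
(a parameter — typically the number of annotated genes; no annotation
database is bundled), annotated-set size K, query size n and observed
overlap k. Both exact one-sided tails P(X ≤ k) and P(X ≥ k) are always
reported together with the expected overlap nK/N, because an observed
overlap *below* expectation makes the enrichment tail uninformative and the
choice of tail is a scientific, not a numerical, decision.

Peak-to-gene assignment takes BED-convention half-open 0-based intervals and
returns the union of genes overlapping any peak and, per peak, the nearest
non-overlapping gene on each side (5′ and 3′ in genomic coordinates),
distances measured between interval boundaries, ties broken toward the
smaller start coordinate. Verified against a quadratic all-pairs oracle.

## Reporter statistics

Background correction is subtraction (nuclear − cytoplasmic); the
nuclear/cytoplasmic ratio is reported separately and flagged undefined at
zero cytoplasmic signal; corrected values may be negative and are never
clipped. The low/high threshold assigns the boundary value to "high".
Correlations (Pearson/Spearman) and group tests (Mann–Whitney,
Kruskal–Wallis, t, ANOVA, chi-squared without continuity correction) wrap
the standard scipy procedures with argument validation.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 2000 genes +
92 spike-ins × 262 cells for the full pipeline, 50-cell groups × 2000 genes
× 20 replicates for the null calibration, 200 cells for the noise fit — the
statistical structure, not the gene-universe size, is what the checks
exercise; a full-size universe (e.g. ~25k genes) is a configuration choice.
All randomness flows through explicit integer seeds of numpy Generators;
reruns under a fixed seed are bit-identical end to end. Tolerances: the
DE group-swap antisymmetry holds to ~10⁻⁵ relative (floating-point summation
order differs between group orderings); BH and hypergeometric values are
exact to ≤ 10⁻¹².

## Known limitations

- The DE test's Wald/moment machinery is a stand-in: it shares the error
  model's interface and qualitative behaviour (dropout-aware, raw counts,
  cZ) but not its per-cell Bayesian posterior; absolute DEG counts are not
  comparable across implementations.
- The QC correlation filter's aggregation (median), the PCA outlier rule,
  the log pseudocount, the clustering linkage and the cZ construction are
  concretizations of under-specified steps; all are parameters and their
  defaults are documented above.
- The generator's independence assumptions (genes independent given lineage,
  no spatial or temporal autocorrelation) make recovery tasks easier than
  real data; recovery thresholds in the tests should be read as sanity
  floors under the assumed model.
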