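"""RPKM quantification and gene/cell quality filtering.

Expression is quantified as reads per kilobase of exon model per million
mapped reads (RPKM). Genes are kept when expressed above a cutoff in a
minimum number of cells; cells are kept when they express enough genes, map
well enough, and correlate with the rest of the dataset. A per-stage PCA
outlier flagger concretizes the usual "additional outliers were identified"
step: it only flags, removal is the caller's choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

__all__ = ["rpkm", "filter_genes", "filter_cells", "flag_pca_outliers", "QCReport"]


def rpkm(counts: CountMatrix, gene_lengths: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """RPKM_gc = count_gc / (length_g / 1e3) / (total_mapped_c / 1e6).

    ``gene_lengths`` may be a Series of exon-model lengths (bp) or a gene
    metadata frame with an ``exon_model_length_bp`` column.
    """
    if isinstance(gene_lengths, pd.DataFrame):
        gene_lengths = gene_lengths["exon_model_length_bp"]
    lengths = gene_lengths.reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing exon model length for genes {missing}")
    if (lengths < 1).any():
        raise ValueError("exon model lengths must be >= 1 bp")
    total = counts.total_mapped_reads
    zero = total.index[total <= 0].tolist()
    if zero:
        raise ValueError(f"zero mapped reads for cell(s) {zero[:3]}")
    kb = lengths.to_numpy(dtype=float) / 1e3
    per_million = total.to_numpy(dtype=float) / 1e6
    values = counts.counts.to_numpy(dtype=float) / kb[:, None] / per_million[None, :]
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.cell_ids)


def filter_genes(expr: pd.DataFrame, min_rpkm: float = 1.0, min_cells: int = 2,
                 spikein_flags: pd.Series | None = None) -> pd.Index:
    """Genes expressed strictly above ``min_rpkm`` in at least ``min_cells``
    cells. Spike-ins (per ``spikein_flags``) are excluded from the retained
    biological set; they stay available separately for the technical fit."""
    expressed = (expr > min_rpkm).sum(axis=1) >= min_cells
    if spikein_flags is not None:
        expressed &= ~spikein_flags.reindex(expr.index).fillna(False).astype(bool)
    return expr.index[expressed]


@dataclass
class QCReport:
    """Per-cell and per-gene filter outcomes.

    ``cells`` records, for every input cell, its expressed-gene count,
    mapping rate, median pairwise Spearman correlation, pass flag and the
    single primary reason for removal (first failed check, in the order
    min_genes, mapping, correlation).
    """

    cells: pd.DataFrame
    n_cells_retained: int
    n_cells_input: int

    def retained_cells(self) -> pd.Index:
        return self.cells.index[self.cells["pass"]]


def _pairwise_spearman_scores(log_expr: np.ndarray) -> np.ndarray:
    """Median Spearman correlation of each cell against all other cells."""
    ranks = np.apply_along_axis(stats.rankdata, 0, log_expr)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[norms == 0] = np.nan
    corr = (centered.T @ centered) / np.outer(norms, norms)
    np.fill_diagonal(corr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(corr, axis=1)


def filter_cells(expr: pd.DataFrame, ann: pd.DataFrame,
                 min_genes: int = 3500, min_map: float = 0.40,
                 min_corr: float = 0.8, expression_cutoff: float = 1.0,
                 genes: pd.Index | None = None) -> tuple[pd.Index, QCReport]:
    """Single-pass cell filter on expressed-gene count, mapping rate and
    median pairwise Spearman correlation (computed on log10(RPKM+1) over
    ``genes``, defaulting to all genes in ``expr``).

    ``ann`` must provide a ``mapping_rate`` column covering every cell.
    """
    missing = expr.columns.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotations missing for cells {missing[:3].tolist()}")
    sub = expr if genes is None else expr.loc[genes]
    n_expressed = (expr > expression_cutoff).sum(axis=0)
    mapping = ann.loc[expr.columns, "mapping_rate"]

    if expr.shape[1] < 3:
        warnings.warn("fewer than 3 cells; pairwise-correlation filter skipped")
        corr_score = pd.Series(np.nan, index=expr.columns)
        corr_ok = pd.Series(True, index=expr.columns)
    else:
        scores = _pairwise_spearman_scores(np.log10(sub.to_numpy(dtype=float) + 1.0))
        corr_score = pd.Series(scores, index=expr.columns)
        corr_ok = corr_score.fillna(-np.inf) >= min_corr

    genes_ok = n_expressed >= min_genes
    map_ok = mapping >= min_map

    reason = pd.Series("", index=expr.columns, dtype=object)
    reason[~corr_ok] = "correlation"
    reason[~map_ok] = "mapping"
    reason[~genes_ok] = "min_genes"  # primary reason: first check in order
    passed = genes_ok & map_ok & corr_ok

    report = QCReport(
        cells=pd.DataFrame(
            {
                "n_expressed_genes": n_expressed,
                "mapping_rate": mapping,
                "median_spearman": corr_score,
                "pass": passed,
                "reason": reason,
            }
        ),
        n_cells_retained=int(passed.sum()),
        n_cells_input=expr.shape[1],
    )
    return expr.columns[passed], report


def flag_pca_outliers(expr: pd.DataFrame, ann: pd.DataFrame,
                      n_mads: float = 5.0) -> pd.Index:
    """Flag, per developmental stage, cells whose distance from the stage
    centroid in the first two principal components exceeds
    ``median + n_mads`` robust deviations (1.4826 x MAD) of those distances.

    Works on log10(RPKM + 1). Flag-only: removal is a caller choice.
    """
    from .embedding import pca

    flagged: list = []
    for stage, cells in ann.groupby("stage", observed=True).groups.items():
        cols = expr.columns.intersection(cells)
        if len(cols) < 5:
            continue
        sub = expr[cols]
        log_expr = np.log10(sub.to_numpy(dtype=float) + 1.0)
        if np.allclose(log_expr.var(axis=1).sum(), 0.0):
            warnings.warn(f"stage {stage} has zero variance; no outliers flagged")
            continue
        result = pca(sub, n_components=min(2, len(cols) - 1))
        pcs = result.scores.to_numpy()[:, :2]
        centroid = np.median(pcs, axis=0)
        dist = np.sqrt(((pcs - centroid) ** 2).sum(axis=1))
        mad = stats.median_abs_deviation(dist, scale="normal")
        cut = np.median(dist) + n_mads * mad
        flagged.extend(sub.columns[dist > cut])
    return pd.Index(flagged)
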