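"""Core in-memory containers shared across the pipeline.

Counts are kept as plain gene x cell pandas DataFrames of non-negative
integers; per-cell metadata travels in ordinary DataFrames so that every
intermediate is inspectable and serializable as text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered developmental stages: early/late 16-cell, early/late 32-cell, 64-cell.
STAGES = ("E16", "L16", "E32", "L32", "C64")

#: Stages after the ICM/TE bifurcation has resolved in the simulation truth.
POST_BIFURCATION_STAGES = ("E32", "L32", "C64")


@dataclass
class CountMatrix:
    """Raw integer gene x cell counts plus per-cell mapped-read totals.

    Parameters
    ----------
    counts
        Gene x cell matrix of non-negative integers (genes on rows).
    total_mapped_reads
        Per-cell total of uniquely mapped reads; must cover at least the
        reads assigned to genes in that cell.
    """

    counts: pd.DataFrame
    total_mapped_reads: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.total_mapped_reads is None:
            self.total_mapped_reads = self.counts.sum(axis=0)
        self.total_mapped_reads = self.total_mapped_reads.reindex(self.counts.columns)
        if self.total_mapped_reads.isna().any():
            raise ValueError("total_mapped_reads missing for some cells")
        assigned = self.counts.sum(axis=0)
        if (self.total_mapped_reads < assigned).any():
            raise ValueError("total_mapped_reads below per-cell assigned read sum")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.total_mapped_reads)

    def subset_cells(self, cells) -> "CountMatrix":
        return CountMatrix(self.counts[list(cells)], self.total_mapped_reads.loc[list(cells)])


def validate_gene_meta(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-metadata table (index gene_id; columns
    ``exon_model_length_bp``, ``is_spikein``, ``true_lineage_role``)."""
    required = {"exon_model_length_bp", "is_spikein"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene metadata missing columns: {sorted(missing)}")
    if (genes["exon_model_length_bp"] < 1).any():
        raise ValueError("exon model lengths must be >= 1 bp")
    if "true_lineage_role" in genes.columns:
        bad = genes.loc[genes["is_spikein"], "true_lineage_role"] != "neutral"
        if bad.any():
            raise ValueError("spike-ins must have neutral lineage role")
    return genes


def validate_cell_annotation(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cell annotation table (index cell_id; columns
    ``embryo_id``, ``stage``, ``egfp_intensity``, ``mapping_rate``,
    ``true_lineage``)."""
    if "stage" in cells.columns:
        unknown = set(cells["stage"].unique()) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "mapping_rate" in cells.columns:
        rate = cells["mapping_rate"]
        if ((rate < 0) | (rate > 1)).any():
            raise ValueError("mapping_rate must lie in [0, 1]")
    return cells
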