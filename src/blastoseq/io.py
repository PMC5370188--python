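"""Text-format persistence: Matrix Market counts, TSV gene metadata and CSV
cell annotations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, validate_cell_annotation, validate_gene_meta

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(outdir, counts: CountMatrix, genes: pd.DataFrame,
                 cells: pd.DataFrame) -> Path:
    """Write counts.mtx + genes.tsv + cells.csv (+ total_mapped_reads column
    in cells.csv) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "counts.mtx", sparse.csr_matrix(counts.counts.to_numpy()))
    genes.to_csv(outdir / "genes.tsv", sep="\t")
    cells_out = cells.copy()
    cells_out["total_mapped_reads"] = counts.total_mapped_reads
    cells_out.to_csv(outdir / "cells.csv")
    return outdir


def load_dataset(indir) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a dataset written by :func:`save_dataset`."""
    indir = Path(indir)
    matrix = spio.mmread(indir / "counts.mtx").toarray().astype(np.int64)
    genes = validate_gene_meta(pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0))
    cells = pd.read_csv(indir / "cells.csv", index_col=0)
    total = cells.pop("total_mapped_reads")
    cells = validate_cell_annotation(cells)
    frame = pd.DataFrame(matrix, index=genes.index, columns=cells.index)
    return CountMatrix(frame, total), genes, cells
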