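"""Stage-resolved DEG dynamics and gene-set overlap enrichment.

Differential expression is run between lineages at every developmental stage
and between consecutive stages within each lineage, with the early and late
16-cell stages pooled (too few lineage-resolved cells otherwise). Overlap of
a query gene set with an annotated set is scored by the exact hypergeometric
test; peak-associated gene sets are built from genomic intervals with the
rule: genes overlapping a peak, plus for each peak the nearest
non-overlapping gene on each side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import CountMatrix
from .diffexp import DEResult, de_test
from .lineage import LineageAssignment

__all__ = ["DegDynamics", "OverlapTest", "deg_dynamics", "hypergeom_overlap",
           "peaks_to_genes"]

#: Analysis stages with the two 16-cell time points pooled.
POOLED_STAGES = ("16", "E32", "L32", "C64")


@dataclass
class DegDynamics:
    """DEG counts and gene lists between lineages per stage and between
    consecutive stages within lineages (including the CO-to-lineage
    transitions out of the pooled 16-cell stage)."""

    between_lineage: pd.DataFrame   # stage, pair, n_deg, genes
    within_lineage: pd.DataFrame    # lineage, stage_pair, n_deg, genes
    de_results: dict                # (kind, key) -> DEResult


def _pooled_stage(stage: str) -> str:
    return "16" if stage in ("E16", "L16") else stage


def deg_dynamics(counts: CountMatrix, assignment: LineageAssignment,
                 ann: pd.DataFrame, alpha: float = 0.05,
                 min_cells: int = 3) -> DegDynamics:
    """Run the DE test across stage/lineage groups and tabulate DEG counts.

    Groups with fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = assignment.labels
    stage = ann.loc[labels.index, "stage"].map(_pooled_stage)
    groups: dict[tuple[str, str], list[str]] = {}
    for (st, lin), cells in labels.groupby([stage, labels]).groups.items():
        groups[(st, lin)] = list(cells)

    de_results: dict = {}
    between_rows = []
    for st in POOLED_STAGES:
        for lin_a, lin_b in (("ICM", "TE"), ("ICM", "CO"), ("TE", "CO")):
            cells_a = groups.get((st, lin_a), [])
            cells_b = groups.get((st, lin_b), [])
            if min(len(cells_a), len(cells_b)) < min_cells:
                if cells_a or cells_b:
                    warnings.warn(f"skipping {lin_a} vs {lin_b} at stage {st}: "
                                  "group below minimum size")
                continue
            de = de_test(counts.subset_cells(cells_a), counts.subset_cells(cells_b),
                         alpha=alpha)
            sig = de.significant_genes.tolist()
            de_results[("between", st, f"{lin_a}-{lin_b}")] = de
            between_rows.append({"stage": st, "pair": f"{lin_a}-{lin_b}",
                                 "n_deg": len(sig), "genes": sig})

    within_rows = []
    transitions = list(zip(POOLED_STAGES[:-1], POOLED_STAGES[1:]))
    lineage_paths = [("ICM", [("16", "ICM")] + [(s, "ICM") for s in POOLED_STAGES[1:]]),
                     ("TE", [("16", "TE")] + [(s, "TE") for s in POOLED_STAGES[1:]]),
                     ("CO/ICM", [("16", "CO"), ("E32", "ICM")]),
                     ("CO/TE", [("16", "CO"), ("E32", "TE")])]
    for lineage_name, path in lineage_paths:
        for (st_a, lin_a), (st_b, lin_b) in zip(path[:-1], path[1:]):
            cells_a = groups.get((st_a, lin_a), [])
            cells_b = groups.get((st_b, lin_b), [])
            if min(len(cells_a), len(cells_b)) < min_cells:
                warnings.warn(f"skipping {lineage_name} {st_a}->{st_b}: "
                              "group below minimum size")
                continue
            de = de_test(counts.subset_cells(cells_a), counts.subset_cells(cells_b),
                         alpha=alpha)
            sig = de.significant_genes.tolist()
            de_results[("within", lineage_name, f"{st_a}-{st_b}")] = de
            within_rows.append({"lineage": lineage_name,
                                "stage_pair": f"{st_a}-{st_b}",
                                "n_deg": len(sig), "genes": sig})

    return DegDynamics(
        between_lineage=pd.DataFrame(between_rows,
                                     columns=["stage", "pair", "n_deg", "genes"]),
        within_lineage=pd.DataFrame(within_rows,
                                    columns=["lineage", "stage_pair", "n_deg", "genes"]),
        de_results=de_results,
    )


@dataclass
class OverlapTest:
    """Exact hypergeometric overlap between a query set of size ``n`` and an
    annotated set of size ``K`` in a universe of ``N`` genes, with observed
    overlap ``k``. Both one-sided tails are reported: which tail (depletion
    or enrichment) is meaningful is the caller's choice."""

    N: int
    K: int
    n: int
    k: int
    expected: float
    p_lower: float   # P(X <= k)
    p_upper: float   # P(X >= k)

    @property
    def p_min(self) -> float:
        return min(self.p_lower, self.p_upper)


def hypergeom_overlap(k: int, n: int, K: int, N: int) -> OverlapTest:
    """Exact one-sided hypergeometric tail probabilities for an overlap of
    ``k`` genes between a query of ``n`` and an annotated set of ``K`` drawn
    from a universe of ``N``."""
    if not (0 <= k <= min(n, K)):
        raise ValueError("need 0 <= k <= min(n, K)")
    if n > N or K > N or n < 0 or K < 0:
        raise ValueError("need n, K <= N and all sizes non-negative")
    rv = hypergeom(N, K, n)
    return OverlapTest(
        N=N, K=K, n=n, k=k,
        expected=n * K / N,
        p_lower=float(rv.cdf(k)),
        p_upper=float(rv.sf(k - 1)),
    )


def _read_intervals(frame_or_path, names) -> pd.DataFrame:
    if isinstance(frame_or_path, pd.DataFrame):
        frame = frame_or_path.copy()
    else:
        frame = pd.read_csv(frame_or_path, sep="\t", header=None, comment="#")
        frame.columns = names[: frame.shape[1]]
    bad = frame.index[frame["start"] >= frame["end"]]
    if len(bad):
        raise ValueError(f"malformed interval (start >= end) at line {bad[0] + 1}")
    return frame


def peaks_to_genes(peaks, genes) -> set[str]:
    """Genes associated with peaks: every gene whose interval overlaps a
    peak, plus for each peak the nearest non-overlapping gene on each side
    (5' and 3' in genomic coordinates).

    Both inputs are BED-convention half-open 0-based intervals: DataFrames
    with columns ``chrom``, ``start``, ``end`` (genes additionally ``name``,
    optionally ``strand``), or paths to BED files with those columns.
    Nearest-gene distance is measured between interval boundaries; ties
    break toward the smaller start coordinate.
    """
    peak_df = _read_intervals(peaks, ["chrom", "start", "end", "name"])
    gene_df = _read_intervals(genes, ["chrom", "start", "end", "name", "score", "strand"])
    if "name" not in gene_df.columns:
        raise ValueError("gene intervals need a name column")

    out: set[str] = set()
    for chrom, chrom_peaks in peak_df.groupby("chrom"):
        cg = gene_df[gene_df["chrom"] == chrom]
        if cg.empty:
            continue
        g_start = cg["start"].to_numpy()
        g_end = cg["end"].to_numpy()
        g_name = cg["name"].to_numpy()
        order = np.lexsort((g_start,))  # stable order by start for tie-breaks
        for p_start, p_end in chrom_peaks[["start", "end"]].itertuples(index=False):
            overlap = (g_start < p_end) & (g_end > p_start)
            out.update(g_name[overlap])
            left = ~overlap & (g_end <= p_start)
            if left.any():
                dist = p_start - g_end
                best = np.min(dist[left])
                cand = left & (dist == best)
                out.add(g_name[order][cand[order]][0])
            right = ~overlap & (g_start >= p_end)
            if right.any():
                dist = g_start - p_end
                best = np.min(dist[right])
                cand = right & (dist == best)
                out.add(g_name[order][cand[order]][0])
    return out
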