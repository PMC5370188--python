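"""Reporter-anchored lineage signatures and ICM/TE/CO assignment.

At the early-32-cell stage, cells are split into reporter-low (putative ICM)
and reporter-high (putative TE) groups; differential expression between them
yields two disjoint signatures (top genes per direction). Every cell is then
assigned a lineage by hierarchical clustering on Spearman-correlation
distance over the signature genes: the cluster with the highest mean
TE-minus-ICM signature score is TE, the lowest is ICM, and the rest are
co-expressing (CO). Assignment never reads ground-truth labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexp import DEResult

__all__ = [
    "LineageSignature",
    "LineageAssignment",
    "reference_split",
    "derive_signatures",
    "assign_lineage",
    "marker_panel_classify",
]


@dataclass
class LineageSignature:
    lineage: str           # "ICM" or "TE"
    genes: list[str]
    source: DEResult | None = None


@dataclass
class LineageAssignment:
    """Per-cell lineage labels with signature scores.

    ``table`` columns: ``label`` ({ICM, TE, CO}), ``cluster_id``,
    ``icm_score``, ``te_score`` (mean per-gene-standardized log expression
    over each signature).
    """

    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def reference_split(ann: pd.DataFrame, cutoff: float = 500.0,
                    stage: str = "E32", method: str = "cutoff",
                    expr: pd.DataFrame | None = None
                    ) -> tuple[pd.Index, pd.Index]:
    """Split stage-``stage`` cells into reporter-low and reporter-high sets.

    With ``method="cutoff"`` (default) cells with ``egfp_intensity`` below
    ``cutoff`` go to the low set and cells at or above it to the high set.
    ``method="pca"`` instead 2-means-clusters the stage's cells in the first
    two principal components of ``expr`` and names the cluster with lower
    mean reporter intensity "low". Each side needs at least 3 cells.
    """
    cells = ann.index[ann["stage"] == stage]
    if method == "cutoff":
        intensity = ann.loc[cells, "egfp_intensity"]
        low = cells[intensity < cutoff]
        high = cells[intensity >= cutoff]
    elif method == "pca":
        if expr is None:
            raise ValueError("method='pca' requires an expression matrix")
        from sklearn.cluster import KMeans

        from .embedding import pca
        result = pca(expr[cells], n_components=2)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(result.scores.to_numpy())
        groups = pd.Series(km.labels_, index=cells)
        means = ann.loc[cells, "egfp_intensity"].groupby(groups).mean()
        low_cluster = means.idxmin()
        low = cells[groups == low_cluster]
        high = cells[groups != low_cluster]
    else:
        raise ValueError("method must be 'cutoff' or 'pca'")
    if len(low) < 3 or len(high) < 3:
        raise ValueError(
            "one-sided reporter split (need >= 3 cells per side); consider "
            "the 2-means fallback via method='pca'"
        )
    return low, high


def derive_signatures(de: DEResult, n_top: int = 50
                      ) -> tuple[LineageSignature, LineageSignature]:
    """Top ``n_top`` significant genes per direction from the low-vs-high
    reference DE (group A = reporter-low): genes up in A form the ICM
    signature, genes up in B the TE signature. Ties break by gene id."""
    icm_genes = de.top_genes("up_in_A", n_top)
    te_genes = de.top_genes("up_in_B", n_top)
    for name, got in (("ICM", icm_genes), ("TE", te_genes)):
        if len(got) < n_top:
            warnings.warn(f"only {len(got)} significant {name} signature genes "
                          f"available (requested {n_top})")
    return (LineageSignature("ICM", icm_genes, de),
            LineageSignature("TE", te_genes, de))


def _signature_scores(log_expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Mean per-gene-standardized log expression over a gene set."""
    sub = log_expr.loc[[g for g in genes if g in log_expr.index]]
    values = sub.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    return pd.Series(z.mean(axis=0), index=log_expr.columns)


def _spearman_distance(log_expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1 - Spearman rho between cell columns; constant cells flagged."""
    ranks = np.apply_along_axis(stats.rankdata, 0, log_expr)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    norms[constant] = 1.0
    corr = (centered.T @ centered) / np.outer(norms, norms)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist, constant


def assign_lineage(expr: pd.DataFrame, signatures, k: int = 3,
                   linkage_method: str = "ward") -> LineageAssignment:
    """Cluster cells on Spearman-correlation distance over the union of
    signature genes and label the ``k`` clusters by signature score.

    Expression is log10(RPKM + 1). Clusters are ranked by the difference
    between their mean TE and ICM scores: the highest is labelled TE, the
    lowest ICM, every other cluster CO. Cells with constant expression over
    the signature genes (undefined rank correlation) are labelled directly
    from their own scores, with a warning.
    """
    icm_sig, te_sig = signatures
    if icm_sig.lineage != "ICM":
        icm_sig, te_sig = te_sig, icm_sig
    union = list(dict.fromkeys(icm_sig.genes + te_sig.genes))
    if len(union) < 2:
        raise ValueError("need at least 2 signature genes")
    if expr.shape[1] < k:
        raise ValueError(f"need at least k={k} cells")

    present = [g for g in union if g in expr.index]
    log_expr = np.log10(expr.loc[present].to_numpy(dtype=float) + 1.0)
    log_frame = pd.DataFrame(log_expr, index=present, columns=expr.columns)

    dist, constant = _spearman_distance(log_expr)
    clusters = fcluster(linkage(squareform(dist, checks=False), method=linkage_method),
                        t=k, criterion="maxclust")
    clusters = pd.Series(clusters, index=expr.columns, name="cluster_id")

    icm_score = _signature_scores(log_frame, icm_sig.genes)
    te_score = _signature_scores(log_frame, te_sig.genes)
    delta = te_score - icm_score
    cluster_delta = delta.groupby(clusters).mean().sort_values()
    label_of_cluster = {c: "CO" for c in cluster_delta.index}
    label_of_cluster[cluster_delta.index[0]] = "ICM"
    label_of_cluster[cluster_delta.index[-1]] = "TE"
    labels = clusters.map(label_of_cluster)

    if constant.any():
        warnings.warn(f"{int(constant.sum())} cell(s) with constant expression "
                      "assigned by signature score alone")
        const_cells = expr.columns[constant]
        centers = delta.groupby(labels).mean()
        for cell in const_cells:
            labels.loc[cell] = (centers - delta.loc[cell]).abs().idxmin()

    table = pd.DataFrame(
        {"label": labels, "cluster_id": clusters,
         "icm_score": icm_score, "te_score": te_score}
    )
    return LineageAssignment(table=table)


def marker_panel_classify(expr: pd.DataFrame, panel: dict[str, list[str]],
                          k: int | None = None,
                          linkage_method: str = "ward") -> LineageAssignment:
    """Assign identities from two user-supplied marker gene lists (e.g. the
    derived ICM/TE signatures, or EPI/PE panels) by the same
    Spearman-correlation clustering as :func:`assign_lineage`.

    ``panel`` maps exactly two identity names to gene lists; with ``k``
    clusters (default: number of panels) the cluster with the highest mean
    second-minus-first panel score takes the second name, the lowest the
    first, and any remaining cluster is labelled CO.
    """
    if len(panel) != 2:
        raise ValueError("panel must name exactly two identities")
    if any(len(genes) == 0 for genes in panel.values()):
        raise ValueError("empty marker panel")
    (name_a, genes_a), (name_b, genes_b) = panel.items()
    k = k if k is not None else len(panel)
    sig_a = LineageSignature("ICM", list(genes_a))
    sig_b = LineageSignature("TE", list(genes_b))
    assignment = assign_lineage(expr, (sig_a, sig_b), k=k,
                                linkage_method=linkage_method)
    rename = {"ICM": name_a, "TE": name_b}
    table = assignment.table.copy()
    table["label"] = table["label"].map(lambda x: rename.get(x, x))
    table = table.rename(columns={"icm_score": f"{name_a}_score",
                                  "te_score": f"{name_b}_score"})
    return LineageAssignment(table=table)
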