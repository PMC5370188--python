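"""Deterministic PCA on log-transformed expression.

Cells are observations, genes are variables; expression enters as
log10(RPKM + 1) with per-gene centering and no unit-variance scaling by
default (gene admission is already governed by the variability statistic).
A fixed sign convention — each component oriented so that its
largest-magnitude gene loading is positive — makes the output independent
of the numerical backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca"]


@dataclass
class PCAResult:
    scores: pd.DataFrame             # cells x components
    loadings: pd.DataFrame           # genes x components
    variance_explained: np.ndarray   # fraction per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(expr: pd.DataFrame, n_components: int = 10, *,
        log_transform: bool = True, scale: bool = False) -> PCAResult:
    """Principal component analysis of cells on the supplied genes.

    Parameters
    ----------
    expr
        Gene x cell expression (RPKM); pass ``log_transform=False`` if the
        values are already on the scale to be decomposed.
    n_components
        Number of components to retain (capped by the data rank).
    scale
        Optionally divide each centered gene by its standard deviation.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("PCA requires at least 2 genes and 2 cells")
    x = expr.to_numpy(dtype=float).T  # cells x genes
    if log_transform:
        x = np.log10(x + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    total_var = (x**2).sum()
    if total_var <= 0:
        raise ValueError("expression matrix has zero total variance")
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
        total_var = (x**2).sum()

    n_components = min(n_components, min(x.shape) - (1 if x.shape[0] <= x.shape[1] else 0))
    n_components = max(n_components, 1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    u, s, vt = u[:, :k], s[:k], vt[:k]

    # Orient each component so its largest-magnitude loading is positive.
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=expr.columns, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=expr.index, columns=comp_names)
    variance_explained = (s**2) / total_var
    return PCAResult(scores=scores, loadings=loadings, variance_explained=variance_explained)
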