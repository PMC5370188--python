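"""Reporter-intensity arithmetic and the correlation/group-test utilities.

Nuclear reporter intensities are corrected for cytoplasmic background by
subtraction, and the nuclear-to-cytoplasmic ratio is reported where defined.
Corrected intensities are thresholded into low/high expression groups at a
fixed cutoff (boundary assigned to "high"). Correlations and group tests
wrap the standard parametric and rank-based procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ReporterMeasure", "reporter_measures", "egfp_threshold",
           "correlate", "group_test"]


@dataclass
class ReporterMeasure:
    cell_id: str
    nuclear_mean: float
    cytoplasmic_mean: float
    corrected: float            # nuclear - cytoplasmic; may be negative
    nc_ratio: float             # nuclear / cytoplasmic; NaN when undefined
    ratio_defined: bool


def reporter_measures(nuclear: float, cytoplasmic: float,
                      cell_id: str = "") -> ReporterMeasure:
    """Background-corrected intensity and nuclear/cytoplasmic ratio."""
    if nuclear < 0 or cytoplasmic < 0:
        raise ValueError("intensities must be non-negative")
    defined = cytoplasmic > 0
    return ReporterMeasure(
        cell_id=cell_id,
        nuclear_mean=float(nuclear),
        cytoplasmic_mean=float(cytoplasmic),
        corrected=float(nuclear - cytoplasmic),
        nc_ratio=float(nuclear / cytoplasmic) if defined else float("nan"),
        ratio_defined=bool(defined),
    )


def egfp_threshold(values, cutoff: float = 500.0) -> np.ndarray:
    """Label background-corrected intensities: >= cutoff -> "high",
    else "low"."""
    arr = np.asarray(values, dtype=float)
    return np.where(arr >= cutoff, "high", "low")


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def group_test(samples, test: str) -> tuple[float, float]:
    """Two-sided group comparison.

    ``samples`` is a sequence of per-group value arrays, except for
    ``test="chi_squared"`` where it is a complete contingency table. Tests:
    mann_whitney, kruskal_wallis, t, anova, chi_squared (no continuity
    correction).
    """
    if test == "chi_squared":
        table = np.asarray(samples, dtype=float)
        if table.ndim != 2 or np.isnan(table).any():
            raise ValueError("chi_squared requires a complete contingency table")
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)

    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney compares exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "kruskal_wallis":
        res = stats.kruskal(*groups)
    elif test == "t":
        if len(groups) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        res = stats.ttest_ind(groups[0], groups[1])
    elif test == "anova":
        res = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown test '{test}'")
    return float(res.statistic), float(res.pvalue)
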