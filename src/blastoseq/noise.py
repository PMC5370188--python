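"""Technical-noise calibration from spike-ins and the gene-variability
statistic used to pick PCA input genes.

Spike-in counts are modelled as negative binomial with a shared technical
overdispersion r: v = m + m^2/r, so cv^2(m) = 1/m + 1/r. The fit regresses
the spike-ins' excess squared coefficient of variation (cv^2 - 1/m) on a
constant with weights proportional to the spike-in mean; biological genes
never enter the technical fit. A gene's variability statistic is the log2
ratio of its observed cv^2 to the technical expectation at its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = ["NoiseFit", "fit_technical_noise", "variability_statistic", "top_variable_genes"]


@dataclass
class NoiseFit:
    """Fitted technical noise model cv^2(m) = 1/m + 1/r_tech."""

    inv_r_tech: float                 # 1/r; 0 means Poisson-limit noise
    spikein_table: pd.DataFrame       # per spike-in: mean, cv2, cv2_tech
    residual_rms: float               # goodness of fit on the spike-ins

    @property
    def r_tech(self) -> float:
        return np.inf if self.inv_r_tech == 0 else 1.0 / self.inv_r_tech

    def cv2_tech(self, mean):
        """Technical cv^2 at mean expression ``mean``."""
        m = np.asarray(mean, dtype=float)
        return 1.0 / m + self.inv_r_tech


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Per-cell totals scaled to their geometric mean."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("cells with zero spike-in counts cannot be normalized")
    return totals / np.exp(np.log(totals).mean())


def fit_technical_noise(spikein_counts: CountMatrix | pd.DataFrame) -> NoiseFit:
    """Estimate the technical overdispersion from spike-in counts.

    Requires at least 3 spike-in species with nonzero mean and at least 10
    cells. Counts are size-factor normalized (per-cell spike-in totals
    scaled to their geometric mean) before the moments are computed. A
    negative overdispersion estimate is clamped to the Poisson limit
    (1/r = 0) with a warning.
    """
    frame = spikein_counts.counts if isinstance(spikein_counts, CountMatrix) else spikein_counts
    if frame.shape[1] < 10:
        raise ValueError("technical fit needs at least 10 cells")
    raw = frame.to_numpy(dtype=float)
    sf = _size_factors(raw)
    norm = raw / sf[None, :]

    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    usable = m > 0
    if usable.sum() < 3:
        raise ValueError("technical fit needs at least 3 spike-ins with nonzero mean")
    m, v = m[usable], v[usable]
    cv2 = v / m**2

    # cv^2 - 1/m = 1/r for every spike-in; weighted least squares on a
    # constant with weights proportional to the mean (high-abundance
    # spike-ins estimate the plateau best).
    y = cv2 - 1.0 / m
    w = m
    inv_r = float((w * y).sum() / w.sum())
    if inv_r < 0:
        warnings.warn("negative overdispersion estimate clamped to Poisson (1/r = 0)")
        inv_r = 0.0

    cv2_tech = 1.0 / m + inv_r
    table = pd.DataFrame(
        {"mean": m, "cv2": cv2, "cv2_tech": cv2_tech},
        index=frame.index[usable],
    )
    rms = float(np.sqrt(np.mean((cv2 - cv2_tech) ** 2)))
    return NoiseFit(inv_r_tech=inv_r, spikein_table=table, residual_rms=rms)


def variability_statistic(counts: CountMatrix | pd.DataFrame, fit: NoiseFit,
                          form: str = "ratio") -> pd.DataFrame:
    """Mean-adjusted variability per biological gene.

    With ``form="ratio"`` (default) the statistic is
    log2(cv2_obs / cv2_tech(m)); ``form="difference"`` returns
    cv2_obs - cv2_tech(m). Genes with zero mean or expressed in fewer than
    2 cells are excluded. Counts are size-factor normalized on per-cell
    totals before moments are taken.
    """
    if form not in ("ratio", "difference"):
        raise ValueError("form must be 'ratio' or 'difference'")
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    raw = frame.to_numpy(dtype=float)
    sf = _size_factors(raw)
    norm = raw / sf[None, :]

    m = norm.mean(axis=1)
    expressed_cells = (raw > 0).sum(axis=1)
    keep = (m > 0) & (expressed_cells >= 2)
    m = m[keep]
    v = norm[keep].var(axis=1, ddof=1)
    cv2 = v / m**2
    cv2_tech = fit.cv2_tech(m)
    if form == "ratio":
        with np.errstate(divide="ignore"):
            stat = np.log2(cv2 / cv2_tech)
    else:
        stat = cv2 - cv2_tech
    return pd.DataFrame(
        {"mean": m, "cv2": cv2, "cv2_tech": cv2_tech, "statistic": stat},
        index=frame.index[keep],
    )


def top_variable_genes(scores: pd.DataFrame, n: int = 100) -> list[str]:
    """The ``n`` genes with the largest variability statistic, descending;
    ties broken lexicographically by gene id for determinism."""
    if n > scores.shape[0]:
        raise ValueError(f"requested {n} genes but only {scores.shape[0]} scored")
    ordered = scores.sort_index().sort_values("statistic", ascending=False, kind="stable")
    return ordered.index[:n].tolist()
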