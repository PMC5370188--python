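"""Synthetic single-cell RNA-seq data with the statistical structure of
ICM/TE lineage segregation in the preimplantation mouse embryo.

The generator emulates five developmental stages (early/late 16-cell,
early/late 32-cell, 64-cell) in which a co-expressing (CO) 16-cell state
bifurcates into inner-cell-mass (ICM) and trophectoderm (TE) transcriptional
profiles. Counts are negative-binomial with logistic dropout concentrated at
low expression; spike-ins have constant expected input per cell with purely
technical overdispersion; a fluorescence reporter channel (the Cdx2-eGFP
analogue) is coupled to the mRNA of one TE signature gene. Ground-truth
lineage labels are recorded for recovery tests and are never visible to the
analysis modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .containers import STAGES, CountMatrix

__all__ = [
    "SimConfig",
    "generate_dataset",
    "generate_null_pair",
    "generate_spikein_counts",
    "generate_variability_dataset",
]


def _default_cells_per_stage() -> Dict[str, int]:
    return {"E16": 70, "L16": 43, "E32": 49, "L32": 39, "C64": 61}


def _default_frac_16cell() -> Dict[str, float]:
    return {"ICM": 33 / 113, "TE": 24 / 113, "CO": 56 / 113}


def _default_post_bifurcation_icm() -> Dict[str, int]:
    # ICM cell counts after the bifurcation; late-32 (18) and 64-cell (33)
    # match the observed compositions, early-32 is an interpolation.
    return {"E32": 22, "L32": 18, "C64": 33}


def _default_te_effect() -> Dict[str, float]:
    # TE profile is fully established from the 16-cell stage onward.
    return {s: 2.0 for s in STAGES}


def _default_icm_effect() -> Dict[str, float]:
    # ICM profile matures gradually, reaching full strength at the 64-cell
    # stage, mirroring the asymmetric stabilisation of the two lineages.
    return {"E16": 1.0, "L16": 1.4, "E32": 1.8, "L32": 2.0, "C64": 2.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo time-course.

    Defaults reproduce the study conditions: 262 cells over five stages
    (70/43/49/39/61) from 36 embryos, 16-cell ICM/TE/CO fractions of
    33/24/56 out of 113, 2000 biological genes of which 100 are truly
    TE-specific and 100 truly ICM-specific, 92 spike-in species, and a
    reporter channel targeting a protein-mRNA Pearson correlation of 0.66
    with TE and ICM cells straddling the 500-intensity-unit cutoff.
    """

    n_genes: int = 2000
    n_spikeins: int = 92
    cells_per_stage: Dict[str, int] = field(default_factory=_default_cells_per_stage)
    n_embryos: int = 36
    frac_16cell: Dict[str, float] = field(default_factory=_default_frac_16cell)
    post_bifurcation_icm: Dict[str, int] = field(default_factory=_default_post_bifurcation_icm)
    n_te_signature: int = 100
    n_icm_signature: int = 100
    te_effect_log2: Dict[str, float] = field(default_factory=_default_te_effect)
    icm_effect_log2: Dict[str, float] = field(default_factory=_default_icm_effect)
    nb_dispersion: float = 0.1
    dropout_midpoint: float = 0.0  # ln(expected count) at which dropout = 50%
    dropout_slope: float = 1.0
    spikein_overdispersion: float = 10.0
    reporter_coupling: float = 0.66
    reporter_baseline_mean: float = 50.0
    reporter_scale: float = 700.0  # intensity units across the ICM-TE latent gap
    library_size_sigma: float = 0.3
    gene_mean_log_mu: float = 1.0  # natural-log scale of baseline mean counts
    gene_mean_log_sigma: float = 1.5
    embryo_effect_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_spikeins", "n_embryos", "n_te_signature", "n_icm_signature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.cells_per_stage.values()):
            raise ValueError("cells_per_stage entries must be positive")
        if set(self.cells_per_stage) - set(STAGES):
            raise ValueError("cells_per_stage keys must be developmental stages")
        if not np.isclose(sum(self.frac_16cell.values()), 1.0):
            raise ValueError("frac_16cell proportions must sum to 1")
        if self.nb_dispersion <= 0 or self.spikein_overdispersion <= 0:
            raise ValueError("dispersions must be positive")
        if not -1.0 <= self.reporter_coupling <= 1.0:
            raise ValueError("reporter_coupling must lie in [-1, 1]")
        for sched in (self.te_effect_log2, self.icm_effect_log2):
            if any(v < 0 for v in sched.values()):
                raise ValueError("effect schedules must be non-negative")
        if self.n_te_signature + self.n_icm_signature > self.n_genes:
            raise ValueError("more signature genes than genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with variance m + dispersion * m^2."""
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def _assign_lineages(rng: np.random.Generator, config: SimConfig,
                     stages: np.ndarray) -> np.ndarray:
    lineage = np.empty(stages.shape, dtype=object)
    is16 = np.isin(stages, ("E16", "L16"))
    n16 = int(is16.sum())
    n_icm = int(round(config.frac_16cell["ICM"] * n16))
    n_te = int(round(config.frac_16cell["TE"] * n16))
    labels16 = np.array(["ICM"] * n_icm + ["TE"] * n_te + ["CO"] * (n16 - n_icm - n_te))
    lineage[is16] = rng.permutation(labels16)
    for stage in ("E32", "L32", "C64"):
        mask = stages == stage
        n = int(mask.sum())
        if n == 0:
            continue
        k = config.post_bifurcation_icm.get(stage, int(round(0.45 * n)))
        k = min(k, n)
        labels = np.array(["ICM"] * k + ["TE"] * (n - k))
        lineage[mask] = rng.permutation(labels)
    return lineage


def _reporter_channel(rng: np.random.Generator, config: SimConfig,
                      latent_log10: np.ndarray, observed_log10: np.ndarray,
                      lineage: np.ndarray, stages: np.ndarray) -> np.ndarray:
    """Protein intensity coupled to the reporter gene's latent expression.

    The coupling runs through the cell's latent (noise-free) log mean, and
    the additive Gaussian noise variance is solved on the realized draws so
    that the population Pearson correlation with the *observed* log mRNA
    equals the configured target. This mirrors a stable protein that
    integrates over transcriptional noise: the channel separates lineages
    sharply even though its correlation with instantaneous mRNA is moderate.
    """
    post = np.isin(stages, ("E32", "L32", "C64"))
    mean_icm = latent_log10[post & (lineage == "ICM")].mean()
    mean_te = latent_log10[post & (lineage == "TE")].mean()
    gap = mean_te - mean_icm
    if gap <= 0:
        warnings.warn("reporter gene shows no ICM-TE gap; channel uncalibrated")
        gap = max(latent_log10.std(), 1e-6)
    slope = config.reporter_scale / gap
    center = 0.5 * (mean_te + mean_icm)
    raw = 500.0 + slope * (latent_log10 - center)
    rho = config.reporter_coupling
    noise = rng.standard_normal(raw.size)
    if rho == 0 or observed_log10.std() == 0:
        return raw + config.reporter_scale / 4 * noise

    def coupling(t: float) -> float:
        return float(np.corrcoef(raw + t * noise, observed_log10)[0, 1])

    if raw.std() == 0 or not np.isfinite(coupling(0.0)):
        warnings.warn("reporter gene carries no expression signal; emitting "
                      "an uninformative channel")
        return raw + config.reporter_scale / 4 * noise
    if coupling(0.0) <= rho:
        warnings.warn(
            "requested reporter coupling exceeds the latent-observed mRNA "
            "correlation; emitting a noise-free channel"
        )
        return raw
    # Noise scale solved on the realized draws so the population Pearson
    # correlation with observed log mRNA equals the target exactly.
    hi = config.reporter_scale
    while coupling(hi) > rho and hi < 1e6 * config.reporter_scale:
        hi *= 2.0
    from scipy.optimize import brentq
    t = brentq(lambda t: coupling(t) - rho, 0.0, hi, xtol=1e-9)
    return raw + t * noise


def generate_dataset(config: SimConfig | None = None
                     ) -> Tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate counts, gene metadata and cell annotations.

    Returns
    -------
    counts : CountMatrix
        Biological genes followed by spike-ins, genes x cells.
    genes : DataFrame
        Indexed by gene id with ``exon_model_length_bp``, ``is_spikein``,
        ``true_lineage_role`` ({TE_sig, ICM_sig, neutral}) and
        ``is_reporter`` (the single Cdx2-analogue gene).
    cells : DataFrame
        Indexed by cell id with ``embryo_id``, ``stage``, ``egfp_intensity``,
        ``mapping_rate`` and the ground-truth ``true_lineage``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"gene-{i:04d}" for i in range(1, config.n_genes + 1)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(1, config.n_spikeins + 1)]

    lengths = np.exp(rng.uniform(np.log(500), np.log(10000), config.n_genes)).round().astype(int)
    spike_lengths = rng.integers(250, 2001, config.n_spikeins)

    roles = np.array(["neutral"] * config.n_genes, dtype=object)
    sig_idx = rng.choice(config.n_genes, config.n_te_signature + config.n_icm_signature,
                         replace=False)
    te_idx = sig_idx[: config.n_te_signature]
    icm_idx = sig_idx[config.n_te_signature:]
    roles[te_idx] = "TE_sig"
    roles[icm_idx] = "ICM_sig"
    reporter_idx = int(te_idx[0])

    base_log = rng.normal(config.gene_mean_log_mu, config.gene_mean_log_sigma, config.n_genes)
    base_mean = np.exp(base_log)
    base_mean[reporter_idx] = config.reporter_baseline_mean

    stage_list = [s for s in STAGES if s in config.cells_per_stage]
    stages = np.concatenate([[s] * config.cells_per_stage[s] for s in stage_list])
    n_cells = stages.size
    cell_ids = [f"cell-{i:04d}" for i in range(1, n_cells + 1)]
    lineage = _assign_lineages(rng, config, stages)

    # Embryos partitioned across stages proportionally to cell counts.
    stage_sizes = np.array([config.cells_per_stage[s] for s in stage_list], dtype=float)
    embryo_share = np.maximum(1, np.round(stage_sizes / stage_sizes.sum() * config.n_embryos)).astype(int)
    embryo_ids = np.empty(n_cells, dtype=object)
    next_embryo = 1
    pos = 0
    for size, share in zip(stage_sizes.astype(int), embryo_share):
        pool = [f"embryo-{e:02d}" for e in range(next_embryo, next_embryo + share)]
        embryo_ids[pos: pos + size] = np.resize(pool, size)
        next_embryo += share
        pos += size

    # Per-cell per-gene log2 effects: TE genes up in TE cells, ICM genes up
    # in ICM cells, CO cells at the arithmetic midpoint of the two lineage
    # log-means.
    effect = np.zeros((config.n_genes, n_cells))
    for j in range(n_cells):
        st, lin = stages[j], lineage[j]
        te_e = config.te_effect_log2.get(st, 0.0)
        icm_e = config.icm_effect_log2.get(st, 0.0)
        if lin == "TE":
            effect[te_idx, j] = te_e
        elif lin == "ICM":
            effect[icm_idx, j] = icm_e
        else:  # CO
            effect[te_idx, j] = 0.5 * te_e
            effect[icm_idx, j] = 0.5 * icm_e

    lib = np.exp(rng.normal(0.0, config.library_size_sigma, n_cells))
    if config.embryo_effect_sigma > 0:
        shift = {e: rng.normal(0.0, config.embryo_effect_sigma)
                 for e in pd.unique(embryo_ids)}
        lib = lib * np.exp(np.array([shift[e] for e in embryo_ids]))

    biology_mean = base_mean[:, None] * np.exp2(effect)
    mean = biology_mean * lib[None, :]
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    # Logistic dropout decreasing in log expected count.
    with np.errstate(divide="ignore"):
        logm = np.log(np.maximum(mean, 1e-12))
    p_drop = 1.0 / (1.0 + np.exp(config.dropout_slope * (logm - config.dropout_midpoint)))
    counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    spike_counts, spike_means = generate_spikein_counts(
        config.n_spikeins, n_cells, config.spikein_overdispersion,
        rng=rng, return_means=True)

    all_counts = pd.DataFrame(
        np.vstack([counts, spike_counts]).astype(np.int64),
        index=pd.Index(gene_ids + spike_ids, name="gene_id"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )

    mapping_rate = rng.uniform(0.55, 0.95, n_cells)
    assigned = all_counts.sum(axis=0).to_numpy()
    total_mapped = np.ceil(assigned / mapping_rate).astype(np.int64)

    # Latent reporter abundance: the cell's biological expected transcript
    # count. Library scaling, counting noise and dropout are sequencing
    # artifacts that arise after the protein was measured, so they enter
    # only the observed mRNA readout.
    latent = np.log10(1.0 + biology_mean[reporter_idx, :])
    observed = np.log10(1.0 + counts[reporter_idx, :])
    egfp = _reporter_channel(rng, config, latent, observed, lineage, stages)

    genes = pd.DataFrame(
        {
            "exon_model_length_bp": np.concatenate([lengths, spike_lengths]),
            "is_spikein": [False] * config.n_genes + [True] * config.n_spikeins,
            "true_lineage_role": list(roles) + ["neutral"] * config.n_spikeins,
            "is_reporter": [i == reporter_idx for i in range(config.n_genes)]
            + [False] * config.n_spikeins,
            "true_mean": np.concatenate([base_mean, spike_means]),
        },
        index=all_counts.index,
    )
    cells = pd.DataFrame(
        {
            "embryo_id": embryo_ids,
            "stage": stages,
            "egfp_intensity": egfp,
            "mapping_rate": mapping_rate,
            "true_lineage": lineage,
        },
        index=all_counts.columns,
    )
    cm = CountMatrix(all_counts, pd.Series(total_mapped, index=all_counts.columns))
    return cm, genes, cells


def generate_null_pair(n_cells_per_group: int, n_genes: int,
                       nb_dispersion: float, seed: int
                       ) -> Tuple[CountMatrix, pd.Series]:
    """Two equal-size cell groups drawn from one negative-binomial model.

    There are no true differentially expressed genes; group labels ("A"/"B")
    are attached for downstream type-I-error studies of the DE test.
    """
    if n_cells_per_group <= 0 or n_genes <= 0:
        raise ValueError("cell and gene counts must be positive")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    base_mean = np.exp(rng.normal(1.0, 1.5, n_genes))
    n_cells = 2 * n_cells_per_group
    counts = _nb_draw(rng, np.broadcast_to(base_mean[:, None], (n_genes, n_cells)).copy(),
                      nb_dispersion)
    frame = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index([f"gene-{i:04d}" for i in range(1, n_genes + 1)], name="gene_id"),
        columns=pd.Index([f"cell-{i:04d}" for i in range(1, n_cells + 1)], name="cell_id"),
    )
    labels = pd.Series(["A"] * n_cells_per_group + ["B"] * n_cells_per_group,
                       index=frame.columns, name="group")
    return CountMatrix(frame), labels


def generate_spikein_counts(n_spikeins: int, n_cells: int, r_tech: float,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            mean_range: Tuple[float, float] = (2.0, 500.0),
                            return_means: bool = False):
    """Spike-in counts with constant expected input per cell and purely
    technical negative-binomial overdispersion ``r_tech``
    (cv^2 = 1/m + 1/r_tech)."""
    if n_spikeins <= 0 or n_cells <= 0 or r_tech <= 0:
        raise ValueError("arguments must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    means = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_spikeins))
    mean_mat = np.broadcast_to(means[:, None], (n_spikeins, n_cells)).copy()
    counts = _nb_draw(rng, mean_mat, 1.0 / r_tech)
    if return_means:
        return counts, means
    frame = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index([f"ERCC-{i:05d}" for i in range(1, n_spikeins + 1)], name="gene_id"),
        columns=pd.Index([f"cell-{i:04d}" for i in range(1, n_cells + 1)], name="cell_id"),
    )
    return CountMatrix(frame)


def generate_variability_dataset(n_genes: int = 2000, n_planted: int = 100,
                                 variance_fold: float = 4.0, n_cells: int = 200,
                                 n_spikeins: int = 92, r_tech: float = 10.0,
                                 seed: int = 0
                                 ) -> Tuple[CountMatrix, pd.DataFrame]:
    """Counts in which most genes follow the technical noise model exactly
    and ``n_planted`` genes carry extra biological variability, inflating
    their cv^2 to ``variance_fold`` times the technical expectation at their
    mean. Spike-ins are included so the technical fit can be recomputed.
    """
    if not 0 < n_planted <= n_genes:
        raise ValueError("n_planted must lie in (0, n_genes]")
    if variance_fold < 1.0:
        raise ValueError("variance_fold must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.exp(rng.uniform(np.log(5.0), np.log(500.0), n_genes))
    planted = rng.choice(n_genes, n_planted, replace=False)
    mean_mat = np.broadcast_to(means[:, None], (n_genes, n_cells)).copy()

    cv2_tech = 1.0 / means[planted] + 1.0 / r_tech
    extra = (variance_fold - 1.0) * cv2_tech / (1.0 + cv2_tech)
    sigma2 = np.log1p(extra)
    factors = np.exp(rng.normal(0.0, 1.0, (n_planted, n_cells))
                     * np.sqrt(sigma2)[:, None] - 0.5 * sigma2[:, None])
    mean_mat[planted] *= factors

    counts = _nb_draw(rng, mean_mat, 1.0 / r_tech)
    spike_counts, spike_means = generate_spikein_counts(
        n_spikeins, n_cells, r_tech, rng=rng, return_means=True)

    gene_ids = [f"gene-{i:04d}" for i in range(1, n_genes + 1)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(1, n_spikeins + 1)]
    frame = pd.DataFrame(
        np.vstack([counts, spike_counts]).astype(np.int64),
        index=pd.Index(gene_ids + spike_ids, name="gene_id"),
        columns=pd.Index([f"cell-{i:04d}" for i in range(1, n_cells + 1)], name="cell_id"),
    )
    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[planted] = True
    genes = pd.DataFrame(
        {
            "exon_model_length_bp": np.full(n_genes + n_spikeins, 1000),
            "is_spikein": [False] * n_genes + [True] * n_spikeins,
            "is_planted": list(is_planted) + [False] * n_spikeins,
        },
        index=frame.index,
    )
    return CountMatrix(frame), genes
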