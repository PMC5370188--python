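"""Stage-wise DEG dynamics, hypergeometric overlap, and peak-to-gene
assignment."""

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blastoseq as bs


# ---------------------------------------------------------------- dynamics

def test_dynamics_on_default_data(default_dataset, default_assignment):
    counts, genes, cells = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dyn = bs.deg_dynamics(counts, default_assignment, cells)
    between = dyn.between_lineage.set_index(["stage", "pair"])["n_deg"]
    # lineages differ strongly at every post-bifurcation stage
    for stage in ("E32", "L32", "C64"):
        assert between.get((stage, "ICM-TE"), 0) > 50
    assert (dyn.between_lineage["n_deg"]
            == dyn.between_lineage["genes"].str.len()).all()

    # TE stabilizes early: its 16-cell -> early-32 transition shows fewer
    # DEGs than the still-maturing ICM's
    within = dyn.within_lineage.set_index(["lineage", "stage_pair"])["n_deg"]
    assert within.get(("TE", "16-E32"), 0) < within.get(("ICM", "16-E32"), 0)


def test_dynamics_alpha_zero_yields_no_degs(default_dataset, default_assignment):
    counts, _, cells = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dyn = bs.deg_dynamics(counts, default_assignment, cells, alpha=0.0)
    assert (dyn.between_lineage["n_deg"] == 0).all()
    assert (dyn.within_lineage["n_deg"] == 0).all()


def test_dynamics_near_null_without_effects():
    cfg = bs.SimConfig(seed=9,
                       te_effect_log2={s: 0.0 for s in bs.STAGES},
                       icm_effect_log2={s: 0.0 for s in bs.STAGES})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, genes, cells = bs.generate_dataset(cfg)
        table = pd.DataFrame({"label": cells["true_lineage"]})
        dyn = bs.deg_dynamics(counts, bs.LineageAssignment(table=table), cells)
    # no lineage effects -> DEG counts stay at the false-positive floor
    assert dyn.between_lineage["n_deg"].max() <= 20
    assert dyn.within_lineage["n_deg"].max() <= 20


# ---------------------------------------------------------- hypergeometric

def test_hypergeom_exact_enumeration_small_case():
    test = bs.hypergeom_overlap(4, 4, 5, 10)
    assert test.p_upper == pytest.approx(
        math.comb(5, 4) * math.comb(5, 0) / math.comb(10, 4), abs=1e-15)
    # full brute-force enumeration over subsets of a 10-element universe
    universe = range(10)
    annotated = set(range(5))
    hits = sum(1 for query in combinations(universe, 4)
               if len(set(query) & annotated) >= 4)
    assert test.p_upper == pytest.approx(hits / math.comb(10, 4), abs=1e-15)


def test_hypergeom_degenerate_and_validation():
    test = bs.hypergeom_overlap(4, 4, 10, 10)
    assert test.p_upper == pytest.approx(1.0)
    assert test.p_lower == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bs.hypergeom_overlap(5, 4, 10, 10)
    with pytest.raises(ValueError):
        bs.hypergeom_overlap(1, 4, 11, 10)


def test_hypergeom_study_scale_parameters():
    test = bs.hypergeom_overlap(162, 404, 8190, 18388)
    assert test.expected == pytest.approx(179.94, abs=0.05)
    assert 0 < test.p_lower < 1 and 0 < test.p_upper < 1
    # the observed overlap sits below expectation, so the depletion tail is
    # the small one
    assert test.p_min == test.p_lower


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_hypergeom_tail_identities(data):
    N = data.draw(st.integers(2, 60))
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
    t = bs.hypergeom_overlap(k, n, K, N)
    assert t.p_lower + t.p_upper >= 1.0 - 1e-12
    if k > max(0, n + K - N):
        prev = bs.hypergeom_overlap(k - 1, n, K, N)
        assert t.p_upper + prev.p_lower == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ peaks

def _brute_force(peaks, genes):
    out = set()
    for _, p in peaks.iterrows():
        for _, g in genes.iterrows():
            if g["chrom"] == p["chrom"] and g["start"] < p["end"] and g["end"] > p["start"]:
                out.add(g["name"])
        for side in ("left", "right"):
            best, best_d = None, None
            for _, g in genes.sort_values(["start"]).iterrows():
                if g["chrom"] != p["chrom"]:
                    continue
                if g["start"] < p["end"] and g["end"] > p["start"]:
                    continue
                if side == "left" and g["end"] <= p["start"]:
                    d = p["start"] - g["end"]
                elif side == "right" and g["start"] >= p["end"]:
                    d = g["start"] - p["end"]
                else:
                    continue
                if best_d is None or d < best_d:
                    best, best_d = g["name"], d
            if best is not None:
                out.add(best)
    return out


def test_peak_inside_gene_and_flanking_rules():
    genes = pd.DataFrame({"chrom": ["chr1"] * 3,
                          "start": [100, 1000, 2000],
                          "end": [400, 1400, 2400],
                          "name": ["gA", "gB", "gC"]})
    inside = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [200]})
    # overlapped gene plus its nearest neighbour on the free side
    assert bs.peaks_to_genes(inside, genes) == {"gA", "gB"}
    between = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
    assert bs.peaks_to_genes(between, genes) == {"gA", "gB"}


def test_malformed_interval_rejected():
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [50],
                          "name": ["gA"]})
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
    with pytest.raises(ValueError, match="start >= end"):
        bs.peaks_to_genes(peaks, genes)


def test_peaks_to_genes_matches_quadratic_oracle():
    rng = np.random.default_rng(42)
    starts = rng.integers(0, 100_000, 200)
    genes = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 200),
                          "start": starts,
                          "end": starts + rng.integers(200, 5000, 200),
                          "name": [f"gene{i}" for i in range(200)]})
    pstarts = rng.integers(0, 100_000, 50)
    peaks = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 50),
                          "start": pstarts,
                          "end": pstarts + rng.integers(50, 1000, 50)})
    assert bs.peaks_to_genes(peaks, genes) == _brute_force(peaks, genes)


def test_peaks_order_invariance_and_monotonicity():
    rng = np.random.default_rng(7)
    starts = rng.integers(0, 50_000, 80)
    genes = pd.DataFrame({"chrom": ["chr1"] * 80, "start": starts,
                          "end": starts + rng.integers(100, 2000, 80),
                          "name": [f"g{i}" for i in range(80)]})
    pstarts = rng.integers(0, 50_000, 20)
    peaks = pd.DataFrame({"chrom": ["chr1"] * 20, "start": pstarts,
                          "end": pstarts + rng.integers(50, 500, 20)})
    shuffled = peaks.sample(frac=1, random_state=1).reset_index(drop=True)
    full = bs.peaks_to_genes(peaks, genes)
    assert bs.peaks_to_genes(shuffled, genes) == full
    assert bs.peaks_to_genes(peaks.iloc[:10], genes) <= full
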