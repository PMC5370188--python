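"""RPKM arithmetic, gene/cell filters and their invariants, PCA outlier
flagging."""

import warnings

import numpy as np
import pandas as pd
import pytest

import blastoseq as bs
from blastoseq.containers import CountMatrix


def _tiny_counts(values, lengths, totals):
    frame = pd.DataFrame(values,
                         index=[f"g{i}" for i in range(len(values))],
                         columns=[f"c{i}" for i in range(len(values[0]))])
    cm = CountMatrix(frame, pd.Series(totals, index=frame.columns))
    lens = pd.Series(lengths, index=frame.index, name="exon_model_length_bp")
    return cm, lens


@pytest.mark.parametrize("count,length,total,expected", [
    (10, 2000, 1_000_000, 5.0),
    (0, 1234, 1_000_000, 0.0),
    (20, 500, 2_000_000, 20.0),
])
def test_rpkm_formula(count, length, total, expected):
    cm, lens = _tiny_counts([[count]], [length], [total])
    assert bs.rpkm(cm, lens).iloc[0, 0] == pytest.approx(expected)


def test_rpkm_errors_name_offending_cell():
    cm, lens = _tiny_counts([[0, 1]], [1000], [0, 100])
    with pytest.raises(ValueError, match="c0"):
        bs.rpkm(cm, lens)


def test_rpkm_conservation(default_dataset, default_expr):
    counts, genes, _ = default_dataset
    kb = genes["exon_model_length_bp"].to_numpy() / 1e3
    recovered = (default_expr.to_numpy() * kb[:, None]).sum(axis=0)
    expected = 1e6 * counts.counts.sum(axis=0).to_numpy() / counts.total_mapped_reads.to_numpy()
    np.testing.assert_allclose(recovered, expected, rtol=1e-9)


def test_filter_genes_boundaries():
    expr = pd.DataFrame(
        [[1.5, 1.5, 0.0],   # >1 in exactly 2 cells -> retained
         [1.0, 1.0, 1.0],   # never strictly >1 -> removed
         [100.0, 0.0, 0.0]],  # 1 cell only -> removed
        index=["keep", "at_cutoff", "single"],
        columns=["c1", "c2", "c3"])
    kept = bs.filter_genes(expr)
    assert list(kept) == ["keep"]


def test_filter_genes_excludes_spikeins():
    expr = pd.DataFrame([[5.0, 5.0], [5.0, 5.0]], index=["g1", "ERCC-1"],
                        columns=["c1", "c2"])
    flags = pd.Series([False, True], index=expr.index)
    assert list(bs.filter_genes(expr, spikein_flags=flags)) == ["g1"]


def test_filter_cells_reasons_and_pass():
    rng = np.random.default_rng(0)
    base = rng.lognormal(1, 1, size=(200, 1))
    expr = pd.DataFrame(np.repeat(base, 5, axis=1) + rng.normal(0, .01, (200, 5)),
                        index=[f"g{i}" for i in range(200)],
                        columns=[f"c{i}" for i in range(5)])
    expr.iloc[150:, 3] = 0.0          # c3 expresses too few genes
    ann = pd.DataFrame({"mapping_rate": [0.9, 0.9, 0.39, 0.9, 0.9]},
                       index=expr.columns)
    kept, report = bs.filter_cells(expr, ann, min_genes=160, min_map=0.40,
                                   min_corr=0.5, expression_cutoff=0.5)
    assert report.cells.loc["c2", "reason"] == "mapping"
    assert report.cells.loc["c3", "reason"] == "min_genes"
    assert set(kept) == {"c0", "c1", "c4"}
    assert report.n_cells_retained == 3


def test_filter_cells_identical_cells_all_pass():
    col = np.arange(1, 51, dtype=float)
    expr = pd.DataFrame(np.tile(col[:, None], (1, 4)),
                        index=[f"g{i}" for i in range(50)],
                        columns=list("abcd"))
    ann = pd.DataFrame({"mapping_rate": [0.9] * 4}, index=expr.columns)
    kept, report = bs.filter_cells(expr, ann, min_genes=10, min_corr=0.8,
                                   expression_cutoff=0.5)
    assert list(kept) == list("abcd")
    assert np.allclose(report.cells["median_spearman"], 1.0)


def test_filters_idempotent_and_order_invariant(default_dataset, default_expr):
    _, genes, cells = default_dataset
    kept_genes = bs.filter_genes(default_expr, spikein_flags=genes["is_spikein"])
    again = bs.filter_genes(default_expr.loc[kept_genes],
                            spikein_flags=genes["is_spikein"])
    assert list(again) == list(kept_genes)

    kept_cells, _ = bs.filter_cells(default_expr, cells, min_genes=500,
                                    min_corr=0.5, genes=kept_genes)
    twice, _ = bs.filter_cells(default_expr[kept_cells], cells, min_genes=500,
                               min_corr=0.5, genes=kept_genes)
    assert list(twice) == list(kept_cells)

    # permuting cell columns permutes but does not change decisions
    rng = np.random.default_rng(3)
    perm = rng.permutation(default_expr.columns)
    kept_perm, _ = bs.filter_cells(default_expr[perm], cells, min_genes=500,
                                   min_corr=0.5, genes=kept_genes)
    assert set(kept_perm) == set(kept_cells)


def test_filter_cells_warns_below_three_cells():
    expr = pd.DataFrame([[2.0, 2.0]], index=["g1"], columns=["c1", "c2"])
    ann = pd.DataFrame({"mapping_rate": [0.9, 0.9]}, index=expr.columns)
    with pytest.warns(UserWarning, match="fewer than 3 cells"):
        kept, _ = bs.filter_cells(expr, ann, min_genes=1, expression_cutoff=0.5)
    assert len(kept) == 2


def test_pca_outlier_flags_displaced_cell():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.lognormal(1, 0.2, size=(100, 50)),
                        index=[f"g{i}" for i in range(100)],
                        columns=[f"c{i}" for i in range(50)])
    cloud_radius = np.log10(expr + 1).std(axis=1).mean()
    expr.iloc[:, 0] = expr.iloc[:, 0] * 10 ** (100 * cloud_radius)
    ann = pd.DataFrame({"stage": ["E16"] * 50}, index=expr.columns)
    flagged = bs.flag_pca_outliers(expr, ann)
    assert "c0" in flagged


def test_pca_outlier_none_when_identical_or_infinite_mads():
    expr = pd.DataFrame(np.ones((20, 10)), index=[f"g{i}" for i in range(20)],
                        columns=[f"c{i}" for i in range(10)])
    ann = pd.DataFrame({"stage": ["E16"] * 10}, index=expr.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert len(bs.flag_pca_outliers(expr, ann)) == 0

    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.lognormal(1, 1, size=(50, 20)),
                        index=[f"g{i}" for i in range(50)],
                        columns=[f"c{i}" for i in range(20)])
    ann = pd.DataFrame({"stage": ["L16"] * 20}, index=expr.columns)
    assert len(bs.flag_pca_outliers(expr, ann, n_mads=np.inf)) == 0
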