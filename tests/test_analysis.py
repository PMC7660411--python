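"""Significant-gene calling, gene-list comparison, and DGE overlap."""

import numpy as np
import pandas as pd
import pytest

from perturbgen.analysis import (DGETable, DirectionSemantics,
                                 dge_overlap, format_dge_overlap,
                                 overlap_ratio, pairwise_overlap_matrix,
                                 perturbation_histogram, rank_gene_extremes,
                                 read_dge_table, significant_genes)

RNG = np.random.default_rng(777)


# -- significant_genes --------------------------------------------------


def test_zero_vector_yields_no_significant_genes():
    res = significant_genes(np.zeros(50), k=2)
    assert res.positive_genes == [] and res.negative_genes == []


def test_single_outlier_gene_detected():
    """99 silent genes and one at 0.9: mean 0.009, population sd
    sqrt(0.81/100 - 0.009^2) ~= 0.0895, so only the outlier clears
    mean + 2 sd."""
    P = np.zeros(100)
    P[42] = 0.9
    res = significant_genes(P, k=2, gene_ids=[f"g{i}" for i in range(100)])
    assert res.mean == pytest.approx(0.009)
    assert res.sd == pytest.approx(np.sqrt(0.81 / 100 - 0.009 ** 2))
    assert res.positive_genes == ["g42"]
    assert res.negative_genes == []


def test_k_zero_strict_inequalities():
    res = significant_genes(np.array([-1.0, 0.0, 1.0]), k=0,
                            gene_ids=["g1", "g2", "g3"])
    assert res.positive_genes == ["g3"]
    assert res.negative_genes == ["g1"]  # g2 sits exactly at the mean


def test_constant_vector_warns_and_returns_empty(caplog):
    res = significant_genes(np.full(10, 0.3), k=2)
    assert res.positive_genes == [] and res.negative_genes == []
    assert any("constant" in r.message for r in caplog.records)


def test_direction_semantics_mapping():
    P = np.array([0.5] + [0.0] * 99)
    P[1] = -0.5
    res_tn = significant_genes(P, k=2, semantics="tumor_to_normal",
                               gene_ids=[f"g{i}" for i in range(100)])
    # perturbing tumor toward normal: a positive shift marks a gene LOW in
    # the tumor, i.e. tumor-downregulated
    assert res_tn.tumor_downregulated == ["g0"]
    assert res_tn.tumor_upregulated == ["g1"]
    res_nt = significant_genes(P, k=2, semantics="normal_to_tumor",
                               gene_ids=[f"g{i}" for i in range(100)])
    assert res_nt.tumor_upregulated == ["g0"]
    assert res_nt.tumor_downregulated == ["g1"]


def test_two_sigma_rate_on_gaussian_noise():
    """For i.i.d. Gaussian perturbations the 2-sigma rule flags ~4.55% of
    genes (two-sided tail mass)."""
    P = np.random.default_rng(123).standard_normal(10_000)
    res = significant_genes(P, k=2)
    rate = (len(res.positive_genes) + len(res.negative_genes)) / 10_000
    assert abs(rate - 0.0455) < 0.015


def test_significance_lists_sorted_by_deviation():
    P = np.array([0.0] * 96 + [0.5, 0.9, -0.6, -0.8])
    ids = [f"g{i}" for i in range(100)]
    res = significant_genes(P, k=1, gene_ids=ids)
    assert res.positive_genes == ["g97", "g96"]
    assert res.negative_genes == ["g99", "g98"]


# -- rank_gene_extremes -------------------------------------------------


def test_rank_gene_extremes_examples():
    P = np.array([0.3, -0.1, 0.5])
    ids = ["g1", "g2", "g3"]
    assert rank_gene_extremes(P, 2, "up", gene_ids=ids) == ["g3", "g1"]
    assert rank_gene_extremes(P, 2, "down", gene_ids=ids) == ["g2", "g1"]
    with pytest.raises(ValueError, match="exceeds"):
        rank_gene_extremes(P, 4, "up", gene_ids=ids)


def test_rank_gene_extremes_full_sort_oracle_and_ties():
    vals = RNG.choice([-0.2, -0.1, 0.0, 0.1, 0.2], size=30)
    ids = [f"g{i:02d}" for i in range(30)]
    up = rank_gene_extremes(vals, 30, "up", gene_ids=ids)
    oracle = [g for _, g in sorted(zip(vals, ids), key=lambda t: (-t[0], t[1]))]
    assert up == oracle
    down = rank_gene_extremes(vals, 30, "down", gene_ids=ids)
    assert down == [g for _, g in sorted(zip(vals, ids),
                                         key=lambda t: (t[0], t[1]))]


# -- overlap ------------------------------------------------------------


def test_overlap_ratio_examples():
    assert overlap_ratio({"a", "b", "c"}, {"b", "c", "d"}) == (0.5, 2, 4)
    assert overlap_ratio({"a", "b"}, {"a", "b"}) == (1.0, 2, 2)
    assert overlap_ratio({"a"}, {"b"}) == (0.0, 0, 2)
    assert overlap_ratio(set(), set()) == (0.0, 0, 0)


def test_overlap_ratio_symmetric_and_bounded():
    for _ in range(200):
        A = set(RNG.integers(0, 30, size=RNG.integers(0, 15)).tolist())
        B = set(RNG.integers(0, 30, size=RNG.integers(0, 15)).tolist())
        r_ab = overlap_ratio(A, B)
        r_ba = overlap_ratio(B, A)
        assert r_ab == r_ba
        assert 0.0 <= r_ab[0] <= 1.0


def _result(sample_id, P, ids):
    return significant_genes(P, k=1, gene_ids=ids, sample_id=sample_id)


def test_pairwise_overlap_matrix():
    ids = [f"g{i}" for i in range(60)]
    P = np.zeros(60)
    P[:4] = -0.9  # tumor-upregulated under tumor->normal semantics
    a = _result("a", P, ids)
    b = _result("b", P.copy(), ids)
    m = pairwise_overlap_matrix([a, b], "tumor_up")
    assert m.ratio.loc["a", "b"] == 1.0
    assert m.ratio.loc["a", "a"] == 1.0
    rng = np.random.default_rng(5)
    results = [_result(f"s{i}", rng.normal(0, 0.1, 60), ids) for i in range(4)]
    m2 = pairwise_overlap_matrix(results, "tumor_down")
    np.testing.assert_allclose(m2.ratio.to_numpy(), m2.ratio.to_numpy().T)
    for i, ri in enumerate(results):
        for j, rj in enumerate(results):
            ratio, ns, nu = overlap_ratio(ri.tumor_downregulated,
                                          rj.tumor_downregulated)
            assert m2.ratio.iloc[i, j] == pytest.approx(ratio)
            assert m2.n_shared.iloc[i, j] == ns
            assert m2.n_union.iloc[i, j] == nu


# -- DGE overlap --------------------------------------------------------


def _dge(genes_pos, genes_neg, alpha=1e-5):
    rows = [{"gene_id": g, "log2_fold_change": 2.0, "adjusted_p": alpha}
            for g in genes_pos]
    rows += [{"gene_id": g, "log2_fold_change": -2.0, "adjusted_p": alpha}
             for g in genes_neg]
    rows += [{"gene_id": "null_gene", "log2_fold_change": 1.0,
              "adjusted_p": 0.9}]
    return DGETable(pd.DataFrame(rows))


def test_dge_overlap_examples():
    ids = [f"g{i}" for i in range(100)]
    P = np.zeros(100)
    P[:4] = -0.9  # four tumor-upregulated genes
    res = significant_genes(P, k=1, gene_ids=ids)
    assert set(res.tumor_upregulated) == {"g0", "g1", "g2", "g3"}
    full = _dge(ids[:4], [])
    pct, ns, nt = dge_overlap(res, full, 1e-4, "tumor_up")
    assert (pct, ns, nt) == (100.0, 4, 4)
    partial = _dge(["g0"], [])
    pct, ns, nt = dge_overlap(res, partial, 1e-4, "tumor_up")
    assert (pct, ns, nt) == (25.0, 1, 4)
    assert format_dge_overlap(pct, ns, nt) == "25.0% (1/4)"


def test_dge_overlap_random_set_oracle():
    ids = [f"g{i}" for i in range(50)]
    for _ in range(1000):
        P = np.zeros(50)
        chosen = RNG.choice(50, size=RNG.integers(1, 8), replace=False)
        P[chosen] = -0.9
        res = significant_genes(P, k=1, gene_ids=ids)
        dge_genes = [ids[i] for i in
                     RNG.choice(50, size=RNG.integers(0, 20), replace=False)]
        table = _dge(dge_genes, [])
        pct, ns, nt = dge_overlap(res, table, 1e-4, "tumor_up")
        expected_shared = len(set(res.tumor_upregulated) & set(dge_genes))
        assert ns == expected_shared
        assert nt == len(res.tumor_upregulated)
        assert pct == pytest.approx(100.0 * expected_shared / nt)


def test_dge_overlap_empty_list_warns(caplog):
    res = significant_genes(np.zeros(10), k=2)
    pct, ns, nt = dge_overlap(res, _dge(["g0"], []), 1e-4, "tumor_up")
    assert (pct, ns, nt) == (0.0, 0, 0)
    assert any("empty" in r.message for r in caplog.records)


def test_read_dge_table_deseq2_aliases(tmp_path):
    p = tmp_path / "dge.tsv"
    p.write_text("gene\tlog2FoldChange\tpadj\nMET\t2.5\t1e-9\nERRFI1\t-1.8\t1e-6\n")
    table = read_dge_table(p)
    assert table.significant(1e-4, "positive") == {"MET"}
    assert table.significant(1e-4, "negative") == {"ERRFI1"}


def test_dge_table_validation():
    with pytest.raises(ValueError, match="duplicate"):
        DGETable(pd.DataFrame({"gene_id": ["a", "a"],
                               "log2_fold_change": [1.0, 2.0],
                               "adjusted_p": [0.1, 0.2]}))
    with pytest.raises(ValueError, match="p-values"):
        DGETable(pd.DataFrame({"gene_id": ["a"], "log2_fold_change": [1.0],
                               "adjusted_p": [1.5]}))


# -- histogram summary --------------------------------------------------


def test_perturbation_histogram_summary(tmp_path):
    ids = [f"g{i}" for i in range(200)]
    P = np.random.default_rng(3).normal(0, 0.1, 200)
    a = significant_genes(P, k=2, gene_ids=ids, sample_id="a")
    b = significant_genes(P.copy(), k=2, gene_ids=ids, sample_id="b")
    summary = perturbation_histogram(a, b, tmp_path / "hist.png")
    assert summary["a"]["sd"] == summary["b"]["sd"]
    assert summary["a"]["sd"] == pytest.approx(float(np.std(P)))
    assert summary["a"]["n_beyond_2sd"] == int(
        (np.abs(P - P.mean()) > 2 * P.std()).sum())
    zero = significant_genes(np.zeros(200), k=2, gene_ids=ids, sample_id="z")
    summary0 = perturbation_histogram(zero, zero, tmp_path / "hist0.png")
    assert summary0["a"]["sd"] == 0.0
    assert summary0["a"]["n_beyond_2sd"] == 0
    assert (tmp_path / "hist.png").exists()
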