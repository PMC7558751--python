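import itertools
import math

import numpy as np
import pandas as pd
import pytest

import parascreen as ps
from parascreen.buffering import PairFilterReport


def gene_matrix(values, kind, genes=None, lines=None):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    lines = lines or [f"L{j}" for j in range(values.shape[1])]
    return ps.GeneMatrix(pd.DataFrame(values, index=genes, columns=lines), kind)


# ---------------------------------------------------------------------------
# LOF calls


def test_lof_or_rule():
    mut = gene_matrix([[True, False, False, False]], "mutation")
    expr = gene_matrix([[5.0, 0.5, 5.0, 1.5]], "log2_tpm")
    cn = gene_matrix([[1.0, 1.0, 0.05, 1.0]], "copy_number")
    lof = ps.call_lof(mut, expr, cn)
    assert lof.calls.iloc[0].tolist() == [True, True, True, False]


def test_lof_thresholds_are_boundaries():
    mut = gene_matrix([[False, False]], "mutation")
    expr = gene_matrix([[1.0, 0.999]], "log2_tpm")  # strict <
    cn = gene_matrix([[0.1, 0.1]], "copy_number")
    lof = ps.call_lof(mut, expr, cn)
    assert lof.calls.iloc[0].tolist() == [False, True]


def test_lof_empty_intersection_raises():
    mut = gene_matrix([[True]], "mutation", genes=["A"])
    expr = gene_matrix([[1.0]], "log2_tpm", genes=["B"])
    cn = gene_matrix([[1.0]], "copy_number", genes=["A"])
    with pytest.raises(ValueError, match="share no genes"):
        ps.call_lof(mut, expr, cn)


def test_lof_coverage_gaps_reported():
    mut = gene_matrix([[True], [False]], "mutation", genes=["A", "B"])
    expr = gene_matrix([[5.0]], "log2_tpm", genes=["A"])
    cn = gene_matrix([[1.0], [1.0]], "copy_number", genes=["A", "B"])
    lof = ps.call_lof(mut, expr, cn)
    assert lof.coverage_gaps["expression"] == ["B"]


# ---------------------------------------------------------------------------
# testable pairs


def pair_table(rows):
    return ps.ParalogPairTable(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_id_a_to_b",
                                    "pct_id_b_to_a"])
    )


def test_directed_pair_filters_by_construction():
    """Cohort built to yield exactly 5 testable directed pairs."""
    n = 10
    lines = [f"L{j}" for j in range(n)]
    genes = ["A", "B", "C", "D", "E", "F"]
    # LOF counts per gene: A:3, B:2, C:1 (fails min_lof), D:2, E:0, F:2
    lof_counts = {"A": 3, "B": 2, "C": 1, "D": 2, "E": 0, "F": 2}
    expr = np.full((len(genes), n), 5.0)
    for i, g in enumerate(genes):
        expr[i, : lof_counts[g]] = 0.0
    # essential counts: A:4, B:3, C:5, D:1 (fails min_essential), E:3, F:2
    ess_counts = {"A": 4, "B": 3, "C": 5, "D": 1, "E": 3, "F": 2}
    bf = np.full((len(genes), n), -10.0)
    for i, g in enumerate(genes):
        bf[i, n - ess_counts[g]:] = 30.0
    mut = gene_matrix(np.zeros((len(genes), n), bool), "mutation", genes, lines)
    cn = gene_matrix(np.ones((len(genes), n)), "copy_number", genes, lines)
    lof = ps.call_lof(mut, gene_matrix(expr, "log2_tpm", genes, lines),
                      cn)
    ess = gene_matrix(bf, "bayes_factor", genes, lines)
    pairs = pair_table(
        [("A", "B", 50, 50), ("C", "D", 50, 50), ("E", "F", 25, 25)]
    )
    directed, report = ps.testable_pairs(pairs, lof, ess, min_identity=30)
    got = set(zip(directed["query_gene"], directed["partner_gene"]))
    # E-F excluded by identity; C|D fails partner min_lof... enumerate:
    # A|B ok, B|A ok, C|D fails (D has 2 LOF? D:2 ok, C essential 5 ok) ->
    # direction C|D ok; D|C fails (partner C has 1 LOF);
    assert got == {("A", "B"), ("B", "A"), ("C", "D")}
    assert report.removed_identity == 1
    assert report.removed_min_lof == 1
    assert report.n_directed == 3


def test_one_to_one_filter_drops_shared_genes():
    pairs = pair_table(
        [("A", "B", 60, 60), ("A", "C", 55, 55), ("D", "E", 70, 70),
         ("F", "G", 20, 20)]
    )
    ident = pairs.min_identity()
    # at 30% identity, A appears in two surviving pairs -> both dropped
    tbl = pairs.table[ident.to_numpy() >= 30]
    counts = pd.concat([tbl["gene_a"], tbl["gene_b"]]).value_counts()
    assert counts["A"] == 2
    lines = [f"L{j}" for j in range(6)]
    genes = list("ABCDEFG")
    expr = np.full((7, 6), 5.0)
    expr[:, :2] = 0.0
    lof = ps.call_lof(
        gene_matrix(np.zeros((7, 6), bool), "mutation", genes, lines),
        gene_matrix(expr, "log2_tpm", genes, lines),
        gene_matrix(np.ones((7, 6)), "copy_number", genes, lines),
    )
    bf = np.full((7, 6), 30.0)
    ess = gene_matrix(bf, "bayes_factor", genes, lines)
    directed, report = ps.testable_pairs(pairs, lof, ess)
    assert set(directed["query_gene"]) <= {"D", "E"}
    assert report.removed_not_one_to_one == 2


# ---------------------------------------------------------------------------
# Fisher test


def hypergeom_tail_oracle(n, k_lof, k_ess, a):
    """P(X >= a) by explicit enumeration of the hypergeometric mass."""
    total = math.comb(n, k_ess)
    return sum(
        math.comb(k_lof, j) * math.comb(n - k_lof, k_ess - j)
        for j in range(a, min(k_lof, k_ess) + 1)
    ) / total


def vectors_with(n, k_lof, k_ess, a):
    lof = np.zeros(n, bool)
    lof[:k_lof] = True
    ess = np.zeros(n, bool)
    ess[:a] = True
    ess[k_lof: k_lof + (k_ess - a)] = True
    return lof, ess


def test_fisher_hand_example():
    """n=10, 4 LOF, 3 essential, overlap 3 -> C(4,3)C(6,0)/C(10,3) = 1/30."""
    lof, ess = vectors_with(10, 4, 3, 3)
    p, degenerate = ps.fisher_buffering_test(lof, ess)
    assert not degenerate
    assert p == pytest.approx(1 / 30)


def test_fisher_zero_overlap_is_one():
    lof, ess = vectors_with(10, 4, 3, 0)
    p, _ = ps.fisher_buffering_test(lof, ess)
    assert p == pytest.approx(1.0)


def test_fisher_degenerate_margins():
    assert ps.fisher_buffering_test([True] * 5, [True, False, True, False, True]) \
        == (1.0, True)
    assert ps.fisher_buffering_test([True, False] * 3, [False] * 6) == (1.0, True)


def test_fisher_matches_exhaustive_enumeration():
    """All non-degenerate tables with n <= 12 against the combinatorial tail."""
    checked = 0
    for n in range(4, 13):
        for k_lof, k_ess in itertools.product(range(1, n), repeat=2):
            lo = max(0, k_lof + k_ess - n)
            hi = min(k_lof, k_ess)
            for a in range(lo, hi + 1):
                lof, ess = vectors_with(n, k_lof, k_ess, a)
                p, degenerate = ps.fisher_buffering_test(lof, ess)
                assert not degenerate
                assert p == pytest.approx(
                    hypergeom_tail_oracle(n, k_lof, k_ess, a), rel=1e-10
                ), (n, k_lof, k_ess, a)
                checked += 1
    assert checked > 1000


def test_fisher_valid_under_permutation_null():
    """With margins fixed, P(p <= 0.05) <= 0.05 over random label shuffles."""
    rng = np.random.default_rng(0)
    n = 30
    lof = np.zeros(n, bool)
    lof[:8] = True
    ess = np.zeros(n, bool)
    ess[:10] = True
    hits = 0
    trials = 10_000
    for _ in range(trials):
        p, _ = ps.fisher_buffering_test(lof, rng.permutation(ess))
        hits += p <= 0.05
    assert hits / trials <= 0.05


# ---------------------------------------------------------------------------
# BH FDR


def bh_oracle(pvals):
    """Textbook step-up: sort, p*(n/rank), running min from the largest."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [None] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adjusted[i] = running
    return adjusted


def test_bh_step_up_hand_example():
    assert np.allclose(ps.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_trivial_cases():
    assert ps.bh_fdr([0.2]).tolist() == [0.2]
    assert np.allclose(ps.bh_fdr([1.0, 1.0, 1.0]), 1.0)
    assert ps.bh_fdr([]).size == 0


def test_bh_matches_textbook_oracle_on_random_vectors():
    rng = np.random.default_rng(11)
    for n in (1, 2, 17, 100):
        p = rng.uniform(1e-6, 1, n)
        assert np.allclose(ps.bh_fdr(p), bh_oracle(list(p)))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        ps.bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# similarity sweep


def sweep_fixture():
    rows = []
    # 4 never-essentials: 2 with a partner at >= 40, 2 at 20
    for i in range(2):
        rows.append((f"N{i}", f"PN{i}", 45, 50))
    for i in range(2, 4):
        rows.append((f"N{i}", f"PN{i}", 20, 22))
    # 4 common essentials: 1 with partner at >= 40
    rows.append(("C0", "PC0", 60, 55))
    for i in range(1, 4):
        rows.append((f"C{i}", f"PC{i}", 15, 18))
    return pair_table(rows)


def test_sweep_fractions_by_hand():
    pairs = sweep_fixture()
    out = ps.similarity_sweep(
        pairs, [f"N{i}" for i in range(4)], [f"C{i}" for i in range(4)],
        thresholds=[0, 40],
    )
    assert out.loc[0, ["frac_never", "frac_common"]].tolist() == [1.0, 1.0]
    assert out.loc[1, "frac_never"] == pytest.approx(0.5)
    assert out.loc[1, "frac_common"] == pytest.approx(0.25)


def test_sweep_fractions_non_increasing(default_screen):
    rng = np.random.default_rng(2)
    rows = [
        (f"A{i}", f"B{i}", rng.uniform(5, 95), rng.uniform(5, 95))
        for i in range(200)
    ]
    pairs = pair_table(rows)
    never = [f"A{i}" for i in range(100)]
    common = [f"A{i}" for i in range(100, 200)]
    out = ps.similarity_sweep(pairs, never, common)
    assert (np.diff(out["frac_never"]) <= 1e-12).all()
    assert (np.diff(out["frac_common"]) <= 1e-12).all()


def test_sweep_detects_planted_enrichment():
    """never: 30% with partner >= 35%; common: 10%; n = 1000 each."""
    rng = np.random.default_rng(8)
    rows = []
    never, common = [], []
    for i in range(1000):
        g = f"N{i}"
        never.append(g)
        ident = rng.uniform(40, 90) if rng.random() < 0.3 else rng.uniform(5, 30)
        rows.append((g, f"PN{i}", ident, ident))
    for i in range(1000):
        g = f"C{i}"
        common.append(g)
        ident = rng.uniform(40, 90) if rng.random() < 0.1 else rng.uniform(5, 30)
        rows.append((g, f"PC{i}", ident, ident))
    out = ps.similarity_sweep(pair_table(rows), never, common, thresholds=[35])
    se_never = np.sqrt(0.3 * 0.7 / 1000)
    se_common = np.sqrt(0.1 * 0.9 / 1000)
    assert out.loc[0, "frac_never"] == pytest.approx(0.3, abs=3 * se_never)
    assert out.loc[0, "frac_common"] == pytest.approx(0.1, abs=3 * se_common)
    assert out.loc[0, "pvalue"] < 1e-6


def test_sweep_empty_set_raises():
    with pytest.raises(ValueError, match="non-empty"):
        ps.similarity_sweep(sweep_fixture(), [], ["C0"])
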