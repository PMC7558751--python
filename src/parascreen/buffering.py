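"""Paralog buffering from monogenic-screen matrices.

The question: is gene A essential specifically in the cell lines where its
paralog partner B has lost function?  Loss of function (LOF) is called per
gene per line from any of three evidence channels — a damaging mutation
(frameshift/nonsense), depleted expression (log2 TPM < 1.0) or deep
copy-number loss (ratio < 0.1).  Essentiality is a Bayes Factor above 10.
Each surviving directed pair (A | B) gets a one-sided Fisher's exact test
on the 2x2 table of cell lines cross-classified by LOF(B) and
essential(A), with Benjamini-Hochberg FDR across all tested pairs.

The module also hosts the paralog similarity sweep: at each percent-identity
threshold, the fraction of never-essential vs common-essential genes that
retain a paralog partner at least that similar.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneMatrix, ParalogPairTable
from .scoring import TwoProportionResult, two_proportion_ztest

BF_ESSENTIAL_THRESHOLD = 10.0
EXPRESSION_LOF_THRESHOLD = 1.0
CN_LOF_THRESHOLD = 0.1


@dataclasses.dataclass
class LOFMatrix:
    """Boolean gene x cell-line loss-of-function calls.

    Defined only on genes and lines present in all three evidence matrices;
    genes dropped for lack of coverage are listed per source.
    """

    calls: pd.DataFrame
    coverage_gaps: dict[str, list[str]]


def call_lof(
    mut: GeneMatrix,
    expr: GeneMatrix,
    cn: GeneMatrix,
    expr_threshold: float = EXPRESSION_LOF_THRESHOLD,
    cn_threshold: float = CN_LOF_THRESHOLD,
) -> LOFMatrix:
    """LOF = damaging mutation OR log2 TPM < 1.0 OR copy number < 0.1."""
    if mut.value_kind != "mutation" or expr.value_kind != "log2_tpm" \
            or cn.value_kind != "copy_number":
        raise ValueError("call_lof expects (mutation, log2_tpm, copy_number)")
    genes = mut.values.index.intersection(expr.values.index).intersection(
        cn.values.index
    )
    lines = mut.values.columns.intersection(expr.values.columns).intersection(
        cn.values.columns
    )
    if len(genes) == 0 or len(lines) == 0:
        raise ValueError("evidence matrices share no genes/cell lines")
    calls = (
        mut.values.loc[genes, lines]
        | (expr.values.loc[genes, lines] < expr_threshold)
        | (cn.values.loc[genes, lines] < cn_threshold)
    )
    all_genes = (
        set(mut.values.index) | set(expr.values.index) | set(cn.values.index)
    )
    gaps = {
        "mutation": sorted(all_genes - set(mut.values.index)),
        "expression": sorted(all_genes - set(expr.values.index)),
        "copy_number": sorted(all_genes - set(cn.values.index)),
    }
    return LOFMatrix(calls, gaps)


@dataclasses.dataclass
class PairFilterReport:
    """How many directed pairs each filter removed."""

    n_input_pairs: int
    removed_identity: int
    removed_not_one_to_one: int
    removed_coverage: int
    removed_min_lof: int
    removed_min_essential: int
    n_directed: int


def testable_pairs(
    pairs: ParalogPairTable,
    lof: LOFMatrix,
    ess: GeneMatrix,
    bf_threshold: float = BF_ESSENTIAL_THRESHOLD,
    min_identity: float = 30.0,
    min_lof: int = 2,
    min_essential: int = 2,
    one_to_one: bool = True,
) -> tuple[pd.DataFrame, PairFilterReport]:
    """Directed (query, partner) pairs that can support the Fisher test.

    A direction (A | B) survives when the pair passes the identity and
    one-to-one filters, both genes are covered, partner B has LOF calls in
    at least ``min_lof`` lines and query A is essential (BF > threshold) in
    at least ``min_essential`` lines.  Both directions of a surviving pair
    are emitted independently.
    """
    if ess.value_kind != "bayes_factor":
        raise ValueError("essentiality matrix must be bayes_factor")
    tbl = pairs.table
    ident = pairs.min_identity()
    n_input = len(tbl)

    pass_ident = tbl[ident.to_numpy() >= min_identity]
    removed_identity = n_input - len(pass_ident)

    removed_one = 0
    if one_to_one:
        gene_counts = pd.concat(
            [pass_ident["gene_a"], pass_ident["gene_b"]]
        ).value_counts()
        multi = set(gene_counts[gene_counts > 1].index)
        keep = ~(pass_ident["gene_a"].isin(multi) | pass_ident["gene_b"].isin(multi))
        removed_one = int((~keep).sum())
        pass_ident = pass_ident[keep]

    lines = lof.calls.columns.intersection(ess.values.columns)
    rows = []
    removed_cov = removed_lof = removed_ess = 0
    for row in pass_ident.itertuples(index=False):
        for query, partner in ((row.gene_a, row.gene_b), (row.gene_b, row.gene_a)):
            if partner not in lof.calls.index or query not in ess.values.index:
                removed_cov += 1
                continue
            n_lof = int(lof.calls.loc[partner, lines].sum())
            n_ess = int((ess.values.loc[query, lines] > bf_threshold).sum())
            if n_lof < min_lof:
                removed_lof += 1
                continue
            if n_ess < min_essential:
                removed_ess += 1
                continue
            rows.append(
                {
                    "query_gene": query,
                    "partner_gene": partner,
                    "pair_id": row.pair_id,
                    "n_lof": n_lof,
                    "n_essential": n_ess,
                }
            )
    directed = pd.DataFrame(
        rows, columns=["query_gene", "partner_gene", "pair_id", "n_lof",
                       "n_essential"]
    )
    report = PairFilterReport(
        n_input_pairs=n_input,
        removed_identity=removed_identity,
        removed_not_one_to_one=removed_one,
        removed_coverage=removed_cov,
        removed_min_lof=removed_lof,
        removed_min_essential=removed_ess,
        n_directed=len(directed),
    )
    return directed, report


def fisher_buffering_test(
    lof_b: Sequence[bool] | np.ndarray, essential_a: Sequence[bool] | np.ndarray
) -> tuple[float, bool]:
    """One-sided Fisher's exact test for essential(A) enrichment in LOF(B).

    Returns ``(p, degenerate)``; the p-value is the upper hypergeometric
    tail P(X >= overlap).  A margin of zero or n makes the table
    uninformative: p = 1 with the degenerate flag set.
    """
    lof_b = np.asarray(lof_b, dtype=bool)
    essential_a = np.asarray(essential_a, dtype=bool)
    if lof_b.shape != essential_a.shape:
        raise ValueError("vectors must have equal length")
    n = lof_b.size
    if n < 4:
        raise ValueError("need >= 4 cell lines")
    k_lof = int(lof_b.sum())
    k_ess = int(essential_a.sum())
    if k_lof in (0, n) or k_ess in (0, n):
        return 1.0, True
    overlap = int((lof_b & essential_a).sum())
    p = float(stats.hypergeom.sf(overlap - 1, n, k_ess, k_lof))
    return min(p, 1.0), False


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving with the input."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def buffering_scan(
    directed: pd.DataFrame,
    lof: LOFMatrix,
    ess: GeneMatrix,
    bf_threshold: float = BF_ESSENTIAL_THRESHOLD,
) -> pd.DataFrame:
    """Fisher test every directed pair; BH-correct across all of them.

    Returns a table sorted by p with the 2x2 contingency counts
    (``n11`` = LOF & essential, ``n10`` = LOF only, ``n01`` = essential
    only, ``n00`` = neither), the one-sided p, and the FDR.
    """
    lines = lof.calls.columns.intersection(ess.values.columns)
    rows = []
    for row in directed.itertuples(index=False):
        lof_b = lof.calls.loc[row.partner_gene, lines].to_numpy()
        ess_a = (ess.values.loc[row.query_gene, lines] > bf_threshold).to_numpy()
        p, degenerate = fisher_buffering_test(lof_b, ess_a)
        n11 = int((lof_b & ess_a).sum())
        rows.append(
            {
                "query_gene": row.query_gene,
                "partner_gene": row.partner_gene,
                "pair_id": row.pair_id,
                "n_lines": int(len(lines)),
                "n11": n11,
                "n10": int(lof_b.sum()) - n11,
                "n01": int(ess_a.sum()) - n11,
                "n00": int(len(lines)) - int(lof_b.sum()) - int(ess_a.sum()) + n11,
                "pvalue": p,
                "degenerate": degenerate,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = bh_fdr(result["pvalue"].to_numpy())
        result = result.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    return result


# ---------------------------------------------------------------------------
# similarity sweep


def similarity_sweep(
    pairs: ParalogPairTable,
    never_set: Iterable[str],
    common_set: Iterable[str],
    thresholds: Sequence[float] = tuple(range(10, 100, 5)),
) -> pd.DataFrame:
    """Fraction of each gene set with a paralog at >= t percent identity.

    A gene "has a paralog at t" when some partner pair has
    min(identity A->B, identity B->A) >= t.  Each threshold row carries a
    two-proportion Z-test comparing the never-essential fraction against
    the common-essential fraction.
    """
    never_set = set(never_set)
    common_set = set(common_set)
    if not never_set or not common_set:
        raise ValueError("gene sets must be non-empty")
    overlap = never_set & common_set
    if overlap:
        import warnings

        warnings.warn(f"{len(overlap)} genes in both sets", stacklevel=2)

    ident = pairs.min_identity().to_numpy()
    tbl = pairs.table
    best: dict[str, float] = {}
    for (a, b), m in zip(zip(tbl["gene_a"], tbl["gene_b"]), ident):
        for g in (a, b):
            if m > best.get(g, -np.inf):
                best[g] = m

    rows = []
    for t in thresholds:
        x1 = sum(best.get(g, -np.inf) >= t for g in never_set)
        x2 = sum(best.get(g, -np.inf) >= t for g in common_set)
        test = two_proportion_ztest(x1, len(never_set), x2, len(common_set))
        rows.append(
            {
                "threshold": float(t),
                "frac_never": x1 / len(never_set),
                "frac_common": x2 / len(common_set),
                "z": test.z,
                "pvalue": test.pvalue,
            }
        )
    return pd.DataFrame(rows)
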