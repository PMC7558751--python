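"""Genetic-interaction scoring: SMF, DMF, dLFC and the trimmed-Z score.

The model is additive in log space.  A gene's single-mutant fitness (SMF)
is the mean screen-level fold change of its gene-control constructs
(gene guide paired with a nonessential guide), averaged over the two array
positions.  A pair's expected double-mutant fitness (DMF) is the sum of the
two SMFs; the observed DMF is the mean fold change of the dual-targeting
constructs.  dLFC = observed - expected, and zdLFC standardizes dLFC per
screen using the mean and SD of the distribution after discarding the top
and bottom 2.5% of values, so a heavy synthetic-lethal tail does not
inflate its own yardstick.  Hits are pairs with zdLFC strictly below -3.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .counts import FoldChangeTable
from .exceptions import DegenerateDistributionError
from .io import CTRL_SENTINEL, GuideLibrary, ParalogPairTable

DEFAULT_TRIM_FRACTION = 0.025
DEFAULT_HIT_THRESHOLD = -3.0


@dataclasses.dataclass
class SMFTable:
    """Gene-level single-mutant fitness per cell line.

    ``smf`` averages the two positional means (A-slot and B-slot control
    constructs), kept separately in ``smf_a``/``smf_b`` for QC.  Genes with
    no control constructs are simply absent; their ids are listed in
    ``missing``.
    """

    smf: pd.DataFrame
    smf_a: pd.DataFrame
    smf_b: pd.DataFrame
    n_constructs: pd.Series
    missing: list[str]

    def save(self, path) -> None:
        out = self.smf.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def single_mutant_fitness(fc: FoldChangeTable, library: GuideLibrary) -> SMFTable:
    """Mean control-construct fold change per gene, averaged over positions."""
    tbl = library.table
    ctrl = tbl[tbl["category"].isin(["gene_control", "essential_control"])]
    lfc = fc.screen_lfc

    # the targeted gene sits in whichever slot is not the CTRL sentinel
    a_side = ctrl[ctrl["gene_a"] != CTRL_SENTINEL]
    b_side = ctrl[ctrl["gene_b"] != CTRL_SENTINEL]

    def positional_mean(sub: pd.DataFrame, gene_col: str) -> pd.DataFrame:
        joined = lfc.reindex(sub["construct_id"]).set_axis(sub.index)
        joined["gene"] = sub[gene_col].to_numpy()
        return joined.groupby("gene").mean()

    smf_a = positional_mean(a_side, "gene_a")
    smf_b = positional_mean(b_side, "gene_b")
    smf = pd.concat([smf_a, smf_b]).groupby(level=0).mean()

    n_a = a_side.groupby("gene_a").size()
    n_b = b_side.groupby("gene_b").size()
    n_constructs = n_a.add(n_b, fill_value=0).astype(int)
    n_constructs.index.name = "gene"

    targeted = set(tbl.loc[tbl["category"] == "pair", "gene_a"]) | set(
        tbl.loc[tbl["category"] == "pair", "gene_b"]
    )
    missing = sorted(targeted - set(smf.index))
    return SMFTable(smf, smf_a, smf_b, n_constructs, missing)


def expected_dmf(smf_a: float, smf_b: float) -> float:
    """Additive expectation: sum of the two SMFs in log space."""
    return smf_a + smf_b


def observed_dmf(
    fc: FoldChangeTable, library: GuideLibrary, pair_id: str, cell_line: str
) -> float:
    """Mean screen LFC over all dual-targeting constructs of a pair."""
    constructs = library.constructs_for_pair(pair_id)["construct_id"]
    if len(constructs) == 0:
        raise KeyError(f"pair {pair_id!r} has no constructs")
    return float(fc.screen_lfc.loc[constructs, cell_line].mean())


def robust_zdlfc(
    dlfc: np.ndarray | pd.Series, trim_fraction: float = DEFAULT_TRIM_FRACTION
) -> np.ndarray | pd.Series:
    """Z-transform using mean/SD of the tail-trimmed distribution.

    ``floor(trim_fraction * n)`` values are dropped from each tail before
    computing the mean and sample SD (ddof=1); every input value — trimmed
    ones included — is then standardized against them.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    values = np.asarray(dlfc, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError(f"need >= 10 values to standardize, got {n}")
    k = math.floor(trim_fraction * n)
    kept = np.sort(values)[k : n - k] if k else np.sort(values)
    mu = kept.mean()
    sigma = kept.std(ddof=1)
    if sigma == 0:
        raise DegenerateDistributionError("trimmed dLFC distribution has zero SD")
    z = (values - mu) / sigma
    if isinstance(dlfc, pd.Series):
        return pd.Series(z, index=dlfc.index)
    return z


@dataclasses.dataclass
class GIScoreTable:
    """Per-pair, per-cell-line interaction scores.

    ``scores`` is a long table: pair_id, cell_line, observed_dmf,
    expected_dmf, dlfc, zdlfc, n_pair_constructs, hit.  Pairs excluded
    because a gene lacked an SMF estimate are listed in ``excluded``.
    """

    scores: pd.DataFrame
    threshold: float
    trim_fraction: float
    excluded: list[str]

    def hits(self, cell_line: str) -> set[str]:
        mask = (self.scores["cell_line"] == cell_line) & self.scores["hit"]
        return set(self.scores.loc[mask, "pair_id"])

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.scores["cell_line"].unique())

    def zdlfc_matrix(self) -> pd.DataFrame:
        return self.scores.pivot(index="pair_id", columns="cell_line",
                                 values="zdlfc")

    def save(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)


def score_pairs(
    fc: FoldChangeTable,
    library: GuideLibrary,
    smf: SMFTable | None = None,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    threshold: float = DEFAULT_HIT_THRESHOLD,
) -> GIScoreTable:
    """Full scoring pass: observed/expected DMF, dLFC, zdLFC, hit flags.

    zdLFC is standardized per cell line over the scored gene pairs only.
    Pairs whose genes lack gene-control constructs cannot be given an
    expectation and are excluded (reported, not silently dropped).
    """
    if smf is None:
        smf = single_mutant_fitness(fc, library)

    pair_tbl = library.table[library.table["category"] == "pair"]
    pair_genes = (
        pair_tbl.groupby("pair_id")
        .apply(
            lambda g: tuple(sorted(set(g["gene_a"]) | set(g["gene_b"]))),
            include_groups=False,
        )
        .to_dict()
    )

    rows = []
    excluded = []
    for pid, genes in sorted(pair_genes.items()):
        if len(genes) != 2 or any(g not in smf.smf.index for g in genes):
            excluded.append(pid)
            continue
        g1, g2 = genes
        constructs = library.constructs_for_pair(pid)["construct_id"]
        for line in fc.cell_lines:
            obs = float(fc.screen_lfc.loc[constructs, line].mean())
            exp = expected_dmf(smf.smf.at[g1, line], smf.smf.at[g2, line])
            rows.append(
                {
                    "pair_id": pid,
                    "gene_a": g1,
                    "gene_b": g2,
                    "cell_line": line,
                    "observed_dmf": obs,
                    "expected_dmf": exp,
                    "dlfc": obs - exp,
                    "n_pair_constructs": int(len(constructs)),
                }
            )
    scores = pd.DataFrame(rows)
    if len(scores):
        scores["zdlfc"] = np.nan
        for line, grp in scores.groupby("cell_line"):
            scores.loc[grp.index, "zdlfc"] = robust_zdlfc(
                grp["dlfc"], trim_fraction
            ).to_numpy()
        scores["hit"] = scores["zdlfc"] < threshold
    return GIScoreTable(scores, threshold, trim_fraction, excluded)


@dataclasses.dataclass
class Concordance:
    """Cross-cell-line agreement of hit calls."""

    per_line: dict[str, set[str]]
    union: set[str]
    in_at_least_two: set[str]
    in_all: set[str]

    def summary(self) -> dict:
        return {
            "n_union": len(self.union),
            "n_at_least_two": len(self.in_at_least_two),
            "n_all_lines": len(self.in_all),
            "per_line": {k: sorted(v) for k, v in self.per_line.items()},
        }


def call_hits(
    scores: GIScoreTable, threshold: float | None = None
) -> Concordance:
    """Hit sets per cell line (zdLFC strictly below threshold) + concordance."""
    if threshold is None:
        threshold = scores.threshold
    per_line = {}
    for line in scores.cell_lines:
        grp = scores.scores[scores.scores["cell_line"] == line]
        per_line[line] = set(grp.loc[grp["zdlfc"] < threshold, "pair_id"])
    union: set[str] = set().union(*per_line.values()) if per_line else set()
    counts = {p: sum(p in s for s in per_line.values()) for p in union}
    return Concordance(
        per_line=per_line,
        union=union,
        in_at_least_two={p for p, c in counts.items() if c >= 2},
        in_all={p for p, c in counts.items() if c == len(per_line)},
    )


# ---------------------------------------------------------------------------
# proportion tests


@dataclasses.dataclass
class TwoProportionResult:
    z: float
    pvalue: float
    degenerate: bool = False


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> TwoProportionResult:
    """Pooled two-proportion Z-test, two-sided normal p-value."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TwoProportionResult(0.0, 1.0, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return TwoProportionResult(float(z), float(p))


@dataclasses.dataclass
class EnrichmentReport:
    """Hit-vs-tested proportion comparison for a pair annotation."""

    n_hits_annotated: int
    n_hits: int
    n_tested_annotated: int
    n_tested: int
    n_missing_annotation: int
    test: TwoProportionResult


def ohnolog_enrichment(
    hits: set[str], tested: set[str], annotations: ParalogPairTable
) -> EnrichmentReport:
    """Are whole-genome-duplication pairs over-represented among hits?

    Pairs without an ``is_ohnolog`` annotation are excluded and counted.
    """
    if "is_ohnolog" not in annotations.table.columns:
        raise ValueError("paralog table has no is_ohnolog column")
    ann = annotations.table.set_index("pair_id")["is_ohnolog"]
    missing = sorted(p for p in tested if p not in ann.index or pd.isna(ann.get(p)))
    usable_tested = [p for p in tested if p not in set(missing)]
    usable_hits = [p for p in hits if p in set(usable_tested)]
    x1 = sum(bool(ann[p]) for p in usable_hits)
    x2 = sum(bool(ann[p]) for p in usable_tested)
    test = two_proportion_ztest(x1, len(usable_hits), x2, len(usable_tested))
    return EnrichmentReport(
        n_hits_annotated=x1,
        n_hits=len(usable_hits),
        n_tested_annotated=x2,
        n_tested=len(usable_tested),
        n_missing_annotation=len(missing),
        test=test,
    )
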