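"""Synthetic gene x cell-line cohort with planted paralog buffering.

Emulates the statistical structure of a DepMap-style panel: per-gene
expression behavior drawn from a three-population (mean, SD) mixture
(never / sometimes / constitutive), per-line log2 TPM draws, sparse
damaging-mutation flags, rare deep deletions, Bayes-Factor essentiality
with a clear essential/nonessential separation, and a paralog-pair table
with directional percent identities.  Planted buffering pairs couple the
channels: in cell lines where the partner carries loss-of-function
evidence, the query gene's Bayes Factor is shifted into the essential
range with a configurable penetrance.

Truth tables (per-gene class, planted directed pairs) are returned so
recovery can be scored without reaching into generator internals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import GeneMatrix, ParalogPairTable, pair_key

# (mean, SD)-plane component centers echoing the three expression
# populations seen across large cell-line panels
DEFAULT_COMPONENTS = {
    "never": {"center": (0.3, 0.3), "weight": 0.26},
    "constitutive": {"center": (6.0, 0.5), "weight": 0.41},
    "sometimes": {"center": (3.0, 2.2), "weight": 0.33},
}
DEFAULT_COMPONENT_SPREAD = 0.3


@dataclasses.dataclass
class PlantedPair:
    """A buffering relationship: LOF of partner makes query essential."""

    query_gene: str
    partner_gene: str
    penetrance: float = 0.9
    lof_rate: float = 0.2

    def __post_init__(self) -> None:
        for rate in (self.penetrance, self.lof_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("rates must be in [0, 1]")


@dataclasses.dataclass
class CohortSpec:
    n_genes: int = 1000
    n_lines: int = 200
    components: dict = dataclasses.field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COMPONENTS.items()
        }
    )
    component_spread: float = DEFAULT_COMPONENT_SPREAD
    n_paralog_pairs: int = 50
    planted: list[PlantedPair] = dataclasses.field(default_factory=list)
    background_lof_rate: float = 0.05
    background_essential_rate: float = 0.05
    mutation_rate: float = 0.005
    cn_deletion_rate: float = 0.005
    nonessential_bf: tuple[float, float] = (-15.0, 5.0)  # mean, sd
    essential_bf: tuple[float, float] = (25.0, 5.0)
    ohnolog_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c["weight"] for c in self.components.values())
        if not np.isclose(total, 1.0):
            raise ConfigError(f"component weights sum to {total}, expected 1")
        if 2 * self.n_paralog_pairs > self.n_genes:
            raise ConfigError("not enough genes for the requested pairs")


@dataclasses.dataclass
class Cohort:
    expression: GeneMatrix
    bf: GeneMatrix
    cn: GeneMatrix
    mutation: GeneMatrix
    pairs: ParalogPairTable
    gene_classes: pd.Series          # truth: generating component per gene
    gene_params: pd.DataFrame        # truth: per-gene (mean, sd) of log2 TPM
    planted_truth: pd.DataFrame      # truth: directed planted pairs

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.expression.save(d / "expression_log2tpm.tsv")
        self.bf.save(d / "bayes_factor.tsv")
        self.cn.save(d / "copy_number.tsv")
        self.mutation.save(d / "mutation.tsv")
        self.pairs.save(d / "paralog_pairs.tsv")
        truth = self.gene_classes.rename("class").to_frame().join(self.gene_params)
        truth.index.name = "gene"
        truth.to_csv(d / "truth_gene_classes.tsv", sep="\t")
        self.planted_truth.to_csv(d / "truth_planted_pairs.tsv", sep="\t",
                                  index=False)


def default_planted_pairs(
    n: int, penetrance: float = 0.9, lof_rate: float = 0.2
) -> list[PlantedPair]:
    """Plant pairs on the first 2n genes (even = query, odd = partner)."""
    return [
        PlantedPair(f"G{2 * i:05d}", f"G{2 * i + 1:05d}", penetrance, lof_rate)
        for i in range(n)
    ]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw all matrices and the paralog table for one synthetic cohort."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    lines = [f"CL{j:03d}" for j in range(spec.n_lines)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for pp in spec.planted:
        if pp.query_gene not in gene_index or pp.partner_gene not in gene_index:
            raise ConfigError(
                f"planted pair {pp.query_gene}/{pp.partner_gene} outside the "
                "gene universe"
            )

    # --- per-gene expression population and per-line expression draws
    names = list(spec.components)
    weights = [spec.components[k]["weight"] for k in names]
    classes = rng.choice(len(names), size=spec.n_genes, p=weights)
    if spec.planted and "constitutive" in names:
        k_const = names.index("constitutive")
        for pp in spec.planted:  # buffering pairs are constitutively expressed
            classes[gene_index[pp.query_gene]] = k_const
            classes[gene_index[pp.partner_gene]] = k_const
    centers = np.array([spec.components[k]["center"] for k in names])
    gene_mean = rng.normal(centers[classes, 0], spec.component_spread)
    gene_sd = rng.normal(centers[classes, 1], spec.component_spread)
    gene_mean = np.clip(gene_mean, 0.0, None)
    gene_sd = np.clip(gene_sd, 0.05, None)

    expr = rng.normal(
        gene_mean[:, None], gene_sd[:, None], size=(spec.n_genes, spec.n_lines)
    )
    expr = np.clip(expr, 0.0, None)  # log2(TPM+1) floor

    # --- background mutation / deletion evidence
    mut = rng.random((spec.n_genes, spec.n_lines)) < spec.mutation_rate
    cn = np.clip(rng.normal(1.0, 0.15, size=(spec.n_genes, spec.n_lines)), 0, None)
    deletions = rng.random((spec.n_genes, spec.n_lines)) < spec.cn_deletion_rate
    cn[deletions] = rng.uniform(0.0, 0.09, size=int(deletions.sum()))

    # --- Bayes factors: background essentiality independent of everything
    ne_mu, ne_sd = spec.nonessential_bf
    es_mu, es_sd = spec.essential_bf
    bf = rng.normal(ne_mu, ne_sd, size=(spec.n_genes, spec.n_lines))
    background_ess = rng.random((spec.n_genes, spec.n_lines)) < spec.background_essential_rate
    bf[background_ess] = rng.normal(es_mu, es_sd, size=int(background_ess.sum()))

    # --- paralog pairs: planted first, then nulls on the remaining genes
    pair_rows = []
    used: set[str] = set()
    planted_truth_rows = []
    for pp in spec.planted:
        ia, ib = gene_index[pp.query_gene], gene_index[pp.partner_gene]
        used.update((pp.query_gene, pp.partner_gene))
        ident = rng.uniform(35.0, 95.0)
        pair_rows.append(
            {
                "gene_a": pp.query_gene,
                "gene_b": pp.partner_gene,
                "pct_id_a_to_b": round(ident + rng.uniform(-2, 2), 2),
                "pct_id_b_to_a": round(ident + rng.uniform(-2, 2), 2),
                "is_ohnolog": bool(rng.random() < spec.ohnolog_fraction),
            }
        )

        # inject LOF evidence for the partner, then couple query essentiality
        lof_lines = rng.random(spec.n_lines) < pp.lof_rate
        channel = rng.integers(0, 3, size=spec.n_lines)
        for j in np.flatnonzero(lof_lines):
            if channel[j] == 0:
                mut[ib, j] = True
            elif channel[j] == 1:
                expr[ib, j] = rng.uniform(0.0, 0.9)
            else:
                cn[ib, j] = rng.uniform(0.0, 0.09)
        responds = lof_lines & (rng.random(spec.n_lines) < pp.penetrance)
        bf[ia, responds] = rng.normal(es_mu, es_sd, size=int(responds.sum()))
        planted_truth_rows.append(
            {
                "query_gene": pp.query_gene,
                "partner_gene": pp.partner_gene,
                "pair_id": pair_key(pp.query_gene, pp.partner_gene),
                "penetrance": pp.penetrance,
                "lof_rate": pp.lof_rate,
                "n_lof_lines": int(lof_lines.sum()),
            }
        )

    # the buffering analysis targets constitutively expressed genes, so the
    # paralog table is built from that population
    constitutive = {g for g, c in zip(genes, classes) if names[c] == "constitutive"}
    free = [g for g in genes if g not in used and g in constitutive]
    n_null = spec.n_paralog_pairs - len(spec.planted)
    if n_null < 0:
        raise ConfigError("more planted pairs than n_paralog_pairs")
    if 2 * n_null > len(free):
        raise ConfigError("not enough constitutive genes for null pairs")
    chosen = rng.choice(len(free), size=2 * n_null, replace=False)
    for i in range(n_null):
        a, b = free[chosen[2 * i]], free[chosen[2 * i + 1]]
        ident = rng.uniform(10.0, 95.0)
        pair_rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "pct_id_a_to_b": round(ident + rng.uniform(-2, 2), 2),
                "pct_id_b_to_a": round(ident + rng.uniform(-2, 2), 2),
                "is_ohnolog": bool(rng.random() < spec.ohnolog_fraction),
            }
        )

    # background LOF evidence on paralog-table genes, so null directed pairs
    # clear the min-LOF filter and the Fisher test has nontrivial margins
    for row in pair_rows:
        for g in (row["gene_a"], row["gene_b"]):
            i = gene_index[g]
            extra = rng.random(spec.n_lines) < spec.background_lof_rate
            expr[i, extra] = rng.uniform(0.0, 0.9, size=int(extra.sum()))

    def gm(values: np.ndarray, kind: str) -> GeneMatrix:
        return GeneMatrix(pd.DataFrame(values, index=genes, columns=lines), kind)

    pairs_tbl = pd.DataFrame(
        pair_rows,
        columns=["gene_a", "gene_b", "pct_id_a_to_b", "pct_id_b_to_a",
                 "is_ohnolog"],
    )
    # directional identities can nick the [0, 100] bounds after jitter
    for col in ("pct_id_a_to_b", "pct_id_b_to_a"):
        pairs_tbl[col] = pairs_tbl[col].clip(0.0, 100.0)

    return Cohort(
        expression=gm(expr, "log2_tpm"),
        bf=gm(bf, "bayes_factor"),
        cn=gm(cn, "copy_number"),
        mutation=gm(mut, "mutation"),
        pairs=ParalogPairTable(pairs_tbl),
        gene_classes=pd.Series([names[c] for c in classes], index=genes),
        gene_params=pd.DataFrame(
            {"mean": gene_mean, "sd": gene_sd}, index=genes
        ),
        planted_truth=pd.DataFrame(
            planted_truth_rows,
            columns=["query_gene", "partner_gene", "pair_id", "penetrance",
                     "lof_rate", "n_lof_lines"],
        ),
    )
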