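"""Synthetic dual-guide screen generator.

The generative model is the additive log-fitness model that the scoring
pipeline assumes, run forwards: a construct's true log2 fold change is the
sum of the single-mutant fitness (SMF) of its two targeted genes plus the
pair's genetic-interaction term (zero unless planted), plus a
guide-efficiency deviation attached to the unordered guide combination and
shared across replicates.  Counts follow a
negative-binomial read model around a log-normally skewed plasmid pool.

There is no positional term by default — mirror constructs (A-B vs B-A)
share a true fold change — but an optional bias can be injected to test the
positional-bias QC.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .design import DesignSpec, GuideSet, build_library
from .exceptions import ConfigError
from .io import CTRL_SENTINEL, CountMatrix, GuideLibrary, pair_key


@dataclasses.dataclass
class FitnessModel:
    """Ground-truth fitness parameters for a simulated screen.

    smf maps gene -> single-mutant fitness in log2 fold-change units per
    screen (~10 doublings); gi maps an unordered pair key -> interaction
    term (negative = synthetic sick/lethal).  Genes absent from smf default
    to 0 if they are the nonessential-control sentinel, and raise otherwise.
    """

    smf: dict[str, float]
    gi: dict[str, float] = dataclasses.field(default_factory=dict)
    guide_noise_sd: float = 0.2
    replicate_noise_sd: float = 0.1
    dispersion: float = 0.01
    depth: float = 500.0
    plasmid_sigma: float = 0.5
    positional_bias: float = 0.0
    cell_lines: tuple[str, ...] = ("LINE1",)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.guide_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")


@dataclasses.dataclass
class SimTruth:
    """True per-construct log2 fold changes and per-pair interaction terms."""

    construct_lfc: pd.Series  # indexed by construct_id
    pair_gi: dict[str, float]
    seed: int

    def save(self, path) -> None:
        out = self.construct_lfc.rename("true_lfc").to_frame()
        out.index.name = "construct_id"
        out.to_csv(path, sep="\t")


def _gene_smf(gene: str, model: FitnessModel) -> float:
    if gene in model.smf:
        return float(model.smf[gene])
    if gene == CTRL_SENTINEL:
        return 0.0
    raise ConfigError(f"gene {gene!r} missing from the fitness model smf map")


def construct_true_lfc(library: GuideLibrary, model: FitnessModel) -> SimTruth:
    """True LFC per construct: smf(A) + smf(B) + gi(pair) + guide noise.

    Guide-efficiency noise is a per-guide effect: every crRNA gets one
    efficiency deviation ~ Normal(0, guide_noise_sd / sqrt(2)), and a
    construct's noise is the sum of its two guides' effects (construct-level
    SD = guide_noise_sd).  The effect travels with the guide across every
    construct, replicate and cell line, so mirror constructs (A-B vs B-A)
    have identical true LFC unless an explicit positional bias is
    configured.
    """
    rng = np.random.default_rng(model.seed)
    tbl = library.table
    lfc = np.empty(len(tbl))
    per_guide_sd = model.guide_noise_sd / np.sqrt(2)
    guide_effect: dict[str, float] = {}

    def effect(guide_id: str) -> float:
        if guide_id not in guide_effect:
            guide_effect[guide_id] = rng.normal(0.0, per_guide_sd)
        return guide_effect[guide_id]

    for i, row in enumerate(tbl.itertuples(index=False)):
        value = _gene_smf(row.gene_a, model) + _gene_smf(row.gene_b, model)
        if row.category == "pair":
            value += model.gi.get(pair_key(row.gene_a, row.gene_b), 0.0)
        value += model.positional_bias * (1 if row.gene_a != CTRL_SENTINEL else -1)
        if model.guide_noise_sd > 0:
            value += effect(row.guide_a_id) + effect(row.guide_b_id)
        lfc[i] = value
    series = pd.Series(lfc, index=tbl["construct_id"].to_numpy())
    return SimTruth(series, dict(model.gi), model.seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2 (gamma-Poisson)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    truth: SimTruth, library: GuideLibrary, model: FitnessModel
) -> CountMatrix:
    """Sample a plasmid pool and post-growth replicate counts.

    Plasmid shares are log-normal with ``plasmid_sigma``; each replicate's
    expected abundance is the plasmid share times 2**(true LFC + replicate
    noise), renormalized, sampled at ``depth`` mean reads per construct.
    """
    rng = np.random.default_rng(truth.seed + 1)
    n = len(library)
    total = model.depth * n

    shares = rng.lognormal(0.0, model.plasmid_sigma, size=n)
    shares = shares / shares.sum()

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    plasmid_mean = shares * total
    columns["plasmid"] = _nb_draw(rng, plasmid_mean, model.dispersion)
    meta_rows.append({"sample_id": "plasmid", "cell_line": "plasmid",
                      "role": "plasmid", "replicate": 0})

    lfc = truth.construct_lfc.to_numpy()
    for line in model.cell_lines:
        for rep in range(1, model.n_replicates + 1):
            noise = (
                rng.normal(0.0, model.replicate_noise_sd, size=n)
                if model.replicate_noise_sd > 0
                else 0.0
            )
            abun = shares * np.exp2(lfc + noise)
            abun = abun / abun.sum()
            sample = f"{line}_rep{rep}"
            columns[sample] = _nb_draw(rng, abun * total, model.dispersion)
            meta_rows.append({"sample_id": sample, "cell_line": line,
                              "role": "replicate", "replicate": rep})

    counts = pd.DataFrame(columns, index=library.table["construct_id"].to_numpy())
    counts.index.name = "construct_id"
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts, samples)


def simulate_screen(
    library: GuideLibrary, model: FitnessModel
) -> tuple[CountMatrix, SimTruth]:
    truth = construct_true_lfc(library, model)
    return simulate_counts(truth, library, model), truth


# ---------------------------------------------------------------------------
# turn-key paralog-screen scenario


def draw_experimental_smf(
    genes: list[str],
    rng: np.random.Generator,
    dropout_fraction: float = 0.2,
    null_mean: float = 0.05,
    null_sd: float = 0.1,
    dropout_mean: float = -0.7,
    dropout_sd: float = 0.3,
) -> dict[str, float]:
    """Left-skewed SMF marginal: most genes near zero, a minority dropping out.

    The default mixture (80% N(0.05, 0.1), 20% N(-0.7, 0.3)) has mean -0.10
    and a slightly positive median, the shape reported for real screens of
    this design.
    """
    is_dropout = rng.random(len(genes)) < dropout_fraction
    values = np.where(
        is_dropout,
        rng.normal(dropout_mean, dropout_sd, len(genes)),
        rng.normal(null_mean, null_sd, len(genes)),
    )
    return dict(zip(genes, values))


def make_paralog_screen(
    n_pairs: int = 100,
    n_planted: int = 10,
    gi_effect: float = -2.0,
    guides_per_gene: int = 3,
    n_nonessential_genes: int = 20,
    n_essential_genes: int = 10,
    essential_smf_range: tuple[float, float] = (-2.0, -1.0),
    cell_lines: tuple[str, ...] = ("LINE1", "LINE2", "LINE3"),
    seed: int = 0,
    **model_kwargs,
) -> tuple[GuideLibrary, FitnessModel, CountMatrix, SimTruth]:
    """Build a library, plant negative interactions, and sample counts.

    The first ``n_planted`` pairs carry ``gi_effect``; all other pairs have
    no interaction.  Returns the library, the ground-truth model, the count
    matrix and the truth table.
    """
    rng = np.random.default_rng(seed)

    def make_sets(prefix, n_genes, gene_class):
        sets = []
        for g in range(n_genes):
            gene = f"{prefix}{g:04d}"
            guides = [(f"{gene}_g{i + 1}", "") for i in range(guides_per_gene)]
            sets.append(GuideSet(gene, guides, gene_class))
        return sets

    pair_genes = [f"GENE{g:04d}" for g in range(2 * n_pairs)]
    gene_guides = {
        g: GuideSet(g, [(f"{g}_g{i + 1}", "") for i in range(guides_per_gene)])
        for g in pair_genes
    }
    pairs = [(pair_genes[2 * i], pair_genes[2 * i + 1]) for i in range(n_pairs)]
    noness = make_sets("NE", n_nonessential_genes, "nonessential_control")
    essential = make_sets("ESS", n_essential_genes, "essential_control")

    spec = DesignSpec(
        pairs=pairs,
        gene_guides=gene_guides,
        nonessential_pool=noness,
        essential_pool=essential,
        seed=seed,
    )
    library = build_library(spec)

    smf = draw_experimental_smf(pair_genes, rng)
    lo, hi = essential_smf_range
    for ess in essential:
        smf[ess.gene] = float(rng.uniform(lo, hi))
    for ne in noness:
        smf[ne.gene] = 0.0

    gi = {pair_key(a, b): gi_effect for a, b in pairs[:n_planted]}
    model = FitnessModel(smf=smf, gi=gi, cell_lines=cell_lines, seed=seed,
                         **model_kwargs)
    counts, truth = simulate_screen(library, model)
    return library, model, counts, truth
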