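"""Combinatorial design of the dual-guide construct library.

Each candidate gene pair is targeted by every cross-combination of its
guides in both orientations (n_A * n_B * 2 constructs; 18 for the usual
3 x 3 case).  Single-knockout fitness is measured by gene-control
constructs: each guide of a gene is paired with one randomly drawn guide
from a nonessential-gene pool, again in both orientations (2 per guide, 6
for a 3-guide gene).  Guides targeting known essential genes get the same
random-nonessential pairing and serve as positive controls for dropout.

Guide selection itself (on-target scoring, PAM constraints) happens
upstream; this module consumes per-gene guide lists.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import CTRL_SENTINEL, GuideLibrary, pair_key

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GuideSet:
    """Up to three guides for one gene.

    ``guides`` is an ordered list of ``(guide_id, sequence)``; sequences may
    be empty strings when only identifiers are known.  ``gene_class`` is one
    of ``experimental``, ``nonessential_control``, ``essential_control``.
    """

    gene: str
    guides: list[tuple[str, str]]
    gene_class: str = "experimental"

    CLASSES = ("experimental", "nonessential_control", "essential_control")

    def __post_init__(self) -> None:
        if self.gene_class not in self.CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if len(self.guides) > 3:
            raise ValueError(f"{self.gene}: more than 3 guides")
        ids = [g for g, _ in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.gene}: duplicate guide ids")

    def __len__(self) -> int:
        return len(self.guides)


@dataclasses.dataclass
class DesignSpec:
    """Everything needed to build a library deterministically."""

    pairs: list[tuple[str, str]]
    gene_guides: dict[str, GuideSet]
    nonessential_pool: list[GuideSet]
    essential_pool: list[GuideSet] = dataclasses.field(default_factory=list)
    seed: int = 0


def _construct_row(
    guide_a: tuple[str, str],
    guide_b: tuple[str, str],
    gene_a: str,
    gene_b: str,
    category: str,
    pair_id: str,
) -> dict:
    return {
        "construct_id": f"{guide_a[0]}__{guide_b[0]}",
        "guide_a_id": guide_a[0],
        "guide_b_id": guide_b[0],
        "guide_a_seq": guide_a[1],
        "guide_b_seq": guide_b[1],
        "gene_a": gene_a,
        "gene_b": gene_b,
        "category": category,
        "pair_id": pair_id,
    }


def enumerate_pair_constructs(set_a: GuideSet, set_b: GuideSet) -> list[dict]:
    """All guide cross-combinations of a gene pair, both orientations.

    Returns ``n_A * n_B * 2`` construct rows.  An empty guide set means the
    pair cannot be screened; it is skipped with a warning (mirroring how
    pairs whose genes had no usable guides are dropped from a real design).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        warnings.warn(
            f"pair {set_a.gene}/{set_b.gene} skipped: gene without guides",
            stacklevel=2,
        )
        return []
    pid = pair_key(set_a.gene, set_b.gene)
    rows = []
    for ga in set_a.guides:
        for gb in set_b.guides:
            rows.append(_construct_row(ga, gb, set_a.gene, set_b.gene, "pair", pid))
            rows.append(_construct_row(gb, ga, set_b.gene, set_a.gene, "pair", pid))
    return rows


def gene_control_constructs(
    set_g: GuideSet,
    pool: Sequence[GuideSet],
    rng: np.random.Generator,
) -> list[dict]:
    """Pair each guide of a gene with a random nonessential guide, both ways.

    Yields ``2 * n_g`` constructs.  Draws are uniform over the pooled
    nonessential guides, without replacement within one gene's draws so a
    gene's controls use distinct partners.
    """
    if len(set_g) == 0:
        warnings.warn(f"gene {set_g.gene}: no guides, no control constructs",
                      stacklevel=2)
        return []
    pool_guides = [(gs.gene, g) for gs in pool for g in gs.guides]
    if not pool_guides:
        raise ConfigError("nonessential guide pool is empty")
    if len(pool_guides) < len(set_g):
        raise ConfigError(
            f"pool smaller than guide count for {set_g.gene}; cannot draw "
            "distinct partners"
        )
    category = (
        "essential_control"
        if set_g.gene_class == "essential_control"
        else "gene_control"
    )
    idx = rng.choice(len(pool_guides), size=len(set_g), replace=False)
    rows = []
    for guide, i in zip(set_g.guides, idx):
        ctrl_gene, ctrl_guide = pool_guides[int(i)]
        # gene in position A, control in position B — and the mirror
        rows.append(
            _construct_row(guide, ctrl_guide, set_g.gene, CTRL_SENTINEL, category, "")
        )
        rows.append(
            _construct_row(ctrl_guide, guide, CTRL_SENTINEL, set_g.gene, category, "")
        )
    return rows


def build_library(spec: DesignSpec) -> GuideLibrary:
    """Assemble pair, gene-control and essential-control constructs.

    Pairs containing a guideless gene are dropped and reported in
    ``library.table.attrs['dropped_pairs']``.  Duplicate constructs (same
    ordered guide combination, possible when a control draw collides with
    another) are deduplicated with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    dropped: list[str] = []
    screened_genes: list[str] = []
    seen_genes: set[str] = set()

    for gene_a, gene_b in spec.pairs:
        try:
            set_a = spec.gene_guides[gene_a]
            set_b = spec.gene_guides[gene_b]
        except KeyError as exc:
            raise ConfigError(f"pair gene without a GuideSet: {exc}") from exc
        if len(set_a) == 0 or len(set_b) == 0:
            dropped.append(pair_key(gene_a, gene_b))
            logger.warning("dropping pair %s/%s: gene without guides",
                           gene_a, gene_b)
            continue
        rows.extend(enumerate_pair_constructs(set_a, set_b))
        for gene in (gene_a, gene_b):
            if gene not in seen_genes:
                seen_genes.add(gene)
                screened_genes.append(gene)

    # gene controls: one batch per distinct experimental gene, in pair order
    for gene in screened_genes:
        rows.extend(
            gene_control_constructs(spec.gene_guides[gene],
                                    spec.nonessential_pool, rng)
        )
    for ess in spec.essential_pool:
        rows.extend(gene_control_constructs(ess, spec.nonessential_pool, rng))

    table = pd.DataFrame(rows)
    dup = table["construct_id"].duplicated()
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate constructs removed from design",
            stacklevel=2,
        )
        table = table.loc[~dup]
    library = GuideLibrary(table)
    library.table.attrs["dropped_pairs"] = dropped
    return library


def expected_construct_count(
    pair_sizes: Iterable[tuple[int, int]],
    gene_sizes: Iterable[int],
    n_essential_guides: int,
) -> int:
    """Closed-form construct count: 2*sum(nA*nB) + 2*sum(n_g) + 2*n_ess."""
    pairs = 2 * sum(a * b for a, b in pair_sizes)
    controls = 2 * sum(gene_sizes)
    return pairs + controls + 2 * n_essential_guides


# ---------------------------------------------------------------------------
# loading per-gene guide tables


def guide_sets_from_table(table: pd.DataFrame) -> dict[str, GuideSet]:
    """Build GuideSets from a long table (gene, guide_id, sequence, class)."""
    required = {"gene", "guide_id", "class"}
    if not required <= set(table.columns):
        raise ConfigError(f"guide table needs columns {sorted(required)}")
    sets = {}
    for gene, grp in table.groupby("gene", sort=False):
        seqs = grp["sequence"] if "sequence" in grp.columns else [""] * len(grp)
        guides = list(zip(grp["guide_id"].astype(str), [str(s) for s in seqs]))
        sets[str(gene)] = GuideSet(str(gene), guides, str(grp["class"].iloc[0]))
    return sets
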