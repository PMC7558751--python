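"""Raw read counts -> construct log fold changes, with screen QC.

Processing order: add a pseudocount (default 5 reads) to every construct in
every sample, scale each sample so its mean is ``target_mean`` reads per
construct (default 500), take log2 of each replicate against the plasmid
reference, and average replicates into a screen-level fold change per
construct per cell line.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SchemaError
from .io import CountMatrix, GuideLibrary

DEFAULT_PSEUDOCOUNT = 5
DEFAULT_TARGET_MEAN = 500.0


def normalize_counts(
    counts: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    target_mean: float = DEFAULT_TARGET_MEAN,
) -> pd.DataFrame:
    """Pseudocount then per-sample scaling to a common mean depth.

    Each sample column becomes ``(count + pseudocount) * target_mean /
    mean(count + pseudocount)``, so all column means equal ``target_mean``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    shifted = counts.counts.astype(float) + pseudocount
    return shifted * target_mean / shifted.mean(axis=0)


@dataclasses.dataclass
class FoldChangeTable:
    """Replicate- and screen-level construct log fold changes.

    ``replicate_lfc``: constructs x replicate samples (log2 vs plasmid).
    ``screen_lfc``: constructs x cell lines, the mean of each line's
    replicate columns.
    """

    replicate_lfc: pd.DataFrame
    screen_lfc: pd.DataFrame
    samples: pd.DataFrame

    @property
    def cell_lines(self) -> list[str]:
        return list(self.screen_lfc.columns)

    def save(self, path) -> None:
        out = self.screen_lfc.copy()
        out.index.name = "construct_id"
        out.to_csv(path, sep="\t")


def log_fold_change(
    normalized: pd.DataFrame, samples: pd.DataFrame, log_base: float = 2.0
) -> FoldChangeTable:
    """Per-replicate fold change vs the plasmid, averaged per cell line."""
    plasmid_ids = samples.index[samples["role"] == "plasmid"]
    if len(plasmid_ids) != 1:
        raise SchemaError(f"expected one plasmid sample, found {len(plasmid_ids)}")
    plasmid = normalized[plasmid_ids[0]]

    rep_meta = samples[samples["role"] == "replicate"]
    rep_lfc = np.log(normalized[rep_meta.index].div(plasmid, axis=0)) / np.log(log_base)

    screen = {}
    for line, grp in rep_meta.groupby("cell_line", sort=True):
        screen[line] = rep_lfc[grp.index].mean(axis=1)
    return FoldChangeTable(rep_lfc, pd.DataFrame(screen), samples)


# ---------------------------------------------------------------------------
# QC


@dataclasses.dataclass
class SeparationResult:
    """Essential-control dropout separation for one cell line."""

    auc: float
    median_difference: float  # median(essential LFC) - median(others)
    essential_lfc: pd.Series
    other_lfc: pd.Series


def qc_separation(
    fc: FoldChangeTable, library: GuideLibrary, cell_line: str
) -> SeparationResult | None:
    """Rank separation of essential-control constructs from everything else.

    AUC is the probability that a random essential-control construct is more
    depleted (lower LFC) than a random other construct; 1.0 is perfect
    separation, 0.5 none.  Returns ``None`` (with a warning) when the
    library has no essential controls.
    """
    tbl = library.table.set_index("construct_id")
    lfc = fc.screen_lfc[cell_line]
    common = lfc.index.intersection(tbl.index)
    ess_mask = tbl.loc[common, "category"] == "essential_control"
    essential = lfc.loc[common[ess_mask]]
    other = lfc.loc[common[~ess_mask]]
    if len(essential) == 0:
        warnings.warn("no essential-control constructs: separation QC skipped",
                      stacklevel=2)
        return None
    # U counts (other > essential) pairs, + half the ties
    u = stats.mannwhitneyu(other, essential, alternative="two-sided").statistic
    auc = float(u / (len(essential) * len(other)))
    return SeparationResult(
        auc=auc,
        median_difference=float(essential.median() - other.median()),
        essential_lfc=essential,
        other_lfc=other,
    )


@dataclasses.dataclass
class MirrorResult:
    """Orientation-mirror consistency for one cell line."""

    pearson_r: float
    n_mirror_pairs: int
    n_unmatched: int


def positional_bias(
    fc: FoldChangeTable, library: GuideLibrary, cell_line: str
) -> MirrorResult:
    """Correlation between screen LFCs of A-B constructs and their B-A mirrors.

    High correlation means guide position in the crRNA array does not bias
    fitness readout.  Constructs without a mirror in the library are counted
    and excluded; with fewer than 3 mirror pairs the correlation is NaN.
    """
    tbl = library.table
    by_guides = {
        (row.guide_a_id, row.guide_b_id): row.construct_id
        for row in tbl.itertuples(index=False)
    }
    lfc = fc.screen_lfc[cell_line]
    x, y = [], []
    unmatched = 0
    for row in tbl.itertuples(index=False):
        mirror = by_guides.get((row.guide_b_id, row.guide_a_id))
        if mirror is None or mirror == row.construct_id:
            unmatched += 1
            continue
        if row.guide_a_id < row.guide_b_id:  # count each mirror pair once
            x.append(lfc.get(row.construct_id, np.nan))
            y.append(lfc.get(mirror, np.nan))
    n = len(x)
    if n < 3:
        warnings.warn(f"only {n} mirror pairs: correlation undefined", stacklevel=2)
        return MirrorResult(np.nan, n, unmatched)
    r = float(stats.pearsonr(x, y).statistic)
    return MirrorResult(r, n, unmatched)


@dataclasses.dataclass
class QCReport:
    """Per-sample depth/skew plus screen-level quality statistics."""

    sample_stats: pd.DataFrame  # total_reads, mean_reads, top10_fraction
    replicate_correlation: pd.DataFrame
    separation: dict[str, SeparationResult | None]
    mirror: dict[str, MirrorResult]

    def summary(self) -> dict:
        return {
            "separation_auc": {
                line: (None if res is None else res.auc)
                for line, res in self.separation.items()
            },
            "mirror_r": {line: res.pearson_r for line, res in self.mirror.items()},
            "min_replicate_r": float(
                np.nanmin(self.replicate_correlation.to_numpy())
            ),
        }


def qc_report(
    counts: CountMatrix, fc: FoldChangeTable, library: GuideLibrary
) -> QCReport:
    raw = counts.counts
    totals = raw.sum(axis=0)
    k = max(1, int(0.1 * len(raw)))
    top10 = raw.apply(lambda col: col.nlargest(k).sum() / max(col.sum(), 1), axis=0)
    sample_stats = pd.DataFrame(
        {
            "total_reads": totals,
            "mean_reads": raw.mean(axis=0),
            "top10_fraction": top10,
        }
    )
    rep_corr = fc.replicate_lfc.corr(method="pearson")
    separation = {
        line: qc_separation(fc, library, line) for line in fc.cell_lines
    }
    mirror = {line: positional_bias(fc, library, line) for line in fc.cell_lines}
    return QCReport(sample_stats, rep_corr, separation, mirror)
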