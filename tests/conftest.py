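import numpy as np
import pandas as pd
import pytest

import parascreen as ps


@pytest.fixture(scope="session")
def default_screen():
    """One simulated paralog screen under the default study-like conditions:
    100 pairs, 10 planted at gi = -2, 3 cell lines x 3 replicates, depth 500."""
    return ps.make_paralog_screen(n_pairs=100, n_planted=10, seed=0)


@pytest.fixture(scope="session")
def default_fc(default_screen):
    _, _, counts, _ = default_screen
    norm = ps.normalize_counts(counts)
    return ps.log_fold_change(norm, counts.samples)


@pytest.fixture(scope="session")
def default_scores(default_screen, default_fc):
    library, _, _, _ = default_screen
    return ps.score_pairs(default_fc, library)


@pytest.fixture
def toy_library():
    """Two pair constructs (mirrors) + two gene controls, built by hand."""
    rows = [
        ("c1", "gA1", "gB1", "A", "B", "pair", "A_B"),
        ("c2", "gB1", "gA1", "B", "A", "pair", "A_B"),
        ("c3", "gA1", "gN1", "A", "CTRL", "gene_control", ""),
        ("c4", "gN1", "gA1", "CTRL", "A", "gene_control", ""),
    ]
    table = pd.DataFrame(
        rows,
        columns=["construct_id", "guide_a_id", "guide_b_id", "gene_a",
                 "gene_b", "category", "pair_id"],
    )
    return ps.GuideLibrary(table)


def make_fold_changes(lfc_by_line: dict[str, dict[str, float]]):
    """Hand-built FoldChangeTable: {cell_line: {construct_id: screen LFC}}."""
    screen = pd.DataFrame(lfc_by_line)
    samples = pd.DataFrame(
        {
            "cell_line": ["plasmid"] + list(lfc_by_line),
            "role": ["plasmid"] + ["replicate"] * len(lfc_by_line),
            "replicate": [0] + [1] * len(lfc_by_line),
        },
        index=["plasmid"] + [f"{line}_rep1" for line in lfc_by_line],
    )
    rep = screen.copy()
    rep.columns = [f"{line}_rep1" for line in lfc_by_line]
    return ps.FoldChangeTable(rep, screen, samples)
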