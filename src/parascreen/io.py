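"""Tabular I/O for screen artifacts.

All tables are UTF-8, tab-separated text with a header row.  The guide
library and the read-count matrix live in separate files joined on
``construct_id``; sample metadata (which column of the count matrix is the
plasmid reference, which cell line and replicate each column belongs to)
comes from a separate sample sheet rather than being guessed from column
names.

The ``"CTRL"`` sentinel in a gene slot marks a nonessential-control guide
position of a single-knockout (gene-control) construct.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError

CTRL_SENTINEL = "CTRL"

CATEGORIES = ("pair", "gene_control", "essential_control")

LIBRARY_COLUMNS = (
    "construct_id",
    "guide_a_id",
    "guide_b_id",
    "gene_a",
    "gene_b",
    "category",
    "pair_id",
)
# sequences are optional
LIBRARY_OPTIONAL_COLUMNS = ("guide_a_seq", "guide_b_seq")

SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "role", "replicate")

ROLES = ("plasmid", "replicate")


def pair_key(gene_a: str, gene_b: str) -> str:
    """Canonical unordered key for a gene pair (sorted, ``_``-joined)."""
    return "_".join(sorted((str(gene_a), str(gene_b))))


@dataclasses.dataclass
class GuideLibrary:
    """Dual-guide construct library.

    ``table`` has one row per construct with the columns in
    :data:`LIBRARY_COLUMNS` (plus optional guide sequences).  Position A and
    B are the first and second slot of the crRNA array; both orientations of
    a guide combination are distinct constructs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"guide library missing columns: {missing}")
        dup = self.table["construct_id"].duplicated()
        if dup.any():
            raise SchemaError(
                "duplicate construct_id values: "
                f"{sorted(self.table.loc[dup, 'construct_id'].unique())[:5]}"
            )
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown construct categories: {sorted(bad)}")
        # empty pair_id / sequence cells read back as NaN; normalize to ""
        for col in ("pair_id", *LIBRARY_OPTIONAL_COLUMNS):
            if col in self.table.columns:
                self.table[col] = self.table[col].fillna("").astype(str)
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> list[str]:
        """Sorted unique pair_ids of dual-targeting constructs."""
        mask = self.table["category"] == "pair"
        return sorted(self.table.loc[mask, "pair_id"].unique())

    def constructs_for_pair(self, pair_id: str) -> pd.DataFrame:
        mask = (self.table["category"] == "pair") & (self.table["pair_id"] == pair_id)
        return self.table.loc[mask]

    def save(self, path: str | Path) -> None:
        cols = list(LIBRARY_COLUMNS) + [
            c for c in LIBRARY_OPTIONAL_COLUMNS if c in self.table.columns
        ]
        self.table[cols].to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class CountMatrix:
    """Integer read counts per construct (rows) per sample (columns).

    ``samples`` is indexed by sample_id with columns ``cell_line``, ``role``
    (``plasmid`` or ``replicate``) and ``replicate`` (index within the cell
    line; 0 for the plasmid).  Exactly one plasmid sample is required — it is
    the shared reference for every cell line's fold changes.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.samples.index):
            unknown = sorted(set(self.counts.columns) - set(self.samples.index))
            raise SchemaError(f"samples missing from sample sheet: {unknown}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise SchemaError(f"unknown sample roles: {sorted(bad_roles)}")
        n_plasmid = int((self.samples["role"] == "plasmid").sum())
        if n_plasmid != 1:
            raise SchemaError(
                f"expected exactly one plasmid sample, found {n_plasmid}"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def plasmid_sample(self) -> str:
        return str(self.samples.index[self.samples["role"] == "plasmid"][0])

    @property
    def cell_lines(self) -> list[str]:
        reps = self.samples[self.samples["role"] == "replicate"]
        return sorted(reps["cell_line"].unique())

    def replicate_samples(self, cell_line: str) -> list[str]:
        mask = (self.samples["role"] == "replicate") & (
            self.samples["cell_line"] == cell_line
        )
        return list(self.samples.index[mask])

    def save(self, counts_path: str | Path, sample_sheet_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "construct_id"
        out.to_csv(counts_path, sep="\t")
        sheet = self.samples.copy()
        sheet.index.name = "sample_id"
        sheet.to_csv(sample_sheet_path, sep="\t")


@dataclasses.dataclass
class GeneMatrix:
    """Gene (rows) x cell line (columns) matrix with a declared value kind.

    ``value_kind`` is one of ``log2_tpm``, ``bayes_factor``, ``copy_number``,
    ``mutation`` (boolean damaging-mutation flags).
    """

    values: pd.DataFrame
    value_kind: str

    VALUE_KINDS = ("log2_tpm", "bayes_factor", "copy_number", "mutation")

    def __post_init__(self) -> None:
        if self.value_kind not in self.VALUE_KINDS:
            raise ValueError(f"unknown value_kind: {self.value_kind!r}")
        if self.values.index.duplicated().any():
            raise SchemaError("duplicate gene keys in GeneMatrix")
        if self.values.columns.duplicated().any():
            raise SchemaError("duplicate cell-line keys in GeneMatrix")
        if self.value_kind == "mutation":
            self.values = self.values.astype(bool)
        else:
            self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None

    def save(self, path: str | Path) -> None:
        out = self.values.copy()
        if self.value_kind == "mutation":
            out = out.astype(int)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclasses.dataclass
class ParalogPairTable:
    """Unordered paralog pairs with directional percent sequence identity."""

    table: pd.DataFrame

    REQUIRED = ("gene_a", "gene_b", "pct_id_a_to_b", "pct_id_b_to_a")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"paralog table missing columns: {missing}")
        keys = self.table.apply(lambda r: pair_key(r.gene_a, r.gene_b), axis=1)
        if keys.duplicated().any():
            raise SchemaError("duplicate unordered pairs in paralog table")
        for col in ("pct_id_a_to_b", "pct_id_b_to_a"):
            vals = self.table[col].astype(float)
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} outside [0, 100]")
        self.table = self.table.assign(pair_id=keys.to_numpy()).reset_index(drop=True)

    def min_identity(self) -> pd.Series:
        """Per-pair min of the two directional identities, indexed by pair_id."""
        m = np.minimum(
            self.table["pct_id_a_to_b"].astype(float),
            self.table["pct_id_b_to_a"].astype(float),
        )
        return pd.Series(m.to_numpy(), index=self.table["pair_id"])

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loaders


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def load_guide_library(path: str | Path) -> GuideLibrary:
    """Load and validate a guide library TSV/CSV."""
    return GuideLibrary(_read_tsv(path))


def load_count_matrix(
    path: str | Path,
    sample_sheet: str | Path,
    library: GuideLibrary | None = None,
) -> CountMatrix:
    """Load a count matrix plus its sample sheet.

    When a :class:`GuideLibrary` is supplied, constructs absent from it are
    recorded in ``matrix.samples.attrs['unmatched_constructs']`` but kept —
    dropping reads silently would distort normalization.
    """
    counts = _read_tsv(path)
    if "construct_id" not in counts.columns:
        raise SchemaError("count matrix must have a construct_id column")
    counts = counts.set_index("construct_id")
    sheet = _read_tsv(sample_sheet)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet missing columns: {missing}")
    sheet = sheet.set_index("sample_id")
    matrix = CountMatrix(counts, sheet)
    if library is not None:
        known = set(library.table["construct_id"])
        unmatched = sorted(set(matrix.counts.index) - known)
        matrix.samples.attrs["unmatched_constructs"] = unmatched
    return matrix


def load_gene_matrix(path: str | Path, value_kind: str) -> GeneMatrix:
    df = _read_tsv(path)
    first = df.columns[0]
    return GeneMatrix(df.set_index(first), value_kind)


def load_paralog_pairs(path: str | Path) -> ParalogPairTable:
    return ParalogPairTable(_read_tsv(path))


# ---------------------------------------------------------------------------
# run manifest


def write_manifest(path: str | Path, parameters: Mapping[str, object]) -> None:
    """Record every tunable parameter actually used by a run as YAML."""
    clean = {}
    for key, value in parameters.items():
        if isinstance(value, (np.integer,)):
            value = int(value)
        elif isinstance(value, (np.floating,)):
            value = float(value)
        clean[str(key)] = value
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
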