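"""Tabular input/output for expression matrices, sample sheets and target predictions.

All files are plain delimited text (tab-separated unless noted), UTF-8, decimal
point ``.``.  Blank cells in an expression matrix are a distinct *not detected*
state, carried as NaN internally and never coerced to zero: downstream means,
tests and distances exclude them pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConfigurationError",
    "ExpressionMatrix",
    "SampleSheet",
    "PredictionSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_prediction_tables",
    "write_prediction_tables",
    "SPECIES",
    "SOURCES",
    "GROUPS",
    "CASE_LABELS",
]

SPECIES = ("rat", "human")
SOURCES = ("pancreas", "liver", "adipose", "skeletal_muscle", "blood")
GROUPS = ("control", "case")
CASE_LABELS = ("T2D", "IFG", "HFD")

SHEET_COLUMNS = ("sample_id", "subject_id", "species", "source", "group")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. a normalizer probe absent from a matrix)."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample intensity matrix.

    Parameters
    ----------
    data
        DataFrame of non-negative intensities, index = feature (probe) ids,
        columns = sample ids.  NaN marks a *not detected* cell.
    normalizer_id
        Optional id of the normalization reference probe (e.g. ``"U6"``);
        must be one of the features when set.
    """

    data: pd.DataFrame
    normalizer_id: str | None = None

    def __post_init__(self) -> None:
        self.data.index.name = None
        self.data.columns.name = None
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("expression intensities must be >= 0")
        if self.normalizer_id is not None and self.normalizer_id not in idx:
            raise ConfigurationError(
                f"normalizer {self.normalizer_id!r} is not among the features"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.normalizer_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.normalizer_id)


@dataclass
class SampleSheet:
    """Per-sample metadata binding samples to subject, species, source and group.

    ``case_label`` is required on ``case`` rows (one of T2D/IFG/HFD) and empty
    on ``control`` rows; one control group per (species, source) stratum serves
    every case label contrasted against it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing required column(s): {missing}")
        if "case_label" not in df.columns:
            df = df.assign(case_label="")
        df = df.fillna({"case_label": ""}).astype(str)
        df["case_label"] = df["case_label"].replace("nan", "")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        bad_species = sorted(set(df["species"]) - set(SPECIES))
        if bad_species:
            raise FormatError(f"unknown species token(s): {bad_species}")
        bad_source = sorted(set(df["source"]) - set(SOURCES))
        if bad_source:
            raise FormatError(f"unknown source token(s): {bad_source}")
        bad_group = sorted(set(df["group"]) - set(GROUPS))
        if bad_group:
            raise FormatError(f"unknown group token(s): {bad_group}")
        case_rows = df["group"] == "case"
        bad_label = sorted(set(df.loc[case_rows, "case_label"]) - set(CASE_LABELS))
        if bad_label:
            raise FormatError(f"unknown case label(s): {bad_label}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def strata(self) -> list[tuple[str, str]]:
        """Distinct (species, source) strata, in order of first appearance."""
        seen = self.data[["species", "source"]].drop_duplicates()
        return [tuple(r) for r in seen.to_numpy()]

    def case_labels(self, species: str, source: str) -> list[str]:
        df = self.data
        mask = (df.species == species) & (df.source == source) & (df.group == "case")
        return sorted(set(df.loc[mask, "case_label"]))

    def samples(
        self,
        species: str,
        source: str,
        group: str | None = None,
        case_label: str | None = None,
    ) -> pd.DataFrame:
        df = self.data
        mask = (df.species == species) & (df.source == source)
        if group is not None:
            mask &= df.group == group
        if case_label is not None:
            mask &= df.case_label == case_label
        return df.loc[mask]


@dataclass
class PredictionSet:
    """miRNA→gene predictions from k independent databases.

    Maps each database name to its deduplicated set of (mirna_id, gene_id)
    pairs.  The consensus vote of a pair is the number of databases listing it.
    """

    databases: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.databases) < 1:
            raise ConfigurationError("a PredictionSet needs at least one database")
        self.databases = {
            name: frozenset((str(m), str(g)) for m, g in pairs)
            for name, pairs in self.databases.items()
        }

    @property
    def k(self) -> int:
        return len(self.databases)

    def votes(self) -> dict[tuple[str, str], set[str]]:
        """Pair → set of database names listing it."""
        out: dict[tuple[str, str], set[str]] = {}
        for name, pairs in self.databases.items():
            for pair in pairs:
                out.setdefault(pair, set()).add(name)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, normalizer_id: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated matrix: first column feature ids, first row sample ids.

    Blank cells become NaN (*not detected*).  Duplicated ids and non-numeric
    cells raise :class:`FormatError` naming the offender; a ``normalizer_id``
    absent from the file raises :class:`ConfigurationError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        converted = pd.to_numeric(cell.replace("", np.nan), errors="coerce")
        bad = converted.isna() & (cell != "")
        if bad.any():
            row = raw.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} at feature {row!r}, sample {col!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric, normalizer_id=normalizer_id)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write tab-separated; *not detected* cells are written as empty strings."""
    matrix.data.to_csv(path, sep="\t", na_rep="", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab- or comma-separated sample sheet with the five required columns."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_prediction_tables(paths: Mapping[str, str | Path] | Iterable[str | Path]) -> PredictionSet:
    """Read per-database two-column (mirna_id, gene_id) tables.

    ``paths`` maps database name → file, or is an iterable of files whose stems
    become the database names.  An empty file yields a warning and an empty set.
    """
    if not isinstance(paths, Mapping):
        paths = {Path(p).stem: p for p in paths}
    databases: dict[str, frozenset[tuple[str, str]]] = {}
    for name, p in paths.items():
        if name in databases:
            raise FormatError(f"duplicate database name {name!r}")
        try:
            df = pd.read_csv(p, sep="\t", header=None, dtype=str, comment="#",
                             keep_default_na=False)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=[0, 1])
        if df.empty:
            warnings.warn(f"prediction table {p} is empty; database {name!r} kept with no pairs")
            databases[name] = frozenset()
            continue
        if df.shape[1] < 2:
            raise FormatError(f"{p}: expected two tab-separated columns (mirna_id, gene_id)")
        databases[name] = frozenset(zip(df[0].str.strip(), df[1].str.strip()))
    return PredictionSet(databases)


def write_prediction_tables(predictions: PredictionSet, directory: str | Path) -> dict[str, Path]:
    """Write one two-column TSV per database into *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, pairs in predictions.databases.items():
        p = directory / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            for mirna, gene in sorted(pairs):
                fh.write(f"{mirna}\t{gene}\n")
        out[name] = p
    return out
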