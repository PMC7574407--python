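"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tab-delimited gene-by-sample matrices (first column gene ids,
header row sample ids), GMT gene-set files, clinical TSV tables with
columns ``sample``, ``time``, ``event``, and one-symbol-per-line gene
lists.  Reading always validates into the typed containers; writing
round-trips bit-exactly for binary matrices and at six significant
digits for continuous ones.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import (
    AlterationMatrix,
    FeatureMatrix,
    GeneSetCollection,
    SurvivalData,
    ValidationError,
)

PathLike = Union[str, Path]

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "read_features",
    "write_features",
]


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


def _read_table(path: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: {exc}") from exc
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in column(s) {non_numeric[:5]}")
    return df


def read_matrix(path: PathLike, flavor: str) -> AlterationMatrix:
    """Read a gene-by-sample TSV into an :class:`AlterationMatrix`.

    ``flavor='binary'`` rejects any cell outside {0, 1}.
    """
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return AlterationMatrix(df, flavor)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(matrix: AlterationMatrix, path: PathLike) -> None:
    df = matrix.values
    if matrix.flavor == "binary":
        df.to_csv(path, sep="\t", index_label="gene")
    else:
        df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes…``.

    Duplicate member symbols within a set are counted once.
    """
    members: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if name in members:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            members[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(members, descriptions)


def write_gmt(sets: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in sets.set_names:
            desc = sets.descriptions.get(name, "na")
            genes = sorted(sets.members[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path: PathLike) -> SurvivalData:
    """Read a clinical TSV with columns ``sample``, ``time``, ``event``."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    try:
        return SurvivalData(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clinical(survival: SurvivalData, path: PathLike) -> None:
    survival.frame.to_csv(path, sep="\t", index_label="sample")


def read_gene_list(path: PathLike) -> frozenset[str]:
    """Read a one-symbol-per-line gene list; blank lines are skipped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    return frozenset(genes)


def write_gene_list(genes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_features(path: PathLike, level: str, source: str) -> FeatureMatrix:
    """Read a sample-by-predictor TSV into a :class:`FeatureMatrix`."""
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return FeatureMatrix(df, level, source)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_features(features: FeatureMatrix, path: PathLike) -> None:
    features.values.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")
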