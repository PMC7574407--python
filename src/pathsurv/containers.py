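"""Core data containers for the somatic-alteration survival pipeline.

Three raw inputs -- a gene-by-sample alteration matrix, a per-sample
survival table and a collection of gene sets -- and one derived object,
the sample-by-predictor feature matrix fed to the Cox models.  All
containers are thin, validated wrappers around pandas objects so the
rest of the package can rely on their invariants (no missing values,
unique identifiers, binary matrices really binary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationMatrix",
    "SurvivalData",
    "GeneSetCollection",
    "FeatureMatrix",
    "align_to_samples",
]


class ValidationError(ValueError):
    """An input object violated a container invariant."""


@dataclass
class AlterationMatrix:
    """Gene-by-sample matrix of somatic alterations.

    ``flavor='binary'`` holds 0/1 non-silent mutation calls (SPM);
    ``flavor='continuous'`` holds gene-level copy-number estimates (CNV).

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows (index), samples as columns.
    flavor : {'binary', 'continuous'}
    """

    values: pd.DataFrame
    flavor: str

    def __post_init__(self) -> None:
        if self.flavor not in ("binary", "continuous"):
            raise ValidationError(f"unknown flavor {self.flavor!r}")
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if df.isna().any().any():
            col = df.columns[df.isna().any(axis=0)][0]
            row = df.index[df.isna().any(axis=1)][0]
            raise ValidationError(f"missing value at gene {row!r}, sample {col!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("matrix contains non-numeric cells")
        if self.flavor == "binary":
            ok = np.isin(arr, (0, 1))
            if not ok.all():
                i, j = np.argwhere(~ok)[0]
                raise ValidationError(
                    f"binary matrix has value {arr[i, j]!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                )
            self.values = df.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sparsity(self) -> float:
        """Fraction of zero entries."""
        return float((self.values.to_numpy() == 0).mean())

    def restrict_genes(self, keep: Iterable[str]) -> "AlterationMatrix":
        """Subset to ``keep`` ∩ genes, preserving row order."""
        keep = set(keep)
        mask = [g in keep for g in self.values.index]
        if not any(mask):
            raise ValidationError("gene restriction leaves an empty matrix")
        return AlterationMatrix(self.values.loc[mask], self.flavor)

    def restrict_samples(self, samples: list[str]) -> "AlterationMatrix":
        return AlterationMatrix(self.values[samples], self.flavor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlterationMatrix):
            return NotImplemented
        return self.flavor == other.flavor and self.values.astype(float).equals(
            other.values.astype(float)
        )


@dataclass
class SurvivalData:
    """Right-censored survival outcomes, one row per sample.

    ``time`` must be strictly positive; ``event`` is 1 for an observed
    death and 0 for censoring.
    """

    frame: pd.DataFrame  # index: sample ids; columns: time, event

    def __post_init__(self) -> None:
        df = self.frame
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table lacks columns {sorted(missing)}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        if df[["time", "event"]].isna().any().any():
            raise ValidationError("missing clinical values")
        if (df["time"] <= 0).any():
            bad = df.index[df["time"] <= 0][0]
            raise ValidationError(f"non-positive survival time for sample {bad!r}")
        if not df["event"].isin((0, 1)).all():
            bad = df.index[~df["event"].isin((0, 1))][0]
            raise ValidationError(f"event indicator not in {{0,1}} for sample {bad!r}")
        self.frame = df[["time", "event"]].astype({"time": float, "event": int})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def event_rate(self) -> float:
        return float(self.frame["event"].mean())

    def subset(self, samples: list[str]) -> "SurvivalData":
        return SurvivalData(self.frame.loc[samples])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurvivalData):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB-style pathway collections)."""

    members: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.members.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        self.members = {k: frozenset(v) for k, v in self.members.items()}

    @property
    def set_names(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.members[name]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.members.items()}

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return frozenset(out)

    def intersect_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to genes present in ``universe``; drop sets
        that become empty (with a logged warning)."""
        uni = set(universe)
        kept: dict[str, frozenset[str]] = {}
        for name, genes in self.members.items():
            g = genes & uni
            if g:
                kept[name] = frozenset(g)
            else:
                logger.warning("gene set %r has no genes in the matrix; dropped", name)
        return GeneSetCollection(kept, dict(self.descriptions))


@dataclass
class FeatureMatrix:
    """Sample-by-predictor matrix fed to the survival models.

    ``level`` records whether predictors are genes or pathway scores;
    ``source`` records the alteration data they came from.
    """

    values: pd.DataFrame  # index: sample ids; columns: predictor ids
    level: str  # {'gene', 'pathway'}
    source: str  # {'spm', 'cnv', 'combined'}

    def __post_init__(self) -> None:
        if self.level not in ("gene", "pathway"):
            raise ValidationError(f"unknown level {self.level!r}")
        if self.source not in ("spm", "cnv", "combined"):
            raise ValidationError(f"unknown source {self.source!r}")
        df = self.values
        if df.columns.duplicated().any():
            raise ValidationError("duplicate predictor ids")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if df.isna().any().any():
            raise ValidationError("missing values in feature matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def predictor_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[samples], self.level, self.source)


def align_to_samples(
    matrix_samples: Iterable[str], clinical: SurvivalData
) -> tuple[list[str], list[str]]:
    """Intersect matrix and clinical sample ids, preserving matrix order.

    Returns ``(shared, dropped)``; samples present on only one side are
    dropped with a logged warning, mirroring a plain inner join.
    """
    clin = set(clinical.sample_ids)
    matrix_samples = list(matrix_samples)
    shared = [s for s in matrix_samples if s in clin]
    dropped = sorted((set(matrix_samples) ^ clin) - set(shared))
    dropped = [s for s in dropped if s not in shared]
    if dropped:
        logger.warning(
            "dropping %d samples without both matrix and clinical data: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "…" if len(dropped) > 5 else "",
        )
    if not shared:
        raise ValidationError("no samples shared between matrix and clinical table")
    return shared, dropped
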