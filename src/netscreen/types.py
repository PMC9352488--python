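"""Core value types shared across the pipeline.

The pipeline moves three kinds of objects around: gene sets (disease genes,
drug targets, markers), expression matrices with a two-level sample grouping,
and plain :class:`pandas.DataFrame` tables for per-cell records and results.
Interaction networks are represented directly as :class:`networkx.Graph`
instances with an optional ``score`` edge attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["GeneSet", "ExpressionMatrix", "SchemaError"]


class SchemaError(ValueError):
    """An input table is missing required columns or violates its contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def __contains__(self, gene: object) -> bool:
        return gene in self.genes

    def intersection(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}&{other.name}", self.genes & other.genes)


def as_gene_set(genes: "GeneSet | Iterable[str]", name: str = "genes") -> GeneSet:
    """Coerce an iterable of identifiers into a :class:`GeneSet`."""
    if isinstance(genes, GeneSet):
        return genes
    return GeneSet(name, frozenset(genes))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an optional two-level grouping.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample (or per cell,
        for cell-level matrices).
    group
        Optional per-sample factor (index = sample ids). Operations that
        compare groups require exactly two non-empty levels.
    """

    values: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            na = self.values.isna()
            gene = na.any(axis=1).idxmax()
            sample = na.loc[gene].idxmax()
            raise SchemaError(f"missing value at gene {gene!r}, sample {sample!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id {dup!r}")
        if self.group is not None:
            missing = self.values.columns.difference(self.group.index)
            if len(missing):
                raise SchemaError(f"sample {missing[0]!r} has no group label")
            self.group = self.group.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_levels(self) -> list[str]:
        if self.group is None:
            raise SchemaError("expression matrix has no group labels")
        levels = sorted(self.group.unique())
        if len(levels) != 2:
            raise SchemaError(f"expected two group levels, found {levels}")
        return levels

    def samples_in(self, level: str) -> pd.Index:
        if self.group is None:
            raise SchemaError("expression matrix has no group labels")
        return self.values.columns[self.group.values == level]
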