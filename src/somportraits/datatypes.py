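"""Core in-memory containers shared across the package.

The central object is the :class:`ExpressionMatrix`, a genes × samples table
that is either on the raw intensity scale or on the log10 fold-change scale
(``logfc``), i.e. log10 expression centered per gene on its cohort mean. All
downstream machinery (SOM training, spot detection, enrichment, similarity,
subtyping) consumes the logfc flavor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOGFC = "logfc"


class ExpressionMatrix:
    """Genes × samples expression values with an explicit scale flag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns. Ids must be
        unique and all values finite; incomplete matrices are rejected because
        the percentile statistics used downstream assume complete data.
    scale:
        ``"raw"`` for positive intensities, ``"logfc"`` for log10 fold-change
        values centered per gene.
    """

    def __init__(self, data: pd.DataFrame, scale: str = RAW):
        if scale not in (RAW, LOGFC):
            raise ValueError(f"scale must be 'raw' or 'logfc', got {scale!r}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)
        self.scale = scale

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], scale=self.scale)

    def drop_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        drop = set(gene_ids)
        keep = [g for g in self.data.index if g not in drop]
        return ExpressionMatrix(self.data.loc[keep], scale=self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"scale={self.scale!r})"
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids with a free-text category tag."""

    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")


class GeneSetCollection:
    """Ordered mapping of gene-set name → :class:`GeneSet`."""

    def __init__(self, sets: Sequence[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self._sets.values() if s.category == category]


@dataclass
class SurvivalTable:
    """Per-sample follow-up records: observation time and event indicator.

    ``event == 1`` marks an observed event (death), ``0`` a censored record
    (alive at last follow-up). ``group`` optionally carries a class label.
    """

    data: pd.DataFrame  # columns: sample_id, time, event, [group]

    def __post_init__(self):
        required = {"sample_id", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        times = self.data["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("survival times must be finite and non-negative")
        events = self.data["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("event flags must be 0 or 1")

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)
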