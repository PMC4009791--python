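"""Functional annotation of spot modules and gene sets.

Three complementary views:

* **Overrepresentation** — given a spot's gene list, the probability of
  observing at least the seen overlap with a predefined gene set under
  random draws from the measured-gene universe (right-tailed hypergeometric
  test). Family-wise control uses a Bonferroni threshold α/n over the number
  of sets tested; with α = 0.05 and n ≈ 5,000 sets this is the conventional
  p < 10⁻⁵ cut.

* **Gene set Z-score (GSZ)** — per sample, the standardized difference
  between the set members' mean log-FC and the global mean log-FC:

      GSZ_m = (⟨Δe⟩_set,m − ⟨Δe⟩_all,m) / (s_m · sqrt(1/n_set − 1/N))

  where s_m is the standard deviation of all N gene values in sample m. The
  denominator is the standard error of a mean of n_set values drawn without
  replacement from the sample's N values, so under random set membership the
  GSZ has zero mean and unit variance.

* **Population maps** — per-tile counts of a gene set's members on the SOM
  grid, localizing the set relative to the detected spots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, GeneSetCollection, LOGFC
from .som import SOMModel


@dataclass
class EnrichmentConfig:
    """Family-wise error control for set overrepresentation screening."""

    alpha: float = 0.05
    n_tests: int = 5000

    @property
    def p_threshold(self) -> float:
        if self.n_tests <= 0:
            raise ValueError("n_tests must be positive")
        t = self.alpha / self.n_tests
        if not 0.0 < t < 1.0:
            raise ValueError("per-test threshold must lie in (0, 1)")
        return t


def overrepresentation_p(spot_genes: Iterable[str], gene_set: Iterable[str],
                         universe: Iterable[str]) -> float:
    """Right-tailed hypergeometric p-value of the spot/set overlap.

    P(X ≥ k) for X ~ Hypergeometric(N = |universe|, K = |set ∩ universe|,
    n = |spot|); genes outside the universe are ignored on the set side but
    are an error on the spot side (the spot comes from the analyzed matrix).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    spot = set(spot_genes)
    extra = spot - universe
    if extra:
        raise ValueError(f"spot genes outside the universe: {sorted(extra)[:5]}")
    members = set(gene_set) & universe
    overlap = len(spot & members)
    N, K, n = len(universe), len(members), len(spot)
    # P(X >= overlap) == sf(overlap - 1)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def significant_sets(p_values: Mapping[str, float],
                     config: EnrichmentConfig) -> tuple[list[str], float]:
    """Names with p strictly below the Bonferroni threshold, plus the threshold."""
    threshold = config.p_threshold
    for name, p in p_values.items():
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value for {name!r} outside (0, 1]: {p}")
    keep = [name for name, p in p_values.items() if p < threshold]
    return keep, threshold


def spot_enrichment(spot_genes: Iterable[str], collection: GeneSetCollection,
                    universe: Iterable[str]) -> pd.DataFrame:
    """Overrepresentation table of every set in the collection for one spot."""
    universe = set(universe)
    spot = set(spot_genes)
    records = []
    for s in collection:
        members = set(s.genes) & universe
        records.append({
            "set": s.name,
            "category": s.category,
            "set_size": len(members),
            "overlap": len(spot & members),
            "p": overrepresentation_p(spot, s.genes, universe),
        })
    df = pd.DataFrame.from_records(records)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


@dataclass
class GSZProfile:
    set_name: str
    values: pd.Series  # per sample


def gsz_profile(gene_set: GeneSet | Iterable[str],
                matrix: ExpressionMatrix) -> GSZProfile:
    """Per-sample gene set Z-score of a set against the full matrix.

    The set must be non-empty after intersection with the measured genes and
    strictly smaller than the universe (otherwise the standard error is 0).
    A zero numerator yields GSZ = 0 exactly.
    """
    if matrix.scale != LOGFC:
        raise ValueError("gsz_profile expects a log-FC matrix")
    if isinstance(gene_set, GeneSet):
        name, members = gene_set.name, set(gene_set.genes)
    else:
        members = set(gene_set)
        name = f"<{len(members)} genes>"
    idx = matrix.data.index
    in_set = idx.isin(members)
    n_set = int(in_set.sum())
    N = matrix.n_genes
    if n_set == 0:
        raise ValueError("gene set has no members in the matrix")
    if n_set >= N:
        raise ValueError("gene set equals the universe; standard error is zero")
    values = matrix.values
    set_mean = values[in_set].mean(axis=0)
    all_mean = values.mean(axis=0)
    s = values.std(axis=0, ddof=1)
    se = s * np.sqrt(1.0 / n_set - 1.0 / N)
    num = set_mean - all_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        gsz = np.where(num == 0.0, 0.0, num / se)
    return GSZProfile(set_name=name,
                      values=pd.Series(gsz, index=matrix.sample_ids, name=name))


def population_map(gene_set: GeneSet | Iterable[str],
                   model: SOMModel) -> tuple[np.ndarray, list[str]]:
    """Per-tile counts of the set's members on the grid.

    Returns the rows × cols count grid and the list of set members absent
    from the model's gene universe (counted as missing, never an error).
    """
    if isinstance(gene_set, GeneSet):
        members = list(dict.fromkeys(gene_set.genes))
    else:
        members = list(dict.fromkeys(gene_set))
    index = {g: i for i, g in enumerate(model.gene_ids)}
    counts = np.zeros(model.n_metagenes, dtype=int)
    missing = []
    for g in members:
        i = index.get(g)
        if i is None:
            missing.append(g)
        else:
            counts[model.assignment[i]] += 1
    return counts.reshape(model.config.rows, model.config.cols), missing
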