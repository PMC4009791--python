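"""Prototype-guided k-means subtyping with bootstrap and consensus validation.

Samples are clustered in metagene space (their K metadata values). Instead
of random initialization, each cluster starts from an *artificial portrait*
derived from a selected spot module: the global maximum of the metadata
matrix on the spot's metagenes and zero elsewhere. Samples dominated by that
spot are immediately attracted to its prototype, so the cluster identities
are fixed from the start and carry the spot labels.

Two resampling checks quantify the result: a per-sample bootstrap stability
score (fraction of subsampled k-means runs that re-assign the sample to its
designated subtype, clusters being anchored by the subtype mean portraits),
and consensus clustering over a range of class numbers k with the consensus
CDF used to judge where adding classes stops paying off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .som import SOMModel
from .spots import Spot


# ---------------------------------------------------------------------------
# prototypes and k-means
# ---------------------------------------------------------------------------

def prototype_from_spot(spot: Spot, model: SOMModel) -> np.ndarray:
    """Artificial portrait of one spot: max metadata value inside, 0 outside."""
    if not spot.metagenes:
        raise ValueError(f"spot {spot.label!r} is empty")
    peak = float(model.metadata.max())
    proto = np.zeros(model.n_metagenes)
    proto[list(spot.metagenes)] = peak
    if peak == 0.0:
        import warnings
        warnings.warn("all-zero metadata: degenerate zero prototype", RuntimeWarning)
    return proto


@dataclass
class SubtypeResult:
    labels: pd.Series                  # sample id -> class name
    centroids: pd.DataFrame            # class × metagene
    objective_path: list[float] = field(default_factory=list)
    stability: pd.Series | None = None

    @property
    def class_names(self) -> list[str]:
        return list(self.centroids.index)


def _kmeans_core(points: np.ndarray, centroids: np.ndarray,
                 max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations from fixed initial centroids.

    Cluster identities are positional: cluster c keeps meaning "the cluster
    initialized by centroid c" throughout. An emptied cluster is re-seeded
    with the point farthest from its current centroid, which keeps the
    objective non-increasing in the subsequent assignment step.
    """
    n, _ = points.shape
    k = centroids.shape[0]
    centroids = centroids.astype(float).copy()
    path: list[float] = []
    assign = None
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(n), new_assign].sum())
        path.append(obj)
        for c in range(k):
            members = points[new_assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
            else:
                dist_own = d2[np.arange(n), new_assign]
                far = int(np.argmax(dist_own))
                centroids[c] = points[far]
                new_assign[far] = c
        if assign is not None and np.array_equal(assign, new_assign):
            if len(path) >= 2 and abs(path[-2] - path[-1]) <= tol:
                assign = new_assign
                break
        assign = new_assign
    # final centroid sync so centroids equal member means at convergence
    for c in range(k):
        members = points[assign == c]
        if len(members):
            centroids[c] = members.mean(axis=0)
    return assign, centroids, path


def kmeans_assign(metadata: np.ndarray,
                  prototypes: Mapping[str, np.ndarray] | np.ndarray,
                  sample_ids: Sequence[str] | None = None,
                  max_iter: int = 100, tol: float = 1e-9) -> SubtypeResult:
    """k-means on sample meta-states, initialized at the given prototypes.

    ``prototypes`` maps class name → initial centroid (length K); an array is
    accepted too, with classes named C1, C2, …. The per-iteration objective
    (within-cluster sum of squares, evaluated at assignment time) is recorded
    and non-increasing.
    """
    metadata = np.asarray(metadata, dtype=float)
    points = metadata.T  # samples × K
    if isinstance(prototypes, Mapping):
        names = list(prototypes)
        init = np.vstack([np.asarray(prototypes[c], dtype=float) for c in names])
    else:
        init = np.asarray(prototypes, dtype=float)
        names = [f"C{i + 1}" for i in range(init.shape[0])]
    if init.ndim != 2 or init.shape[1] != points.shape[1]:
        raise ValueError("prototypes must be k × K")
    if init.shape[0] < 1:
        raise ValueError("need at least one prototype")
    assign, centroids, path = _kmeans_core(points, init, max_iter, tol)
    ids = list(sample_ids) if sample_ids is not None else list(range(points.shape[0]))
    labels = pd.Series([names[c] for c in assign], index=ids, name="class")
    return SubtypeResult(
        labels=labels,
        centroids=pd.DataFrame(centroids, index=names),
        objective_path=path,
    )


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

def bootstrap_stability(metadata: np.ndarray, labels: pd.Series,
                        subsample_fraction: float = 0.8, n_reps: int = 500,
                        seed: int = 0) -> pd.Series:
    """Per-sample fraction of resampling runs that confirm its class.

    Each repetition subsamples the cohort without replacement, runs k-means
    initialized at the subtypes' mean meta-states (computed on the
    subsample), and records for every drawn sample whether it lands in its
    designated class. Because clusters are anchored by their initializing
    class means, no label matching is needed. Repetitions in which a class
    vanishes from the subsample are discarded (and counted); the score is
    agreements / times drawn in valid repetitions.
    """
    if not 0.0 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1)")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    metadata = np.asarray(metadata, dtype=float)
    points = metadata.T
    label_arr = labels.to_numpy()
    n = points.shape[0]
    size = max(int(round(subsample_fraction * n)), len(classes))
    rng = np.random.default_rng(seed)
    drawn = np.zeros(n, dtype=int)
    agreed = np.zeros(n, dtype=int)
    discarded = 0
    for _ in range(n_reps):
        idx = rng.choice(n, size=size, replace=False)
        sub_labels = label_arr[idx]
        if len(set(sub_labels)) < len(classes):
            discarded += 1
            continue
        init = np.vstack([points[idx][sub_labels == c].mean(axis=0) for c in classes])
        assign, _, _ = _kmeans_core(points[idx], init, max_iter=100, tol=1e-9)
        drawn[idx] += 1
        agreed[idx] += (np.array(classes)[assign] == sub_labels).astype(int)
    with np.errstate(invalid="ignore"):
        score = np.where(drawn > 0, agreed / np.maximum(drawn, 1), np.nan)
    out = pd.Series(score, index=labels.index, name="stability")
    out.attrs["discarded_reps"] = discarded
    return out


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per class number k: consensus matrix, item ordering and CDF curve."""

    consensus: dict[int, pd.DataFrame]
    orderings: dict[int, list[str]]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (grid on [0,1], CDF values)
    k_range: list[int]

    def cdf_areas(self) -> dict[int, float]:
        """Area under each CDF curve (larger = more binary consensus)."""
        return {k: float(np.trapezoid(v, x)) for k, (x, v) in self.cdf.items()}

    def incremental_gains(self) -> dict[int, float]:
        """Relative gain in CDF area from k−1 to k, as in the elbow criterion."""
        areas = self.cdf_areas()
        ks = sorted(areas)
        gains = {ks[0]: areas[ks[0]]}
        for prev, k in zip(ks, ks[1:]):
            gains[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        return gains


def consensus_cluster(metadata: np.ndarray,
                      sample_ids: Sequence[str] | None = None,
                      k_range: Sequence[int] = (2, 3, 4, 5, 6),
                      n_reps: int = 500, subsample_fraction: float = 0.8,
                      seed: int = 0, linkage_method: str = "average") -> ConsensusResult:
    """Subsampled hierarchical clustering aggregated into consensus matrices.

    For every k and repetition, a random subsample (without replacement) of
    the cohort is cut into k classes by hierarchical clustering on Euclidean
    distances; the consensus entry of a sample pair is its co-clustering
    count divided by its co-drawing count. The CDF of the upper-triangle
    consensus values summarizes how binary (i.e., stable) the matrix is.
    """
    metadata = np.asarray(metadata, dtype=float)
    points = metadata.T
    n = points.shape[0]
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n_samples − 1]")
    size = int(round(subsample_fraction * n))
    if size < k_range[-1]:
        raise ValueError("subsample smaller than the largest k")
    rng = np.random.default_rng(seed)

    consensus: dict[int, pd.DataFrame] = {}
    orderings: dict[int, list[str]] = {}
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_range:
        together = np.zeros((n, n))
        drawn = np.zeros((n, n))
        for _ in range(n_reps):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = points[idx]
            z = linkage(sub, method=linkage_method, metric="euclidean")
            cut = fcluster(z, t=k, criterion="maxclust")
            same = cut[:, None] == cut[None, :]
            drawn[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(drawn > 0, together / np.maximum(drawn, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        df = pd.DataFrame(cons, index=ids, columns=ids)
        consensus[k] = df
        # order samples by hierarchical clustering of (1 − consensus)
        dist = squareform(1.0 - cons, checks=False)
        z = linkage(dist, method=linkage_method)
        order = _leaf_order(z, n)
        orderings[k] = [ids[i] for i in order]
        tri = cons[np.triu_indices(n, k=1)]
        grid = np.linspace(0.0, 1.0, 101)
        cdf = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        cdfs[k] = (grid, cdf)
    return ConsensusResult(consensus=consensus, orderings=orderings,
                           cdf=cdfs, k_range=k_range)


def _leaf_order(z: np.ndarray, n: int) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list
    return leaves_list(z).tolist()
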