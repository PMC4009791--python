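"""Sample-similarity analyses on the metagene (metadata) level.

Working on K metagene values per sample instead of the full gene space
denoises the comparison while keeping the multivariate structure. Four views
are provided: the pairwise Pearson correlation map (PCM), its thresholded
graph form (the correlation network), an unrooted neighbor-joining tree on
Euclidean distances, and a two-component ICA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode


# ---------------------------------------------------------------------------
# correlation map and network
# ---------------------------------------------------------------------------

def pairwise_correlation(metadata: np.ndarray,
                         sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Pearson r between all pairs of sample meta-states (columns).

    Requires at least three metagenes; a zero-variance sample column has no
    defined correlation and is an error.
    """
    metadata = np.asarray(metadata, dtype=float)
    if metadata.shape[0] < 3:
        raise ValueError("need at least three metagenes")
    sd = metadata.std(axis=0)
    if np.any(sd < 1e-15):
        bad = np.flatnonzero(sd < 1e-15)
        names = [sample_ids[i] for i in bad] if sample_ids else bad.tolist()
        raise ValueError(f"zero-variance sample column(s): {names}")
    r = np.corrcoef(metadata, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    ids = sample_ids if sample_ids is not None else list(range(metadata.shape[1]))
    return pd.DataFrame(r, index=ids, columns=ids)


@dataclass
class CorrelationNetwork:
    """Samples as nodes, edges where pairwise r exceeds the threshold."""

    graph: nx.Graph
    r_threshold: float
    layout: dict = field(default_factory=dict)


def correlation_network(r_matrix: pd.DataFrame, threshold: float = 0.5,
                        seed: int = 0) -> CorrelationNetwork:
    """Build the thresholded correlation graph with a force-directed layout.

    An edge connects two samples exactly when their r strictly exceeds the
    threshold; edge weights carry r so the spring layout draws strongly
    correlated samples closer together.
    """
    ids = list(r_matrix.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    values = r_matrix.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if values[i, j] > threshold:
                g.add_edge(ids[i], ids[j], weight=float(values[i, j]))
    layout = nx.spring_layout(g, seed=seed, weight="weight")
    return CorrelationNetwork(graph=g, r_threshold=threshold, layout=layout)


def sample_distance_matrix(metadata: np.ndarray,
                           sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Euclidean distances between sample meta-states."""
    metadata = np.asarray(metadata, dtype=float)
    g = metadata.T @ metadata
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    ids = sample_ids if sample_ids is not None else list(range(metadata.shape[1]))
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTree:
    """Unrooted NJ tree over samples; negative branch lengths are clamped to
    zero and the affected leaf/node names recorded."""

    tree: TreeNode
    clamped_branches: list[str] = field(default_factory=list)


def nj_tree(distances: pd.DataFrame) -> SimilarityTree:
    """Neighbor joining with the standard Q-criterion.

    At each agglomeration the pair (i, j) minimizing
    ``Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`` is joined; ties take
    the lowest index pair in current node order, making the result
    deterministic. For additive input distances the tree's path lengths
    reproduce the input exactly.
    """
    d = distances.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(d < -1e-12):
        raise ValueError("distances must be non-negative")

    names = [str(x) for x in distances.index]
    clamped: list[str] = []

    def _clamp(length: float, name: str) -> float:
        if length < 0:
            clamped.append(name)
            return 0.0
        return length

    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    n = len(nodes)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return SimilarityTree(tree=nodes[0])
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = _clamp(d[0, 1] / 2.0, node.name)
            root.append(node)
        return SimilarityTree(tree=root, clamped_branches=clamped)

    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima (row-major scan)
        flat = np.argmin(q)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = _clamp(li, ni.name or "internal")
        nj.length = _clamp(lj, nj.name or "internal")
        parent.append(ni)
        parent.append(nj)
        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        n -= 1

    # final three nodes: closed-form branch lengths around the central vertex
    root = TreeNode()
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = _clamp(length, node.name or "internal")
        root.append(node)
    return SimilarityTree(tree=root, clamped_branches=clamped)


def tree_path_lengths(tree: TreeNode, names: list[str]) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    n = len(names)
    out = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            dist = tips[names[i]].distance(tips[names[j]])
            out[i, j] = out[j, i] = dist
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# independent component analysis
# ---------------------------------------------------------------------------

def ica_embed(metadata: np.ndarray, n_components: int = 2, seed: int = 0,
              sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Project samples onto the axes of minimal mutual statistical dependence.

    FastICA on the samples-as-observations view of the metadata. Since ICA is
    defined only up to permutation and sign, components are canonicalized:
    ordered by decreasing excess kurtosis (non-Gaussianity) and signed so
    each component's skewness is non-negative.
    """
    from sklearn.decomposition import FastICA

    metadata = np.asarray(metadata, dtype=float)
    m = metadata.shape[1]
    if n_components > m:
        raise ValueError(f"n_components={n_components} exceeds {m} samples")
    X = metadata.T  # samples × metagenes
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-6)
    S = ica.fit_transform(X)  # samples × components
    kurt = stats.kurtosis(S, axis=0)
    order = np.argsort(-kurt, kind="stable")
    S = S[:, order]
    skew = stats.skew(S, axis=0)
    S = S * np.where(skew < 0, -1.0, 1.0)
    ids = sample_ids if sample_ids is not None else list(range(m))
    cols = [f"IC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(S, index=ids, columns=cols)
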