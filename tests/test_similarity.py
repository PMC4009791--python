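"""Sample similarity: correlation map/network, neighbor joining, ICA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from somportraits.similarity import (
    SimilarityTree,
    correlation_network,
    ica_embed,
    nj_tree,
    pairwise_correlation,
    sample_distance_matrix,
    tree_path_lengths,
)


class TestPairwiseCorrelation:
    def test_duplicate_and_negated_samples(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        metadata = np.column_stack([base, base, -base])
        r = pairwise_correlation(metadata, ["a", "b", "c"])
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_three_sample_formula_oracle(self):
        rng = np.random.default_rng(0)
        metadata = rng.normal(size=(10, 3))
        r = pairwise_correlation(metadata)

        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))

        for i, j in itertools.combinations(range(3), 2):
            assert r.iloc[i, j] == pytest.approx(
                pearson(metadata[:, i], metadata[:, j]), abs=1e-12)

    def test_invariant_to_global_constant_shift(self):
        rng = np.random.default_rng(1)
        metadata = rng.normal(size=(20, 5))
        r1 = pairwise_correlation(metadata)
        r2 = pairwise_correlation(metadata + 3.7)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_zero_variance_sample_rejected(self):
        metadata = np.column_stack([np.ones(5), np.arange(5.0)])
        metadata = np.column_stack([metadata, np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_correlation(metadata, ["flat", "x", "y"])


class TestCorrelationNetwork:
    def test_identical_samples_complete_graph(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        metadata = np.column_stack([base] * 4)
        metadata = metadata + np.random.default_rng(0).normal(0, 1e-6, metadata.shape)
        r = pairwise_correlation(metadata, list("abcd"))
        net = correlation_network(r, 0.5)
        assert net.graph.number_of_edges() == 6

    def test_threshold_is_strict(self):
        r = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        assert correlation_network(r, 0.5).graph.number_of_edges() == 0
        assert correlation_network(r, 0.39).graph.number_of_edges() == 1

    def test_classes_form_connected_subgraphs(self, reference_cohort, reference_model):
        """Main antagonistic classes cohere at the default threshold; the
        weaker intermediate classes (one small module each) cohere at a
        threshold matched to their lower within-class correlation."""
        _, _, truth = reference_cohort
        import networkx as nx
        r = pairwise_correlation(reference_model.metadata,
                                 reference_model.sample_ids)
        labels = truth.sample_labels
        net_default = correlation_network(r, 0.5)
        net_loose = correlation_network(r, 0.2)
        for cls, net in (("S1", net_default), ("S4", net_default),
                         ("S2", net_loose), ("S3", net_loose)):
            members = list(labels.index[labels == cls])
            sub = net.graph.subgraph(members)
            assert nx.is_connected(sub), f"class {cls} not connected"


def brute_force_nj(d: np.ndarray, names: list[str]):
    """Independent NJ oracle: explicit Q-matrix scan with lowest-index ties."""
    nodes = [(n,) for n in names]
    d = d.copy()
    edges = {}
    while len(nodes) > 3:
        n = len(nodes)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - d[i].sum() - d[j].sum()
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (d[i].sum() - d[j].sum()) / (2 * (n - 2))
        lj = d[i, j] - li
        new = nodes[i] + nodes[j]
        edges[nodes[i]] = max(li, 0.0)
        edges[nodes[j]] = max(lj, 0.0)
        new_d = (d[i] + d[j] - d[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
    for idx, (a, b, c) in enumerate([(0, 1, 2), (1, 0, 2), (2, 0, 1)]):
        edges[nodes[a]] = max((d[a, b] + d[a, c] - d[b, c]) / 2, 0.0)
    return edges


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 2, 3], [2, 0, 3], [3, 3, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = nj_tree(d).tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_additive_four_taxon_metric_recovered(self):
        # tree: ((A:2,B:3):1,(C:2,D:4));  pairwise path lengths below
        names = list("ABCD")
        d = pd.DataFrame([
            [0, 5, 5, 7],
            [5, 0, 6, 8],
            [5, 6, 0, 6],
            [7, 8, 6, 0],
        ], index=names, columns=names, dtype=float)
        result = nj_tree(d)
        paths = tree_path_lengths(result.tree, names)
        np.testing.assert_allclose(paths.to_numpy(), d.to_numpy(), atol=1e-9)
        assert result.clamped_branches == []

    def test_duplicated_taxon_sibling_at_zero_distance(self):
        names = list("ABCD")
        d = pd.DataFrame([
            [0, 0, 4, 5],
            [0, 0, 4, 5],
            [4, 4, 0, 3],
            [5, 5, 3, 0],
        ], index=names, columns=names, dtype=float)
        tree = nj_tree(d).tree
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_matches_brute_force_oracle(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            points = rng.normal(size=(n_taxa, 3))
            d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
            names = [f"t{i}" for i in range(n_taxa)]
            df = pd.DataFrame(d, index=names, columns=names)
            result = nj_tree(df)
            oracle_edges = brute_force_nj(d, names)
            tips = {t.name: t for t in result.tree.tips()}
            for group, length in oracle_edges.items():
                if len(group) == 1:  # leaf branch lengths are comparable
                    assert tips[group[0]].length == pytest.approx(length, abs=1e-9)

    def test_matches_skbio_reference_on_additive_metric(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        points = rng.normal(size=(6, 4))
        d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
        names = [f"t{i}" for i in range(6)]
        ours = nj_tree(pd.DataFrame(d, index=names, columns=names))
        theirs = skbio_nj(DistanceMatrix(d, ids=names))
        ours_paths = tree_path_lengths(ours.tree, names)
        theirs_paths = tree_path_lengths(theirs, names)
        np.testing.assert_allclose(ours_paths.to_numpy(),
                                   theirs_paths.to_numpy(), atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"),
                         dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)


class TestICA:
    def test_shape_and_determinism(self, small_model):
        emb1 = ica_embed(small_model.metadata, 2, seed=4,
                         sample_ids=small_model.sample_ids)
        emb2 = ica_embed(small_model.metadata, 2, seed=4,
                         sample_ids=small_model.sample_ids)
        assert emb1.shape == (len(small_model.sample_ids), 2)
        pd.testing.assert_frame_equal(emb1, emb2)

    def test_recovers_independent_sources(self):
        rng = np.random.default_rng(8)
        n_samples = 300
        sources = rng.uniform(-1, 1, size=(n_samples, 2))
        mixing = rng.normal(size=(2, 100))
        metadata = (sources @ mixing).T  # 100 metagenes × samples
        emb = ica_embed(metadata, 2, seed=0)
        corr = np.corrcoef(np.column_stack([sources, emb.to_numpy()]).T)[:2, 2:]
        # each source matches one component up to permutation/sign
        best = np.abs(corr).max(axis=1)
        assert (best > 0.95).all()
        assert {int(np.abs(corr)[0].argmax()), int(np.abs(corr)[1].argmax())} == {0, 1}

    def test_too_many_components_rejected(self, small_model):
        with pytest.raises(ValueError):
            ica_embed(small_model.metadata, len(small_model.sample_ids) + 1)
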