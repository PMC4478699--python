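"""Correlation distance, UPGMA merge sequence, PCA."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from amdcomp.abundance import relative_abundance, tabulate
from amdcomp.multivariate import (
    average_linkage,
    correlation_distance,
    pca_scores,
)
from amdcomp.simulate import SimulationConfig, simulate_paired_counts


def brute_force_upgma(D, labels):
    """O(n^3) re-scan oracle: cluster distances recomputed from the original
    leaf matrix at every step (never incrementally updated)."""
    clusters = [[i] for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                key = (d, tuple(sorted(labels[a] for a in clusters[i] + clusters[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _), i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return merges


class TestCorrelationDistance:
    def test_identical_vectors_have_zero_distance(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        D = correlation_distance(X)
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_have_distance_two(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        assert correlation_distance(X).loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(5, 12)))
        D = correlation_distance(X)
        for i in range(5):
            for j in range(5):
                x, y = X.iloc[i] - X.iloc[i].mean(), X.iloc[j] - X.iloc[j].mean()
                r = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
                assert D.iloc[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_item_is_named(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="'flat'"):
            correlation_distance(X)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(4, 10)))
        Y = X.copy()
        Y.iloc[2] = 5.0 * Y.iloc[2] + 11.0
        assert np.allclose(correlation_distance(X), correlation_distance(Y), atol=1e-12)


class TestUPGMA:
    def test_two_items_merge_at_their_distance(self):
        D = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["a", "b"], columns=["a", "b"])
        dendro = average_linkage(D)
        assert dendro.heights.tolist() == [0.7]
        assert sorted(dendro.root.leaves()) == ["a", "b"]

    def test_duplicate_item_merges_first_at_zero(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(4, 8)), index=["a", "b", "c", "a2"])
        X.loc["a2"] = X.loc["a"]
        dendro = average_linkage(correlation_distance(X))
        assert dendro.heights[0] == pytest.approx(0.0, abs=1e-12)
        first = dendro.merges[0, :2].astype(int)
        assert {X.index[first[0]], X.index[first[1]]} == {"a", "a2"}

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_matches_brute_force_rescan(self, n):
        rng = np.random.default_rng(n)
        for rep in range(5):
            M = rng.uniform(0.1, 2.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            labels = [f"L{i}" for i in range(n)]
            df = pd.DataFrame(D, index=labels, columns=labels)
            dendro = average_linkage(df)
            oracle = brute_force_upgma(D, labels)
            members = {i: frozenset([i]) for i in range(n)}
            for step, (set_a, set_b, height) in enumerate(oracle):
                ia, ib, h, _ = dendro.merges[step]
                fa, fb = members[int(ia)], members[int(ib)]
                members[n + step] = fa | fb
                assert h == pytest.approx(height, rel=1e-12)
                assert {fa, fb} == {set_a, set_b}

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_scipy_average_linkage(self, n):
        rng = np.random.default_rng(100 + n)
        M = rng.uniform(0.1, 2.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"L{i}" for i in range(n)]
        dendro = average_linkage(pd.DataFrame(D, index=labels, columns=labels))
        Z = sch.linkage(squareform(D, checks=False), method="average")
        assert np.allclose(dendro.merges[:, 2], Z[:, 2], atol=1e-12)
        assert np.array_equal(
            np.sort(dendro.merges[:, :2], axis=1), np.sort(Z[:, :2], axis=1)
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        M = rng.uniform(0.1, 2.0, size=(6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"L{i}" for i in range(6)]
        df = pd.DataFrame(D, index=labels, columns=labels)
        perm = rng.permutation(6)
        df_perm = df.iloc[perm, perm]
        a, b = average_linkage(df), average_linkage(df_perm)
        assert np.allclose(a.heights, b.heights, atol=1e-12)
        assert a.to_newick().count("(") == b.to_newick().count("(")

    def test_heights_monotone(self):
        rng = np.random.default_rng(12)
        M = rng.uniform(0.1, 2.0, size=(7, 7))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        dendro = average_linkage(pd.DataFrame(D))
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_newick_is_parseable_and_ultrametric(self):
        import io

        from Bio import Phylo

        rng = np.random.default_rng(21)
        M = rng.uniform(0.1, 2.0, size=(5, 5))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = list("abcde")
        dendro = average_linkage(pd.DataFrame(D, index=labels, columns=labels))
        tree = Phylo.read(io.StringIO(dendro.to_newick()), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == labels
        depths = tree.depths()
        leaf_depths = [d for t, d in depths.items() if t.name]
        assert np.allclose(leaf_depths, dendro.heights[-1] / 2, atol=1e-9)

    def test_shared_truth_communities_merge_first(self):
        """Two communities simulated from identical truth proportions form
        the first community-level merge of the transcript-profile dendrogram."""
        from dataclasses import replace

        from amdcomp.simulate import PlantedIndicator, community_expectations

        base = SimulationConfig.realistic(
            seed=41, n_communities=4, n_genera=3, n_cogs=40,
            depth_dna=20_000, depth_cdna=20_000,
            community_labels=("S01", "S02", "S03", "S04"),
        )
        # perturb abundant features of S03 and S04; S01 and S02 stay identical
        top = community_expectations(base).cdna_proportions["S01"].nlargest(6).index
        plants = tuple(
            PlantedIndicator(f, "S03", 3.0, "higher") for f in top[:3]
        ) + tuple(PlantedIndicator(f, "S04", 3.0, "lower") for f in top[3:])
        config = replace(base, planted_indicators=plants)
        _, cdna, _ = simulate_paired_counts(config)
        profiles = relative_abundance(cdna).values.T
        dendro = average_linkage(correlation_distance(profiles))
        first = dendro.merges[0, :2].astype(int)
        assert {dendro.labels[first[0]], dendro.labels[first[1]]} == {"S01", "S02"}


class TestPCA:
    def test_collinear_points_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 8)
        X = pd.DataFrame({"x": t, "y": 2 * t})
        result = pca_scores(X)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(6, 10)))
        result = pca_scores(X)
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_sklearn_up_to_sign(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(6, 10)))
        mine = pca_scores(X)
        ref = sklearn.PCA().fit(X.to_numpy())
        assert np.allclose(
            np.abs(mine.scores.to_numpy()[:, :5]),
            np.abs(ref.transform(X.to_numpy())[:, :5]),
            atol=1e-8,
        )
        assert np.allclose(
            mine.explained_variance_ratio[:5], ref.explained_variance_ratio_[:5], atol=1e-9
        )

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(5, 6)))
        result = pca_scores(X)
        for comp in result.loadings.columns:
            col = result.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_standardize_mode_and_degenerate_variables(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        X["flat"] = 1.0
        result = pca_scores(X, standardize=True)
        assert "flat" not in result.loadings.index
        with pytest.raises(ValueError, match="non-degenerate"):
            pca_scores(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}))
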