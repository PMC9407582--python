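import itertools

import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_complete_linkage, pca_eigen_oracle
from ripscan.structure_analysis import (
    breed_pool_matrix,
    cut_clusters,
    decode_matrix,
    encode_matrix,
    hierarchical_cluster,
    pca,
)
from ripscan.synthetic_data import simulate_genotypes


def genotype_table(rows):
    return pd.DataFrame(rows, columns=["individual_id", "breed", "locus", "genotype"])


class TestEncodeMatrix:
    def test_dose_coding_follows_the_legend(self):
        table = genotype_table(
            [
                ("i1", "B", "L1", "+/+"), ("i1", "B", "L2", "+/-"),
                ("i2", "B", "L1", "-/-"), ("i2", "B", "L2", None),
            ]
        )
        matrix = encode_matrix(table)
        assert matrix.loc["i1", "L1"] == 2 and matrix.loc["i1", "L2"] == 1
        assert matrix.loc["i2", "L1"] == 0 and np.isnan(matrix.loc["i2", "L2"])

    def test_all_homozygous_insertion_panel(self):
        rows = [(f"i{k}", "B", l, "+/+") for k in range(3) for l in ("L1", "L2")]
        matrix = encode_matrix(genotype_table(rows))
        assert (matrix.to_numpy() == 2).all() and matrix.shape == (3, 2)

    def test_round_trip_decode(self):
        table = simulate_genotypes(0.4, 40, seed=8, breed="B", locus="L1")
        matrix = encode_matrix(table)
        back = decode_matrix(matrix, breed_of={i: "B" for i in table["individual_id"]})
        merged = table.merge(back, on=["individual_id", "locus"], suffixes=("_a", "_b"))
        assert (merged["genotype_a"] == merged["genotype_b"]).all()

    def test_unknown_symbol_rejected(self):
        table = genotype_table([("i1", "B", "L1", "++")])
        with pytest.raises(ValueError, match="unknown genotype"):
            encode_matrix(table)


class TestPca:
    def test_two_blocks_separate_on_pc1_with_zero_within_spread(self):
        data = {"L1": [2, 2, 2, 0, 0, 0], "L2": [2, 2, 2, 0, 0, 0], "L3": [0, 0, 0, 2, 2, 2]}
        matrix = pd.DataFrame(data, index=[f"i{k}" for k in range(6)], dtype=float)
        result = pca(matrix, k=2)
        pc1 = result.scores["PC1"]
        assert pc1.iloc[:3].std() == pytest.approx(0, abs=1e-10)
        assert abs(pc1.iloc[0] - pc1.iloc[3]) > 1

    def test_variance_explained_sums_to_one_at_full_rank(self, rng):
        matrix = pd.DataFrame(rng.integers(0, 3, size=(6, 4)).astype(float))
        matrix.index = [f"i{k}" for k in range(6)]
        result = pca(matrix, k=4)
        assert np.all(np.diff(result.variance_explained) <= 1e-12)
        assert result.variance_explained.sum() <= 1 + 1e-9

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(6, 4))
            matrix = pd.DataFrame(x, index=[f"i{k}" for k in range(6)])
            result = pca(matrix, k=3)
            scores, loadings, var = pca_eigen_oracle(x, 3)
            np.testing.assert_allclose(result.scores.to_numpy(), scores, atol=1e-8)
            np.testing.assert_allclose(result.loadings.to_numpy(), loadings, atol=1e-8)
            np.testing.assert_allclose(result.variance_explained, var[:3], atol=1e-8)

    def test_translation_invariance_of_scores(self, rng):
        x = rng.normal(size=(8, 5))
        a = pca(pd.DataFrame(x), k=2)
        b = pca(pd.DataFrame(x + np.array([3.0, -1.0, 0.5, 0.0, 7.0])), k=2)
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-9)

    def test_admixed_rows_fall_between_profile_clusters_on_pc1(self):
        # two divergent allele-frequency profiles (indigenous-like vs
        # commercial-like) plus admixed intermediates
        loci = [f"L{k}" for k in range(8)]
        rows = []
        rng = np.random.default_rng(17)

        def draw(individual, breed, p_by_locus):
            for locus, p in zip(loci, p_by_locus):
                dose = rng.binomial(2, p)
                genotype = {0: "-/-", 1: "+/-", 2: "+/+"}[dose]
                rows.append((individual, breed, locus, genotype))

        for k in range(8):
            draw(f"ind_{k}", "indigenous", [0.9] * 4 + [0.1] * 4)
        for k in range(8):
            draw(f"com_{k}", "commercial", [0.1] * 4 + [0.9] * 4)
        for k in range(6):
            draw(f"mix_{k}", "admixed", [0.5] * 8)
        matrix = encode_matrix(genotype_table(rows))
        scores = pca(matrix, k=2).scores["PC1"]
        left = scores[[i for i in scores.index if i.startswith("ind")]].mean()
        right = scores[[i for i in scores.index if i.startswith("com")]].mean()
        mid = scores[[i for i in scores.index if i.startswith("mix")]].mean()
        lo, hi = sorted((left, right))
        assert lo < mid < hi

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"L1": [1.0], "L2": [2.0]}), k=1)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        matrix = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]], index=["a", "b", "c"])
        result = hierarchical_cluster(matrix)
        first = result.merge_tree[0]
        assert first[2] == 0.0
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_matches_brute_force_agglomeration_oracle(self, rng):
        x = rng.normal(size=(5, 3))
        matrix = pd.DataFrame(x, index=[f"r{k}" for k in range(5)])
        result = hierarchical_cluster(matrix, linkage="complete")
        oracle = brute_force_complete_linkage(x)
        np.testing.assert_allclose(
            sorted(result.merge_tree[:, 2]), sorted(h for *_, h in oracle), atol=1e-9
        )
        # partitions agree at every cut size
        for n_clusters in (2, 3, 4):
            got = cut_clusters(result, n_clusters)
            partition = {}
            clusters = [frozenset([i]) for i in range(5)]
            for a, b, _ in oracle[: 5 - n_clusters]:
                clusters = [c for c in clusters if c not in (a, b)] + [a | b]
            expected_sets = {frozenset(f"r{i}" for i in c) for c in clusters}
            got_sets = {
                frozenset(k for k, v in got.items() if v == label)
                for label in set(got.values())
            }
            assert got_sets == expected_sets

    def test_permutation_equivariance_of_leaf_order(self, rng):
        x = rng.normal(size=(6, 3))
        matrix = pd.DataFrame(x, index=[f"r{k}" for k in range(6)])
        base = hierarchical_cluster(matrix)
        perm = [3, 1, 5, 0, 2, 4]
        permuted = hierarchical_cluster(matrix.iloc[perm])
        assert set(base.row_order) == set(permuted.row_order)
        # same partition at every cut
        assert cut_clusters(base, 3).keys() == cut_clusters(permuted, 3).keys()
        base_sets = {
            frozenset(k for k, v in cut_clusters(base, 3).items() if v == lab)
            for lab in set(cut_clusters(base, 3).values())
        }
        perm_sets = {
            frozenset(k for k, v in cut_clusters(permuted, 3).items() if v == lab)
            for lab in set(cut_clusters(permuted, 3).values())
        }
        assert base_sets == perm_sets

    def test_euclidean_distances_satisfy_metric_axioms(self, rng):
        from scipy.spatial.distance import squareform, pdist

        x = rng.normal(size=(6, 4))
        d = squareform(pdist(x))
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_planted_breed_profiles_recovered_at_four_cluster_cut(self):
        rng = np.random.default_rng(4)
        profiles = {
            "taihu": [0.95] * 3 + [0.05] * 9,
            "mini": [0.05] * 3 + [0.95] * 3 + [0.05] * 6,
            "commercial": [0.05] * 6 + [0.95] * 3 + [0.05] * 3,
            "hybrid": [0.5] * 12,
        }
        rows = []
        for group, p_vec in profiles.items():
            for rep in range(3):
                breed = f"{group}_{rep}"
                for locus_i, p in enumerate(p_vec):
                    dose = rng.binomial(2 * 24, p) / 24.0  # pooled mean dose
                    rows.append((breed, f"L{locus_i}", dose))
        matrix = (
            pd.DataFrame(rows, columns=["breed", "locus", "dose"])
            .pivot(index="breed", columns="locus", values="dose")
        )
        result = hierarchical_cluster(matrix)
        labels = cut_clusters(result, 4)
        for group in profiles:
            members = {b for b in labels if b.startswith(group)}
            assert len({labels[m] for m in members}) == 1, group

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))


def test_breed_pool_matrix_averages_dose():
    table = genotype_table(
        [
            ("i1", "B1", "L1", "+/+"), ("i2", "B1", "L1", "-/-"),
            ("i3", "B2", "L1", "+/-"),
        ]
    )
    pools = breed_pool_matrix(table)
    assert pools.loc["B1", "L1"] == 1.0 and pools.loc["B2", "L1"] == 1.0
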