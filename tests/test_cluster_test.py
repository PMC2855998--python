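import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from nlepi.cluster_test import (
    _agglomerate,
    concordance_pattern,
    cut_two,
    hierarchical_cluster,
    permutation_cluster_test,
    spearman_fold_correlation,
)
from nlepi.io_formats import ExpressionMatrix, load_table2_fixture
from nlepi.synthetic import SimulationConfig, generate_expression


def _matrix_from_profiles(profiles, groups):
    """Build a matrix whose log2(x+1) sample profiles equal ``profiles``."""
    profiles = np.asarray(profiles, dtype=float)  # samples x probes
    samples = [f"s{i}" for i in range(profiles.shape[0])]
    probes = [f"p{j}" for j in range(profiles.shape[1])]
    intens = pd.DataFrame(2.0**profiles.T - 1.0, index=probes, columns=samples)
    det = pd.DataFrame(np.full(intens.shape, "P"), index=probes, columns=samples)
    return ExpressionMatrix(intens, det, pd.Series(groups, index=samples))


class TestHierarchicalCluster:
    def test_two_samples_single_merge_at_distance(self):
        matrix = _matrix_from_profiles([[0.0], [3.0]], ["RM", "HN"])
        tree = hierarchical_cluster(matrix, ["p0"])
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(3.0)

    def test_collinear_points_merge_closest_pair_first(self):
        matrix = _matrix_from_profiles(
            [[0.0], [1.0], [10.0]], ["RM", "RM", "HN"]
        )
        tree = hierarchical_cluster(matrix, ["p0"])
        assert sorted(tree.merges[0, :2]) == [0.0, 1.0]

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(17)
        profiles = rng.uniform(0, 8, (15, 20))
        matrix = _matrix_from_profiles(profiles, ["RM"] * 8 + ["HN"] * 7)
        for linkage in ("average", "complete"):
            tree = hierarchical_cluster(matrix, matrix.probe_ids, linkage=linkage)
            reference = sch.linkage(
                np.log2(matrix.intensities.to_numpy().T + 1.0), method=linkage
            )
            np.testing.assert_allclose(tree.merges[:, 2], reference[:, 2], rtol=1e-9)
            np.testing.assert_allclose(tree.merges[:, 3], reference[:, 3])

    def test_tie_break_is_deterministic_lowest_index(self):
        # four identical samples: every pairwise distance ties at 0
        matrix = _matrix_from_profiles([[1.0, 2.0]] * 4, ["RM", "RM", "HN", "HN"])
        tree = hierarchical_cluster(matrix, matrix.probe_ids)
        tree2 = hierarchical_cluster(matrix, matrix.probe_ids)
        np.testing.assert_array_equal(tree.merges, tree2.merges)
        assert list(tree.merges[0, :2]) == [0.0, 1.0]  # lowest-index pair first

    def test_probe_order_invariance(self, planted_matrix):
        matrix, truth = planted_matrix
        tree = hierarchical_cluster(matrix, truth.de_probe_ids)
        tree_rev = hierarchical_cluster(matrix, truth.de_probe_ids[::-1])
        np.testing.assert_allclose(tree.merges[:, 2], tree_rev.merges[:, 2])

    def test_unknown_probes_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            hierarchical_cluster(tiny_matrix, ["nope"])
        with pytest.raises(ValueError, match="empty"):
            hierarchical_cluster(tiny_matrix, [])


class TestCutTwo:
    def test_toy_partition(self):
        matrix = _matrix_from_profiles([[0.0], [1.0], [10.0]], ["RM", "RM", "HN"])
        tree = hierarchical_cluster(matrix, ["p0"])
        blocks = set(map(frozenset, cut_two(tree)))
        assert blocks == {frozenset({"s0", "s1"}), frozenset({"s2"})}

    def test_separated_groups_recover_labels(self, planted_matrix):
        matrix, truth = planted_matrix
        tree = hierarchical_cluster(matrix, truth.de_probe_ids)
        blocks = cut_two(tree)
        by_group = {
            frozenset(matrix.samples_in_group("RM")),
            frozenset(matrix.samples_in_group("HN")),
        }
        assert set(blocks) == by_group

    def test_single_sample_rejected(self):
        matrix = _matrix_from_profiles([[0.0], [1.0]], ["RM", "HN"])
        tree = hierarchical_cluster(matrix, ["p0"])
        tree.merges = tree.merges[:0]
        tree.sample_ids = ["s0"]
        with pytest.raises(ValueError):
            cut_two(tree)


class TestConcordancePattern:
    labels = pd.Series(
        ["RM"] * 3 + ["HN"] * 3, index=[f"s{i}" for i in range(6)]
    )

    def test_perfect_separation(self):
        partition = (frozenset({"s0", "s1", "s2"}), frozenset({"s3", "s4", "s5"}))
        assert concordance_pattern(partition, self.labels, "RM", "HN") == (0, 3)
        assert concordance_pattern(partition, self.labels, "HN", "HN") == (3, 0)

    def test_single_focal_sample_sums_to_one(self):
        labels = pd.Series(["PM", "HN", "HN"], index=["a", "b", "c"])
        partition = (frozenset({"a", "b"}), frozenset({"c"}))
        pattern = concordance_pattern(partition, labels, "PM", "HN")
        assert sum(pattern) == 1

    def test_absent_groups_rejected(self):
        partition = (frozenset({"s0"}), frozenset({"s1", "s2", "s3", "s4", "s5"}))
        with pytest.raises(ValueError, match="focal"):
            concordance_pattern(partition, self.labels, "PM", "HN")
        with pytest.raises(ValueError, match="anchor"):
            concordance_pattern(partition, self.labels, "RM", "PM")


@pytest.fixture(scope="module")
def balanced():
    config = SimulationConfig(
        n_probes=60, n_rm=4, n_hn=4, n_pm=0, n_de=40,
        fold_range=(6.0, 6.0), cv=0.05, frac_unexpressed=0.0, seed=9,
    )
    return generate_expression(config)


class TestPermutationTest:
    def test_tree_unchanged_by_label_permutation(self, balanced):
        matrix, truth = balanced
        result = permutation_cluster_test(
            matrix, truth.de_probe_ids, matrix.groups, "RM", "HN",
            n_permutations=10, seed=1,
        )
        shuffled = matrix.groups.sample(frac=1.0, random_state=0)
        relabeled = ExpressionMatrix(
            matrix.intensities, matrix.detection, shuffled.loc[matrix.sample_ids]
        )
        tree2 = hierarchical_cluster(relabeled, truth.de_probe_ids)
        np.testing.assert_array_equal(result.tree.merges, tree2.merges)

    def test_matches_exhaustive_enumeration(self, balanced):
        """Empirical match frequency agrees with brute-force enumeration of
        all C(8,4)=70 labelings of the fixed partition."""
        matrix, truth = balanced
        result = permutation_cluster_test(
            matrix, truth.de_probe_ids, matrix.groups, "RM", "HN",
            n_permutations=20_000, seed=5,
        )
        samples = matrix.sample_ids
        observed = result.observed_pattern
        matches = 0
        for rm_set in itertools.combinations(samples, 4):
            labels = pd.Series(
                ["RM" if s in rm_set else "HN" for s in samples], index=samples
            )
            if concordance_pattern(result.partition, labels, "RM", "HN") == observed:
                matches += 1
        exact = matches / 70
        assert exact == pytest.approx(2 / 70)
        sd = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(result.match_frequency - exact) < 3.3 * sd

    def test_at_least_mode_is_no_stricter(self, balanced):
        matrix, truth = balanced
        exact = permutation_cluster_test(
            matrix, truth.de_probe_ids, matrix.groups, "RM", "HN",
            n_permutations=2000, seed=3, mode="exact",
        )
        at_least = permutation_cluster_test(
            matrix, truth.de_probe_ids, matrix.groups, "RM", "HN",
            n_permutations=2000, seed=3, mode="at-least",
        )
        assert at_least.n_matches >= exact.n_matches

    def test_pm_samples_track_hn_when_mimicking(self):
        config = SimulationConfig(
            n_probes=80, n_rm=9, n_hn=9, n_pm=6, n_de=50,
            fold_range=(4.0, 4.0), cv=0.1, frac_unexpressed=0.0,
            pm_mimics_hn=True, seed=9,
        )
        matrix, truth = generate_expression(config)
        tree = hierarchical_cluster(matrix, truth.de_probe_ids)
        pattern = concordance_pattern(cut_two(tree), matrix.groups, "PM", "HN")
        assert pattern[0] >= 5  # at least 5 of 6 PM in the HN-majority block

    def test_single_class_labels_rejected(self, balanced):
        matrix, truth = balanced
        flat = pd.Series("RM", index=matrix.sample_ids)
        with pytest.raises(ValueError, match="two classes"):
            permutation_cluster_test(
                matrix, truth.de_probe_ids, flat, "RM", "HN", n_permutations=5
            )


class TestSpearman:
    def test_identity_and_reciprocal(self):
        rng = np.random.default_rng(2)
        folds = rng.uniform(0.2, 5.0, 20)
        assert spearman_fold_correlation(folds, folds) == pytest.approx(1.0)
        assert spearman_fold_correlation(folds, 1.0 / folds) == pytest.approx(-1.0)

    def test_fixture_matches_manual_rank_computation(self):
        table = load_table2_fixture()
        a, b = table["fold_rm_hn"].to_numpy(), table["fold_rm_pm"].to_numpy()
        from scipy.stats import rankdata

        manual = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        assert spearman_fold_correlation(a, b) == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_fold_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman_fold_correlation([1.0, 2.0], [1.0, 2.0])
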