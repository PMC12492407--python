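"""SOM training, fit metrics, the grid-search selection rule, macrostate
clustering and representative-frame selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from loopsom.errors import ValidationError
from loopsom.geometry import ResidueRange, build_backbone
from loopsom.som import (MacrostateAssignment, SelfOrganizingMap,
                         SomMacrostateClusterer, choose_k, cluster_neurons,
                         grid_search, select_best_model,
                         select_representatives, standardize)
from loopsom.synthetic import FluctuationSpec, simulate_fluctuating_trajectory


class TestStandardize:
    def test_two_point_feature(self):
        xs, _ = standardize(np.array([[-1.0], [1.0]]))
        assert np.allclose(xs, [[-1.0], [1.0]])

    def test_constant_feature_rejected(self):
        with pytest.raises(ValidationError, match="column"):
            standardize(np.array([[1.0, 2.0], [1.0, 3.0]]))

    def test_random_matrix_centered_and_scaled(self):
        rng = np.random.default_rng(0)
        xs, _ = standardize(rng.normal(5.0, 3.0, size=(500, 4)))
        assert np.all(np.abs(xs.mean(axis=0)) <= 1e-9)
        assert np.allclose(xs.var(axis=0), 1.0, atol=1e-6)


class TestSomTraining:
    def test_repeated_point_collapses(self):
        X = np.tile([[2.0, -1.0]], (50, 1))
        som = SelfOrganizingMap(grid_side=3, sigma=1.0, n_epochs=500,
                                random_state=0).fit(X)
        assert som.metrics(X).quantization_error <= 1e-3

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        a = SelfOrganizingMap(grid_side=4, sigma=1.5, n_epochs=300,
                              random_state=7).fit(X)
        b = SelfOrganizingMap(grid_side=4, sigma=1.5, n_epochs=300,
                              random_state=7).fit(X)
        assert np.array_equal(a.weights_, b.weights_)

    def test_separated_blobs_have_disjoint_bmu_sets(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=(300, 2))
        b = rng.normal(10.0, 1.0, size=(300, 2))
        som = SelfOrganizingMap(grid_side=10, sigma=2.0, n_epochs=2000,
                                random_state=3).fit(np.vstack([a, b]))
        assert not (set(som.predict(a)) & set(som.predict(b)))

    def test_training_improves_on_random_initialization(self):
        """Trained QE beats the sample-initialized untrained map, 10-seed mean."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(6, 1, (150, 2))])
        trained, untrained = [], []
        for seed in range(10):
            som = SelfOrganizingMap(grid_side=5, sigma=1.5, n_epochs=1000,
                                    random_state=seed).fit(X)
            trained.append(som.metrics(X).quantization_error)
            init_idx = np.random.default_rng(seed).integers(0, len(X), 25)
            raw = SelfOrganizingMap.from_weights(X[init_idx], (5, 5), 1.0)
            untrained.append(raw.metrics(X).quantization_error)
        assert np.mean(trained) <= np.mean(untrained)

    def test_sigma_must_fit_grid(self):
        with pytest.raises(ValidationError):
            SelfOrganizingMap(grid_side=3, sigma=5.0).fit(np.zeros((5, 2)))


class TestSomMetrics:
    def test_weights_equal_samples_gives_zero_qe(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        som = SelfOrganizingMap.from_weights(X, (2, 2), 1.0)
        assert som.metrics(X).quantization_error == pytest.approx(0.0)

    def test_hand_computed_two_sample_example(self):
        """QE, TE and distortion on a 2-unit map match hand arithmetic."""
        som = SelfOrganizingMap.from_weights([[0.0], [1.0]], (2, 1),
                                             sigma_final=0.8)
        X = np.array([[0.2], [0.9]])
        met = som.metrics(X)
        assert met.quantization_error == pytest.approx((0.2 + 0.1) / 2, abs=1e-9)
        assert met.topographic_error == 0.0  # the two units are grid-adjacent
        h = math.exp(-1.0 / (2 * 0.8**2))  # neighbor weight at grid distance 1
        expected = (0.2**2 + 0.1**2) + h * (0.8**2 + 0.9**2)
        assert met.distortion == pytest.approx(expected, abs=1e-9)

    def test_distant_second_unit_counts_as_topographic_error(self):
        weights = [[0.0], [0.4], [10.0], [0.3]]
        som = SelfOrganizingMap.from_weights(weights, (4, 1), 1.0)
        # best unit 0, second-best unit 3 -> grid distance 3, not adjacent
        met = som.metrics(np.array([[0.0]]))
        assert met.topographic_error == 1.0


def literal_selection_rule(table: pd.DataFrame) -> int:
    """Line-by-line restatement of the documented selection rule."""
    n = len(table)
    m = max(1, math.ceil(0.10 * n))
    by_te = sorted(range(n), key=lambda i: (table["te"][i], i))
    candidates = by_te[:m]
    ranked = sorted(
        candidates,
        key=lambda i: (table["qe"][i], table["distortion"][i], i),
    )
    return ranked[0]


class TestSelectionRule:
    def test_strict_winner_selected(self):
        table = pd.DataFrame(
            {"qe": [0.1, 0.5, 0.9], "te": [0.0, 0.2, 0.4],
             "distortion": [1.0, 2.0, 3.0]}
        )
        assert select_best_model(table) == 0

    def test_global_min_qe_outside_te_decile_is_rejected(self):
        n = 20
        qe = np.linspace(0.5, 1.0, n)
        te = np.linspace(0.01, 0.5, n)
        dist = np.ones(n)
        qe[-1] = 0.001     # lowest QE of all, but worst TE
        table = pd.DataFrame({"qe": qe, "te": te, "distortion": dist})
        winner = select_best_model(table)
        assert winner != n - 1
        assert winner == literal_selection_rule(table)

    def test_agrees_with_literal_reimplementation_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            table = pd.DataFrame(
                {
                    "qe": rng.choice([0.1, 0.2, 0.3, 0.5], n),
                    "te": rng.choice([0.0, 0.1, 0.2, 0.3], n),
                    "distortion": rng.choice([1.0, 2.0, 3.0], n),
                }
            )
            assert select_best_model(table) == literal_selection_rule(table)

    def test_grid_search_deterministic_and_flags_winner(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(8, 1, (150, 2))])
        xs, _ = standardize(X)
        best_a, table_a = grid_search(xs, [5, 10], [1.0, 1.5], n_epochs=500,
                                      random_state=9)
        best_b, table_b = grid_search(xs, [5, 10], [1.0, 1.5], n_epochs=500,
                                      random_state=9)
        assert table_a.equals(table_b)
        assert np.array_equal(best_a.weights_, best_b.weights_)
        assert table_a["selected"].sum() == 1

    def test_sigma_exceeding_smallest_side_rejected(self):
        with pytest.raises(ValidationError):
            grid_search(np.zeros((10, 2)), [5], [5.0])


class TestChooseK:
    def test_second_largest_value(self):
        sil = {5: 0.9, 6: 0.8, 7: 0.4, 8: 0.3}
        assert choose_k(sil) == 6

    def test_tie_resolves_to_smaller_k(self):
        assert choose_k({5: 0.9, 6: 0.9, 7: 0.5}) == 6
        assert choose_k({5: 0.9, 6: 0.5, 7: 0.5}) == 6

    def test_global_max_flag(self):
        assert choose_k({5: 0.9, 6: 0.8}, selection="global_max") == 5


class TestClusterNeurons:
    def test_single_bmu_degenerate(self):
        som = SelfOrganizingMap.from_weights([[0.0], [50.0], [60.0], [70.0]],
                                             (2, 2), 1.0)
        X = np.zeros((20, 1))
        with pytest.raises(ValidationError, match="distinct BMU"):
            cluster_neurons(som, X)

    def test_k_range_truncated_with_warning(self):
        weights = np.arange(16, dtype=float).reshape(-1, 1) * 10
        som = SelfOrganizingMap.from_weights(weights, (4, 4), 1.0)
        X = weights[:6] + 0.01
        with pytest.warns(UserWarning, match="truncating"):
            assignment = cluster_neurons(som, X, k_range=(5, 20))
        assert assignment.k <= 5

    def test_populations_sum_and_bmu_map_consistency(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(c, 0.5, (120, 2)) for c in (0.0, 5.0, 10.0)])
        som = SelfOrganizingMap(grid_side=6, sigma=1.5, n_epochs=1500,
                                random_state=1).fit(X)
        assignment = cluster_neurons(som, X, k_range=(2, 8),
                                     selection="global_max")
        assert assignment.populations.sum() == len(X)
        for frame, bmu in enumerate(assignment.frame_bmus):
            assert assignment.labels[frame] == assignment.bmu_to_cluster[int(bmu)]


class TestRepresentatives:
    def make_assignment(self, labels):
        labels = np.asarray(labels)
        k = labels.max() + 1
        return MacrostateAssignment(
            labels, k, {}, np.bincount(labels, minlength=k), {},
            np.zeros_like(labels),
        )

    def test_exhaustive_scan_oracle(self, helix_frame):
        rng = np.random.default_rng(7)
        traj = simulate_fluctuating_trajectory(
            FluctuationSpec(helix_frame, np.full(20, 0.4), 100, seed=8))
        labels = rng.integers(0, 4, size=100)
        scores = rng.normal(size=100)
        subset = ResidueRange(5, 12)
        reps = select_representatives(self.make_assignment(labels), scores,
                                      traj, subset, helix_frame)
        # independent RMSD oracle via scipy on the CA subset
        sel = (traj.residue_indices >= 5) & (traj.residue_indices <= 12)
        ref = helix_frame.coords[sel, 1, :]
        ref_c = ref - ref.mean(0)
        oracle_rmsd = np.empty(100)
        for i in range(100):
            mob = traj.coords[i, sel, 1, :]
            mob_c = mob - mob.mean(0)
            _, rssd = Rotation.align_vectors(ref_c, mob_c)
            oracle_rmsd[i] = rssd / np.sqrt(len(ref))
        for c in range(4):
            members = np.nonzero(labels == c)[0]
            assert reps[c].min_score_frame == members[np.argmin(scores[members])]
            assert reps[c].max_rmsd_frame == members[np.argmax(oracle_rmsd[members])]

    def test_single_frame_cluster_serves_both_roles(self, helix_frame):
        traj = simulate_fluctuating_trajectory(
            FluctuationSpec(helix_frame, np.full(20, 0.4), 4, seed=9))
        labels = np.array([0, 0, 0, 1])
        reps = select_representatives(self.make_assignment(labels),
                                      np.array([5.0, 1.0, 3.0, 2.0]),
                                      traj, None, helix_frame)
        assert reps[1].min_score_frame == 3
        assert reps[1].max_rmsd_frame == 3

    def test_missing_scores_rejected(self):
        assignment = self.make_assignment([0, 0, 1])
        scores = pd.DataFrame({"frame": [0, 2], "score": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="missing scores"):
            select_representatives(assignment, scores)


def test_full_clusterer_deterministic():
    rng = np.random.default_rng(10)
    X = np.vstack([rng.normal(c, 1.0, (200, 3)) for c in (0.0, 8.0, 16.0)])
    kwargs = dict(grid_side=[5], sigma=[1.0, 1.5], n_epochs=800,
                  k_range=(2, 6), selection="global_max", random_state=2)
    a = SomMacrostateClusterer(**kwargs).fit(X)
    b = SomMacrostateClusterer(**kwargs).fit(X)
    assert np.array_equal(a.labels_, b.labels_)
    assert a.metrics_table_.equals(b.metrics_table_)
    assert a.assignment_.k == b.assignment_.k
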