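"""Tests for profile building, k-means, hierarchical clustering and typing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dgeprof import cluster, mapping, synthetic
from dgeprof.cluster import (
    TYPE_COMPLEX,
    TYPE_DOWN,
    TYPE_UP,
    ClusterAssignment,
    ProfileMatrix,
    build_profiles,
    classify_cluster_types,
    hierarchical_cluster,
    kmeans_cluster,
    within_cluster_ss,
)
from dgeprof.de import DegSet

LIBS = ["15d", "25d", "35d", "45d", "55d", "65d"]


def _matrix(tpm_rows: dict[str, list[float]], total=1_000_000):
    raw = {
        lib: {g: int(v[i]) for g, v in tpm_rows.items()}
        for i, lib in enumerate(LIBS)
    }
    return mapping.from_counts(raw, {lib: total for lib in LIBS}, LIBS)


def brute_force_average_linkage(points: np.ndarray) -> list[float]:
    """Exhaustive agglomeration oracle: merge heights under average linkage."""
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(points))}
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dists = [
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            ]
            d = float(np.mean(dists))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


def profiles_from_rows(rows: dict[str, list[float]]) -> ProfileMatrix:
    frame = pd.DataFrame(rows, index=LIBS).T
    frame.index.name = "gene"
    return ProfileMatrix(values=frame, transform="log")


class TestBuildProfiles:
    def test_constant_gene_zscores_to_zero_row(self):
        matrix = _matrix({"g1": [5, 5, 5, 5, 5, 5]})
        profiles = build_profiles(matrix, ["g1"], transform="zscore")
        assert np.allclose(profiles.values.loc["g1"], 0.0)

    def test_log2_values_with_zero_floor(self):
        matrix = _matrix({"g1": [10, 40, 10, 40, 10, 40]})
        profiles = build_profiles(matrix, ["g1"], transform="log", floor=0.0)
        row = profiles.values.loc["g1"]
        assert row.iloc[0] == pytest.approx(np.log2(10))
        assert row.iloc[1] - row.iloc[0] == pytest.approx(2.0)

    def test_missing_deg_gene_errors(self):
        matrix = _matrix({"g1": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(ValueError, match="absent"):
            build_profiles(matrix, ["g1", "ghost"])

    def test_accepts_degset(self):
        matrix = _matrix({"g1": [1, 2, 3, 4, 5, 6], "g2": [6, 5, 4, 3, 2, 1]})
        degs = DegSet(genes={"g1", "g2"})
        profiles = build_profiles(matrix, degs)
        assert sorted(profiles.genes) == ["g1", "g2"]

    def test_round_trips_through_tsv(self, tmp_path):
        matrix = _matrix({"g1": [1, 2, 3, 4, 5, 6], "g2": [9, 8, 7, 6, 5, 4]})
        profiles = build_profiles(matrix, ["g1", "g2"])
        path = tmp_path / "profiles.tsv"
        profiles.values.to_csv(path, sep="\t", float_format="%.17g")
        back = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        assert np.array_equal(profiles.values.to_numpy(), back.to_numpy())


class TestKmeans:
    def test_identical_profiles_share_cluster(self):
        rows = {
            "g1": [1, 2, 3, 4, 5, 6],
            "g2": [1, 2, 3, 4, 5, 6],
            "g3": [9, 7, 5, 3, 2, 1],
            "g4": [9, 7, 5, 3, 2, 1],
        }
        assignment = kmeans_cluster(profiles_from_rows(rows), k=2, seed=0)
        assert assignment.labels["g1"] == assignment.labels["g2"]
        assert assignment.labels["g3"] == assignment.labels["g4"]
        assert assignment.labels["g1"] != assignment.labels["g3"]

    def test_k_equals_n_singletons(self):
        rows = {f"g{i}": list(np.arange(6) * (i + 1.0)) for i in range(5)}
        profiles = profiles_from_rows(rows)
        assignment = kmeans_cluster(profiles, k=5, seed=1)
        assert len(set(assignment.labels)) == 5
        assert within_cluster_ss(profiles, assignment) == 0.0

    def test_k_too_large_errors(self):
        rows = {"g1": [1, 2, 3, 4, 5, 6]}
        with pytest.raises(ValueError):
            kmeans_cluster(profiles_from_rows(rows), k=2)

    def test_deterministic_under_seed(self, rng):
        rows = {f"g{i}": list(rng.normal(size=6)) for i in range(40)}
        p = profiles_from_rows(rows)
        a1 = kmeans_cluster(p, k=5, seed=42)
        a2 = kmeans_cluster(p, k=5, seed=42)
        assert a1.labels.equals(a2.labels)

    def test_down_clusters_come_first(self):
        rows = {
            "down1": [9.0, 8, 6, 4, 2, 1],
            "down2": [9.0, 8, 6, 4, 2, 1.5],
            "up1": [1.0, 2, 4, 6, 8, 9],
            "up2": [1.5, 2, 4, 6, 8, 9],
        }
        assignment = kmeans_cluster(profiles_from_rows(rows), k=2, seed=0)
        assert assignment.labels["down1"] == 1
        assert assignment.labels["up1"] == 2

    def test_recovers_separated_patterns(self, rng):
        rows = {}
        labels = {}
        for i in range(100):
            noise = rng.normal(0, 0.05, size=6)
            if i % 2:
                rows[f"g{i}"] = list(np.linspace(3, -3, 6) + noise)
                labels[f"g{i}"] = "down"
            else:
                rows[f"g{i}"] = list(np.linspace(-3, 3, 6) + noise)
                labels[f"g{i}"] = "up"
        assignment = kmeans_cluster(profiles_from_rows(rows), k=2, seed=3)
        # co-membership must match generated patterns
        down_clusters = {assignment.labels[g] for g, l in labels.items() if l == "down"}
        up_clusters = {assignment.labels[g] for g, l in labels.items() if l == "up"}
        assert down_clusters == {1}
        assert up_clusters == {2}

    def test_assignment_is_fixed_point_of_objective(self, rng):
        rows = {f"g{i}": list(rng.normal(size=6)) for i in range(60)}
        p = profiles_from_rows(rows)
        assignment = kmeans_cluster(p, k=4, seed=7)
        x = p.values.to_numpy()
        centers = np.vstack(
            [
                x[(assignment.labels == c).to_numpy()].mean(axis=0)
                for c in range(1, 5)
            ]
        )
        relabel = {c: i for i, c in enumerate(range(1, 5))}
        for gi, gene in enumerate(p.genes):
            d = np.linalg.norm(x[gi] - centers, axis=1)
            assert d[relabel[assignment.labels[gene]]] == pytest.approx(d.min())


class TestHierarchical:
    def test_coincident_pair_merges_first(self):
        rows = {
            "g1": [0.0] * 6,
            "g2": [0.0] * 6,
            "g3": [5.0] * 6,
        }
        z, order = hierarchical_cluster(profiles_from_rows(rows))
        assert z[0, 2] == 0.0
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_merge_heights_non_decreasing(self, rng):
        rows = {f"g{i}": list(rng.normal(size=6)) for i in range(30)}
        z, _ = hierarchical_cluster(profiles_from_rows(rows))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles_from_rows({"g1": [1.0] * 6}))

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_oracle(self, n, rng):
        rows = {f"g{i}": list(rng.normal(size=6)) for i in range(n)}
        p = profiles_from_rows(rows)
        z, _ = hierarchical_cluster(p)
        oracle = brute_force_average_linkage(p.values.to_numpy())
        np.testing.assert_allclose(sorted(z[:, 2]), sorted(oracle), rtol=1e-9)

    def test_leaf_order_deterministic(self, rng):
        rows = {f"g{i}": list(rng.normal(size=6)) for i in range(20)}
        p = profiles_from_rows(rows)
        _, o1 = hierarchical_cluster(p)
        _, o2 = hierarchical_cluster(p)
        assert o1 == o2


def _assignment_with_means(means: dict[int, list[float]]) -> ClusterAssignment:
    frame = pd.DataFrame.from_dict(means, orient="index", columns=LIBS)
    frame.index.name = "cluster"
    labels = pd.Series({f"g{c}": c for c in means})
    return ClusterAssignment(labels=labels, means=frame, k=len(means), seed=0)


class TestClassifyTypes:
    def test_strictly_decreasing_is_type_one(self):
        a = classify_cluster_types(_assignment_with_means({1: [9, 8, 6, 4, 2, 1]}))
        assert a.types[1] == TYPE_DOWN

    def test_strictly_increasing_is_type_two(self):
        a = classify_cluster_types(_assignment_with_means({1: [1, 2, 4, 6, 8, 9]}))
        assert a.types[1] == TYPE_UP

    def test_peak_is_complex(self):
        a = classify_cluster_types(_assignment_with_means({1: [1, 4, 9, 8, 3, 1]}))
        assert a.types[1] == TYPE_COMPLEX

    def test_flat_is_complex(self):
        a = classify_cluster_types(_assignment_with_means({1: [2, 2, 2, 2, 2, 2]}))
        assert a.types[1] == TYPE_COMPLEX

    def test_small_drift_below_threshold_is_complex(self):
        a = classify_cluster_types(
            _assignment_with_means({1: [2.0, 1.9, 1.8, 1.7, 1.6, 1.5]}),
            min_change=1.0,
        )
        assert a.types[1] == TYPE_COMPLEX

    def test_label_permutation_invariance(self):
        means = {1: [9, 8, 6, 4, 2, 1], 2: [1, 2, 4, 6, 8, 9]}
        a1 = classify_cluster_types(_assignment_with_means(means))
        swapped = {1: means[2], 2: means[1]}
        a2 = classify_cluster_types(_assignment_with_means(swapped))
        assert a1.types[1] == a2.types[2] == TYPE_DOWN
        assert a1.types[2] == a2.types[1] == TYPE_UP

    def test_gene_types_follow_cluster_types(self):
        a = classify_cluster_types(
            _assignment_with_means({1: [9, 8, 6, 4, 2, 1], 2: [1, 2, 4, 6, 8, 9]})
        )
        gt = a.gene_types()
        assert gt["g1"] == TYPE_DOWN
        assert gt["g2"] == TYPE_UP


class TestAgreementWithGeneratorPatterns:
    def test_types_match_truth_on_synthetic_trajectories(self):
        config = synthetic.SimulationConfig(
            pattern_mix={"down": 0.4, "up": 0.4, "peak": 0.2},
            de_fold=8.0,
            seed=33,
            abundance_sigma=0.5,
        )
        genes = [f"g{i}" for i in range(300)]
        truth = synthetic.simulate_trajectories(genes, config)
        rows = {t.gene_id: list(np.log2(t.abundances)) for t in truth}
        frame = pd.DataFrame(rows, index=LIBS).T
        frame.index.name = "gene"
        # z-score rows so pattern shape, not level, drives the clustering
        arr = frame.to_numpy()
        arr = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
        profiles = ProfileMatrix(
            values=pd.DataFrame(arr, index=frame.index, columns=frame.columns),
            transform="zscore",
        )
        assignment = classify_cluster_types(kmeans_cluster(profiles, k=3, seed=1),
                                            min_change=0.5)
        expected = {"down": TYPE_DOWN, "up": TYPE_UP, "peak": TYPE_COMPLEX}
        agree = sum(
            assignment.gene_types()[t.gene_id] == expected[t.pattern] for t in truth
        )
        assert agree / len(truth) >= 0.95
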