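"""The ten goodness-of-clustering indices against hand values and oracles."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from bioreg.cluster import Partition
from bioreg.community import AnalysisConfig, to_presence_absence
from bioreg.dissimilarity import DissimilarityMatrix
from bioreg.indices import (INDEX_DIRECTIONS, INDEX_NAMES, avg_silhouette,
                            calinski_harabasz, disdiam, evaluate_partition,
                            indval_total, isamic, optimclass, partana_ratio,
                            tabdev, totchi, wss_from_dissimilarity)
from test_cluster import dmat_from_points
from test_community import table_of
from conftest import random_labels, random_table


def part_of(labels):
    labels = np.asarray(labels, dtype=int)
    ids = tuple(f"s{i}" for i in range(len(labels)))
    return Partition(ids, labels, k=len(np.unique(labels)))


class TestIndvalHand:
    def test_perfect_indicator_scores_100(self):
        t = table_of([[3], [3], [0], [0]], state="log")
        r = indval_total(t, part_of([1, 1, 2, 2]))
        assert r.value == pytest.approx(100.0)
        assert r.direction == "higher_better"

    def test_ubiquitous_species_scores_50(self):
        t = table_of([[1], [1], [1], [1]], state="log")
        assert indval_total(t, part_of([1, 1, 2, 2])).value == pytest.approx(50.0)

    def test_mean_of_species_maxima(self):
        t = table_of([[3, 1], [3, 1], [0, 1], [0, 1]], state="log")
        assert indval_total(t, part_of([1, 1, 2, 2])).value == pytest.approx(75.0)

    def test_absent_species_warns_and_scores_zero(self):
        t = table_of([[1, 0], [1, 0]], state="log")
        with pytest.warns(UserWarning, match="absent"):
            r = indval_total(t, part_of([1, 2]))
        assert r.value == pytest.approx(25.0)  # (50 + 0) / 2


class TestIsamicHand:
    def test_extreme_constancy_is_one(self):
        t = table_of([[1], [1], [0], [0]])
        assert isamic(to_presence_absence(t), part_of([1, 1, 2, 2])).value == 1.0

    def test_intermediate_constancy_is_zero(self):
        t = table_of([[1], [0], [1], [0]])
        assert isamic(to_presence_absence(t), part_of([1, 1, 2, 2])).value == 0.0

    def test_half_case(self):
        # constancy 1 in cluster 1, 0.5 in cluster 2 -> 2*mean(0.5, 0) = 0.5
        t = table_of([[1], [1], [1], [0]])
        assert isamic(to_presence_absence(t), part_of([1, 1, 2, 2])).value == 0.5


class TestOptimclassHand:
    def test_hypergeometric_point_mass_at_boundary(self):
        # 5/5 in-cluster, 0/5 outside: p = 1/C(10,5) = 1/252
        t = table_of([[1]] * 5 + [[0]] * 5)
        part = part_of([1] * 5 + [2] * 5)
        pa = to_presence_absence(t)
        assert optimclass(pa, part, alpha=1 / 252 * 1.01).value == 1.0
        assert optimclass(pa, part, alpha=1 / 252 * 0.99).value == 0.0

    def test_degenerate_species_never_counted(self):
        t = table_of([[1, 0], [1, 0], [1, 0], [1, 0]])
        part = part_of([1, 1, 2, 2])
        assert optimclass(to_presence_absence(t), part, alpha=0.5).value == 0.0

    def test_bounded_by_species_times_clusters(self, curated, cfg):
        labels = random_labels(np.random.default_rng(0), curated.n_samples, 4)
        part = Partition(tuple(curated.sample_ids), labels, k=4)
        r = optimclass(to_presence_absence(curated), part)
        assert 0 <= r.value <= curated.n_taxa * 4
        assert float(r.value).is_integer()


class TestTabdevHand:
    def test_crisp_pattern_zero_deviance(self):
        t = table_of([[1], [1], [0], [0]])
        assert tabdev(to_presence_absence(t), part_of([1, 1, 2, 2])).value == 0.0

    def test_half_occupancy_cluster(self):
        t = table_of([[1], [1], [0], [0]])
        r = tabdev(to_presence_absence(t), part_of([1, 1, 1, 1]))
        assert r.value == pytest.approx(8 * np.log(2))

    def test_merging_identical_profile_clusters_invariant(self):
        rng = np.random.default_rng(3)
        block = (rng.random((4, 6)) > 0.5).astype(float)
        t = table_of(np.vstack([block, block]))
        pa = to_presence_absence(t)
        merged = tabdev(pa, part_of([1] * 8)).value
        split = tabdev(pa, part_of([1] * 4 + [2] * 4)).value
        assert merged == pytest.approx(split)


class TestTotchiHand:
    def test_proportional_rows_zero_inertia(self):
        t = table_of([[1, 2], [2, 4], [5, 10]], state="log")
        assert totchi(t, part_of([1, 1, 1])).value == pytest.approx(0.0)

    def test_all_singletons_zero(self):
        t = table_of([[1, 2], [3, 4], [5, 6]], state="log")
        assert totchi(t, part_of([1, 2, 3])).value == 0.0

    def test_identity_2x2(self):
        t = table_of([[1, 0], [0, 1]], state="log")
        assert totchi(t, part_of([1, 1])).value == pytest.approx(1.0)


class TestDissimilarityIndicesHand:
    def test_disdiam_is_mean_of_max_within(self):
        d = dmat_from_points([0.0, 0.2, 0.4, 5.0, 5.2])
        # cluster 1 diameters 0.4, cluster 2 diameter 0.2 -> mean 0.3
        r = disdiam(d, part_of([1, 1, 1, 2, 2]))
        assert r.value == pytest.approx(0.3)

    def test_disdiam_singletons_zero(self):
        d = dmat_from_points([0.0, 1.0, 2.0])
        assert disdiam(d, part_of([1, 2, 3])).value == 0.0

    def test_partana_hand_ratio(self):
        m = np.array([[0.0, 0.1, 0.9, 0.9],
                      [0.1, 0.0, 0.9, 0.9],
                      [0.9, 0.9, 0.0, 0.1],
                      [0.9, 0.9, 0.1, 0.0]])
        d = DissimilarityMatrix(("a", "b", "c", "d"), m)
        p = Partition(("a", "b", "c", "d"), np.array([1, 1, 2, 2]), k=2)
        assert partana_ratio(d, p).value == pytest.approx(9.0)

    def test_partana_equal_dissimilarities_is_one(self):
        m = np.ones((4, 4)) - np.eye(4)
        d = DissimilarityMatrix(("a", "b", "c", "d"), m * 0.5)
        p = Partition(("a", "b", "c", "d"), np.array([1, 1, 2, 2]), k=2)
        assert partana_ratio(d, p).value == pytest.approx(1.0)

    def test_partana_all_singletons_errors(self):
        d = dmat_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="singleton"):
            partana_ratio(d, part_of([1, 2, 3]))

    def test_silhouette_hand_with_singleton(self):
        d = dmat_from_points([0.0, 1.0, 10.0])
        r = avg_silhouette(d, part_of([1, 1, 2]))
        assert r.value == pytest.approx((0.9 + 8 / 9 + 0.0) / 3)

    def test_silhouette_duplicated_pair(self):
        d = dmat_from_points([0.0, 0.0, 9.0, 9.5])
        r = avg_silhouette(d, part_of([1, 1, 2, 2]))
        s = np.array([1.0, 1.0, (9 - 0.5) / 9, (9.5 - 0.5) / 9.5])
        assert r.value == pytest.approx(s.mean())

    def test_wss_two_point_cluster(self):
        d = dmat_from_points([0.0, 2.0])
        assert wss_from_dissimilarity(d, part_of([1, 1])).value == pytest.approx(2.0)

    def test_wss_singletons_zero(self):
        d = dmat_from_points([0.0, 1.0, 5.0])
        assert wss_from_dissimilarity(d, part_of([1, 2, 3])).value == 0.0

    def test_ch_errors_for_degenerate_k(self):
        d = dmat_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            calinski_harabasz(d, part_of([1, 1, 1]))
        with pytest.raises(ValueError):
            calinski_harabasz(d, part_of([1, 2, 3]))

    def test_ch_infinite_when_wss_zero(self):
        d = dmat_from_points([0.0, 0.0, 5.0, 5.0])
        r = calinski_harabasz(d, part_of([1, 1, 2, 2]))
        assert np.isinf(r.value)


class TestCoordinateOracles:
    """On Euclidean dissimilarities the pairwise forms equal the centroid forms."""

    @pytest.mark.parametrize("seed", range(5))
    def test_wss_and_ch_match_coordinates(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((12, 3))
        labels = random_labels(rng, 12, 3)
        d = dmat_from_points(x)
        p = part_of(labels)
        assert wss_from_dissimilarity(d, p).value == pytest.approx(
            orc.oracle_wss_coords(x, labels), abs=1e-9)
        assert calinski_harabasz(d, p).value == pytest.approx(
            orc.oracle_ch_coords(x, labels), abs=1e-9)


class TestEvaluatePartition:
    def make_inputs(self, seed=0, n=14, s=8, k=3):
        rng = np.random.default_rng(seed)
        from bioreg.community import log_transform, log_chord_transform
        from bioreg.dissimilarity import euclidean
        cfg = AnalysisConfig()
        raw = random_table(rng, n=n, s=s)
        log_tab = log_transform(raw, cfg)
        d = euclidean(log_chord_transform(raw, cfg))
        labels = random_labels(rng, n, k)
        return log_tab, d, part_of(labels)

    def test_returns_ten_with_declared_directions(self):
        log_tab, d, p = self.make_inputs()
        results = evaluate_partition(log_tab, d, p)
        assert [r.index_name for r in results] == list(INDEX_NAMES)
        assert {r.index_name: r.direction for r in results} == INDEX_DIRECTIONS

    def test_pure_function(self):
        log_tab, d, p = self.make_inputs()
        a = [r.value for r in evaluate_partition(log_tab, d, p)]
        b = [r.value for r in evaluate_partition(log_tab, d, p)]
        assert a == b

    @pytest.mark.parametrize("seed", range(3))
    def test_label_permutation_invariance(self, seed):
        log_tab, d, p = self.make_inputs(seed=seed)
        rng = np.random.default_rng(seed + 100)
        perm = rng.permutation(p.k) + 1
        relabeled = Partition(p.sample_ids,
                              np.array([perm[l - 1] for l in p.labels]), p.k)
        a = [r.value for r in evaluate_partition(log_tab, d, p)]
        b = [r.value for r in evaluate_partition(log_tab, d, relabeled)]
        assert a == pytest.approx(b, abs=1e-12)

    def test_undefined_values_flagged_not_dropped(self):
        # all-singleton partition: PARTANA undefined, CH undefined
        log_tab, d, _ = self.make_inputs(n=5, s=6)
        p = part_of([1, 2, 3, 4, 5])
        results = {r.index_name: r for r in evaluate_partition(log_tab, d, p)}
        assert len(results) == 10
        assert np.isnan(results["partana"].value)
        assert np.isnan(results["calinski_harabasz"].value)

    def test_planted_partition_beats_random_direction_aware(self, curated, cfg, bundle):
        from bioreg.community import log_transform, log_chord_transform
        from bioreg.dissimilarity import euclidean
        log_tab = log_transform(curated, cfg)
        d = euclidean(log_chord_transform(curated, cfg))
        truth_labels = bundle.truth.labels_for(curated.sample_ids)
        truth = Partition(tuple(curated.sample_ids), truth_labels, k=4)
        rng = np.random.default_rng(42)
        rand = Partition(tuple(curated.sample_ids),
                         random_labels(rng, curated.n_samples, 4), k=4)
        planted = {r.index_name: r for r in evaluate_partition(log_tab, d, truth)}
        random_ = {r.index_name: r for r in evaluate_partition(log_tab, d, rand)}
        for name in INDEX_NAMES:
            p, q = planted[name].value, random_[name].value
            if INDEX_DIRECTIONS[name] == "higher_better":
                assert p >= q, name
            else:
                assert p <= q, name
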