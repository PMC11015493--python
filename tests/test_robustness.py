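"""Label matching, classification error, experiment builders, and the battery."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from bioreg.cluster import Partition
from bioreg.community import AnalysisConfig
from bioreg.robustness import (ExperimentSpec, categorize_error,
                               classification_error, cluster_subset,
                               dominant_levels, experiment_battery,
                               iteration_seeds, match_labels, run_robustness)
from conftest import random_labels


def part(ids, labels):
    labels = np.asarray(labels, dtype=int)
    return Partition(tuple(ids), labels, k=len(np.unique(labels)))


class TestMatchLabels:
    def test_diagonal_dominant_identity(self):
        c = np.array([[9, 1], [0, 8]])
        assert match_labels(c) == {1: 1, 2: 2}

    def test_permutation_matrix(self):
        c = np.array([[0, 5, 0], [0, 0, 4], [6, 0, 0]])
        assert match_labels(c) == {1: 3, 2: 1, 3: 2}

    def test_empty_contingency_errors(self):
        with pytest.raises(ValueError, match="empty contingency"):
            match_labels(np.zeros((2, 2)))

    @pytest.mark.parametrize("size", [3, 4, 5])
    def test_agreement_matches_exhaustive(self, size):
        rng = np.random.default_rng(size)
        for _ in range(50):
            c = rng.integers(0, 20, (size, size))
            mapping = match_labels(c)
            agree = sum(c[i - 1, j - 1] for j, i in mapping.items())
            assert agree == orc.exhaustive_match_agreement(c)

    def test_rectangular_contingency(self):
        c = np.array([[5, 0, 0, 2], [0, 7, 1, 0]])   # more test than ref clusters
        mapping = match_labels(c)
        assert len(mapping) == 2
        agree = sum(c[i - 1, j - 1] for j, i in mapping.items())
        assert agree == orc.exhaustive_match_agreement(c)


class TestClassificationError:
    def test_identical_partitions_zero(self):
        ids = [f"s{i}" for i in range(10)]
        p = part(ids, [1, 1, 2, 2, 3, 3, 1, 2, 3, 1])
        overall, contrib = classification_error(p, p)
        assert overall == 0.0
        assert all(v == 0.0 for v in contrib.values())

    def test_relabeling_absorbed(self):
        ids = [f"s{i}" for i in range(6)]
        ref = part(ids, [1, 1, 2, 2, 3, 3])
        test = part(ids, [3, 3, 1, 1, 2, 2])
        overall, _ = classification_error(ref, test)
        assert overall == 0.0

    def test_single_mismatch_of_twenty(self):
        ids = [f"s{i}" for i in range(20)]
        labels = np.array([1] * 10 + [2] * 10)
        moved = labels.copy()
        moved[0] = 2                     # one reference-cluster-1 sample strays
        overall, contrib = classification_error(part(ids, labels), part(ids, moved))
        assert overall == pytest.approx(5.0)
        assert contrib[1] == pytest.approx(5.0)
        assert contrib[2] == 0.0

    def test_contributions_sum_to_overall(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(40)]
        for _ in range(20):
            ref = part(ids, random_labels(rng, 40, 4))
            test = part(ids, random_labels(rng, 40, 4))
            overall, contrib = classification_error(ref, test)
            assert sum(contrib.values()) == pytest.approx(overall, abs=1e-9)

    def test_invariant_to_cluster_id_permutation(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(30)]
        ref = part(ids, random_labels(rng, 30, 3))
        test_labels = random_labels(rng, 30, 3)
        test = part(ids, test_labels)
        perm = {1: 2, 2: 3, 3: 1}
        permuted = part(ids, np.array([perm[l] for l in test_labels]))
        assert classification_error(ref, test)[0] == pytest.approx(
            classification_error(ref, permuted)[0])

    def test_restricted_to_shared_samples(self):
        ref = part([f"s{i}" for i in range(8)], [1, 1, 1, 1, 2, 2, 2, 2])
        test = part([f"s{i}" for i in range(4, 8)] + ["x1", "x2"],
                    [1, 1, 1, 2, 2, 2])
        overall, _ = classification_error(ref, test)
        # shared = s4..s7, ref all cluster 2, test (1,1,1,2): best map 1->2
        assert overall == pytest.approx(25.0)

    def test_no_shared_samples_errors(self):
        ref = part(["a", "b"], [1, 2])
        test = part(["c", "d"], [1, 2])
        with pytest.raises(ValueError, match="shared"):
            classification_error(ref, test)


class TestCategorizeError:
    @pytest.mark.parametrize("pct,expected", [
        (0.0, "very low"), (4.4, "very low"), (5.0, "very low"),
        (5.4, "low"), (9.18, "low"), (10.0, "low"),
        (11.18, "moderately low"), (15.0, "moderately low"),
        (16.87, "moderately high"), (17.2, "moderately high"), (33.0, "moderately high"),
        (34.0, "high"), (53.99, "high"), (100.0, "high"),
    ])
    def test_bins(self, pct, expected):
        assert categorize_error(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_error(-1)
        with pytest.raises(ValueError):
            categorize_error(101)


class TestExperimentSpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown experiment kind"):
            ExperimentSpec("bogus", {})

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError, match="missing parameters"):
            ExperimentSpec("sample_fraction", {})

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            ExperimentSpec("sample_fraction", {"fraction": 1.5})


class TestRunRobustness:
    def test_full_fraction_matched_seed_is_exact_zero(self, curated, cfg):
        spec = ExperimentSpec("sample_fraction", {"fraction": 1.0},
                              n_iterations=1, seed=42)
        ref = cluster_subset(curated, 4, cfg, iteration_seeds(42, 1)[0])
        res = run_robustness(curated, None, None, ref, spec, cfg)
        assert res.overall.tolist() == [0.0]
        assert (res.contributions.iloc[0] == 0.0).all()

    def test_category_subset_deterministic(self, curated, cfg, bundle):
        spec = ExperimentSpec("category_subset",
                              {"field": "net_type", "levels": ["bongo_vnh"]},
                              n_iterations=1, seed=3)
        ref = cluster_subset(curated, 4, cfg, iteration_seeds(3, 1)[0])
        res = run_robustness(curated, bundle.sample_metadata,
                             bundle.taxon_metadata, ref, spec, cfg)
        assert res.overall.size == 1
        md = bundle.sample_metadata.data.loc[list(curated.sample_ids)]
        assert res.n_shared[0] == int((md["net_type"] == "bongo_vnh").sum())

    def test_subset_below_k_is_skipped(self, cfg):
        ids = [f"s{i}" for i in range(6)]
        import pandas as pd
        from bioreg.community import AbundanceTable
        rng = np.random.default_rng(0)
        tab = AbundanceTable(pd.DataFrame(rng.integers(1, 9, (6, 5)).astype(float),
                                          index=ids, columns=list("abcde")))
        ref = part(ids, [1, 2, 3, 4, 1, 2])
        spec = ExperimentSpec("sample_fraction", {"fraction": 0.34},
                              n_iterations=3, seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            res = run_robustness(tab, None, None, ref, spec, cfg)
        assert res.n_skipped == 3 and res.overall.size == 0

    def test_spatial_grid_floor_cells(self):
        # lat 48.26, lon -126.74 at 0.25 degrees -> cell (193, -507)
        assert int(np.floor(48.26 / 0.25)) == 193
        assert int(np.floor(-126.74 / 0.25)) == -507

    def test_spatial_grid_one_sample_per_cell(self, curated, cfg, bundle):
        spec = ExperimentSpec("spatial_grid", {"resolution_deg": 2.0},
                              n_iterations=1, seed=5)
        ref = cluster_subset(curated, 4, cfg, iteration_seeds(5, 1)[0])
        res = run_robustness(curated, bundle.sample_metadata,
                             bundle.taxon_metadata, ref, spec, cfg)
        md = bundle.sample_metadata.data.loc[list(curated.sample_ids)]
        cells = set(zip(np.floor(md["latitude"] / 2.0).astype(int),
                        np.floor(md["longitude"] / 2.0).astype(int)))
        assert res.n_shared[0] == len(cells)

    def test_taxonomic_presence_absence_variant(self, curated, cfg):
        spec = ExperimentSpec("taxonomic_variant",
                              {"variant": "data_type",
                               "data_type": "presence_absence"},
                              n_iterations=1, seed=9)
        ref = cluster_subset(curated, 4, cfg, iteration_seeds(9, 1)[0])
        res = run_robustness(curated, None, None, ref, spec, cfg)
        assert res.overall.size == 1
        assert 0 <= res.overall[0] <= 100


class TestBattery:
    def test_dominant_levels_cover_threshold(self):
        s = pd.Series(["a"] * 70 + ["b"] * 20 + ["c"] * 10)
        assert dominant_levels(s, coverage=0.8) == ["a", "b"]
        assert dominant_levels(s, coverage=0.5) == ["a"]

    def test_fraction_and_spatial_spec_counts(self, curated, cfg, bundle):
        ref = cluster_subset(curated, 4, cfg, 0)
        specs = experiment_battery(curated, bundle.sample_metadata,
                                   bundle.taxon_metadata, ref, cfg)
        kinds = [s.kind for s in specs]
        assert kinds.count("sample_fraction") == 20
        assert kinds.count("species_fraction") == 20
        assert kinds.count("spatial_grid") == 7
        assert all(s.name for s in specs)

    def test_every_spec_runs_on_fixture(self, curated, cfg, bundle):
        """Integration: the whole battery executes at 1 iteration per spec."""
        quick = AnalysisConfig(**{**cfg.to_dict(), "n_iterations": 1,
                                  "kmeans_n_init": 5})
        ref = cluster_subset(curated, 4, quick, iteration_seeds(1, 1)[0])
        specs = experiment_battery(curated, bundle.sample_metadata,
                                   bundle.taxon_metadata, ref, quick,
                                   raw_table=bundle.table)
        for spec in specs:
            res = run_robustness(curated, bundle.sample_metadata,
                                 bundle.taxon_metadata, ref, spec, quick,
                                 raw_table=bundle.table)
            assert res.overall.size + res.n_skipped == spec.n_iterations
        assert {s.kind for s in specs} >= {"sample_fraction", "species_fraction",
                                           "category_subset", "category_balanced",
                                           "temporal_subset", "temporal_balanced",
                                           "spatial_grid", "taxonomic_variant"}
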