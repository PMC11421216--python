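"""Split strategies, identity scoring, density clustering and leakage guards."""

from functools import lru_cache

import numpy as np
import pytest

from ophpred.data import CuratedDataset, ProteinRecord
from ophpred.errors import ValidationError
from ophpred.splitting import (
    ClusterAssignment,
    DistanceMatrix,
    ECSplit,
    SimilarityMatrix,
    SplitAssignment,
    clusters_to_split,
    density_cluster,
    ec_split,
    enrich_training,
    homology_split,
    identity_score,
    pairwise_similarity,
    parse_ec_class,
    pfam_holdout_splits,
    random_split,
    similarity_to_distance,
)


def _dataset(n, prefix="s"):
    records = [ProteinRecord(f"{prefix}{i}", "MKVLYAGH") for i in range(n)]
    return CuratedDataset(records, {r.id: 7.0 for r in records})


def lcs_length(a: str, b: str) -> int:
    """Independent oracle: classic LCS dynamic program."""
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[len(a)][len(b)]


def components_union_find(D: np.ndarray, eps: float) -> list[int]:
    """Independent oracle: connected components of the eps-threshold graph."""
    n = D.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= eps:
                parent[find(i)] = find(j)
    roots = {}
    return [roots.setdefault(find(i), len(roots)) for i in range(n)]


class TestRandomSplit:
    @pytest.mark.parametrize("n,expected_val", [(8, 2), (100, 25)])
    def test_three_to_one_ratio(self, n, expected_val):
        split = random_split(_dataset(n), 0.25, seed=0)
        assert len(split.validation_ids) == expected_val
        assert len(split.train_ids) == n - expected_val

    def test_deterministic_per_seed(self):
        a = random_split(_dataset(30), seed=5)
        b = random_split(_dataset(30), seed=5)
        c = random_split(_dataset(30), seed=6)
        assert a.validation_ids == b.validation_ids
        assert a.validation_ids != c.validation_ids

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            random_split(_dataset(10), validation_fraction=1.0)


class TestIdentityScore:
    def test_identical_sequences_score_one(self):
        assert identity_score("MKVLYA", "MKVLYA") == 1.0

    def test_matches_lcs_oracle_on_example(self):
        # best alignment of MKVL / MKWW keeps the MK prefix: 2 identities / 4
        assert identity_score("MKVL", "MKWW") == 0.5
        assert identity_score("MKVL", "MKWW") == lcs_length("MKVL", "MKWW") / 4

    def test_disjoint_alphabets_score_zero(self):
        assert identity_score("AAAA", "WWWW") == 0.0

    def test_matches_lcs_oracle_on_random_pairs(self, rng):
        letters = np.array(list("ACDEFGH"))
        for _ in range(25):
            a = "".join(rng.choice(letters, rng.integers(1, 15)))
            b = "".join(rng.choice(letters, rng.integers(1, 15)))
            assert identity_score(a, b) == lcs_length(a, b) / min(len(a), len(b))

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        records = [
            ProteinRecord("a", "MKVLYA"),
            ProteinRecord("b", "MKVLWW"),
            ProteinRecord("c", "GGGG"),
        ]
        sim = pairwise_similarity(records)
        np.testing.assert_allclose(sim.S, sim.S.T)
        np.testing.assert_allclose(np.diag(sim.S), 1.0)


class TestSimilarityToDistance:
    def test_elementwise_complement(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        dist = similarity_to_distance(sim)
        assert dist.D[0, 1] == pytest.approx(0.6)
        assert dist.D[0, 0] == 0.0


class TestDensityCluster:
    def test_two_close_points_form_one_cluster(self):
        dist = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        clusters = density_cluster(dist, eps=0.2, min_samples=1)
        assert clusters.assignments["a"] == clusters.assignments["b"]
        assert clusters.orphan_cluster_index is None

    def test_chain_connects_transitively(self):
        D = np.array([[0, 0.1, 0.3], [0.1, 0, 0.1], [0.3, 0.1, 0]])
        clusters = density_cluster(
            DistanceMatrix(["A", "B", "C"], D), eps=0.12, min_samples=1
        )
        assert len(set(clusters.assignments.values())) == 1

    def test_all_noise_merges_into_one_orphan_cluster(self):
        D = np.full((2, 2), 0.9)
        np.fill_diagonal(D, 0.0)
        clusters = density_cluster(
            DistanceMatrix(["a", "b"], D), eps=0.2, min_samples=2
        )
        assert clusters.orphan_cluster_index is not None
        assert clusters.assignments["a"] == clusters.assignments["b"]
        assert clusters.n_clusters == 1

    def test_invalid_eps_rejected(self):
        dist = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValidationError):
            density_cluster(dist, eps=0.0)

    def _random_distance(self, rng, n):
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D

    def test_min_samples_one_equals_connected_components(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 30))
            D = self._random_distance(rng, n)
            eps = float(rng.uniform(0.05, 0.95))
            ids = [f"s{i}" for i in range(n)]
            got = density_cluster(DistanceMatrix(ids, D), eps, min_samples=1)
            expected = components_union_find(D, eps)
            got_labels = [got.assignments[i] for i in ids]
            # same partition up to relabeling
            assert len(set(got_labels)) == len(set(expected))
            pairs = {(a, b) for a, b in zip(got_labels, expected)}
            assert len(pairs) == len(set(got_labels))

    def test_raising_eps_never_splits_components(self, rng):
        D = self._random_distance(rng, 25)
        ids = [f"s{i}" for i in range(25)]
        previous = None
        for eps in (0.1, 0.3, 0.5, 0.7, 0.9):
            k = density_cluster(DistanceMatrix(ids, D), eps, min_samples=1).n_clusters
            if previous is not None:
                assert k <= previous
            previous = k


class TestClustersToSplit:
    def test_four_singletons_give_one_validation_id(self):
        clusters = ClusterAssignment({f"s{i}": i for i in range(4)})
        split = clusters_to_split(clusters, 0.25, seed=0)
        assert len(split.validation_ids) == 1
        assert len(split.train_ids) == 3

    def test_three_one_packing_isolates_singleton(self):
        clusters = ClusterAssignment({"a": 0, "b": 0, "c": 0, "d": 1})
        split = clusters_to_split(clusters, 0.25, seed=0)
        # whole clusters on one side: the singleton is alone on its side
        assert {frozenset(split.train_ids), frozenset(split.validation_ids)} == {
            frozenset({"a", "b", "c"}),
            frozenset({"d"}),
        }

    def test_single_cluster_cannot_be_split(self):
        clusters = ClusterAssignment({"a": 0, "b": 0})
        with pytest.raises(ValidationError):
            clusters_to_split(clusters)

    def test_deterministic_and_disjoint(self, rng):
        assignments = {f"s{i}": int(rng.integers(0, 8)) for i in range(60)}
        clusters = ClusterAssignment(assignments)
        a = clusters_to_split(clusters, seed=3)
        b = clusters_to_split(clusters, seed=3)
        assert a.validation_ids == b.validation_ids
        assert not a.train_ids & a.validation_ids
        assert a.train_ids | a.validation_ids == set(assignments)

    def test_clusters_stay_whole(self, rng):
        assignments = {f"s{i}": int(rng.integers(0, 6)) for i in range(40)}
        clusters = ClusterAssignment(assignments)
        split = clusters_to_split(clusters, seed=1)
        for c, members in clusters.clusters().items():
            sides = {m in split.validation_ids for m in members}
            assert len(sides) == 1  # never straddles the split


class TestHomologyLeakage:
    def test_cross_split_pairs_exceed_eps(self, rng):
        for trial in range(10):
            n = int(rng.integers(6, 40))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            eps = float(rng.uniform(0.1, 0.6))
            ids = [f"s{i}" for i in range(n)]
            clusters = density_cluster(DistanceMatrix(ids, D), eps, min_samples=1)
            if clusters.n_clusters < 2:
                continue
            split = clusters_to_split(clusters, seed=trial)
            index = {rid: i for i, rid in enumerate(ids)}
            for t in split.train_ids:
                for v in split.validation_ids:
                    assert D[index[t], index[v]] > eps


class TestPfamHoldout:
    def test_holdout_construction(self):
        dataset = _dataset(3, prefix="r")
        holdout = pfam_holdout_splits(
            dataset, {"r0": ["P1"], "r1": ["P1"], "r2": ["P2"]}
        )
        by_acc = dict(holdout.splits)
        assert by_acc["P1"].validation_ids == {"r0", "r1"}
        assert by_acc["P1"].train_ids == {"r2"}
        assert by_acc["P2"].validation_ids == {"r2"}

    def test_accession_covering_everything_skipped(self):
        dataset = _dataset(2, prefix="r")
        holdout = pfam_holdout_splits(dataset, {"r0": ["PX"], "r1": ["PX"]})
        assert holdout.splits == []
        assert holdout.skipped == ["PX"]

    def test_unannotated_record_always_trains(self):
        dataset = _dataset(4, prefix="r")
        holdout = pfam_holdout_splits(
            dataset, {"r0": ["P1"], "r1": ["P2"], "r2": ["P1"]}
        )
        for _, split in holdout.splits:
            assert "r3" in split.train_ids


class TestECSplit:
    def test_top_level_class_parsing(self):
        assert parse_ec_class("1.1.1.194") == 1
        assert parse_ec_class("3.2.1.-") == 3
        with pytest.raises(ValidationError, match="idX"):
            parse_ec_class("EC?", "idX")

    def test_partition_and_bifunctional_discard(self):
        dataset = _dataset(12, prefix="e")
        annotations = {}
        for i in range(12):
            if i < 6:
                annotations[f"e{i}"] = ["3.2.1.4"]
            elif i < 10:
                annotations[f"e{i}"] = ["1.1.1.194"]
            elif i == 10:
                annotations[f"e{i}"] = ["3.5.1.10", "1.5.1.5"]  # bifunctional
            # e11 left unannotated
        result = ec_split(dataset, annotations, n_folds=3, seed=0)
        hydro = set().union(*result.hydrolase_folds)
        assert hydro == {f"e{i}" for i in range(6)}
        assert result.nonhydrolase_train == {f"e{i}" for i in range(6, 10)}
        assert result.discarded == {"e10", "e11"}
        assert sorted(len(f) for f in result.hydrolase_folds) == [2, 2, 2]
        # partition: no id lost or duplicated
        assert hydro | result.nonhydrolase_train | result.discarded == set(
            dataset.ids
        )

    def test_too_few_hydrolases_rejected(self):
        dataset = _dataset(3, prefix="e")
        with pytest.raises(ValidationError):
            ec_split(dataset, {"e0": ["3.1.1.1"]}, n_folds=5)


class TestEnrichment:
    def _split(self):
        return SplitAssignment(train_ids={"t1"}, validation_ids={"v1", "v2"})

    def test_guard_excludes_near_validation(self):
        new = _dataset(1, prefix="n")
        out = enrich_training(
            self._split(), new, lambda a, b: 0.5 if b == "v1" else 0.9, eps=0.6
        )
        assert "n0" not in out.train_ids

    def test_guard_admits_distant_sequences(self):
        new = _dataset(1, prefix="n")
        out = enrich_training(self._split(), new, lambda a, b: 0.9, eps=0.6)
        assert "n0" in out.train_ids
        assert out.validation_ids == {"v1", "v2"}

    def test_random_mode_admits_everything(self):
        new = _dataset(3, prefix="n")
        out = enrich_training(self._split(), new)
        assert {"n0", "n1", "n2"} <= out.train_ids

    def test_id_collision_rejected(self):
        new = _dataset(1, prefix="v")  # v0 fine; collide explicitly
        split = SplitAssignment(train_ids={"n0"}, validation_ids={"v1"})
        with pytest.raises(ValidationError):
            enrich_training(split, _dataset(1, prefix="n"), lambda a, b: 1.0, 0.5)

    def test_validation_never_shrinks(self):
        new = _dataset(5, prefix="n")
        out = enrich_training(self._split(), new, lambda a, b: 0.0, eps=0.6)
        assert out.validation_ids == {"v1", "v2"}
        assert out.train_ids == {"t1"}


class TestHomologySplitOnFamilies:
    def test_families_never_straddle_the_split(self, small_sim, small_dataset):
        split, clusters = homology_split(
            small_dataset, eps=0.4, min_samples=1, seed=0
        )
        fam = small_sim.family_of()
        train_fams = {fam[i] for i in split.train_ids}
        val_fams = {fam[i] for i in split.validation_ids}
        assert not train_fams & val_fams
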