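import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrdist import (
    BootstrapConfig,
    ClusteringRecipe,
    CorrdistError,
    Partition,
    ValidationError,
    adjusted_rand_index,
    bootstrap_run,
    cluster_matrix,
    compare_distances,
    dissolution,
    jaccard,
    pair_consistency,
)
from corrdist.robustness import BootstrapReplicate
from corrdist.synthetic import PlantedDesign, generate


def make_replicate(classes: dict[int, set[str]], sampled=None) -> BootstrapReplicate:
    """Hand-build a bootstrap replicate from its class sets."""
    sampled = sampled if sampled is not None else set().union(*classes.values())
    first_copy = {item: lab for lab, members in classes.items() for item in members}
    return BootstrapReplicate(
        indices=np.array([]), sampled_items=sampled,
        classes=classes, first_copy_label=first_copy,
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({1, 2, 3}, {2, 3, 4}, 0.5), ({1, 2}, {1, 2}, 1.0), ({1, 2}, {3, 4}, 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_empty_first_set_rejected(self):
        with pytest.raises(ValidationError):
            jaccard(set(), {1})
        assert jaccard({1}, set()) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.sets(st.integers(0, 20), min_size=1, max_size=10),
        b=st.sets(st.integers(0, 20), max_size=10),
    )
    def test_bounded(self, a, b):
        assert 0.0 <= jaccard(a, b) <= 1.0


@pytest.fixture(scope="module")
def planted():
    design = PlantedDesign(n_items=18, n_dims=10, k=3, noise_sd=0.0, flip_prob=0.2, seed=3)
    matrix, truth, _ = generate(design)
    return matrix, truth


RECIPE_R = ClusteringRecipe(method="pam", distance_kind="d_r", k=3)
SMALL_CFG = BootstrapConfig(n_bootstraps=20, n_iterations=2, dissolve_count=8, seed=7)


class TestBootstrapRun:
    def test_deterministic_under_seed(self, planted):
        matrix, _ = planted
        runs1 = bootstrap_run(matrix, RECIPE_R, SMALL_CFG)
        runs2 = bootstrap_run(matrix, RECIPE_R, SMALL_CFG)
        assert len(runs1) == SMALL_CFG.n_bootstraps
        for a, b in zip(runs1, runs2):
            assert np.array_equal(a.indices, b.indices)
            assert a.classes == b.classes
            assert a.first_copy_label == b.first_copy_label

    def test_single_bootstrap_recovers_original_on_separable_data(self, planted):
        matrix, truth = planted
        cfg = BootstrapConfig(n_bootstraps=1, n_iterations=1, dissolve_count=1, seed=5)
        (rep,) = bootstrap_run(matrix, RECIPE_R, cfg)
        sampled = sorted(rep.sampled_items)
        p_boot = Partition({i: rep.first_copy_label[i] for i in sampled})
        p_true = Partition({i: truth.assignment[i] for i in sampled})
        assert adjusted_rand_index(p_boot, p_true) == pytest.approx(1.0)

    def test_k_larger_than_n_rejected(self, planted):
        matrix, _ = planted
        with pytest.raises(ValidationError):
            bootstrap_run(matrix, ClusteringRecipe(method="pam", k=99), SMALL_CFG)


class TestDissolution:
    def test_identical_partitions_nothing_dissolves(self, planted):
        matrix, truth = planted
        p_o = cluster_matrix(matrix, RECIPE_R)
        runs = bootstrap_run(matrix, RECIPE_R, SMALL_CFG)
        res = dissolution(p_o, runs, SMALL_CFG)
        assert res.n_dissolved == 0
        assert all(s["dissolve_count"] == 0 for s in res.per_class.values())

    def test_jaccard_exactly_half_is_not_a_dissolve_event(self):
        # class {a,b,c} best-matched by {a,b,c,d,e,f}: J = 3/6 = 0.5 exactly
        p_o = Partition({i: 0 for i in "abc"} | {i: 1 for i in "gh"})
        rep = make_replicate({0: set("abcdef"), 1: set("gh")})
        cfg = BootstrapConfig(n_bootstraps=100, n_iterations=1, dissolve_count=40, seed=0)
        res = dissolution(p_o, [rep] * 100, cfg)
        assert res.per_class[0]["dissolve_count"] == 0
        assert res.n_dissolved == 0

    def test_strict_count_threshold(self):
        p_o = Partition({i: 0 for i in "abcd"} | {i: 1 for i in "efgh"})
        shattered = make_replicate(
            {0: {"a", "e"}, 1: {"b", "f"}, 2: {"c", "g"}, 3: {"d", "h"}}
        )  # best J for class 0 = 1/5 < 0.5
        intact = make_replicate({0: set("abcd"), 1: set("efgh")})
        cfg = BootstrapConfig(n_bootstraps=100, n_iterations=1, dissolve_count=40, seed=0)
        at_forty = dissolution(p_o, [shattered] * 40 + [intact] * 60, cfg)
        assert at_forty.per_class[0]["dissolve_count"] == 40
        assert at_forty.per_class[0]["dissolved"] is False  # strictly > 40 required
        at_fifty = dissolution(p_o, [shattered] * 50 + [intact] * 50, cfg)
        assert at_fifty.per_class[0]["dissolved"] is True
        assert at_fifty.n_dissolved == 2

    def test_unsampled_class_is_skipped_and_recorded(self):
        p_o = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        rep = make_replicate({0: {"c", "d"}}, sampled={"c", "d"})
        cfg = BootstrapConfig(n_bootstraps=10, n_iterations=1, dissolve_count=5, seed=0)
        res = dissolution(p_o, [rep] * 10, cfg)
        assert res.per_class[0]["skipped"] == 10
        assert res.per_class[0]["dissolve_count"] == 0

    def test_raising_jaccard_threshold_never_lowers_counts(self, planted):
        matrix, _ = planted
        noisy, _, _ = generate(
            PlantedDesign(n_items=18, n_dims=10, k=3, noise_sd=0.5, flip_prob=0.2, seed=9)
        )
        p_o = cluster_matrix(noisy, RECIPE_R)
        runs = bootstrap_run(noisy, RECIPE_R, SMALL_CFG)
        lo = dissolution(p_o, runs, BootstrapConfig(20, 2, 0.3, 10, 7))
        hi = dissolution(p_o, runs, BootstrapConfig(20, 2, 0.8, 10, 7))
        for c in lo.per_class:
            assert hi.per_class[c]["dissolve_count"] >= lo.per_class[c]["dissolve_count"]


class TestPairConsistency:
    def test_perfectly_stable_clustering_gives_one(self, planted):
        matrix, _ = planted
        p_o = cluster_matrix(matrix, RECIPE_R)
        runs = bootstrap_run(matrix, RECIPE_R, SMALL_CFG)
        res = pair_consistency(p_o, runs)
        assert res.upsilon == pytest.approx(1.0)
        assert res.m_together == pytest.approx(1.0)
        assert res.m_not_together == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        """Hand medians: together ratios {0.6, 1.0}, apart {0.6, 0.6, 1.0, 1.0}.

        m_together = 0.8, m_not_together = 0.8, upsilon = 0.64.
        """
        p_o = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        clean = make_replicate({0: {"a", "b"}, 1: {"c", "d"}})
        a_alone = make_replicate({0: {"a"}, 1: {"b", "c", "d"}})
        # (a,b): same in 3 of 5 -> together, 0.6;  (c,d): same in 5 of 5 -> 1.0
        # (b,c),(b,d): same in 2 of 5 -> apart, 0.6;  (a,c),(a,d): apart, 1.0
        runs = [clean] * 3 + [a_alone] * 2
        res = pair_consistency(p_o, runs)
        per = res.per_pair.set_index(["item_a", "item_b"])
        assert per.loc[("a", "b"), "n2"] / per.loc[("a", "b"), "n1"] == pytest.approx(0.6)
        assert per.loc[("a", "b"), "orientation"] == "together"
        assert per.loc[("c", "d"), "n2"] / per.loc[("c", "d"), "n1"] == pytest.approx(1.0)
        assert per.loc[("b", "c"), "orientation"] == "apart"
        assert res.m_together == pytest.approx(0.8)
        assert res.m_not_together == pytest.approx(0.8)
        assert res.upsilon == pytest.approx(0.64)

    def test_never_cosampled_pair_excluded(self):
        p_o = Partition({"a": 0, "b": 0, "c": 1})
        r1 = make_replicate({0: {"a"}, 1: {"c"}}, sampled={"a", "c"})
        r2 = make_replicate({0: {"b", "c"}}, sampled={"b", "c"})
        res = pair_consistency(p_o, [r1, r2, r1, r2])
        pairs = set(zip(res.per_pair["item_a"], res.per_pair["item_b"]))
        assert ("a", "b") not in pairs

    def test_undefined_when_single_class(self, planted):
        matrix, _ = planted
        recipe = ClusteringRecipe(method="pam", distance_kind="d_r", k=1)
        p_o = cluster_matrix(matrix, recipe)
        runs = bootstrap_run(matrix, recipe, SMALL_CFG)
        with pytest.raises(CorrdistError, match="upsilon undefined"):
            pair_consistency(p_o, runs)

    def test_upsilon_bounded(self):
        rng = np.random.default_rng(2)
        noisy, _, _ = generate(
            PlantedDesign(n_items=15, n_dims=8, k=3, noise_sd=0.6, seed=int(rng.integers(100)))
        )
        p_o = cluster_matrix(noisy, RECIPE_R)
        runs = bootstrap_run(noisy, RECIPE_R, SMALL_CFG)
        res = pair_consistency(p_o, runs)
        assert 0.0 <= res.upsilon <= 1.0


class TestCompareDistances:
    def test_recipes_must_differ_only_in_distance(self, planted):
        matrix, _ = planted
        other = ClusteringRecipe(method="pam", distance_kind="d_a", k=4)
        with pytest.raises(ValidationError):
            compare_distances(matrix, RECIPE_R, other, SMALL_CFG)

    def test_identical_recipes_tie_everywhere(self, planted):
        matrix, _ = planted
        res = compare_distances(matrix, RECIPE_R, RECIPE_R, SMALL_CFG)
        assert res.n_win_a == res.n_win_b == 0
        assert res.n_tie == SMALL_CFG.n_iterations
        assert res.upsilon_a == res.upsilon_b

    def test_single_iteration_summary(self, planted):
        matrix, _ = planted
        cfg = BootstrapConfig(n_bootstraps=10, n_iterations=1, dissolve_count=4, seed=1)
        recipe_a = ClusteringRecipe(method="pam", distance_kind="d_a", k=3)
        res = compare_distances(matrix, recipe_a, RECIPE_R, cfg)
        assert len(res.upsilon_a) == len(res.upsilon_b) == 1
        assert len(res.dissolved_a) == 1
        assert res.n_win_a + res.n_win_b + res.n_tie == 1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_bootstraps": 0},
            {"dissolve_jaccard": 0.0},
            {"dissolve_jaccard": 1.0},
            {"dissolve_count": 0},
            {"dissolve_count": 101},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            BootstrapConfig(**kwargs)
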