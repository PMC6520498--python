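"""Inference tests: cosine similarity, the run-label permutation test against
an exhaustive-enumeration oracle, impact-map recovery, mediation correlation,
and the temporal-variability control."""
import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonofc.connectivity import Fingerprint
from sonofc.core import NodeAtlas, Region
from sonofc.inference import (cosine_similarity, fingerprint_permutation_test,
                              impact_heatmap, mediation_correlation,
                              temporal_variability_summary,
                              temporal_variability_test)
from sonofc.synth import apply_decoupling, build_network, simulate_run


def _fps(mat: np.ndarray, condition="control", sources=None) -> list[Fingerprint]:
    targets = [f"t{j}" for j in range(mat.shape[1])]
    sources = sources or [f"s{i}" for i in range(mat.shape[0])]
    return [Fingerprint(targets, row, "seed", condition, src)
            for row, src in zip(mat, sources)]


class TestCosine:
    @pytest.mark.parametrize("a,b,expected", [
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 1.0),
        ((1.0, 0.0), (0.0, 1.0), 0.0),
        ((1.0, 2.0, 3.0), (2.0, 4.0, 6.0), 1.0),
        ((1.0, 1.0), (1.0, -1.0), 0.0),
    ])
    def test_reference_values(self, a, b, expected):
        assert cosine_similarity(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.1, 50.0))
    def test_positive_scale_invariance(self, c):
        a = np.array([0.3, -1.2, 0.7])
        b = np.array([1.1, 0.2, -0.4])
        assert cosine_similarity(c * a, b) == pytest.approx(cosine_similarity(a, b))


class TestPermutationTest:
    def test_identical_conditions_degenerate(self):
        mat = np.tile([0.5, 0.2, 0.1], (4, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fingerprint_permutation_test(_fps(mat[:2]), _fps(mat[2:], "acc_tus"))
        assert res.observed_similarity == 1.0
        assert res.p_value == 1.0

    def test_two_vs_two_matches_hand_enumeration(self, rng):
        """Exhaustive oracle: all C(4,2)=6 balanced relabelings, by loops."""
        mat = rng.standard_normal((4, 5)) + 2.0
        res = fingerprint_permutation_test(_fps(mat[:2]), _fps(mat[2:], "acc_tus"),
                                           rng_seed=1)
        assert res.exhaustive and res.n_perm == 6

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        obs = cos(mat[:2].mean(0), mat[2:].mean(0))
        null = []
        for comb in combinations(range(4), 2):
            rest = [i for i in range(4) if i not in comb]
            null.append(cos(mat[list(comb)].mean(0), mat[rest].mean(0)))
        expected_p = np.mean(np.array(null) <= obs + 1e-12)
        assert res.observed_similarity == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_monte_carlo_agrees_with_exact(self, rng):
        mat = rng.standard_normal((8, 6)) + 1.5
        a, b = _fps(mat[:4]), _fps(mat[4:], "acc_tus")
        exact = fingerprint_permutation_test(a, b, method="exact")
        mc = fingerprint_permutation_test(a, b, n_perm=5000,
                                          method="monte_carlo", rng_seed=3)
        assert not mc.exhaustive
        assert abs(mc.p_value - exact.p_value) <= 0.02

    def test_plus_one_convention(self, rng):
        mat = rng.standard_normal((4, 4)) + 1.0
        a, b = _fps(mat[:2]), _fps(mat[2:], "acc_tus")
        plain = fingerprint_permutation_test(a, b)
        plus = fingerprint_permutation_test(a, b, plus_one=True)
        n = plain.n_perm
        assert plus.p_value == pytest.approx((plain.p_value * n + 1) / (n + 1))

    def test_subject_exchange_unit_keeps_runs_together(self, rng):
        # 3 subjects x 2 runs per condition side
        mat = rng.standard_normal((8, 4)) + 1.0
        a = _fps(mat[:4], sources=["s0", "s0", "s1", "s1"])
        b = _fps(mat[4:], "acc_tus", sources=["s2", "s2", "s3", "s3"])
        res = fingerprint_permutation_test(a, b, exchange_unit="subject")
        assert res.exhaustive and res.n_perm == 6  # C(4,2) subject splits

    def test_inconsistent_targets_raise(self, rng):
        a = _fps(rng.standard_normal((2, 3)))
        bad = Fingerprint(["x", "y", "z"], np.ones(3), "seed", "acc_tus", "s")
        with pytest.raises(ValueError):
            fingerprint_permutation_test(a, [bad, bad])


class TestImpactMap:
    def test_identical_series_give_zero_map(self, toy_atlas, rng):
        series = rng.standard_normal((200, toy_atlas.n_points))
        imap = impact_heatmap(series, series, toy_atlas)
        np.testing.assert_allclose(imap.values, 0.0, atol=1e-12)

    def test_summed_equals_row_sum_of_region_deltas(self, toy_atlas, rng):
        a = rng.standard_normal((150, toy_atlas.n_points))
        b = rng.standard_normal((150, toy_atlas.n_points))
        imap = impact_heatmap(a, b, toy_atlas)
        np.testing.assert_allclose(imap.values, imap.per_region.sum(axis=1),
                                   atol=1e-12)

    def test_sonicated_region_in_set_raises(self, toy_atlas, rng):
        series = rng.standard_normal((100, toy_atlas.n_points))
        with pytest.raises(ValueError, match="sonicated"):
            impact_heatmap(series, series, toy_atlas, region_set=["alpha", "beta"])

    def test_decoupled_node_recovered_at_argmax(self):
        """Ground-truth recovery: strong decoupling localises to the node."""
        atlas = NodeAtlas(
            [Region(f"n{k}", f"n{k}", "midline", tuple(range(3 * k, 3 * k + 3)))
             for k in range(5)],
            roles={f"n{k}": ({"sonication_target"} if k == 0 else {"apriori_heatmap"})
                   for k in range(5)},
        )
        net = build_network(5, 0.5, 0.5, [list(range(5))],
                           node_names=tuple(atlas.nodes))
        tus = apply_decoupling(net, "n0", 0.3)
        ctl_run, _ = simulate_run(net, atlas, 3000, point_noise_sd=0.5, rng_seed=1)
        tus_run, _ = simulate_run(tus, atlas, 3000, point_noise_sd=0.5, rng_seed=2)
        imap = impact_heatmap(ctl_run.data - ctl_run.data.mean(0),
                              tus_run.data - tus_run.data.mean(0), atlas)
        assert imap.argmax_node(atlas) == "n0"


class TestMediation:
    def test_identical_vectors(self):
        d = np.array([0.1, -0.2, 0.3, 0.05])
        r, p = mediation_correlation(d, d)
        assert r == pytest.approx(1.0)

    def test_negated_vectors(self):
        d = np.array([0.1, -0.2, 0.3, 0.05])
        r, _ = mediation_correlation(d, -d)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r = cov/sd1 sd2 = 3 / 5 for these vectors, by direct formula
        r, p = mediation_correlation(np.array([1.0, 2, 3, 4]),
                                     np.array([2.0, 1, 4, 3]))
        assert r == pytest.approx(0.6, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_permutation_p_close_to_parametric(self, rng):
        a = rng.standard_normal(10)
        b = a + rng.standard_normal(10)
        _, p_par = mediation_correlation(a, b)
        _, p_perm = mediation_correlation(a, b, method="permutation",
                                          n_perm=4000, rng_seed=0)
        assert abs(p_par - p_perm) < 0.1

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            mediation_correlation(np.ones(4), np.array([1.0, 2, 3, 4]))


class TestTemporalVariability:
    def test_constant_series_zero(self, toy_atlas):
        series = np.ones((100, toy_atlas.n_points))
        out = temporal_variability_summary(series, toy_atlas)
        assert all(v == 0.0 for v in out.values())

    def test_homogeneous_under_scaling(self, toy_atlas, rng):
        series = rng.standard_normal((200, toy_atlas.n_points))
        one = temporal_variability_summary(series, toy_atlas)
        two = temporal_variability_summary(2 * series, toy_atlas)
        for node in one:
            assert two[node] == pytest.approx(2 * one[node])

    def test_unit_white_noise_close_to_one(self, toy_atlas, rng):
        series = rng.standard_normal((1000, toy_atlas.n_points))
        out = temporal_variability_summary(series, toy_atlas)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_group_comparison_reports_p_per_region(self, toy_atlas, rng):
        sums_a = [temporal_variability_summary(rng.standard_normal((100, 8)), toy_atlas)
                  for _ in range(4)]
        sums_b = [temporal_variability_summary(rng.standard_normal((100, 8)), toy_atlas)
                  for _ in range(4)]
        out = temporal_variability_test(sums_a, sums_b, n_perm=500, rng_seed=0)
        assert set(out) == set(toy_atlas.nodes)
        assert all(0.0 <= v["p_value"] <= 1.0 for v in out.values())


def test_null_impact_map_shrinks_with_run_length(toy_atlas, toy_network):
    """Without an effect the summed-delta map is sampling noise that decays
    with the amount of data."""
    small, big = [], []
    for seed in range(3):
        r1, _ = simulate_run(toy_network, toy_atlas, 100, rng_seed=seed)
        r2, _ = simulate_run(toy_network, toy_atlas, 100, rng_seed=seed + 50)
        small.append(np.abs(impact_heatmap(r1.data - r1.data.mean(0),
                                           r2.data - r2.data.mean(0),
                                           toy_atlas).values).max())
        r1, _ = simulate_run(toy_network, toy_atlas, 4000, rng_seed=seed)
        r2, _ = simulate_run(toy_network, toy_atlas, 4000, rng_seed=seed + 50)
        big.append(np.abs(impact_heatmap(r1.data - r1.data.mean(0),
                                         r2.data - r2.data.mean(0),
                                         toy_atlas).values).max())
    assert np.mean(big) < np.mean(small)
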