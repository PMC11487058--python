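import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xolint.datatypes import ChromosomeDataset, CrossoverSample, Space
from xolint.errors import ClusteringWarning, DegenerateDataError
from xolint.interference import (
    compute_pair_statistics,
    interference_length,
    mean_cross_distance,
    mean_pairwise_distance,
    mixed_interference_length,
)
from xolint.simulate import SimulationConfig, simulate

from conftest import dataset_from_counts


def brute_force_mpd(x):
    x = np.asarray(x, dtype=float)
    total, m = 0.0, len(x)
    for i in range(m):
        for j in range(i + 1, m):
            total += abs(x[i] - x[j])
    return total / (m * (m - 1) / 2)


class TestMeanPairwiseDistance:
    def test_single_pair(self):
        assert mean_pairwise_distance([0.0, 3.5]) == pytest.approx(3.5)

    def test_duplicated_endpoints(self):
        # 6 pairs: 4 at distance L, 2 at distance 0 -> 2L/3
        assert mean_pairwise_distance([0.0, 0.0, 1.0, 1.0]) == pytest.approx(2 / 3)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            mean_pairwise_distance([0.5])

    def test_uniform_closed_form(self):
        # E|X - Y| = 1/3 for independent uniforms on [0, 1]
        x = np.random.default_rng(7).uniform(0, 1, 100_000)
        assert mean_pairwise_distance(x) == pytest.approx(1 / 3, abs=3e-3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
            min_size=2,
            max_size=200,
        )
    )
    def test_prefix_sum_matches_brute_force(self, positions):
        fast = mean_pairwise_distance(positions)
        slow = brute_force_mpd(positions)
        assert fast == pytest.approx(slow, rel=1e-12, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=1, max_size=50),
        st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=1, max_size=50),
    )
    def test_cross_distance_matches_brute_force(self, a, b):
        fast = mean_cross_distance(np.array(a), np.array(b))
        slow = np.abs(np.subtract.outer(np.array(a), np.array(b))).mean()
        assert fast == pytest.approx(slow, rel=1e-12, abs=1e-12)


class TestPairStatistics:
    def test_pair_counts_broad_vs_narrow(self):
        # counts (1,2,3) -> mean pair count 4/3; (2,2,2) -> 1; same <N> = 2
        assert compute_pair_statistics(dataset_from_counts([1, 2, 3])).n_obs_pair == 4 / 3
        assert compute_pair_statistics(dataset_from_counts([2, 2, 2])).n_obs_pair == 1.0

    def test_phi_from_counts(self):
        ps = compute_pair_statistics(dataset_from_counts([2, 2, 2]))
        assert ps.mean_count == 2.0
        assert ps.n_noint_pair == 2.0
        assert ps.phi == 0.5

    def test_phi_zero_without_multi_co_samples(self):
        ps = compute_pair_statistics(dataset_from_counts([1, 1, 0, 1]))
        assert ps.phi == 0.0
        assert ps.d_obs is None

    def test_worked_example(self, worked_dataset):
        ps = compute_pair_statistics(worked_dataset)
        assert ps.phi == pytest.approx(12 / 25)
        assert ps.d_obs == pytest.approx(0.7)
        assert ps.d_noint == pytest.approx(0.44)  # 10 pooled pairs summing to 4.4
        assert ps.n_noint_pair == pytest.approx(ps.mean_count**2 / 2)

    def test_zero_co_samples_enter_mean_count(self):
        with_empty = dataset_from_counts([2, 2, 0, 0])
        assert compute_pair_statistics(with_empty).mean_count == 1.0

    def test_all_empty_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compute_pair_statistics(dataset_from_counts([0, 0, 0]))


class TestInterferenceLength:
    def test_worked_example(self, worked_dataset):
        res = interference_length(worked_dataset)
        assert res.l_int == pytest.approx(0.416)
        assert res.l_int_norm == pytest.approx(0.416 * (5 / 3))
        assert res.n_samples == 3

    def test_reconstructible_from_pair_stats(self, worked_dataset):
        res = interference_length(worked_dataset)
        ps = res.pair_stats
        expected = ps.phi * (ps.d_obs - ps.d_noint) + (1 - ps.phi) * (
            worked_dataset.length_L - ps.d_noint
        )
        assert res.l_int == pytest.approx(expected, rel=1e-12)

    def test_identical_positions_give_full_length(self):
        ds = ChromosomeDataset(
            "c",
            2.0,
            Space.SC_UM,
            [CrossoverSample(f"s{i}", np.array([0.7])) for i in range(5)],
        )
        assert interference_length(ds).l_int == 2.0  # phi = 0, d_noint = 0

    def test_bound_l_int_le_l_minus_dnoint(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            samples = [
                CrossoverSample(f"s{i}", rng.uniform(0, 1, rng.integers(0, 4)))
                for i in range(30)
            ]
            ds = ChromosomeDataset("c", 1.0, Space.SC_UM, samples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ClusteringWarning)
                res = interference_length(ds)
            ps = res.pair_stats
            if 0 <= ps.phi <= 1:
                assert res.l_int <= ds.length_L - ps.d_noint + 1e-12

    def test_scale_equivariance(self, worked_dataset):
        c = 7.5
        scaled = ChromosomeDataset(
            "c",
            worked_dataset.length_L * c,
            Space.SC_UM,
            [
                CrossoverSample(s.sample_id, s.positions * c)
                for s in worked_dataset.samples
            ],
        )
        r0, r1 = interference_length(worked_dataset), interference_length(scaled)
        assert r1.l_int == pytest.approx(r0.l_int * c, rel=1e-12)
        assert r1.pair_stats.d_obs == pytest.approx(r0.pair_stats.d_obs * c, rel=1e-12)
        assert r1.pair_stats.phi == r0.pair_stats.phi
        assert r1.l_int_norm == pytest.approx(r0.l_int_norm, rel=1e-12)

    def test_bivalent_correction_doubles_normalization(self, worked_dataset):
        plain = interference_length(worked_dataset)
        corrected = interference_length(worked_dataset, bivalent_correction=True)
        assert corrected.l_int == plain.l_int
        assert corrected.l_int_norm == pytest.approx(2 * plain.l_int_norm)

    def test_clustering_warns_and_can_go_negative(self):
        # all COs paired tightly in the same samples: far more pairs than Poisson
        samples = [
            CrossoverSample("a", np.array([0.1, 0.12, 0.5, 0.52])),
            CrossoverSample("b", np.array([])),
            CrossoverSample("c", np.array([])),
            CrossoverSample("d", np.array([])),
        ]
        ds = ChromosomeDataset("c", 1.0, Space.SC_UM, samples)
        with pytest.warns(ClusteringWarning):
            res = interference_length(ds)
        assert res.pair_stats.n_mis_pair < 0
        assert res.pair_stats.d_int is None


class TestMixedClass:
    @staticmethod
    def _two_class_dataset(rng, n, rate_a, rate_b, coupled=False):
        samples = []
        for i in range(n):
            na, nb = rng.poisson(rate_a), rng.poisson(rate_b)
            a = rng.uniform(0, 1, na)
            if coupled and na:
                b = []
                attempts = 0
                while len(b) < nb and attempts < 200:
                    attempts += 1
                    x = rng.uniform(0, 1)
                    if np.min(np.abs(a - x)) >= 0.3:
                        b.append(x)
                b = np.array(b)
            else:
                b = rng.uniform(0, 1, nb)
            pos = np.concatenate([a, b])
            cls = np.array(["I"] * na + ["II"] * len(b), dtype=object)
            samples.append(CrossoverSample(f"s{i}", pos, cls))
        return ChromosomeDataset("c", 1.0, Space.SC_UM, samples)

    def test_independent_classes_give_zero(self):
        ds = self._two_class_dataset(np.random.default_rng(11), 20_000, 1.5, 1.0)
        assert mixed_interference_length(ds).l_int == pytest.approx(0.0, abs=0.02)

    def test_cross_class_exclusion_detected(self):
        ds = self._two_class_dataset(
            np.random.default_rng(12), 10_000, 1.0, 1.0, coupled=True
        )
        assert mixed_interference_length(ds).l_int > 0.05

    def test_same_class_reduces_to_standard_estimator(self):
        rng = np.random.default_rng(13)
        samples = []
        for i in range(5_000):
            pos = rng.uniform(0, 1, rng.poisson(2))
            samples.append(
                CrossoverSample(f"s{i}", pos, np.array(["I"] * pos.size, dtype=object))
            )
        ds = ChromosomeDataset("c", 1.0, Space.SC_UM, samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClusteringWarning)
            res = mixed_interference_length(ds, "I", "I")
        assert res.l_int == pytest.approx(0.0, abs=0.02)

    def test_absent_class_is_degenerate(self):
        samples = [
            CrossoverSample("a", np.array([0.5]), np.array(["I"], dtype=object))
        ]
        ds = ChromosomeDataset("c", 1.0, Space.SC_UM, samples)
        with pytest.raises(DegenerateDataError):
            mixed_interference_length(ds, "I", "II")

    def test_unknown_class_excluded(self):
        samples = [
            CrossoverSample(
                "a",
                np.array([0.2, 0.5, 0.8]),
                np.array(["I", "unknown", "II"], dtype=object),
            )
            for _ in range(3)
        ]
        ds = ChromosomeDataset("c", 1.0, Space.SC_UM, samples)
        res = mixed_interference_length(ds)
        # one cross pair (0.2, 0.8) per sample; the unknown CO plays no role
        assert res.pair_stats.d_obs == pytest.approx(0.6)


class TestNoInterferenceLimit:
    @pytest.mark.parametrize("density", ["uniform", "bimodal"])
    def test_poisson_data_give_zero(self, density):
        ds = simulate(
            SimulationConfig(
                "poisson_null", 50_000, mean_count=2.0, position_density=density, seed=21
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClusteringWarning)
            res = interference_length(ds)
        assert res.l_int == pytest.approx(0.0, abs=0.02)
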