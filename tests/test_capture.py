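"""Capture statistics: exact Poisson-binomial oracle, Monte Carlo null,
per-TC profiling, and arbor-asymmetry vectors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import islandcircuit.capture as cap
from islandcircuit.model import MissingSomaError, NoRGCInputsError, SYNAPSE_COLUMNS

from conftest import make_chain_skeleton


def brute_force_capture_distribution(counts):
    """Independent oracle: enumerate all 2**sum(k) dendrite assignments."""
    K = int(sum(counts))
    assert K <= 20
    states = np.arange(2**K, dtype=np.int64)
    bits = (states[:, None] >> np.arange(K)) & 1
    captured = np.zeros(len(states), dtype=np.int64)
    off = 0
    for k in counts:
        s = bits[:, off : off + k].sum(axis=1)
        captured += (s == 0) | (s == k)
        off += k
    return np.bincount(captured, minlength=len(counts) + 1) / float(2**K)


class TestCaptureProbability:
    def test_single_dendrite_always_agrees(self):
        assert cap.capture_probability(1) == 1.0

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_matches_enumeration(self, k):
        agree = sum(
            1 for bits in itertools.product((0, 1), repeat=k)
            if len(set(bits)) == 1
        )
        assert cap.capture_probability(k) == agree / 2**k

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cap.capture_probability(0)


class TestExactDistribution:
    def test_single_cell_one_dendrite(self):
        np.testing.assert_allclose(cap.exact_capture_distribution([1]), [0.0, 1.0])

    def test_two_cells_two_dendrites(self):
        np.testing.assert_allclose(
            cap.exact_capture_distribution([2, 2]), [0.25, 0.5, 0.25], atol=1e-15
        )
        np.testing.assert_allclose(
            brute_force_capture_distribution([2, 2]), [0.25, 0.5, 0.25], atol=1e-15
        )

    def test_reference_counts_mean(self):
        counts = (2, 2, 3, 4, 4, 4, 5, 5, 7)
        dist = cap.exact_capture_distribution(counts)
        assert abs(dist.sum() - 1.0) < 1e-12
        assert cap.exact_capture_mean(counts) == 1.765625
        np.testing.assert_allclose(
            (dist * np.arange(len(dist))).sum(), 1.765625, atol=1e-12
        )

    def test_empty_counts_concentrate_at_zero(self):
        np.testing.assert_allclose(cap.exact_capture_distribution([]), [1.0])

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=4).filter(
            lambda c: sum(c) <= 12
        )
    )
    def test_convolution_equals_enumeration(self, counts):
        np.testing.assert_allclose(
            cap.exact_capture_distribution(counts),
            brute_force_capture_distribution(counts),
            atol=1e-12,
        )


class TestMonteCarloNull:
    def test_all_single_dendrite_cells_always_captured(self):
        null = cap.monte_carlo_null([1, 1, 1], trials=500, seed=0)
        assert null.captured_count_histogram[3] == 500

    def test_histogram_sums_to_trials_and_is_deterministic(self):
        a = cap.monte_carlo_null([2, 3, 4], trials=10_000, seed=5)
        b = cap.monte_carlo_null([2, 3, 4], trials=10_000, seed=5)
        assert a.captured_count_histogram.sum() == 10_000
        np.testing.assert_array_equal(
            a.captured_count_histogram, b.captured_count_histogram
        )

    def test_empirical_close_to_exact(self):
        null = cap.monte_carlo_null([2, 2, 3, 4], trials=30_000, seed=3)
        tv = 0.5 * np.abs(null.empirical_distribution - null.exact_distribution).sum()
        assert tv < 0.02

    def test_quantile_convention_smallest_m_reaching_level(self):
        # CDF: 0.5, 0.75, 1.0 -> smallest m with CDF >= 0.7 is 1
        hist = np.array([50, 25, 25])
        assert cap.empirical_quantile(hist, 100, 0.7) == 1
        assert cap.empirical_quantile(hist, 100, 0.5) == 0
        assert cap.empirical_quantile(hist, 100, 0.76) == 2


class TestExceedance:
    def test_observed_zero_tail_is_one(self):
        null = cap.monte_carlo_null([2, 2], trials=1000, seed=1)
        rep = cap.compare_observed_to_null(0, null)
        assert rep["exact_tail"] == 1.0
        assert rep["empirical_tail"] == 1.0

    def test_full_capture_tail_is_product_of_probabilities(self):
        counts = (2, 2, 3, 4, 4, 4, 5, 5, 7)
        null = cap.monte_carlo_null(counts, trials=1000, seed=2)
        rep = cap.compare_observed_to_null(9, null)
        np.testing.assert_allclose(rep["exact_tail"], 2.0 ** (9 - sum(counts)), rtol=1e-12)

    def test_threshold_consistency_with_empirical_tail(self):
        null = cap.monte_carlo_null([2, 2, 3, 4, 5], trials=20_000, seed=4, levels=[0.99])
        m = null.empirical_quantile_thresholds[0.99]
        for obs in range(null.n_tc + 1):
            rep = cap.compare_observed_to_null(obs, null)
            exceeds = rep["thresholds"]["0.99"]["observed_exceeds"]
            # above the 99% threshold <=> empirical tail below 1% + one trial
            assert exceeds == (obs > m)
            if exceeds:
                assert rep["empirical_tail"] < 0.01 + 1.0 / null.trials


class TestClassifyTC:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((118, 0, 0), "pure_island"),
            ((10, 0, 0), "pure_island"),
            ((0, 8, 0), "pure_nonisland"),
            ((1, 1, 0), "mixed"),
            ((0, 0, 0), "no_rgc"),
            ((2, 0, 3), "ambiguous_zone"),  # 3/5 ambiguous, over the 0.5 cutoff
            ((0, 0, 4), "ambiguous_zone"),
        ],
    )
    def test_examples(self, counts, expected):
        assert cap.classify_tc(*counts) == expected

    @given(
        st.tuples(
            st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
        ),
        st.sampled_from([0.3, 0.5, 0.8]),
    )
    def test_exhaustive_and_symmetric(self, counts, frac):
        i, n, a = counts
        c = cap.classify_tc(i, n, a, ambiguous_fraction=frac)
        assert c in cap.CAPTURE_CLASSES
        swapped = cap.classify_tc(n, i, a, ambiguous_fraction=frac)
        swap_map = {"pure_island": "pure_nonisland", "pure_nonisland": "pure_island"}
        assert swapped == swap_map.get(c, c)


def _synapses_for(tc_id, positions, start=0):
    rows = [
        (f"s{start + j:04d}", f"b{start + j:04d}", tc_id, p[0], p[1], p[2], "RGC", "TC")
        for j, p in enumerate(positions)
    ]
    return pd.DataFrame(rows, columns=list(SYNAPSE_COLUMNS))


class TestProfileTC:
    def test_counts_primary_dendrites_and_fields(self, stub_labeling_factory):
        sk = make_chain_skeleton(n_dendrites=3)
        # two synapses on dendrite +x, one on dendrite +y, none on +z
        syn = _synapses_for("tc_test", [(2000, 0, 0), (6000, 0, 0), (0, 4000, 0)])
        labeling = stub_labeling_factory(
            {"s0000": "island", "s0001": "island", "s0002": "island"}
        )
        prof = cap.profile_tc(sk, syn, labeling)
        assert (prof.n_island, prof.n_nonisland, prof.n_ambiguous) == (3, 0, 0)
        assert prof.primary_dendrite_count == 2
        assert prof.capture_class == "pure_island"

    def test_no_rgc_inputs(self, stub_labeling_factory):
        sk = make_chain_skeleton()
        prof = cap.profile_tc(sk, _synapses_for("other_tc", [(0, 0, 1000)]),
                              stub_labeling_factory({}))
        assert prof.capture_class == "no_rgc"
        assert prof.primary_dendrite_count == 0

    def test_mostly_ambiguous_inputs_give_ambiguous_zone(self, stub_labeling_factory):
        """A TC like TC17: a few boutons, most sitting mid-exclusion-zone."""
        sk = make_chain_skeleton(n_dendrites=2)
        syn = _synapses_for(
            "tc_test",
            [(2000, 0, 0), (4000, 0, 0), (0, 2000, 0), (0, 4000, 0), (0, 6000, 0)],
        )
        labeling = stub_labeling_factory(
            {
                "s0000": "island",
                "s0001": "island",
                "s0002": "ambiguous",
                "s0003": "ambiguous",
                "s0004": "ambiguous",
            }
        )
        prof = cap.profile_tc(sk, syn, labeling)
        assert prof.n_ambiguous == 3
        assert prof.capture_class == "ambiguous_zone"

    def test_distant_synapse_warns_but_counts(self, stub_labeling_factory):
        sk = make_chain_skeleton()
        syn = _synapses_for("tc_test", [(50000, 50000, 0)])
        with pytest.warns(UserWarning, match="farther"):
            prof = cap.profile_tc(sk, syn, stub_labeling_factory({"s0000": "island"}))
        assert prof.n_total_rgc == 1


class TestSomaSynapseVector:
    def test_offset_of_colinear_inputs(self):
        sk = make_chain_skeleton()
        v = cap.soma_synapse_vector(sk, [(1000, 0, 0), (3000, 0, 0)])
        np.testing.assert_allclose(v.offset, [2000, 0, 0])
        assert v.offset_norm == 2000.0

    def test_symmetric_inputs_cancel(self):
        sk = make_chain_skeleton()
        v = cap.soma_synapse_vector(sk, [(1000, 2000, 0), (-1000, -2000, 0)])
        assert v.offset_norm < 1e-9

    def test_signed_projection_away_from_island_is_positive(self):
        sk = make_chain_skeleton()
        island_centroid = np.array([-50000.0, 0.0, 0.0])  # island far on -x
        v = cap.soma_synapse_vector(sk, [(4000, 0, 0)], island_centroid=island_centroid)
        assert v.signed_offset_along_island_normal > 0

    def test_error_types_distinct(self):
        sk = make_chain_skeleton()
        with pytest.raises(NoRGCInputsError):
            cap.soma_synapse_vector(sk, np.zeros((0, 3)))
        nosoma = make_chain_skeleton(cell_class="other")
        nosoma.structure_codes[:] = 3
        with pytest.raises(MissingSomaError):
            cap.soma_synapse_vector(nosoma, [(1000, 0, 0)])


class TestCumulativeCurve:
    def test_sorted_ascending_with_running_total(self, stub_labeling_factory):
        profiles = [
            cap.InnervationProfile(f"tc{i}", n, 0, 0, 2, "pure_island")
            for i, n in enumerate([5, 2, 9])
        ]
        curve = cap.cumulative_bouton_curve(profiles)
        assert list(curve["n_rgc_boutons"]) == [2, 5, 9]
        assert list(curve["cumulative_boutons"]) == [2, 7, 16]
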