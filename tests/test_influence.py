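"""Step 2: discretization, lag alignment, MI estimation, influence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bruteforce_time_delayed_mi
from tdgrn.exceptions import ValidationError
from tdgrn.influence import (
    EQUAL_WIDTH,
    InfluenceRecord,
    MiConfig,
    compute_influence,
    discretize_profile,
    lagged_samples,
    time_delayed_mi,
)
from tdgrn.sce import CaseTag, PairCase


class TestDiscretize:
    def test_equal_frequency_thirds(self):
        syms = discretize_profile([1, 2, 3, 4, 5, 6], MiConfig(n_bins=3))
        assert syms.tolist() == [0, 0, 1, 1, 2, 2]

    def test_constant_profile_maps_to_zero(self):
        assert discretize_profile([5, 5, 5], MiConfig(n_bins=4)).tolist() == [0, 0, 0]

    def test_equal_width_endpoints(self):
        syms = discretize_profile([0, 10], MiConfig(n_bins=2, binning=EQUAL_WIDTH))
        assert syms.tolist() == [0, 1]

    def test_ties_go_to_lower_bin(self):
        # median of [1,2,2,3] is 2; values equal to the edge take the lower bin
        syms = discretize_profile([1, 2, 2, 3], MiConfig(n_bins=2))
        assert syms.tolist() == [0, 0, 0, 1]

    def test_pooled_binning_across_series(self):
        prof = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        syms = discretize_profile(prof, MiConfig(n_bins=3))
        assert syms.shape == prof.shape
        assert syms[0].tolist() == [0, 0, 1] and syms[1].tolist() == [1, 2, 2]

    @settings(derandomize=True, max_examples=100)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        bins=st.integers(2, 6),
    )
    def test_symbols_within_range(self, values, bins):
        syms = discretize_profile(values, MiConfig(n_bins=bins))
        assert syms.min() >= 0 and syms.max() <= bins - 1


class TestLaggedSamples:
    def test_window_length_single_series(self):
        x = np.zeros((1, 21), dtype=int)
        assert len(lagged_samples(x, x, 2)) == 19

    def test_pairs_do_not_span_series(self):
        x = np.zeros((10, 21), dtype=int)
        assert len(lagged_samples(x, x, 1)) == 200

    def test_lag_beyond_series_is_empty(self):
        x = np.zeros((1, 3), dtype=int)
        assert lagged_samples(x, x, 3) == []

    def test_alignment_is_x_before_y(self):
        x = np.array([[1, 2, 3, 4]])
        y = np.array([[5, 6, 7, 8]])
        assert lagged_samples(x, y, 2) == [(1, 7), (2, 8)]


class TestTimeDelayedMi:
    def test_constant_x_gives_zero(self):
        x = [0, 0, 0, 0, 0, 0]
        y = [0, 1, 2, 0, 1, 2]
        assert time_delayed_mi(x, y, 1, MiConfig(n_bins=3)) == 0.0

    def test_perfect_dependence_equals_marginal_entropy(self):
        # y_{i+1} = x_i for all 5 lagged pairs; marginals 3/5 and 2/5
        x = [0, 1, 0, 1, 0, 1]
        y = [0, 0, 1, 0, 1, 0]
        expected = -(3 / 5) * math.log2(3 / 5) - (2 / 5) * math.log2(2 / 5)
        assert time_delayed_mi(x, y, 1) == pytest.approx(expected, abs=1e-12)
        assert round(expected, 4) == 0.9710

    def test_empirical_independence_gives_zero(self):
        x = [0, 0, 1, 1, 9]
        y = [9, 0, 1, 0, 1]  # lag-1 pairs (0,0),(0,1),(1,0),(1,1)
        assert time_delayed_mi(x, y, 1, MiConfig(n_bins=2)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_samples_raises(self):
        with pytest.raises(ValidationError):
            time_delayed_mi([0, 1], [1, 0], 5)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        """Plug-in MI equals an explicit contingency-table computation."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            b = int(rng.integers(2, 6))
            s = int(rng.integers(1, 4))
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, 4))
            x = rng.integers(0, b, size=(s, n))
            y = rng.integers(0, b, size=(s, n))
            ours = time_delayed_mi(x, y, k, MiConfig(max_lag=3, n_bins=b))
            ref = bruteforce_time_delayed_mi(x, y, k, b)
            worst = max(worst, abs(ours - ref))
            assert 0.0 <= ours <= math.log2(b) + 1e-12
        assert worst < 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_invariant_under_symbol_relabeling(self, data):
        b = data.draw(st.integers(2, 4))
        n = data.draw(st.integers(5, 25))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        x = rng.integers(0, b, size=(1, n))
        y = rng.integers(0, b, size=(1, n))
        perm = rng.permutation(b)
        cfg = MiConfig(n_bins=b)
        assert time_delayed_mi(perm[x], y, 1, cfg) == pytest.approx(
            time_delayed_mi(x, y, 1, cfg), abs=1e-12
        )

    def test_nats_scale_by_log2(self):
        x = [0, 1, 0, 1, 0, 1]
        y = [0, 0, 1, 0, 1, 0]
        bits = time_delayed_mi(x, y, 1, MiConfig(log_base=2.0))
        nats = time_delayed_mi(x, y, 1, MiConfig(log_base=math.e))
        assert nats == pytest.approx(bits * math.log(2), abs=1e-12)


class TestComputeInfluence:
    def _profiles(self, seed=5, s=2, n=12):
        rng = np.random.default_rng(seed)
        return {g: rng.lognormal(0, 1, size=(s, n)) for g in ("a", "b")}

    def test_influence_is_max_over_lags(self):
        rec = InfluenceRecord("a", "b", {1: 0.2, 2: 0.5, 3: 0.3}, 0.5, 2)
        assert rec.influence == 0.5 and rec.best_lag == 2

    def test_record_rejects_wrong_maximum(self):
        with pytest.raises(ValidationError):
            InfluenceRecord("a", "b", {1: 0.2, 2: 0.5}, 0.2, 1)

    def test_case1_evaluates_single_ordering(self):
        case = PairCase(CaseTag.CASE1, (("a", "b"),))
        rec = compute_influence(case, self._profiles(), MiConfig())
        assert (rec.source, rec.target) == ("a", "b")
        assert len(rec.mi_by_lag) == 3
        assert rec.influence == pytest.approx(max(rec.mi_by_lag.values()))

    def test_case3_keeps_larger_influence(self):
        profiles = self._profiles(seed=11)
        case = PairCase(CaseTag.CASE3, (("a", "b"), ("b", "a")))
        winner = compute_influence(case, profiles, MiConfig())
        fwd = compute_influence(PairCase(CaseTag.CASE1, (("a", "b"),)), profiles, MiConfig())
        rev = compute_influence(PairCase(CaseTag.CASE1, (("b", "a"),)), profiles, MiConfig())
        assert winner.influence == max(fwd.influence, rev.influence)
        expect = fwd if fwd.influence >= rev.influence else rev
        assert (winner.source, winner.target) == (expect.source, expect.target)

    def test_case3_exact_tie_resolves_to_first_ordering(self):
        # symmetric profiles make both orderings exactly equal
        prof = np.array([[1.0, 2.0, 1.0, 2.0, 1.0, 2.0]])
        profiles = {"a": prof, "b": prof.copy()}
        case = PairCase(CaseTag.CASE3, (("a", "b"), ("b", "a")))
        rec = compute_influence(case, profiles, MiConfig())
        assert (rec.source, rec.target) == ("a", "b")

    def test_lag_count_capped_by_series_length(self):
        rng = np.random.default_rng(3)
        profiles = {g: rng.lognormal(0, 1, size=(1, 3)) for g in ("a", "b")}
        rec = compute_influence(
            PairCase(CaseTag.CASE1, (("a", "b"),)), profiles, MiConfig(max_lag=5)
        )
        assert set(rec.mi_by_lag) == {1, 2}

    def test_best_lag_ties_take_smallest(self):
        prof_x = np.array([[1.0, 1.0, 1.0, 1.0]])  # constant -> all lags MI 0
        prof_y = np.array([[1.0, 2.0, 1.0, 2.0]])
        rec = compute_influence(
            PairCase(CaseTag.CASE1, (("a", "b"),)),
            {"a": prof_x, "b": prof_y},
            MiConfig(max_lag=3),
        )
        assert rec.influence == 0.0 and rec.best_lag == 1

    def test_increasing_h_never_decreases_influence(self):
        profiles = self._profiles(seed=21, n=15)
        case = PairCase(CaseTag.CASE1, (("a", "b"),))
        values = [
            compute_influence(case, profiles, MiConfig(max_lag=h)).influence
            for h in (1, 2, 3, 5, 8)
        ]
        assert values == sorted(values)


def test_config_validation():
    with pytest.raises(ValidationError):
        MiConfig(max_lag=0)
    with pytest.raises(ValidationError):
        MiConfig(n_bins=1)
    with pytest.raises(ValidationError):
        MiConfig(binning="fancy")
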