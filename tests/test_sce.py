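"""Step 1: change classification, ScE, and pair case routing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdgrn.exceptions import ValidationError
from tdgrn.sce import (
    UNDEFINED,
    CaseTag,
    Change,
    SceConfig,
    SceResult,
    classify_pair,
    classify_ratio,
    compute_sce,
    compute_sce_for_gene,
)


class TestClassifyRatio:
    @pytest.mark.parametrize(
        "g_t, g_1, tau, expected",
        [
            (1.3, 1.0, 1.2, Change.INDUCED),
            (1.2, 1.0, 1.2, Change.NEUTRAL),  # boundary ratio = tau stays neutral
            (0.8, 1.0, 1.2, Change.REPRESSED),  # 0.8 < 1/1.2
            (1 / 1.2, 1.0, 1.2, Change.NEUTRAL),  # lower boundary inclusive
            (5.0, 0.0, 1.2, Change.INDUCED),  # zero baseline, positive value
            (0.0, 0.0, 1.2, Change.NEUTRAL),
            (-1.0, 0.0, 1.2, Change.REPRESSED),
        ],
    )
    def test_band_examples(self, g_t, g_1, tau, expected):
        assert classify_ratio(g_t, g_1, tau) is expected

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            classify_ratio(float("nan"), 1.0, 1.2)

    @settings(derandomize=True, max_examples=200)
    @given(
        ratio=st.floats(min_value=1e-6, max_value=1e6),
        tau=st.floats(min_value=1.01, max_value=10.0),
    )
    def test_partitions_positive_ratios(self, ratio, tau):
        """Exactly one of the three labels applies to any positive ratio."""
        label = classify_ratio(ratio, 1.0, tau)
        if ratio > tau:
            assert label is Change.INDUCED
        elif ratio < 1 / tau:
            assert label is Change.REPRESSED
        else:
            assert label is Change.NEUTRAL

    @settings(derandomize=True, max_examples=200)
    @given(
        ratio=st.floats(min_value=1e-3, max_value=1e3),
        tau1=st.floats(min_value=1.01, max_value=5.0),
        bump=st.floats(min_value=0.01, max_value=5.0),
    )
    def test_raising_tau_never_shrinks_neutral_band(self, ratio, tau1, bump):
        if classify_ratio(ratio, 1.0, tau1) is Change.NEUTRAL:
            assert classify_ratio(ratio, 1.0, tau1 + bump) is Change.NEUTRAL


class TestComputeSce:
    def test_induced_and_repressed_points(self):
        res = compute_sce([1.0, 1.1, 1.3, 0.8], SceConfig(1.2))
        assert res.induced_timepoints == {3}
        assert res.repressed_timepoints == {4}
        assert res.sce == 3

    def test_all_neutral_is_undefined(self):
        res = compute_sce([1.0, 1.1, 1.0, 1.15], SceConfig(1.2))
        assert res.induced_timepoints == set() == res.repressed_timepoints
        assert res.sce is UNDEFINED

    def test_earliest_change_wins(self):
        res = compute_sce([2.0, 1.0, 3.0], SceConfig(1.2))
        assert res.repressed_timepoints == {2}
        assert res.induced_timepoints == {3}
        assert res.sce == 2

    def test_constant_profile_undefined(self):
        assert compute_sce([5.0] * 8).sce is UNDEFINED

    def test_multi_series_uses_per_series_baseline(self):
        # series 2 changes at t=2 against its own baseline of 10
        prof = np.array([[1.0, 1.1, 1.0, 1.05], [10.0, 20.0, 10.0, 10.0]])
        res = compute_sce(prof)
        assert res.induced == frozenset({(2, 2)})
        assert res.sce == 2

    def test_negative_values_are_shifted_not_sign_flipped(self):
        res = compute_sce([-1.0, -1.0, 5.0])
        assert res.sce == 3
        assert res.induced_timepoints == {3}

    def test_members_within_bounds(self):
        rng = np.random.default_rng(0)
        res = compute_sce(rng.lognormal(0, 1, size=(3, 7)))
        pts = res.induced_timepoints | res.repressed_timepoints
        assert all(2 <= t <= 7 for t in pts)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            compute_sce([1.0])


class TestClassifyPair:
    def _res(self, gene, sce):
        if sce is UNDEFINED:
            return SceResult(gene, frozenset(), frozenset(), UNDEFINED)
        return SceResult(gene, frozenset({(1, sce)}), frozenset(), sce)

    def test_case1_earlier_first_gene(self):
        case = classify_pair(self._res("a", 2), self._res("b", 5))
        assert case.case_tag is CaseTag.CASE1
        assert case.ordered_pairs == (("a", "b"),)

    def test_case2_earlier_second_gene(self):
        case = classify_pair(self._res("a", 5), self._res("b", 2))
        assert case.case_tag is CaseTag.CASE2
        assert case.ordered_pairs == (("b", "a"),)

    def test_case3_carries_both_orderings(self):
        case = classify_pair(self._res("a", 3), self._res("b", 3))
        assert case.case_tag is CaseTag.CASE3
        assert case.ordered_pairs == (("a", "b"), ("b", "a"))

    def test_undefined_orders_as_infinity(self):
        case = classify_pair(self._res("a", 4), self._res("b", UNDEFINED))
        assert case.case_tag is CaseTag.CASE1
        assert case.ordered_pairs == (("a", "b"),)

    def test_two_undefined_fall_into_case3(self):
        case = classify_pair(self._res("a", UNDEFINED), self._res("b", UNDEFINED))
        assert case.case_tag is CaseTag.CASE3

    def test_routing_matches_bruteforce_enumeration(self):
        """Exhaustive check of the case table over small ScE combinations."""
        values = [2, 3, 4, UNDEFINED]
        for sa in values:
            for sb in values:
                case = classify_pair(self._res("a", sa), self._res("b", sb))
                ka = float("inf") if sa is UNDEFINED else sa
                kb = float("inf") if sb is UNDEFINED else sb
                if ka < kb:
                    assert case.case_tag is CaseTag.CASE1
                elif kb < ka:
                    assert case.case_tag is CaseTag.CASE2
                else:
                    assert case.case_tag is CaseTag.CASE3


def test_sce_result_rejects_overlapping_sets():
    with pytest.raises(ValidationError):
        SceResult("g", frozenset({(1, 2)}), frozenset({(1, 2)}), 2)


def test_config_requires_tau_above_one():
    with pytest.raises(ValidationError):
        SceConfig(1.0)


def test_compute_sce_for_gene_carries_identifier():
    assert compute_sce_for_gene("G7", [1.0, 2.0]).gene == "G7"
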