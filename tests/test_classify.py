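"""Response-pattern classification rules and replicate reconciliation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dosetrace import (ClassifyParams, InputError, PairingError,
                       ResponseCategory, classify_curve, fit_curve,
                       reconcile_replicates, upward_interval_metric)
from dosetrace.smoothing import FittedCurve, average_slope, run_statistics
from _oracles import oracle_classify

DEFAULTS = ClassifyParams()  # T, C, B, E = 0.3, 5, 3, 0.45


def curve_from_fitted(y_hat, x=None):
    """Build a FittedCurve directly from fitted values (bandwidth moot)."""
    y_hat = np.asarray(y_hat, dtype=float)
    x = np.asarray(x if x is not None else range(1, len(y_hat) + 1))
    up, down = run_statistics(y_hat)
    return FittedCurve(
        x=tuple(int(v) for v in x), y=tuple(y_hat), y_hat=tuple(y_hat),
        bandwidth=1.0, average_slope=average_slope(y_hat, x),
        range_fitted=float(y_hat.max() - y_hat.min()), max_up_run=up,
        max_down_run=down, end_diff=float(abs(y_hat[-1] - y_hat[0])))


FIXTURES = [
    # small range: 0.2 <= T = 0.3
    ([1.0, 1.1, 1.05, 1.15, 1.1, 1.2, 1.15, 1.1, 1.05], ResponseCategory.NR),
    # monotone rise: range 0.42, up-run 8, positive slope
    ([1.00, 1.05, 1.12, 1.20, 1.28, 1.33, 1.37, 1.40, 1.42], ResponseCategory.HYPER),
    # the mirror-image fall: down-run 8 >= C = 5, negative slope
    ([1.42, 1.40, 1.37, 1.33, 1.28, 1.20, 1.12, 1.05, 1.00], ResponseCategory.HYPO),
    # rise then symmetric return: up 3, down 5, ends equal
    ([1.00, 1.20, 1.40, 1.50, 1.45, 1.30, 1.15, 1.05, 1.00], ResponseCategory.BIPHASIC),
]


class TestClassifyCurve:
    @pytest.mark.parametrize("y_hat, expected", FIXTURES)
    def test_rule_table_fixtures(self, y_hat, expected):
        assert classify_curve(curve_from_fitted(y_hat), DEFAULTS) is expected

    @pytest.mark.parametrize("y_hat, expected", FIXTURES)
    def test_fixtures_agree_with_independent_rule_checker(self, y_hat, expected):
        label = oracle_classify(y_hat, list(range(1, 10)), T=0.3, C=5, B=3, E=0.45)
        assert label == expected.value

    @given(hnp.arrays(float, 9, elements=st.floats(min_value=0.0, max_value=3.0,
                                                   allow_nan=False)))
    def test_random_curves_agree_with_rule_checker(self, y_hat):
        got = classify_curve(curve_from_fitted(y_hat), DEFAULTS)
        want = oracle_classify(list(y_hat), list(range(1, 10)), T=0.3, C=5, B=3, E=0.45)
        assert got.value == want

    @given(hnp.arrays(float, 9, elements=st.floats(min_value=0.0, max_value=3.0,
                                                   allow_nan=False)))
    def test_raising_t_never_leaves_nr(self, y_hat):
        curve = curve_from_fitted(y_hat)
        low = classify_curve(curve, DEFAULTS)
        high = classify_curve(curve, dataclasses.replace(DEFAULTS, range_t=0.6))
        if low is ResponseCategory.NR:
            assert high is ResponseCategory.NR

    @given(hnp.arrays(int, 9, elements=st.integers(0, 384)))
    def test_mirror_swaps_hyper_and_hypo_when_b_equals_c(self, steps):
        # dyadic-rational curves keep the reflection exact in floating point
        y_hat = steps / 128.0
        params = dataclasses.replace(DEFAULTS, down_run_c=3)  # B == C == 3
        mirrored = 2.0 * y_hat[0] - y_hat
        got = classify_curve(curve_from_fitted(y_hat), params)
        swap = classify_curve(curve_from_fitted(mirrored), params)
        expected = {ResponseCategory.HYPER: ResponseCategory.HYPO,
                    ResponseCategory.HYPO: ResponseCategory.HYPER}.get(got, got)
        assert swap is expected

    def test_methods_end_rule_variant(self):
        # ends differ by 0.12: within E*range (0.225) but beyond E*T (0.135)?
        y_hat = [1.00, 1.20, 1.40, 1.50, 1.45, 1.30, 1.20, 1.15, 1.14]
        curve = curve_from_fitted(y_hat)
        assert classify_curve(curve, DEFAULTS) is ResponseCategory.BIPHASIC
        strict = dataclasses.replace(DEFAULTS, end_rule="threshold", end_factor_e=0.2)
        assert classify_curve(curve, strict) is not ResponseCategory.BIPHASIC

    def test_biphasic_down_run_variant_uses_c(self):
        # down arm of length 4: passes with B (3), fails with C (5)
        y_hat = [1.00, 1.20, 1.40, 1.55, 1.50, 1.30, 1.15, 1.02, 1.02]
        curve = curve_from_fitted(y_hat)
        assert classify_curve(curve, DEFAULTS) is ResponseCategory.BIPHASIC
        variant = dataclasses.replace(DEFAULTS, biphasic_down_run="C")
        assert classify_curve(curve, variant) is not ResponseCategory.BIPHASIC


class TestReconcileReplicates:
    def fitted(self, y):
        return fit_curve(range(1, len(y) + 1), y, 1.0)

    def test_concordant_hyper_takes_mean_slope(self):
        a = curve_from_fitted([1.00, 1.05, 1.12, 1.20, 1.28, 1.33, 1.37, 1.40, 1.42])
        b = dataclasses.replace(a, average_slope=a.average_slope + 0.1)
        call = reconcile_replicates("site", (a, b), DEFAULTS)
        assert call.final_category is ResponseCategory.HYPER
        assert call.mean_average_slope == pytest.approx(a.average_slope + 0.05)

    def test_discordant_categories_yield_nr(self):
        hyper = curve_from_fitted([1.00, 1.05, 1.12, 1.20, 1.28, 1.33, 1.37, 1.40, 1.42])
        hypo = curve_from_fitted([1.42, 1.40, 1.37, 1.33, 1.28, 1.20, 1.12, 1.05, 1.00])
        call = reconcile_replicates("site", (hyper, hypo), DEFAULTS)
        assert call.rep_categories == (ResponseCategory.HYPER, ResponseCategory.HYPO)
        assert call.final_category is ResponseCategory.NR

    def test_responsive_with_nr_partner_yields_nr(self):
        biph = curve_from_fitted([1.00, 1.20, 1.40, 1.50, 1.45, 1.30, 1.15, 1.05, 1.00])
        flat = curve_from_fitted([1.0] * 9)
        call = reconcile_replicates("site", (biph, flat), DEFAULTS)
        assert call.final_category is ResponseCategory.NR

    def test_more_than_two_replicates_rejected(self):
        c = curve_from_fitted([1.0] * 9)
        with pytest.raises(InputError):
            reconcile_replicates("site", (c, c, c), DEFAULTS)

    @given(st.lists(hnp.arrays(float, 9, elements=st.floats(0.0, 3.0)),
                    min_size=2, max_size=2))
    def test_non_nr_final_call_implies_concordance(self, pair):
        call = reconcile_replicates("s", tuple(curve_from_fitted(y) for y in pair),
                                    DEFAULTS)
        if call.final_category is not ResponseCategory.NR:
            assert call.rep_categories[0] is call.rep_categories[1]
            assert call.rep_categories[0] is call.final_category


class TestUpwardIntervalMetric:
    def test_both_replicates_strictly_increasing(self):
        a = curve_from_fitted(np.linspace(1.0, 2.0, 9))
        b = curve_from_fitted(np.linspace(1.0, 1.8, 9))
        assert upward_interval_metric((a, b)) == 8

    def test_constant_mean_curve(self):
        up = curve_from_fitted([1.0, 1.2, 1.4, 1.2, 1.0, 1.0, 1.0, 1.0, 1.0])
        down = curve_from_fitted([1.0, 0.8, 0.6, 0.8, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert upward_interval_metric((up, down)) == 0

    def test_mean_curve_run_differs_from_either_replicate(self):
        # up 3 then flat vs up 4 then flat: the mean rises for 4 intervals
        a = curve_from_fitted([1.0, 1.1, 1.2, 1.3, 1.3, 1.3, 1.3, 1.3, 1.3])
        b = curve_from_fitted([1.0, 1.1, 1.2, 1.3, 1.4, 1.4, 1.4, 1.4, 1.4])
        assert upward_interval_metric((a, b)) == 4

    def test_mismatched_grids_rejected(self):
        a = curve_from_fitted([1.0] * 9)
        b = curve_from_fitted([1.0] * 8, x=range(1, 9))
        with pytest.raises(PairingError):
            upward_interval_metric((a, b))
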