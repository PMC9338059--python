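"""Impact records, phospho-response table, heterogeneity and enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosetrace import (EntityCurve, InputError, ResponseCategory,
                       category_proportions, heterogeneity_summary,
                       hypergeom_enrichment, phospho_response, proteome_impact)
from dosetrace.classify import SiteCall
from dosetrace.smoothing import FittedCurve
from _oracles import enum_hypergeom_sf


def slope_curve(slope):
    """A minimal FittedCurve carrying only the slope (other stats moot here)."""
    return FittedCurve(x=(1, 2, 3), y=(1.0, 1.0, 1.0), y_hat=(1.0, 1.0, 1.0),
                       bandwidth=1.0, average_slope=slope, range_fitted=0.0,
                       max_up_run=0, max_down_run=0, end_diff=0.0)


def entity_curves(protein, s37=None, s52=None, gene=""):
    out = []
    for temp, slope in ((37, s37), (52, s52)):
        if slope is not None:
            out.append(EntityCurve(entity_id=protein, gene=gene, temperature=temp,
                                   replicate_id=1, curve=slope_curve(slope)))
    return out


def make_call(site, protein, category, slope=0.1, upward=3):
    cat = ResponseCategory(category)
    return SiteCall(entity_id=site, protein_id=protein, gene="",
                    rep_curves=(slope_curve(slope), slope_curve(slope)),
                    rep_categories=(cat, cat), final_category=cat,
                    mean_average_slope=slope, upward_intervals=upward)


class TestProteomeImpact:
    @pytest.mark.parametrize("s37, s52, expected", [
        (0.6, 0.1, True),    # either axis beyond the threshold
        (0.2, 0.3, False),
        (-0.7, 0.0, True),   # magnitude reading
    ])
    def test_hit_rule(self, s37, s52, expected):
        [rec] = proteome_impact(entity_curves("P1", s37, s52), hit_threshold=0.5)
        assert rec.is_hit is expected
        assert rec.slope_37 == s37 and rec.slope_52 == s52

    def test_one_sided_option_ignores_negative_slopes(self):
        [rec] = proteome_impact(entity_curves("P1", -0.7, 0.0),
                                hit_threshold=0.5, two_sided=False)
        assert rec.is_hit is False

    def test_missing_temperature_flagged_absent_and_hit_on_present_axis(self):
        [rec] = proteome_impact(entity_curves("P1", s37=0.9), hit_threshold=0.5)
        assert math.isnan(rec.slope_52) and rec.is_hit is True

    def test_slope_is_replicate_mean(self):
        curves = [EntityCurve("P1", "", 37, rep, slope_curve(s))
                  for rep, s in ((1, 0.2), (2, 0.4))]
        [rec] = proteome_impact(curves)
        assert rec.slope_37 == pytest.approx(0.3)

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(0)
        curves = []
        for i in range(50):
            curves += entity_curves(f"P{i}", rng.normal(0, 0.5), rng.normal(0, 0.5))
        for lo, hi in [(0.2, 0.5), (0.5, 0.8)]:
            hits_lo = {r.protein_id for r in proteome_impact(curves, lo) if r.is_hit}
            hits_hi = {r.protein_id for r in proteome_impact(curves, hi) if r.is_hit}
            assert hits_hi <= hits_lo


class TestPhosphoResponse:
    def test_all_nr_gives_full_nr_proportion(self):
        calls = [make_call(f"s{i}", f"p{i}", "NR") for i in range(10)]
        props = category_proportions(phospho_response(calls))
        assert props == {"NR": 1.0}

    def test_one_site_per_category_gives_quarters(self):
        calls = [make_call(f"s{i}", f"p{i}", c)
                 for i, c in enumerate(["hyper", "hypo", "biphasic", "NR"])]
        props = category_proportions(phospho_response(calls))
        assert props == {c: 0.25 for c in ("hyper", "hypo", "biphasic", "NR")}

    def test_proportions_sum_to_one_exactly(self):
        rng = np.random.default_rng(1)
        cats = rng.choice(["hyper", "hypo", "biphasic", "NR"], size=101)
        calls = [make_call(f"s{i}", f"p{i}", c) for i, c in enumerate(cats)]
        props = category_proportions(phospho_response(calls))
        assert sum(props.values()) == 1.0


class TestHeterogeneity:
    def test_bucketing_by_category_sets(self):
        calls = [
            make_call("a1", "A", "biphasic"), make_call("a2", "A", "hypo"),
            make_call("b1", "B", "hyper"), make_call("b2", "B", "hypo"),
            make_call("c1", "C", "biphasic"), make_call("c2", "C", "hyper"),
            make_call("c3", "C", "hypo"),
            make_call("d1", "D", "NR"),
        ]
        summary = heterogeneity_summary(calls)
        B, H, O = (ResponseCategory.BIPHASIC, ResponseCategory.HYPER,
                   ResponseCategory.HYPO)
        assert summary.combination_counts == {
            frozenset({B, O}): 1, frozenset({H, O}): 1, frozenset({B, H, O}): 1}
        assert "D" not in summary.per_protein

    def test_single_category_protein_is_homogeneous(self):
        summary = heterogeneity_summary([make_call("a1", "A", "hypo")])
        assert summary.per_protein["A"] == frozenset({ResponseCategory.HYPO})

    def test_counts_sum_to_proteins_with_responsive_sites(self):
        calls = [make_call(f"s{i}", f"p{i % 7}", c) for i, c in
                 enumerate(["hyper", "hypo", "NR", "biphasic"] * 5)]
        summary = heterogeneity_summary(calls)
        assert sum(summary.combination_counts.values()) == len(summary.per_protein)


class TestHypergeomEnrichment:
    BACKGROUND = [f"g{i}" for i in range(10)]

    def test_worked_value_five_over_210(self):
        hits = self.BACKGROUND[:4]
        [res] = hypergeom_enrichment(hits, self.BACKGROUND,
                                     {"S": self.BACKGROUND[:5]})
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)
        assert (res.overlap_k, res.set_size_K, res.hits_n, res.background_N) == (4, 5, 4, 10)
        assert res.significant

    def test_empty_set_and_full_hit_list_give_p_one(self):
        [res] = hypergeom_enrichment(self.BACKGROUND[:3], self.BACKGROUND, {"S": []})
        assert res.p_value == 1.0
        [res] = hypergeom_enrichment(self.BACKGROUND, self.BACKGROUND,
                                     {"S": self.BACKGROUND[:5]})
        assert res.p_value == pytest.approx(1.0)

    def test_hit_outside_background_is_named(self):
        with pytest.raises(InputError, match="stray"):
            hypergeom_enrichment(["stray"], self.BACKGROUND, {"S": []})

    def test_set_members_intersected_with_background(self):
        [res] = hypergeom_enrichment(self.BACKGROUND[:4], self.BACKGROUND,
                                     {"S": self.BACKGROUND[:5] + ["alien"] * 3})
        assert res.set_size_K == 5

    def test_p_monotone_nonincreasing_in_overlap(self):
        from scipy.stats import hypergeom
        for N, K, n in [(10, 5, 4), (12, 6, 6), (8, 3, 5)]:
            ps = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(n, K) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @settings(max_examples=30)
    @given(st.integers(1, 12), st.data())
    def test_matches_exhaustive_enumeration(self, N, data):
        from scipy.stats import hypergeom
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        closed = float(hypergeom.sf(k - 1, N, K, n))
        assert closed == pytest.approx(enum_hypergeom_sf(N, K, n, k), abs=1e-12)
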