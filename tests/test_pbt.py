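"""Geometric PBT aggregation, compound ranks and the PBTr site statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotoxrank.data_model import MeasurementRecord
from ecotoxrank.pbt import (
    MecStatistic,
    PbtScores,
    RankClass,
    classify_pbtr,
    compound_rank,
    pbt_score,
    pbtr,
    site_pbtr,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
positive_unit = st.floats(min_value=1e-6, max_value=1.0, allow_nan=False)


class TestPbtScore:
    @pytest.mark.parametrize(
        "p,b,t,expected",
        [
            (1.0, 1.0, 1.0, 1.0),
            (0.0, 0.9, 0.9, 0.0),          # zero factor annihilates
            (0.8, 0.6, 0.4, 0.620738),     # frozen from independent evaluation
            (0.5, 0.5, 0.5, 0.5),          # exponents sum to 1
        ],
    )
    def test_examples(self, p, b, t, expected):
        assert pbt_score(p, b, t) == pytest.approx(expected, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pbt_score(1.2, 0.5, 0.5)
        with pytest.raises(ValueError, match="missing"):
            pbt_score(None, 0.5, 0.5)

    @given(unit, unit, unit, unit)
    @settings(max_examples=100)
    def test_monotone_in_each_argument(self, p, b, t, bump):
        base = pbt_score(p, b, t)
        assert pbt_score(min(p + bump, 1.0), b, t) >= base
        assert pbt_score(p, min(b + bump, 1.0), t) >= base
        assert pbt_score(p, b, min(t + bump, 1.0)) >= base

    @given(unit, unit, unit)
    @settings(max_examples=100)
    def test_stays_in_unit_interval(self, p, b, t):
        assert 0.0 <= pbt_score(p, b, t) <= 1.0


class TestCompoundRank:
    @pytest.mark.parametrize(
        "score,conc,expected",
        [(0.5, 100.0, 50.0), (0.0, 1e6, 0.0), (0.620738, 250.0, 155.18)],
    )
    def test_examples(self, score, conc, expected):
        assert compound_rank(score, conc) == pytest.approx(expected, abs=0.1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            compound_rank(0.5, -1.0)


class TestPbtr:
    def test_unit_weights_give_mean(self):
        assert pbtr([2.0, 4.0]) == pytest.approx(3.0)
        assert pbtr([7.5]) == pytest.approx(7.5)

    def test_weight_rescaling_invariance(self):
        assert pbtr([2.0, 4.0], [10.0, 10.0]) == pytest.approx(3.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            pbtr([])
        with pytest.raises(ValueError):
            pbtr([1.0], [0.0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                 min_size=1, max_size=50),
        st.data(),
    )
    @settings(max_examples=200)
    def test_matches_brute_force_oracle(self, ranks, data):
        weights = data.draw(
            st.lists(st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
                     min_size=len(ranks), max_size=len(ranks))
        )
        num = 0.0
        den = 0.0
        for r, w in zip(ranks, weights):
            num += r * w
            den += w
        expected = num / den
        assert pbtr(ranks, weights) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False),
                    min_size=1, max_size=20),
           st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(max_examples=100)
    def test_common_weight_cancels(self, ranks, c):
        assert pbtr(ranks, [c] * len(ranks)) == pytest.approx(
            pbtr(ranks), rel=1e-9, abs=1e-12
        )


class TestClassification:
    def test_zero_is_none(self):
        assert classify_pbtr({"A": 0.0})["A"] is RankClass.none

    def test_terciles_on_three_sites(self):
        classes = classify_pbtr({"A": 10.0, "B": 100.0, "C": 1000.0})
        assert classes == {"A": RankClass.low, "B": RankClass.medium,
                           "C": RankClass.high}

    def test_single_nonzero_site_collapses_to_high(self):
        assert classify_pbtr({"A": 5.0})["A"] is RankClass.high

    def test_explicit_cutoffs(self):
        classes = classify_pbtr({"A": 1.0, "B": 20.0, "C": 90.0},
                                cutoffs=(10.0, 50.0))
        assert [classes[k].value for k in "ABC"] == ["low", "medium", "high"]

    def test_nonmonotone_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            classify_pbtr({"A": 1.0}, cutoffs=(5.0, 5.0))


def _measurement(site, cas, conc, detected=True):
    return MeasurementRecord(
        site=site, campaign="C1", substance=cas,
        concentration=conc if detected else None,
        lod=0.5, lab="lab_A", detected=detected,
    )


def _scores(cas, p=0.8, b=0.6, t=0.4):
    return PbtScores(substance=cas, p_score=p, b_score=b, t_score=t,
                     pbt=pbt_score(p, b, t))


class TestSitePbtr:
    def test_undetected_substances_excluded(self):
        records = [
            _measurement("S1", "50-00-0", 100.0),
            _measurement("S1", "64-17-5", None, detected=False),
        ]
        scores = {c: _scores(c) for c in ("50-00-0", "64-17-5")}
        (result,) = site_pbtr(records, scores)
        assert set(result.compound_ranks) == {"50-00-0"}
        assert result.n == 1

    def test_missing_scores_excluded_not_imputed(self):
        records = [_measurement("S1", "50-00-0", 100.0),
                   _measurement("S1", "64-17-5", 40.0)]
        scores = {"50-00-0": _scores("50-00-0")}
        (result,) = site_pbtr(records, scores)
        assert set(result.compound_ranks) == {"50-00-0"}

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_equivariance(self, measurements, c, catalog):
        subset = measurements[:500]
        substances, _ = catalog
        scores = {s.cas: _scores(s.cas) for s in substances}
        base = site_pbtr(subset, scores)
        scaled_records = [
            m.model_copy(
                update={"concentration": m.concentration * c if m.detected else None,
                        "lod": m.lod * c}
            )
            for m in subset
        ]
        scaled = site_pbtr(scaled_records, scores)
        for r0, r1 in zip(base, scaled):
            assert r1.pbtr == pytest.approx(c * r0.pbtr, rel=1e-9)

    def test_max_statistic_dominates_median(self, measurements, catalog):
        substances, _ = catalog
        scores = {s.cas: _scores(s.cas) for s in substances}
        med = {r.site: r.pbtr for r in site_pbtr(measurements, scores)}
        mx = {
            r.site: r.pbtr
            for r in site_pbtr(measurements, scores, statistic=MecStatistic.max)
        }
        for site in med:
            assert mx[site] >= med[site]
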