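import math

import pytest
from hypothesis import given, strategies as st

from ohra import (
    BandingConfig, band_exposure_ratio, geometric_mean_index,
    gbz_exposure_index_method, gbz_exposure_ratio_method, gbz_synthesis_index_method,
    mom_exposure_index_method, mom_exposure_ratio_method, risk_rating,
    round_half_away, weekly_exposure,
)
from ohra.core_types import MethodId
from ohra.hazard_rating import HazardRating, RatingBasis
from ohra.model_semiquant import IndexFactorSet
from conftest import make_record


def hr(v):
    return HazardRating(value=v, basis=RatingBasis.acute_toxicity)


class TestWeeklyExposure:
    def test_formula(self):
        assert weekly_exposure(f=6, d=8, m=10) == pytest.approx(12.0)

    def test_reference_week_identity(self):
        assert weekly_exposure(f=5, d=8, m=1) == pytest.approx(1.0)

    def test_zero_magnitude(self):
        assert weekly_exposure(f=6, d=8, m=0) == 0.0

    def test_zero_week_rejected(self):
        with pytest.raises(ValueError):
            weekly_exposure(f=6, d=8, m=1, w=0)


class TestExposureRatioBanding:
    @pytest.mark.parametrize("ratio,er", [(0.0, 1), (0.22, 2), (0.5, 3), (1.853, 4), (2.5, 5)])
    def test_default_bands(self, cfg, ratio, er):
        assert band_exposure_ratio(ratio, cfg.semiquant.mom) == er


class TestGeometricMean:
    def test_idempotent_on_constant(self):
        assert geometric_mean_index(IndexFactorSet(factors={"a": 3, "b": 3, "c": 3, "d": 3})) == pytest.approx(3.0)

    def test_fourth_root_of_product(self):
        fs = IndexFactorSet(factors={"a": 1, "b": 2, "c": 4, "d": 4})
        assert geometric_mean_index(fs) == pytest.approx(32 ** 0.25, abs=1e-3)

    def test_single_factor(self):
        assert geometric_mean_index(IndexFactorSet(factors={"a": 4})) == pytest.approx(4.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            IndexFactorSet(factors={})

    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=8))
    def test_bounded_by_min_and_max(self, vals):
        fs = IndexFactorSet(factors={f"f{i}": v for i, v in enumerate(vals)})
        g = geometric_mean_index(fs)
        assert min(vals) - 1e-9 <= g <= max(vals) + 1e-9

    def test_neutral_extras_leave_mean_unchanged(self):
        """Adding factors equal to the existing geometric mean is a no-op."""
        base = IndexFactorSet(factors={"a": 2, "b": 2})
        extended = IndexFactorSet(factors={"a": 2, "b": 2, "c": 2, "d": 2})
        assert geometric_mean_index(base) == pytest.approx(geometric_mean_index(extended))


class TestRiskRating:
    def test_perfect_square(self):
        r = risk_rating(hr(2), 2, method=MethodId.mom_er, group_id="g")
        assert (r.raw, r.level, r.label) == (pytest.approx(2.0), 2, "low")

    def test_sqrt_of_ten_rounds_to_medium(self):
        r = risk_rating(hr(2), 5, method=MethodId.mom_er, group_id="g")
        assert r.raw == pytest.approx(math.sqrt(10), abs=1e-3) and r.level == 3

    def test_ceiling_of_scale(self):
        assert risk_rating(hr(5), 5, method=MethodId.mom_er, group_id="g").level == 5

    def test_round_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(2.4999) == 2
        assert round_half_away(0.5) == 1

    def test_hazard_rating_2_caps_at_level_3(self):
        """A hazard-rating-2 substance cannot exceed medium risk: sqrt(2*5)~3.16."""
        for er in (1, 2, 3, 4, 5):
            assert risk_rating(hr(2), er, method=MethodId.mom_er, group_id="g").level <= 3

    @given(st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=5),
           st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=5))
    def test_monotone_in_hr_and_er(self, h1, h2, e1, e2):
        hlo, hhi = sorted([h1, h2])
        elo, ehi = sorted([e1, e2])
        lo = risk_rating(hr(hlo), elo, method=MethodId.mom_er, group_id="g").level
        hi = risk_rating(hr(hhi), ehi, method=MethodId.mom_er, group_id="g").level
        assert lo <= hi


class TestMethods:
    def test_ratio_method_low_exposure_floor(self, cfg, hexane):
        # pasting-like: tiny TWA -> E/OEL ~ 0 -> ER 1 -> round(sqrt(2)) = 1
        res = mom_exposure_ratio_method(make_record(c_twa=0.10), hexane, cfg)
        assert res.er == 1 and res.level == 1

    def test_ratio_method_zero_twa(self, cfg, hexane):
        res = mom_exposure_ratio_method(make_record(c_twa=0.0), hexane, cfg)
        assert res.er == 1 and res.level == round_half_away(math.sqrt(2))

    def test_ratio_method_needs_measurement(self, cfg, hexane):
        with pytest.raises(ValueError, match="index method"):
            mom_exposure_ratio_method(make_record(c_twa=None), hexane, cfg)

    def test_index_method_composition(self, cfg, hexane):
        """Factor set (2,4,4,2) -> geometric mean 2.828 -> sqrt(2*2.828) -> level 2."""
        er = geometric_mean_index(IndexFactorSet(factors={"a": 2, "b": 4, "c": 4, "d": 2}))
        assert er == pytest.approx(2.828, abs=1e-3)
        r = risk_rating(hr(2), er, method=MethodId.mom_ei, group_id="g")
        assert r.raw == pytest.approx(2.378, abs=1e-2) and r.level == 2

    def test_index_method_all_minimal(self, cfg, hexane):
        er = geometric_mean_index(IndexFactorSet(factors={"a": 1, "b": 1, "c": 1, "d": 1}))
        assert risk_rating(hr(2), er, method=MethodId.mom_ei, group_id="g").level == 1

    def test_index_method_all_maximal_caps_at_3_with_hr2(self):
        er = geometric_mean_index(IndexFactorSet(factors={"a": 5, "b": 5, "c": 5, "d": 5}))
        assert risk_rating(hr(2), er, method=MethodId.mom_ei, group_id="g").level == 3

    def test_mom_index_typical_printing_record_is_medium(self, cfg, hexane, record):
        assert mom_exposure_index_method(record, hexane, cfg).level == 3

    def test_gbz_ratio_agrees_with_mom_under_equal_config(self, cfg, hexane, record):
        a = mom_exposure_ratio_method(record, hexane, cfg)
        b = gbz_exposure_ratio_method(record, hexane, cfg)
        assert (a.er, a.raw, a.level) == (b.er, b.raw, b.level)

    def test_gbz_index_good_controls_lowers_level(self, cfg, hexane):
        good = make_record(automation="full", ventilation="local_exhaust", ppe_used=True,
                           emergency_complete=True, health_mgmt="good", daily_usage=0.1)
        poor = make_record(automation="manual", ventilation="general", ppe_equipped=False,
                           ppe_used=False, emergency_complete=False, health_mgmt="none")
        assert gbz_exposure_index_method(good, hexane, cfg).level < \
            gbz_exposure_index_method(poor, hexane, cfg).level

    def test_synthesis_index_is_index_set_plus_exposure_ratio(self, cfg, hexane, record):
        """EI vs SI differ only through the banded E/OEL sub-index."""
        ei = gbz_exposure_index_method(record, hexane, cfg)
        si = gbz_synthesis_index_method(record, hexane, cfg)
        extra = set(si.factors) - set(ei.factors)
        assert extra == {"e_over_oel"}
        assert all(si.factors[k] == ei.factors[k] for k in ei.factors)
        n = len(si.factors)
        expected_er = (ei.er ** (n - 1) * si.factors["e_over_oel"]) ** (1 / n)
        assert si.er == pytest.approx(expected_er)

    def test_synthesis_index_requires_measurement(self, cfg, hexane):
        with pytest.raises(ValueError):
            gbz_synthesis_index_method(make_record(c_twa=None), hexane, cfg)

    def test_all_methods_emit_valid_level_and_label(self, cfg, hexane, record):
        labels = {1: "potential", 2: "low", 3: "medium", 4: "high", 5: "very_high"}
        for fn in (mom_exposure_ratio_method, mom_exposure_index_method,
                   gbz_exposure_ratio_method, gbz_exposure_index_method,
                   gbz_synthesis_index_method):
            res = fn(record, hexane, cfg)
            assert res.level in labels and res.label == labels[res.level]
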