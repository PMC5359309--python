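"""VPD-limited transpiration: piecewise response, hourly integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgsim import vpd_transpiration as vt


def tv_oracle(v, m1, m2, bp):
    """Independent closed-form evaluation of the breakpoint response."""
    if v < bp:
        return max(m1 * (v - 0.25), 0.0)
    return max(m1 * (bp - 0.25) + m2 * (v - bp), 0.0)


class TestTv:
    @pytest.mark.parametrize("name", sorted(vt.TRAIT_PRESETS))
    def test_no_transpiration_at_quarter_kpa(self, name):
        assert vt.tv(0.25, vt.TRAIT_PRESETS[name]) == 0.0
        assert vt.tv(0.0, vt.TRAIT_PRESETS[name]) == 0.0

    @pytest.mark.parametrize("name", sorted(vt.TRAIT_PRESETS))
    def test_matches_closed_form_oracle_on_grid(self, name):
        p = vt.TRAIT_PRESETS[name]
        for v in np.linspace(0.0, 6.0, 601):
            expect = tv_oracle(float(v), p.m1, p.m2, p.vpd_bp)
            assert vt.tv(float(v), p) == pytest.approx(expect, abs=1e-12)

    def test_bql41_reference_points(self):
        p = vt.TRAIT_PRESETS["bql41"]
        assert vt.tv(1.17, p) == pytest.approx(20.26 * 0.92, abs=1e-9)
        assert vt.tv(2.00, p) == pytest.approx(
            20.26 * 0.92 + 7.27 * 0.83, abs=1e-9
        )

    def test_steep_negative_m2_clamps_to_zero(self):
        # theoretical m2 = -290 for a BTx623-like m1: the line crosses zero
        # near 2.40 kPa and stays clamped beyond
        p = vt.TraitParams(m1=56.3, m2=-290.0, vpd_bp=2.05)
        zero_crossing = 2.05 + 56.3 * (2.05 - 0.25) / 290.0
        assert vt.tv(zero_crossing - 0.01, p) > 0.0
        assert vt.tv(zero_crossing + 0.01, p) == 0.0
        assert vt.tv(3.0, p) == 0.0

    def test_continuous_at_breakpoint(self):
        for p in vt.TRAIT_PRESETS.values():
            lo = vt.tv(p.vpd_bp - 1e-9, p)
            hi = vt.tv(p.vpd_bp + 1e-9, p)
            assert abs(hi - lo) < 1e-6

    def test_no_breakpoint_is_single_line(self):
        p = vt.no_breakpoint(20.26)
        for v in (0.5, 1.0, 2.5, 5.0, 9.0, 15.0):
            assert vt.tv(v, p) == pytest.approx(
                max(20.26 * (v - 0.25), 0.0)
            )

    def test_m2_zero_plateaus_above_breakpoint(self):
        p = vt.TraitParams(m1=20.26, m2=0.0, vpd_bp=1.17)
        cap = 20.26 * (1.17 - 0.25)
        for v in (1.17, 2.0, 4.0, 8.0):
            assert vt.tv(v, p) == pytest.approx(cap)

    def test_printed_intercept_convention_available(self):
        p = vt.TraitParams(
            m1=20.26, m2=7.27, vpd_bp=1.17,
            intercept_convention="printed",
        )
        assert p.tv_at_bp() == pytest.approx(20.26 * (1.17 + 0.25))


class TestTr:
    def test_value(self):
        assert vt.tr(4.5, 2.0, 9.0, 3.0) == pytest.approx(1.0 / 3.0)

    def test_zero_radiation_share(self):
        assert vt.tr(0.0, 2.0, 9.0, 3.0) == 0.0

    def test_halves_with_doubled_lai(self):
        assert vt.tr(4.5, 2.0, 9.0, 6.0) == pytest.approx(
            vt.tr(4.5, 2.0, 9.0, 3.0) / 2.0
        )

    def test_no_canopy_inactive(self):
        assert vt.tr(4.5, 2.0, 9.0, 0.0) == 0.0


class TestHourlyBr:
    def test_zero_daily_all_zero(self):
        shares = vt.hourly_br(0.0, 6.0, 19.0)
        assert (shares == 0.0).all()

    def test_conservation(self):
        shares = vt.hourly_br(42.7, 6.2, 19.4)
        assert shares.sum() == pytest.approx(42.7, abs=1e-9)

    def test_zero_at_night_peak_at_noon(self):
        shares = vt.hourly_br(30.0, 6.0, 18.0)
        hours = np.arange(24) + 0.5
        assert (shares[(hours < 6.0) | (hours > 18.0)] == 0.0).all()
        assert hours[int(np.argmax(shares))] == pytest.approx(12.0, abs=0.5)


class TestHourlyT:
    def test_exhausted_soil_blocks_transpiration(self):
        t, rem = vt.hourly_t(1.0, 1.0, 0.0, 3.0)
        assert t == 0.0
        assert rem == 0.0

    def test_soil_clamp_arithmetic(self):
        t, rem = vt.hourly_t(10.0, 10.0, 0.6, 3.0)
        assert t == pytest.approx(0.2)
        assert rem == pytest.approx(0.0)

    def test_ample_soil_gives_min_of_rates(self):
        t, rem = vt.hourly_t(0.3, 0.2, 100.0, 3.0)
        assert t == 0.2
        assert rem == pytest.approx(100.0 - 0.6)


class TestIntegrateDay:
    def test_constant_rate_closed_form(self):
        """10 daylight hours at t = 0.1 mm/h, lai 3, vpd 1, TEc 9:
        W = 3 mm and B = 27 g m-2 by the closed-form sums."""
        lai, tec = 3.0, 9.0
        vpd = np.zeros(24)
        br = np.zeros(24)
        day = slice(7, 17)
        vpd[day] = 1.0
        # choose br so tr = 0.1 exactly, and tv far above
        br[day] = 0.1 * tec * lai / 1.0
        p = vt.no_breakpoint(1e6)
        out = vt.integrate_day(vpd, br, lai, tec, p, soil_supply=1e9)
        assert out.w_demand == pytest.approx(3.0, abs=1e-9)
        assert out.b == pytest.approx(27.0, abs=1e-9)

    def test_all_night_day_zeros(self):
        out = vt.integrate_day(
            np.zeros(24), np.zeros(24), 3.0, 9.0,
            vt.no_breakpoint(20.0), 5.0,
        )
        assert out.w_demand == 0.0
        assert out.b == 0.0

    def test_trait_disabled_limit_recovers_radiation_biomass(self):
        """With the breakpoint pushed to infinity and ample water, the
        hourly integration returns exactly the daily radiation-limited
        biomass."""
        rng = np.random.default_rng(3)
        vpd = np.clip(rng.normal(1.5, 0.6, 24), 0.05, None)
        br = np.zeros(24)
        br[6:20] = rng.uniform(0.5, 5.0, 14)
        delta_br = br.sum()
        p = vt.no_breakpoint(1e9)
        out = vt.integrate_day(vpd, br, 4.0, 9.0, p, soil_supply=1e9)
        assert out.b == pytest.approx(delta_br, rel=1e-9)

    def test_soil_conservation_and_limit(self):
        rng = np.random.default_rng(4)
        vpd = np.clip(rng.normal(1.8, 0.7, 24), 0.05, None)
        br = np.zeros(24)
        br[6:20] = rng.uniform(1.0, 6.0, 14)
        p = vt.TRAIT_PRESETS["btx623"]
        for supply in (0.5, 2.0, 5.0, 50.0):
            out = vt.integrate_day(vpd, br, 4.0, 9.0, p, supply)
            assert out.w_demand <= supply + 1e-9
        unconstrained = vt.integrate_day(vpd, br, 4.0, 9.0, p, 1e9)
        tight = vt.integrate_day(vpd, br, 4.0, 9.0, p, 0.5)
        assert tight.w_demand == pytest.approx(0.5, abs=1e-9)
        assert tight.b < unconstrained.b

    def test_low_vpd_hours_are_more_water_efficient(self):
        """Shifting the same water to lower-VPD hours never decreases
        biomass: the efficiency weight is 1/vpd."""
        lai, tec = 3.0, 9.0
        br = np.zeros(24)
        br[7:17] = 100.0  # radiation never limiting
        vpd = np.full(24, 0.05)
        vpd[7:12] = 1.0   # morning, low vpd
        vpd[12:17] = 3.0  # afternoon, high vpd
        supply = 3.0
        # morning-first sequential use exhausts soil in low-vpd hours
        p_any = vt.no_breakpoint(1e9)
        out = vt.integrate_day(vpd, br, lai, tec, p_any, supply)
        # forcing use into afternoon hours only (no morning share)
        br_pm = br.copy()
        br_pm[7:12] = 0.0
        out_pm = vt.integrate_day(vpd, br_pm, lai, tec, p_any, supply)
        assert out.w_demand == pytest.approx(out_pm.w_demand, abs=1e-9)
        assert out.b >= out_pm.b
        assert out.b == pytest.approx(out_pm.b * 3.0, rel=1e-9)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    m1=st.floats(0.5, 200.0),
    m2=st.floats(-300.0, 60.0),
    bp=st.floats(0.3, 4.0),
    v=st.floats(0.0, 8.0),
)
def test_tv_never_negative_and_never_above_unclamped_line(m1, m2, bp, v):
    p = vt.TraitParams(m1=m1, m2=m2, vpd_bp=bp)
    val = vt.tv(v, p)
    assert val >= 0.0
    assert val == pytest.approx(tv_oracle(v, m1, m2, bp), abs=1e-9)
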