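"""Mass-balance rate calculations: closed-form cases, errors, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemoflux.physiology import (
    ConditionWindow,
    RatePanel,
    SamplePoint,
    UndefinedRateError,
    WindowError,
    accumulation_rate,
    co2_evolution_rate,
    compute_rate_panel,
    specific_growth_rate,
    specific_production_rate,
    specific_uptake_rate,
    summarize_condition,
    to_cmol,
    volumetric_uptake_rate,
    yields_and_cbalance,
)
from chemoflux.species import SpeciesCard, default_registry


def window(x0=5.0, x1=5.0, c0=None, c1=None, dt=10.0, v=2.0, v_in=0.0, v_out=0.0,
           v_bleed=0.0, feed=None):
    return ConditionWindow(
        start=SamplePoint(t=0.0, x=x0, conc=c0 or {}, v_reactor=v),
        end=SamplePoint(t=dt, x=x1, conc=c1 or {}, v_reactor=v),
        v_in=v_in, v_out=v_out, v_bleed=v_bleed, feed_conc=feed or {},
    )


class TestGrowthRate:
    def test_constant_biomass_no_bleed_gives_zero(self):
        assert specific_growth_rate(window()) == 0.0

    @pytest.mark.parametrize("d", [0.02, 0.05, 0.1])
    def test_steady_state_returns_dilution_rate(self, d):
        # constant x with bleed D*V*dt: the growth rate must equal D exactly
        w = window(v_bleed=d * 2.0 * 10.0, v_out=d * 2.0 * 10.0)
        assert specific_growth_rate(w) == pytest.approx(d, rel=1e-14)

    def test_zero_biomass_is_an_error(self):
        with pytest.raises(UndefinedRateError):
            specific_growth_rate(window(x0=0.0, x1=0.0))

    def test_nonadvancing_window_rejected(self):
        with pytest.raises(WindowError):
            ConditionWindow(
                start=SamplePoint(t=5.0, x=1.0), end=SamplePoint(t=5.0, x=1.0)
            )


class TestUptakeRate:
    def test_absent_substrate_gives_zero(self):
        w = window(x0=10.0, x1=10.0, c0={"s": 0.0}, c1={"s": 0.0}, feed={"s": 0.0})
        assert specific_uptake_rate(w, "s") == 0.0

    def test_full_consumption_closed_form(self):
        # s_in=10 g/L over 1 L into 2 L with x=10 g/L for 10 h -> 0.05 g/g/h
        w = window(x0=10.0, x1=10.0, c0={"s": 0.0}, c1={"s": 0.0},
                   v_in=1.0, feed={"s": 10.0})
        assert specific_uptake_rate(w, "s") == pytest.approx(0.05)
        assert volumetric_uptake_rate(w, "s") == pytest.approx(1.0)

    def test_volumetric_consistency_with_specific(self):
        w = window(x0=8.0, x1=9.0, c0={"s": 1.0}, c1={"s": 0.5},
                   v_in=0.8, v_out=0.7, feed={"s": 12.0})
        q = specific_uptake_rate(w, "s")
        r = volumetric_uptake_rate(w, "s")
        assert r == pytest.approx(q * w.x_mean * w.v_reactor, rel=1e-12)

    def test_verbatim_form_differs_by_twice_the_accumulation(self):
        w = window(c0={"s": 1.0}, c1={"s": 2.0}, v_in=1.0, feed={"s": 10.0})
        q_mb = specific_uptake_rate(w, "s")
        q_vb = specific_uptake_rate(w, "s", verbatim_eq2=True)
        ds_term = 2.0 * (2.0 - 1.0) * w.v_reactor / (w.x_mean * w.v_reactor * w.dt)
        assert q_vb - q_mb == pytest.approx(ds_term)

    def test_zero_biomass_is_an_error(self):
        with pytest.raises(UndefinedRateError):
            specific_uptake_rate(window(x0=0.0, x1=0.0), "s")


class TestProductionRate:
    def test_no_product_anywhere_gives_zero(self):
        w = window(c0={"p": 0.0}, c1={"p": 0.0})
        assert specific_production_rate(w, "p") == 0.0

    def test_steady_state_closed_form(self):
        # constant p, p_in = 0, V_out = D*V*dt  ->  q_P = p*D/x
        d, p, x = 0.05, 1.4, 5.0
        w = window(x0=x, x1=x, c0={"p": p}, c1={"p": p}, v_out=d * 2.0 * 10.0)
        assert specific_production_rate(w, "p") == pytest.approx(p * d / x, rel=1e-12)


class TestAccumulationRate:
    def test_linear_rise(self):
        w = window(c0={"s": 1.0}, c1={"s": 1.5}, dt=2.0)
        assert accumulation_rate(w, "s") == pytest.approx(0.25)

    def test_constant_concentration(self):
        w = window(c0={"s": 3.0}, c1={"s": 3.0})
        assert accumulation_rate(w, "s") == 0.0

    def test_reported_msg_glucose_ratio_exceeds_35(self):
        # windows embodying accumulation of 0.18 (MSG) and 0.0048 (glucose) g/L/h
        dt = 6.0
        w = window(c0={"msg": 2.0, "glucose": 0.3},
                   c1={"msg": 2.0 + 0.18 * dt, "glucose": 0.3 + 0.0048 * dt}, dt=dt)
        ratio = accumulation_rate(w, "msg") / accumulation_rate(w, "glucose")
        assert ratio == pytest.approx(37.5)
        assert ratio >= 35.0


class TestCO2Evolution:
    def test_zero_offgas_gives_zero(self):
        pts = [SamplePoint(t=t, x=5.0, co2_offgas=0.0, gas_flow=30.0) for t in (0.0, 10.0)]
        w = ConditionWindow(start=pts[0], end=pts[1])
        assert co2_evolution_rate(pts, w, inlet_co2_frac=0.0) == 0.0

    def test_constant_trace_arithmetic(self):
        # 1% CO2 at 30 L/h over x*V = 10 g with Vm = 24 L/mol -> 0.00125 Cmol/g/h
        pts = [SamplePoint(t=t, x=5.0, co2_offgas=0.01, gas_flow=30.0) for t in (0.0, 10.0)]
        w = ConditionWindow(start=pts[0], end=pts[1])
        q = co2_evolution_rate(pts, w, molar_volume=24.0, inlet_co2_frac=0.0)
        assert q == pytest.approx(0.00125, rel=1e-12)

    def test_missing_offgas_reports_not_available(self):
        pts = [SamplePoint(t=t, x=5.0) for t in (0.0, 10.0)]
        w = ConditionWindow(start=pts[0], end=pts[1])
        assert co2_evolution_rate(pts, w) is None


class TestCmolConversion:
    def test_glucose_gram_to_cmol(self):
        card = default_registry()["glucose"]
        assert to_cmol(1.0, card) == pytest.approx(6.0 / 180.16, rel=1e-12)

    def test_carbon_free_species_contributes_nothing(self):
        assert to_cmol(5.0, SpeciesCard("water", 18.02, 0)) == 0.0


class TestYields:
    def test_zero_products_and_co2_reduces_to_biomass_yield(self):
        panel = RatePanel(mu=0.05, q={"glucose": 0.1}, q_co2=0.0,
                          substrates=("glucose",), products=())
        y = yields_and_cbalance(panel)
        assert y.c_balance == y.y_xs
        assert y.y_co2s == 0.0 and y.y_tres == 0.0 and y.y_aas == 0.0

    def test_zero_uptake_is_an_error(self):
        panel = RatePanel(mu=0.05, q={"glucose": 0.0}, substrates=("glucose",))
        with pytest.raises(UndefinedRateError):
            yields_and_cbalance(panel)

    def test_missing_co2_marks_balance_partial(self):
        panel = RatePanel(mu=0.05, q={"glucose": 0.1}, q_co2=None, substrates=("glucose",))
        y = yields_and_cbalance(panel)
        assert y.partial and y.y_co2s == 0.0


class TestSummaries:
    def test_three_replicates(self):
        table = summarize_condition([{"v": 1.0}, {"v": 2.0}, {"v": 3.0}])
        assert table.loc["v", "mean"] == pytest.approx(2.0)
        assert table.loc["v", "sd"] == pytest.approx(1.0)
        assert table.loc["v", "n"] == 3

    def test_single_replicate_flagged(self):
        table = summarize_condition([{"v": 4.2}])
        assert table.loc["v", "sd"] == 0.0 and table.loc["v", "n"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(Exception):
            summarize_condition([])


@settings(derandomize=True, max_examples=50)
@given(
    x0=st.floats(1.0, 20.0), x1=st.floats(1.0, 20.0),
    s0=st.floats(0.0, 10.0), s1=st.floats(0.0, 10.0),
    v_in=st.floats(0.0, 2.0), v_out=st.floats(0.0, 2.0), v_bleed=st.floats(0.0, 2.0),
    k=st.floats(1.5, 8.0),
)
def test_specific_rates_are_scale_invariant(x0, x1, s0, s1, v_in, v_out, v_bleed, k):
    """Scaling the reactor (volumes and flows) by k leaves specific rates unchanged."""
    def make(scale):
        return ConditionWindow(
            start=SamplePoint(t=0.0, x=x0, conc={"s": s0}, v_reactor=2.0 * scale),
            end=SamplePoint(t=6.0, x=x1, conc={"s": s1}, v_reactor=2.0 * scale),
            v_in=v_in * scale, v_out=v_out * scale, v_bleed=v_bleed * scale,
            feed_conc={"s": 10.0},
        )
    w1, wk = make(1.0), make(k)
    assert specific_growth_rate(wk) == pytest.approx(specific_growth_rate(w1), rel=1e-9, abs=1e-12)
    assert specific_uptake_rate(wk, "s") == pytest.approx(specific_uptake_rate(w1, "s"), rel=1e-9, abs=1e-12)
    assert specific_production_rate(wk, "s") == pytest.approx(specific_production_rate(w1, "s"), rel=1e-9, abs=1e-12)


def test_rate_panel_collects_all_quantities():
    w = window(x0=10.0, x1=10.0, c0={"s": 0.0, "p": 1.0}, c1={"s": 0.0, "p": 1.0},
               v_in=1.0, v_out=1.0, feed={"s": 10.0})
    panel = compute_rate_panel(w, ["s"], ["p"])
    assert panel.q["s"] == pytest.approx(0.05)
    assert panel.q["p"] == pytest.approx(1.0 * 1.0 / (10.0 * 2.0 * 10.0))
    assert panel.accumulation["s"] == 0.0
    assert panel.q_co2 is None  # no off-gas data on these points
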