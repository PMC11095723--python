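"""Unit and property tests for the candidate-model family and simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellgrowth.models import (
    CandidateModel,
    CultureCondition,
    EffectKind,
    FixedConstants,
    ModulatingEffect,
    ParameterSet,
    enumerate_candidates,
    filter_candidates,
    model_by_name,
    modulating_factor,
    ode_rhs,
    oxygen_percent_to_concentration,
    reaction_rate,
    simulate,
    simulate_conditions,
    substrate_dependence,
)

ZERO = EffectKind.ZERO_ORDER
FIRST = EffectKind.FIRST_ORDER
POS = EffectKind.MMK_POSITIVE
NEG = EffectKind.MMK_NEGATIVE


class TestModulatingEffect:
    def test_zero_order_is_one(self):
        assert modulating_factor(ModulatingEffect(ZERO), 7.3) == 1.0

    def test_first_order_is_identity(self):
        assert modulating_factor(ModulatingEffect(FIRST), 2.5) == 2.5

    def test_mmk_half_saturation(self):
        eff = ModulatingEffect(POS, K=3.0)
        assert modulating_factor(eff, 3.0) == pytest.approx(0.5)

    def test_mmk_negative_limits(self):
        eff = ModulatingEffect(NEG, K=2.0)
        assert modulating_factor(eff, 0.0) == pytest.approx(1.0)
        assert modulating_factor(eff, 1e12) == pytest.approx(0.0, abs=1e-11)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            modulating_factor(ModulatingEffect(ZERO), -1.0)

    @pytest.mark.parametrize("kind", [POS, NEG])
    def test_mmk_requires_positive_K(self, kind):
        with pytest.raises(ValueError):
            ModulatingEffect(kind)
        with pytest.raises(ValueError):
            ModulatingEffect(kind, K=-1.0)

    def test_non_mmk_rejects_K(self):
        with pytest.raises(ValueError):
            ModulatingEffect(ZERO, K=1.0)

    @given(
        kind=st.sampled_from([POS, NEG]),
        K=st.floats(1e-6, 1e6),
        c=st.floats(0, 1e9),
    )
    @settings(max_examples=200, deadline=None)
    def test_mmk_output_in_unit_interval(self, kind, K, c):
        f = modulating_factor(ModulatingEffect(kind, K=K), c)
        assert 0.0 <= f <= 1.0


class TestReactionRate:
    def test_zero_order(self):
        assert reaction_rate("zero", V=5.0, c=123.0) == 5.0

    def test_michaelis_menten_half_saturation(self):
        assert reaction_rate("michaelis_menten", V=2.0, c=4.0, cbar=4.0) == 1.0

    def test_competitive_without_inhibitor_equals_mmk(self):
        assert reaction_rate(
            "competitive_inhibition", V=2.0, c=4.0, cbar=4.0,
            c_inhibitor=0.0, cbar_inhibition=1.0,
        ) == pytest.approx(1.0)

    def test_unknown_kinetics_rejected(self):
        with pytest.raises(ValueError):
            reaction_rate("cubic", V=1.0)


class TestEnumeration:
    def test_27_candidates(self):
        assert len(enumerate_candidates()) == 27

    def test_deterministic_and_distinct(self):
        models = enumerate_candidates()
        assert models == enumerate_candidates()
        assert len({m.kinds for m in models}) == 27
        assert len({m.name for m in models}) == 27

    def test_brute_force_oracle(self):
        # independent exhaustive listing over permitted kinds
        expected = {
            (o, g, l)
            for o in (ZERO, FIRST, POS)
            for g in (ZERO, FIRST, POS)
            for l in (ZERO, FIRST, NEG)
        }
        assert {m.kinds for m in enumerate_candidates()} == expected

    def test_restricted_enumeration(self):
        assert len(enumerate_candidates(oxygen_kinds=[POS],
                                        glucose_kinds=[ZERO],
                                        lactate_kinds=[NEG])) == 1
        four = enumerate_candidates(
            oxygen_kinds=[ZERO, FIRST], glucose_kinds=[ZERO, FIRST],
            lactate_kinds=[ZERO],
        )
        assert len(four) == 4 and len(set(four)) == 4

    def test_mmk_based_names(self):
        assert CandidateModel(POS, POS, NEG).name == "OxyGluLac"
        assert CandidateModel(ZERO, ZERO, NEG).name == "Lac"
        assert CandidateModel(POS, POS, ZERO).name == "OxyGlu"
        assert model_by_name("OxyGluLac").kinds == (POS, POS, NEG)

    def test_forbidden_kinds_rejected(self):
        with pytest.raises(ValueError):
            CandidateModel(NEG, ZERO, ZERO)
        with pytest.raises(ValueError):
            CandidateModel(ZERO, ZERO, POS)

    def test_free_parameter_count(self):
        assert len(model_by_name("OxyGluLac").free_parameter_names()) == 7
        assert len(model_by_name("Lac").free_parameter_names()) == 5


class TestDependenceFilter:
    def test_no_effects_no_dependence(self):
        dep = substrate_dependence(CandidateModel(ZERO, ZERO, ZERO),
                                   FixedConstants())
        assert dep == (False, False)

    def test_direct_oxygen_only(self):
        dep = substrate_dependence(CandidateModel(POS, ZERO, ZERO),
                                   FixedConstants())
        assert dep == (True, False)

    def test_lactate_routes_both(self):
        dep = substrate_dependence(CandidateModel(ZERO, ZERO, NEG),
                                   FixedConstants())
        assert dep == (True, True)

    def test_filter_counts(self):
        models = enumerate_candidates()
        assert len(filter_candidates(models, {"oxygen", "glucose"})) == 22
        assert len(filter_candidates(models, set())) == 27
        assert len(filter_candidates(models, {"oxygen"})) == 24

    def test_filter_against_brute_force(self):
        # independent rule: population depends on a substrate iff its own
        # effect is non-zero-order, or lactate feeds back (f3 active)
        models = enumerate_candidates()
        brute = [
            m for m in models
            if (m.f_oxygen != ZERO or m.f_lactate != ZERO)
            and (m.f_glucose != ZERO or m.f_lactate != ZERO)
        ]
        assert filter_candidates(models, {"oxygen", "glucose"}) == brute

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ValueError):
            filter_candidates(enumerate_candidates(), {"lactate"})


@pytest.fixture
def params():
    return ParameterSet(beta=3.83e-5, delta=5e-6, V_g=2e-12, cbar_g=1.66,
                        K_o=0.08, K_g=2.0, K_l=8.0)


@pytest.fixture
def consts():
    return FixedConstants(V_o=1e-13, cbar_o=6.66e-9, n_max=3e6)


class TestRhs:
    def test_death_only_limit(self, params, consts):
        from dataclasses import replace

        p = replace(params, beta=1e-30, delta=2e-5)  # beta must stay positive
        d = ode_rhs(model_by_name("OxyGluLac"), p, consts,
                    (1e5, 5.0, 2.0, 0.18))
        assert d[0] == pytest.approx(-2e-5 * 1e5, rel=1e-9)

    def test_no_consumption_when_Vg_zero(self, params, consts):
        from dataclasses import replace

        p = replace(params, V_g=0.0)
        d = ode_rhs(model_by_name("OxyGluLac"), p, consts,
                    (1e5, 5.0, 2.0, 0.18))
        assert d[1] == 0.0

    def test_carrying_capacity_fixed_point(self, params, consts):
        from dataclasses import replace

        p = replace(params, delta=0.0)
        d = ode_rhs(model_by_name("OxyGluLac"), p, consts,
                    (consts.n_max, 5.0, 2.0, 0.18))
        assert d[0] == pytest.approx(0.0, abs=1e-20)

    def test_oxygen_clamped(self, params, consts):
        d = ode_rhs(model_by_name("OxyGluLac"), params, consts,
                    (1e5, 5.0, 2.0, 0.18))
        assert d[3] == 0.0

    def test_non_finite_state_rejected(self, params, consts):
        with pytest.raises(ValueError):
            ode_rhs(model_by_name("OxyGluLac"), params, consts,
                    (np.nan, 5.0, 2.0, 0.18))


class TestSimulate:
    def test_exponential_decay_closed_form(self, consts):
        # beta effectively 0: n(t) = n0 exp(-delta t)
        p = ParameterSet(beta=1e-30, delta=2e-5, V_g=0.0, cbar_g=1.0)
        model = CandidateModel(ZERO, ZERO, ZERO)
        cond = CultureCondition(n0=1e5, cg0=5.0, cl0=2.0, co=0.18)
        half_life_h = np.log(2) / (2e-5 * 3600.0)
        times = np.array([half_life_h / 2, half_life_h, 100.0])
        tr = simulate(model, p, consts, cond, times)
        exact = 1e5 * np.exp(-2e-5 * times * 3600.0)
        assert np.max(np.abs(tr.n - exact) / exact) < 1e-6
        assert tr.n[1] == pytest.approx(5e4, rel=1e-6)

    def test_logistic_closed_form(self, consts):
        p = ParameterSet(beta=3.83e-5, delta=0.0, V_g=0.0, cbar_g=1.0)
        model = CandidateModel(ZERO, ZERO, ZERO)
        cond = CultureCondition(n0=1e5, cg0=5.0, cl0=2.0, co=0.18)
        times = np.linspace(1.0, 114.0, 30)
        tr = simulate(model, p, consts, cond, times)
        b = 3.83e-5 * 3600.0
        nm, n0 = consts.n_max, 1e5
        exact = nm * n0 * np.exp(b * times) / (nm + n0 * (np.exp(b * times) - 1))
        assert np.max(np.abs(tr.n - exact) / exact) < 1e-6

    def test_stoichiometric_conservation_without_oxygen_sink(self, params):
        consts = FixedConstants(V_o=0.0, cbar_o=6.66e-9, n_max=3e6)
        cond = CultureCondition(n0=2e5, cg0=25.0, cl0=2.0, co=0.18)
        times = np.linspace(6, 500, 40)
        tr = simulate(model_by_name("OxyGluLac"), params, consts, cond, times)
        invariant = tr.cl + 2 * tr.cg
        assert np.max(np.abs(invariant - (2.0 + 2 * 25.0))) < 1e-6

    def test_states_non_negative_and_glucose_monotone(self, params, consts):
        rng = np.random.default_rng(0)
        model = model_by_name("OxyGluLac")
        for _ in range(5):
            cond = CultureCondition(
                n0=float(rng.uniform(2e4, 2e5)),
                cg0=float(rng.uniform(2, 25)),
                cl0=float(rng.uniform(0, 5)),
                co=float(rng.uniform(0.05, 0.18)),
            )
            tr = simulate(model, params, consts, cond,
                          np.linspace(1, 1000, 50))
            assert (tr.n >= 0).all() and (tr.cg >= 0).all() and (tr.cl >= 0).all()
            assert (np.diff(tr.cg) <= 1e-9).all()
            assert np.allclose(tr.co, cond.co)

    def test_initial_condition_applies_at_seeding_time(self, params, consts):
        # first output at 6 h already reflects 6 h of growth from t=0
        cond = CultureCondition(n0=1e5, cg0=25.0, cl0=2.0, co=0.18)
        tr = simulate(model_by_name("OxyGluLac"), params, consts, cond, [6.0])
        assert tr.n[0] > 1e5

    def test_unsorted_times_rejected(self, params, consts):
        cond = CultureCondition(n0=1e5, cg0=25.0, cl0=2.0, co=0.18)
        with pytest.raises(ValueError):
            simulate(model_by_name("OxyGluLac"), params, consts, cond,
                     [10.0, 6.0])

    def test_stacked_simulation_matches_individual(self, params, consts):
        model = model_by_name("OxyGluLac")
        conds = [
            CultureCondition(n0=5e4, cg0=25.0, cl0=2.0, co=0.18),
            CultureCondition(n0=2e5, cg0=5.5, cl0=2.0, co=0.05),
        ]
        times = np.arange(6, 115, 24.0)
        stacked = simulate_conditions(model, params, consts, conds, times)
        for ci, cond in enumerate(conds):
            tr = simulate(model, params, consts, cond, times)
            assert np.allclose(stacked[ci, 0], tr.n, rtol=1e-5)
            assert np.allclose(stacked[ci, 1], tr.cg, rtol=1e-5)
            assert np.allclose(stacked[ci, 2], tr.cl, rtol=1e-5)


def test_oxygen_percent_mapping():
    assert oxygen_percent_to_concentration(18.6) == pytest.approx(0.18)
    assert oxygen_percent_to_concentration(5.0) == pytest.approx(0.0484, rel=1e-3)


def test_lactate_sign_switch(params):
    plus = FixedConstants(V_o=1e-13, lactate_sign=1)
    minus = FixedConstants(V_o=1e-13, lactate_sign=-1)
    state = (1e5, 5.0, 2.0, 0.18)
    model = model_by_name("OxyGluLac")
    d_plus = ode_rhs(model, params, plus, state)
    d_minus = ode_rhs(model, params, minus, state)
    assert d_plus[2] == pytest.approx(-d_minus[2])
    assert d_plus[2] > 0  # glycolysis produces lactate by default
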