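import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvcompete.models import (
    ConfigurationError,
    DrugSchedule,
    ModelSpec,
    ParameterSet,
    TrajectoryState,
    drug_concentration,
    enumerate_model_family,
    monoculture_models,
    rhs_drug_term,
    two_population_rhs,
)


def make_params(**kw):
    base = dict(rho1=1.0, rho2=1.0, K1=100.0, K2=100.0, alpha_sr=0.0,
                alpha_rs=0.0, lam=0.0)
    base.update(kw)
    return ParameterSet(**base)


class TestDrugConcentration:
    def test_zero_before_onset(self):
        s = DrugSchedule(drug_present=True, onset_h=20.0, dose=1.0)
        assert drug_concentration(10.0, s) == 0.0

    def test_zero_when_absent(self):
        s = DrugSchedule(drug_present=False)
        assert drug_concentration(50.0, s) == 0.0

    def test_right_continuous_at_onset(self):
        s = DrugSchedule(drug_present=True, onset_h=20.0, dose=1.0)
        assert drug_concentration(20.0, s) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            drug_concentration(-1.0, DrugSchedule())


class TestParameterSet:
    @pytest.mark.parametrize("bad", [dict(rho1=0.0), dict(K2=-1.0),
                                     dict(alpha_sr=-0.1), dict(lam=-1.0)])
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            make_params(**bad)


class TestGrowthLawDirectEvaluation:
    """Hand-evaluated right-hand sides of the three growth laws."""

    def test_logistic_half_capacity(self):
        p = make_params(rho1=1.0, K1=100.0)
        dS, _ = two_population_rhs("logistic", "ratio_dependent", 50.0, 0.0, 0.0, p)
        assert dS == pytest.approx(25.0)

    def test_logistic_at_capacity_is_equilibrium(self):
        p = make_params()
        dS, _ = two_population_rhs("logistic", "norton_simon", 100.0, 0.0, 0.0, p)
        assert dS == pytest.approx(0.0)

    def test_logistic_shared_capacity_line(self):
        p = make_params(alpha_sr=1.0, alpha_rs=1.0, K1=100.0, K2=100.0)
        dS, dR = two_population_rhs("logistic", "norton_simon", 40.0, 60.0, 0.0, p)
        assert dS == pytest.approx(0.0)
        assert dR == pytest.approx(0.0)

    def test_gompertz_log_of_e(self):
        p = make_params(rho1=1.0, K1=math.e * 10.0)
        dS, _ = two_population_rhs("gompertz", "norton_simon", 10.0, 0.0, 0.0, p)
        assert dS == pytest.approx(10.0)

    def test_gompertz_extinction_absorbing(self):
        p = make_params()
        assert two_population_rhs("gompertz", "norton_simon", 0.0, 0.0, 0.0, p) == (0.0, 0.0)

    def test_von_bertalanffy_direct(self):
        p = make_params(rho1=1.0, K1=8.0)
        dS, _ = two_population_rhs("von_bertalanffy", "norton_simon", 1.0, 0.0, 0.0, p)
        assert dS == pytest.approx(0.5)

    def test_von_bertalanffy_capacity_equilibrium(self):
        p = make_params(K1=8.0)
        dS, _ = two_population_rhs("von_bertalanffy", "norton_simon", 8.0, 0.0, 0.0, p)
        assert dS == pytest.approx(0.0)

    def test_von_bertalanffy_zero_population(self):
        p = make_params()
        dS, _ = two_population_rhs("von_bertalanffy", "linear", 0.0, 0.0, 0.0, p)
        assert dS == 0.0


class TestDrugTerms:
    def test_norton_simon_pathology_above_capacity(self):
        # with lam > 1 and S > K the multiplied negative growth term turns
        # positive: the population can grow without bound under treatment
        p = make_params(rho1=1.0, K1=100.0, lam=2.0)
        dS, _ = two_population_rhs("logistic", "norton_simon", 150.0, 0.0, 1.0, p)
        assert dS > 0

    def test_ratio_dependent_kill_at_capacity(self):
        p = make_params(rho1=1.0, K1=100.0, lam=0.5)
        dS, _ = two_population_rhs("logistic", "ratio_dependent", 100.0, 0.0, 1.0, p)
        assert dS == pytest.approx(-50.0)

    def test_linear_subtracts_constant(self):
        assert rhs_drug_term("linear", 5.0, 10.0, 1.0, 2.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("dm", ["norton_simon", "linear", "ratio_dependent"])
    def test_no_drug_reduces_to_growth(self, dm):
        p = make_params(rho1=1.0, K1=100.0, lam=5.0)
        dS, _ = two_population_rhs("logistic", dm, 50.0, 0.0, 0.0, p)
        assert dS == pytest.approx(25.0)

    def test_unknown_drug_model_rejected(self):
        with pytest.raises(ConfigurationError):
            rhs_drug_term("quadratic", 1.0, 1.0, 1.0, 1.0)

    def test_drug_never_touches_resistant_equation(self):
        p = make_params(rho2=1.0, K2=100.0, lam=5.0)
        _, dR0 = two_population_rhs("logistic", "ratio_dependent", 10.0, 50.0, 0.0, p)
        _, dR1 = two_population_rhs("logistic", "ratio_dependent", 10.0, 50.0, 1.0, p)
        assert dR0 == dR1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    law=st.sampled_from(["logistic", "gompertz", "von_bertalanffy"]),
    frac=st.floats(0.01, 0.99),
    above=st.floats(1.01, 3.0),
    rho=st.floats(0.01, 2.0),
)
def test_monotone_density_dependence(law, frac, above, rho):
    """Drug-free single population: growth below K, decline above K."""
    p = make_params(rho1=rho, K1=1000.0)
    dS_below, _ = two_population_rhs(law, "norton_simon", frac * 1000.0, 0.0, 0.0, p)
    dS_above, _ = two_population_rhs(law, "norton_simon", above * 1000.0, 0.0, 0.0, p)
    assert dS_below > 0
    assert dS_above < 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rho_lo=st.floats(0.01, 0.5), rho_hi_mult=st.floats(1.1, 4.0),
       law=st.sampled_from(["logistic", "gompertz"]))
def test_small_population_growth_increases_in_rho(law, rho_lo, rho_hi_mult):
    S = 1.0  # far below K
    d_lo, _ = two_population_rhs(law, "norton_simon", S, 0.0, 0.0,
                                 make_params(rho1=rho_lo, K1=1000.0))
    d_hi, _ = two_population_rhs(law, "norton_simon", S, 0.0, 0.0,
                                 make_params(rho1=rho_lo * rho_hi_mult, K1=1000.0))
    assert 0 < d_lo < d_hi


class TestModelFamily:
    def test_exactly_fifteen_models(self):
        specs = enumerate_model_family()
        assert len(specs) == 15

    def test_deterministic_ordering(self):
        labels = [s.label() for s in enumerate_model_family()]
        assert labels[:5] == [f"logistic-{v}" for v in range(1, 6)]
        assert labels[5:10] == [f"gompertz-{v}" for v in range(1, 6)]
        assert labels[10:] == [f"von_bertalanffy-{v}" for v in range(1, 6)]

    @pytest.mark.parametrize(
        "variant,no_drug,with_drug",
        [(1, 2, 3), (2, 3, 4), (3, 3, 4), (4, 3, 4), (5, 4, 5)],
    )
    def test_free_parameter_counts(self, variant, no_drug, with_drug):
        spec = ModelSpec(variant=variant)
        assert len(spec.free_params(False)) == no_drug
        assert len(spec.free_params(True)) == with_drug

    def test_no_variant_frees_more_than_five(self):
        assert all(len(s.free_params(True)) <= 5 for s in enumerate_model_family())

    def test_variant_five_free_set(self):
        spec = ModelSpec(variant=5)
        assert spec.free_params(True) == ("rho", "K", "alpha_sr", "alpha_rs", "lam")

    def test_full_model_has_seven_parameters(self):
        spec = ModelSpec(variant=None)
        assert len(spec.free_params(True)) == 7

    def test_variant_one_ties_everything(self):
        p = ModelSpec(variant=1).build_parameters({"rho": 0.1, "K": 500.0})
        assert p.rho1 == p.rho2 == 0.1
        assert p.K1 == p.K2 == 500.0
        assert p.alpha_sr == p.alpha_rs == 1.0

    def test_json_round_trip(self):
        spec = ModelSpec("gompertz", "linear", 3)
        assert ModelSpec.from_json(spec.to_json()) == spec


class TestMonocultureModels:
    def test_resistant_model_has_no_drug_term(self):
        _, res = monoculture_models()
        assert "lam" not in res.free_params(True)
        p = res.build_parameters({"rho2": 0.1, "K2": 100.0})
        _, dR0 = two_population_rhs(res.growth_law, res.drug_model, 0.0, 50.0, 0.0, p)
        _, dR1 = two_population_rhs(res.growth_law, res.drug_model, 0.0, 50.0, 1.0, p)
        assert dR0 == dR1

    def test_sensitive_without_drug_is_pure_logistic(self):
        sens, _ = monoculture_models()
        p = sens.build_parameters({"rho1": 1.0, "K1": 100.0, "lam": 0.5})
        dS, _ = two_population_rhs(sens.growth_law, sens.drug_model, 50.0, 0.0, 0.0, p)
        assert dS == pytest.approx(25.0)

    def test_sensitive_extinction_is_fixed(self):
        sens, _ = monoculture_models()
        p = sens.build_parameters({"rho1": 1.0, "K1": 100.0, "lam": 0.5})
        dS, _ = two_population_rhs(sens.growth_law, sens.drug_model, 0.0, 0.0, 1.0, p)
        assert dS == 0.0
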