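import numpy as np
import pytest

from lvcompete.models import ModelSpec, ParameterSet
from lvcompete.phaseplane import (
    STABILITY_TOL,
    UnsupportedModelError,
    classify,
    equilibria,
    jacobian,
    nullclines,
    simulate_to_equilibrium,
    sweep_outcomes,
)


def params(**kw):
    base = dict(rho1=0.5, rho2=0.5, K1=3.0, K2=3.0, alpha_sr=0.5,
                alpha_rs=0.5, lam=0.0)
    base.update(kw)
    return ParameterSet(**base)


def rhs(p, C, S, R):
    dS = p.rho1 * (1 - (S + p.alpha_sr * R) / p.K1) * S - p.lam * C * S
    dR = p.rho2 * (1 - (p.alpha_rs * S + R) / p.K2) * R
    return dS, dR


class TestEquilibria:
    def test_symmetric_interior_point(self):
        eqs = {e.kind: e for e in equilibria(params(), 0.0)}
        assert eqs["interior"].S == pytest.approx(2.0)
        assert eqs["interior"].R == pytest.approx(2.0)

    def test_no_sensitive_boundary_when_kill_exceeds_growth(self):
        p = params(lam=1.0)  # lam*C = 1.0 > rho1 = 0.5
        kinds = {e.kind for e in equilibria(p, 1.0)}
        assert "sensitive_only" not in kinds

    def test_interior_from_reported_drug_alphas(self):
        # competition coefficients in the drug regime; position checked by an
        # independent 2x2 linear solve
        p = ParameterSet(rho1=0.06, rho2=0.055, K1=1000.0, K2=2000.0,
                         alpha_sr=0.961, alpha_rs=2.144, lam=0.5 / 12.0)
        C = 1.0
        k1e = p.K1 * (1 - p.lam * C / p.rho1)
        expect = np.linalg.solve(
            np.array([[1.0, p.alpha_sr], [p.alpha_rs, 1.0]]),
            np.array([k1e, p.K2]),
        )
        eqs = {e.kind: e for e in equilibria(p, C)}
        if np.all(expect > 0):
            assert eqs["interior"].S == pytest.approx(expect[0])
            assert eqs["interior"].R == pytest.approx(expect[1])
        else:
            assert "interior" not in eqs

    def test_all_reported_points_are_equilibria(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = params(
                rho1=rng.uniform(0.01, 1), rho2=rng.uniform(0.01, 1),
                K1=rng.uniform(10, 1e4), K2=rng.uniform(10, 1e4),
                alpha_sr=rng.uniform(0, 2), alpha_rs=rng.uniform(0, 2),
                lam=rng.uniform(0, 0.5),
            )
            C = float(rng.integers(0, 2))
            for e in equilibria(p, C):
                dS, dR = rhs(p, C, e.S, e.R)
                scale = max(p.K1, p.K2)
                assert abs(dS) / scale < 1e-9 and abs(dR) / scale < 1e-9

    def test_interior_satisfies_both_nullclines(self):
        p = params(K1=5000.0, K2=8000.0, alpha_sr=0.519, alpha_rs=0.576)
        eqs = {e.kind: e for e in equilibria(p, 0.0)}
        e = eqs["interior"]
        assert e.S + p.alpha_sr * e.R == pytest.approx(p.K1, abs=1e-10 * p.K1)
        assert p.alpha_rs * e.S + e.R == pytest.approx(p.K2, abs=1e-10 * p.K2)

    def test_non_logistic_spec_rejected(self):
        with pytest.raises(UnsupportedModelError):
            equilibria(params(), 0.0, spec=ModelSpec("gompertz", "ratio_dependent"))


class TestJacobian:
    def test_origin_linearization_is_diagonal_growth_rates(self):
        p = params(rho1=0.3, rho2=0.7)
        J = jacobian(p, 0.0, (0.0, 0.0))
        np.testing.assert_allclose(J, np.diag([0.3, 0.7]))

    def test_resistant_boundary_self_derivative(self):
        p = params(rho2=0.4, K2=100.0)
        J = jacobian(p, 0.0, (0.0, 100.0))
        assert J[1, 1] == pytest.approx(-0.4)

    def test_matches_finite_differences_at_random_points(self):
        rng = np.random.default_rng(8)
        h = 1e-6
        for _ in range(100):
            p = params(
                rho1=rng.uniform(0.01, 1), rho2=rng.uniform(0.01, 1),
                K1=rng.uniform(1, 100), K2=rng.uniform(1, 100),
                alpha_sr=rng.uniform(0, 2), alpha_rs=rng.uniform(0, 2),
                lam=rng.uniform(0, 1),
            )
            C = rng.uniform(0, 1)
            S, R = rng.uniform(0.1, 50, size=2)
            J = jacobian(p, C, (S, R))
            num = np.empty((2, 2))
            for j, (dS_, dR_) in enumerate(((h, 0.0), (0.0, h))):
                up = rhs(p, C, S + dS_, R + dR_)
                dn = rhs(p, C, S - dS_, R - dR_)
                num[0, j] = (up[0] - dn[0]) / (2 * h)
                num[1, j] = (up[1] - dn[1]) / (2 * h)
            np.testing.assert_allclose(J, num, rtol=1e-5, atol=1e-6)


class TestClassify:
    def test_weak_symmetric_competition_coexists(self):
        assert classify(params(alpha_sr=0.5, alpha_rs=0.5), 0.0).outcome == "coexistence"

    def test_strong_symmetric_competition_is_bistable(self):
        rep = classify(params(alpha_sr=2.0, alpha_rs=2.0), 0.0)
        assert rep.outcome == "bistable"
        assert rep.get("interior").stability == "saddle"

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.9, 1.1, 2.0, 5.0])
    def test_classical_lv_threshold(self, alpha):
        outcome = classify(params(alpha_sr=alpha, alpha_rs=alpha), 0.0).outcome
        assert outcome == ("coexistence" if alpha < 1 else "bistable")

    def test_overwhelming_drug_excludes_sensitive(self):
        rep = classify(params(lam=1.0), 1.0)  # effective K1 < 0
        assert rep.outcome == "exclusion_of_sensitive"

    def test_degenerate_determinant_flagged(self):
        rep = classify(params(alpha_sr=2.0, alpha_rs=0.5), 0.0)
        assert rep.outcome == "degenerate"


class TestSimulateToEquilibrium:
    def test_coexistence_attracts_random_interior_starts(self):
        p = params()
        res = simulate_to_equilibrium(p, 0.0, [(0.5, 0.5), (4.0, 1.0), (1.0, 4.0)])
        assert all(r.converged for r in res)
        assert all(r.attractor.kind == "interior" for r in res)

    def test_unstable_start_remains_within_drift(self):
        p = params()
        eq = {e.kind: e for e in equilibria(p, 0.0)}["interior"]
        # start exactly at the stable interior point: no movement at all
        res = simulate_to_equilibrium(p, 0.0, [(eq.S, eq.R)], block_h=50.0)
        assert res[0].converged
        assert res[0].final[0] == pytest.approx(eq.S, rel=1e-6)

    def test_bistable_separatrix_splits_outcomes(self):
        p = params(alpha_sr=2.0, alpha_rs=2.0)
        res = simulate_to_equilibrium(p, 0.0, [(2.5, 0.3), (0.3, 2.5)])
        kinds = [r.attractor.kind for r in res]
        assert kinds == ["sensitive_only", "resistant_only"]


class TestSweep:
    def test_lam_zero_column_matches_drug_free_classification(self):
        p = params(K1=5000.0, K2=8000.0, alpha_rs=0.576, lam=0.02)
        alphas = np.linspace(0.0, 1.5, 7)
        mat = sweep_outcomes(p, "lam", np.array([0.0, 0.05]), "alpha_sr", alphas, C=1.0)
        for i, a in enumerate(alphas):
            assert mat[i, 0] == classify(p.replace(alpha_sr=float(a), lam=0.0), 0.0).outcome

    def test_outcome_shifts_toward_sensitive_exclusion_with_lam(self):
        p = params(rho1=0.05, rho2=0.055, K1=6000.0, K2=9000.0,
                   alpha_sr=0.519, alpha_rs=0.576)
        lams = np.linspace(0.0, 0.1, 11)
        mat = sweep_outcomes(p, "lam", lams, "alpha_sr", np.array([0.519]), C=1.0)
        row = list(mat[0])
        assert row[0] == "coexistence"
        assert row[-1] == "exclusion_of_sensitive"
        # once the sensitive type is excluded it stays excluded as lam grows;
        # lam*C == rho1 is a transcritical bifurcation flagged as degenerate
        first = row.index("exclusion_of_sensitive")
        assert all(o in ("exclusion_of_sensitive", "degenerate") for o in row[first:])

    def test_single_point_grid_equals_classify(self):
        p = params()
        mat = sweep_outcomes(p, "lam", np.array([0.1]), "alpha_sr", np.array([0.5]), C=1.0)
        assert mat.shape == (1, 1)
        assert mat[0, 0] == classify(p.replace(lam=0.1, alpha_sr=0.5), 1.0).outcome


def test_stable_equilibria_attract_perturbed_starts():
    """Classified stability agrees with long-run integration from 1% - of - K
    perturbations on random parameter sets."""
    rng = np.random.default_rng(12)
    checked = 0
    for _ in range(25):
        p = params(
            rho1=rng.uniform(0.02, 0.5), rho2=rng.uniform(0.02, 0.5),
            K1=rng.uniform(100, 5000), K2=rng.uniform(100, 5000),
            alpha_sr=rng.uniform(0, 2), alpha_rs=rng.uniform(0, 2),
            lam=rng.uniform(0, 0.1),
        )
        C = float(rng.integers(0, 2))
        rep = classify(p, C)
        if rep.outcome == "degenerate":
            continue
        for e in rep.stable():
            eps = 0.01 * max(p.K1, p.K2)
            start = (max(e.S + eps, eps), max(e.R + eps, eps))
            [res] = simulate_to_equilibrium(p, C, [start])
            assert res.converged
            assert res.attractor.kind == e.kind
            checked += 1
    assert checked >= 10


def test_nullclines_lie_on_zero_growth_curves():
    p = params(K1=5000.0, K2=8000.0, alpha_sr=0.519, alpha_rs=0.576, lam=0.02)
    lines = nullclines(p, C=1.0)
    for S, R in lines["sensitive"]:
        if S > 0:
            dS, _ = rhs(p, 1.0, S, R)
            assert abs(dS / S) < 1e-9
    for S, R in lines["resistant"]:
        if R > 0:
            _, dR = rhs(p, 1.0, S, R)
            assert abs(dR / R) < 1e-9
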