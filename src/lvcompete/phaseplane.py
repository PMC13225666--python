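"""Phase-plane analysis of the selected co-culture model.

The selected model is logistic growth with ratio-dependent drug efficacy in
the post-onset constant-dose regime C(t) = C:

    dS/dt = rho1 * (1 - (S + alpha_sr R)/K1) * S - lam*C*S
    dR/dt = rho2 * (1 - (alpha_rs S + R)/K2) * R

Absorbing the kill term into the density dependence gives an effective
sensitive capacity K1_eff = K1 * (1 - lam*C/rho1): the S-nullcline is the
line S + alpha_sr R = K1_eff and the R-nullcline alpha_rs S + R = K2, so
all equilibria are available in closed form and stability follows from the
analytic Jacobian.  Outcomes are the classical two-species competition
labels: coexistence (stable interior), exclusion of either type, or
bistability (both boundary equilibria stable, interior saddle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrate import integrate
from .models import DrugSchedule, ModelSpec, ParameterSet, TrajectoryState

__all__ = [
    "STABILITY_TOL",
    "Equilibrium",
    "EquilibriumReport",
    "UnsupportedModelError",
    "equilibria",
    "jacobian",
    "classify",
    "simulate_to_equilibrium",
    "sweep_outcomes",
    "nullclines",
]

#: absolute tolerance on eigenvalue real parts below which stability is
#: declared marginal (double-precision linear algebra)
STABILITY_TOL = 1e-9

_SELECTED = ("logistic", "ratio_dependent")


class UnsupportedModelError(ValueError):
    """Equilibrium analysis is implemented for logistic + ratio-dependent only."""


def _check_spec(spec: ModelSpec | None) -> None:
    if spec is not None and (spec.growth_law, spec.drug_model) != _SELECTED:
        raise UnsupportedModelError(
            "closed-form phase-plane analysis requires the logistic model "
            "with ratio-dependent drug efficacy"
        )


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium point with (optionally) its local stability."""

    kind: str  # origin | sensitive_only | resistant_only | interior
    S: float
    R: float
    eigenvalues: tuple[complex, complex] | None = None
    stability: str | None = None  # stable | saddle | unstable | marginal


@dataclass
class EquilibriumReport:
    """All equilibria of a parameter set plus the competition outcome."""

    params: ParameterSet
    C: float
    equilibria: list[Equilibrium] = field(default_factory=list)
    outcome: str = ""  # coexistence | exclusion_of_sensitive |
    #                    exclusion_of_resistant | bistable | degenerate

    def get(self, kind: str) -> Equilibrium:
        for e in self.equilibria:
            if e.kind == kind:
                return e
        raise KeyError(kind)

    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "outcome": self.outcome,
            "equilibria": [
                {
                    "kind": e.kind,
                    "S": e.S,
                    "R": e.R,
                    "eigenvalues": None if e.eigenvalues is None else [
                        [ev.real, ev.imag] for ev in e.eigenvalues
                    ],
                    "stability": e.stability,
                }
                for e in self.equilibria
            ],
        }


def _rhs(p: ParameterSet, C: float, S: float, R: float) -> tuple[float, float]:
    dS = p.rho1 * (1.0 - (S + p.alpha_sr * R) / p.K1) * S - p.lam * C * S
    dR = p.rho2 * (1.0 - (p.alpha_rs * S + R) / p.K2) * R
    return dS, dR


def _k1_eff(p: ParameterSet, C: float) -> float:
    return p.K1 * (1.0 - p.lam * C / p.rho1)


def equilibria(p: ParameterSet, C: float = 0.0, spec: ModelSpec | None = None) -> list[Equilibrium]:
    """Equilibrium positions (no stability) of the selected model at dose C.

    Returns the origin, the boundary equilibria that lie in the closed
    positive quadrant, and the interior solution of the linear nullcline
    system when both of its components are positive.  A degenerate nullcline
    determinant (alpha_sr * alpha_rs = 1) suppresses the interior point; the
    degeneracy is reported by :func:`classify`.
    """
    _check_spec(spec)
    out = [Equilibrium("origin", 0.0, 0.0)]
    k1e = _k1_eff(p, C)
    if k1e > 0:
        out.append(Equilibrium("sensitive_only", k1e, 0.0))
    out.append(Equilibrium("resistant_only", 0.0, p.K2))
    det = 1.0 - p.alpha_sr * p.alpha_rs
    if abs(det) > 1e-12:
        S = (k1e - p.alpha_sr * p.K2) / det
        R = (p.K2 - p.alpha_rs * k1e) / det
        if S > 0 and R > 0:
            out.append(Equilibrium("interior", S, R))
    return out


def jacobian(p: ParameterSet, C: float, point: tuple[float, float],
             spec: ModelSpec | None = None) -> np.ndarray:
    """Analytic Jacobian of (dS/dt, dR/dt) with respect to (S, R) at a point."""
    _check_spec(spec)
    S, R = point
    return np.array(
        [
            [
                p.rho1 * (1.0 - (2.0 * S + p.alpha_sr * R) / p.K1) - p.lam * C,
                -p.rho1 * p.alpha_sr * S / p.K1,
            ],
            [
                -p.rho2 * p.alpha_rs * R / p.K2,
                p.rho2 * (1.0 - (p.alpha_rs * S + 2.0 * R) / p.K2),
            ],
        ]
    )


def _stability(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) <= STABILITY_TOL):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def classify(p: ParameterSet, C: float = 0.0, spec: ModelSpec | None = None) -> EquilibriumReport:
    """Full equilibrium report: positions, eigenvalues, stability, outcome.

    The outcome follows from the stable set: a stable interior equilibrium is
    coexistence; a single stable boundary equilibrium excludes the other
    population; two stable boundary equilibria mean bistability.  Degenerate
    nullclines or marginal eigenvalues are labeled ``degenerate`` rather than
    silently classified.
    """
    _check_spec(spec)
    report = EquilibriumReport(params=p, C=C)
    degenerate_det = abs(1.0 - p.alpha_sr * p.alpha_rs) <= 1e-12
    eqs = []
    for e in equilibria(p, C):
        J = jacobian(p, C, (e.S, e.R))
        eigs = np.linalg.eigvals(J)
        eqs.append(
            Equilibrium(e.kind, e.S, e.R,
                        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
                        stability=_stability(eigs))
        )
    report.equilibria = eqs

    if degenerate_det:
        report.outcome = "degenerate"
        return report
    if any(e.stability == "marginal" for e in eqs):
        report.outcome = "degenerate"
        return report

    stable = {e.kind for e in eqs if e.stability == "stable"}
    if "interior" in stable:
        report.outcome = "coexistence"
    elif "sensitive_only" in stable and "resistant_only" in stable:
        report.outcome = "bistable"
    elif "resistant_only" in stable:
        report.outcome = "exclusion_of_sensitive"
    elif "sensitive_only" in stable:
        report.outcome = "exclusion_of_resistant"
    else:
        report.outcome = "degenerate"
    return report


@dataclass
class AttractorResult:
    """Long-run integration from one initial state."""

    init: tuple[float, float]
    final: tuple[float, float]
    attractor: Equilibrium | None
    converged: bool
    t_end: float
    path: np.ndarray  # (n_blocks+1, 3): t, S, R at block endpoints


def simulate_to_equilibrium(
    p: ParameterSet,
    C: float,
    inits: list[tuple[float, float]],
    spec: ModelSpec | None = None,
    block_h: float = 100.0,
    tol: float = 1e-8,
    t_max: float = 1e5,
    rtol: float = 1e-10,
) -> list[AttractorResult]:
    """Integrate each initial state until the flow stalls, then match it to
    the nearest classified equilibrium.

    Convergence is declared when the relative state change over a 100 h block
    drops below ``tol``; failure to converge by ``t_max`` is flagged.
    """
    _check_spec(spec)
    model = ModelSpec(growth_law="logistic", drug_model="ratio_dependent", variant=None)
    schedule = DrugSchedule(drug_present=C > 0, onset_h=0.0, dose=C)
    report = classify(p, C)
    results = []
    for S0, R0 in inits:
        if S0 < 0 or R0 < 0:
            raise ValueError("initial states must lie in the closed positive quadrant")
        t = 0.0
        state = (float(S0), float(R0))
        path = [(t, *state)]
        converged = False
        while t < t_max:
            times = np.array([t, t + block_h])
            traj = integrate(model, p, TrajectoryState(state[0], state[1], t),
                             times, schedule, rtol=rtol, atol=1e-12)
            new = (float(traj.S[-1]), float(traj.R[-1]))
            scale = max(abs(new[0]), abs(new[1]), 1.0)
            change = max(abs(new[0] - state[0]), abs(new[1] - state[1])) / scale
            state = new
            t += block_h
            path.append((t, *state))
            if change < tol:
                converged = True
                break
        nearest = None
        if report.equilibria:
            dists = [np.hypot(e.S - state[0], e.R - state[1]) for e in report.equilibria]
            nearest = report.equilibria[int(np.argmin(dists))]
        results.append(
            AttractorResult(init=(S0, R0), final=state, attractor=nearest,
                            converged=converged, t_end=t, path=np.array(path))
        )
    return results


def sweep_outcomes(
    p_base: ParameterSet,
    param_x: str,
    values_x: np.ndarray,
    param_y: str,
    values_y: np.ndarray,
    C: float = 1.0,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Outcome label matrix over a 2-d parameter grid.

    Rows follow ``values_y``, columns ``values_x`` (matrix indexing
    ``out[i, j]`` = outcome at ``(values_y[i], values_x[j])``).  Typically
    used for the (lam, alpha_sr) coexistence map at constant post-onset dose.
    """
    _check_spec(spec)
    values_x = np.atleast_1d(np.asarray(values_x, dtype=float))
    values_y = np.atleast_1d(np.asarray(values_y, dtype=float))
    out = np.empty((len(values_y), len(values_x)), dtype=object)
    for i, vy in enumerate(values_y):
        for j, vx in enumerate(values_x):
            p = p_base.replace(**{param_x: float(vx), param_y: float(vy)})
            out[i, j] = classify(p, C).outcome
    return out


def nullclines(p: ParameterSet, C: float = 0.0, n: int = 200,
               spec: ModelSpec | None = None) -> dict[str, np.ndarray]:
    """Nontrivial nullcline polylines as (n, 2) arrays of (S, R) points.

    The S-nullcline is S + alpha_sr R = K1_eff, the R-nullcline
    alpha_rs S + R = K2, both clipped to the positive quadrant.
    """
    _check_spec(spec)
    k1e = _k1_eff(p, C)
    out: dict[str, np.ndarray] = {}
    s_max = max(k1e, p.K2 / p.alpha_rs if p.alpha_rs > 0 else p.K2, 1.0)
    S = np.linspace(0.0, s_max, n)
    if p.alpha_sr > 0:
        R = (k1e - S) / p.alpha_sr
        mask = R >= 0
        out["sensitive"] = np.column_stack([S[mask], R[mask]])
    else:
        R = np.linspace(0.0, p.K2 * 1.5, n)
        out["sensitive"] = np.column_stack([np.full(n, k1e), R])
    Rr = p.K2 - p.alpha_rs * S
    mask = Rr >= 0
    out["resistant"] = np.column_stack([S[mask], Rr[mask]])
    return out
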