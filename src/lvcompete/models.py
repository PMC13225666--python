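"""Two-population tumor growth laws, drug-efficacy terms, and the model family.

The core object of study is a pair of competing cell populations — drug-sensitive
S(t) and drug-resistant R(t) — growing in a shared well.  Density dependence
enters through carrying capacities K1, K2; frequency dependence through the
competition coefficients alpha_sr (effect of resistant on sensitive) and
alpha_rs (effect of sensitive on resistant); drug pressure through a constant
post-onset concentration C(t) acting on the sensitive population only, scaled
by the efficacy parameter lam.

Three growth laws are supported (logistic, Gompertz, von Bertalanffy with the
classic 1/3 exponent) and three drug-efficacy terms:

* ``norton_simon``     — multiplies the sensitive growth term by (1 - lam*C),
  i.e. kill rate proportional to growth rate;
* ``linear``           — density-independent subtractive kill, -lam*C;
* ``ratio_dependent``  — subtractive kill proportional to the sensitive
  population, -lam*C*S.

A :class:`ModelSpec` names a growth law, a drug model and a parameter-sharing
variant; :func:`enumerate_model_family` produces the fifteen stepwise variants
(five sharing patterns per growth law) used for model comparison, and
:func:`monoculture_models` the two one-population models used to seed the
staged fitting protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping

__all__ = [
    "GROWTH_LAWS",
    "DRUG_MODELS",
    "PARAM_NAMES",
    "ParameterSet",
    "DrugSchedule",
    "ModelSpec",
    "TrajectoryState",
    "drug_concentration",
    "two_population_rhs",
    "rhs_logistic",
    "rhs_gompertz",
    "rhs_von_bertalanffy",
    "rhs_drug_term",
    "enumerate_model_family",
    "monoculture_models",
]

GROWTH_LAWS = ("logistic", "gompertz", "von_bertalanffy")
DRUG_MODELS = ("norton_simon", "linear", "ratio_dependent")

#: the seven parameters of the fully general two-population model
PARAM_NAMES = ("rho1", "rho2", "K1", "K2", "alpha_sr", "alpha_rs", "lam")

# floor on the Gompertz log argument, as a fraction of K: keeps ln(K/x) finite
# as populations approach zero; the RHS is multiplied by the population so the
# product still vanishes at extinction.
GOMPERTZ_FLOOR_FRAC = 1e-12


class ConfigurationError(ValueError):
    """An inconsistent model configuration (unknown label, missing entry)."""


@dataclass(frozen=True)
class ParameterSet:
    """The seven parameters of the two-population competition model.

    Parameters
    ----------
    rho1, rho2
        Intrinsic growth rates of sensitive / resistant cells (1/h).
    K1, K2
        Carrying capacities (fluorescence a.u.).
    alpha_sr
        Per-capita effect of resistant cells on the sensitive population's
        density dependence (dimensionless).
    alpha_rs
        Per-capita effect of sensitive cells on the resistant population
        (dimensionless).
    lam
        Drug efficacy: a dimensionless multiplier for the Norton-Simon term,
        a rate per unit dose for the subtractive terms.
    """

    rho1: float
    rho2: float
    K1: float
    K2: float
    alpha_sr: float = 1.0
    alpha_rs: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho1", "rho2", "K1", "K2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("alpha_sr", "alpha_rs", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DrugSchedule:
    """A single constant dose switched on at ``onset_h`` (right-continuous)."""

    drug_present: bool = False
    onset_h: float = 20.0
    dose: float = 1.0

    def concentration(self, t: float) -> float:
        return drug_concentration(t, self)


@dataclass(frozen=True)
class TrajectoryState:
    """Instantaneous state of a well: populations (a.u.) and time (h)."""

    S: float
    R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.R < 0:
            raise ValueError("populations must be nonnegative")


def drug_concentration(t: float, schedule: DrugSchedule) -> float:
    """Drug level at time ``t`` (h): 0 before onset, ``dose`` thereafter.

    Right-continuous at the onset time; identically 0 when the schedule has
    no drug.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t!r}")
    if not schedule.drug_present:
        return 0.0
    return schedule.dose if t >= schedule.onset_h else 0.0


def _growth_terms(growth_law: str, S: float, R: float, p: ParameterSet) -> tuple[float, float]:
    """Drug-free derivative (dS/dt, dR/dt) of the chosen growth law."""
    if growth_law == "logistic":
        dS = p.rho1 * (1.0 - (S + p.alpha_sr * R) / p.K1) * S
        dR = p.rho2 * (1.0 - (p.alpha_rs * S + R) / p.K2) * R
    elif growth_law == "gompertz":
        xS = max(S + p.alpha_sr * R, GOMPERTZ_FLOOR_FRAC * p.K1)
        xR = max(p.alpha_rs * S + R, GOMPERTZ_FLOOR_FRAC * p.K2)
        dS = p.rho1 * math.log(p.K1 / xS) * S
        dR = p.rho2 * math.log(p.K2 / xR) * R
    elif growth_law == "von_bertalanffy":
        # cube root applied to the full density quotient so S = K1 (R = 0)
        # remains the carrying-capacity equilibrium, as in the other laws
        dS = p.rho1 * (1.0 - ((S + p.alpha_sr * R) / p.K1) ** (1.0 / 3.0)) * S ** (2.0 / 3.0)
        dR = p.rho2 * (1.0 - ((p.alpha_rs * S + R) / p.K2) ** (1.0 / 3.0)) * R ** (2.0 / 3.0)
    else:
        raise ConfigurationError(f"unknown growth law {growth_law!r}")
    return dS, dR


def rhs_drug_term(drug_model: str, growth_term: float, S: float, C: float, lam: float) -> float:
    """Sensitive-population derivative after applying the drug-efficacy term.

    ``growth_term`` is the drug-free dS/dt of the growth law.  The drug acts
    on the sensitive equation only.
    """
    if drug_model == "norton_simon":
        return growth_term * (1.0 - lam * C)
    if drug_model == "linear":
        return growth_term - lam * C
    if drug_model == "ratio_dependent":
        return growth_term - lam * C * S
    raise ConfigurationError(f"unknown drug model {drug_model!r}")


def two_population_rhs(
    growth_law: str,
    drug_model: str,
    S: float,
    R: float,
    C: float,
    p: ParameterSet,
) -> tuple[float, float]:
    """(dS/dt, dR/dt) for the given growth law and drug-efficacy term.

    Populations are floored at zero before evaluation and extinction is
    absorbing: a nonpositive population with a negative derivative is held
    at zero (the linear kill term would otherwise drive S negative).
    """
    S = max(S, 0.0)
    R = max(R, 0.0)
    dS0, dR = _growth_terms(growth_law, S, R, p)
    dS = rhs_drug_term(drug_model, dS0, S, C, p.lam)
    if S <= 0.0 and dS < 0.0:
        dS = 0.0
    if R <= 0.0 and dR < 0.0:
        dR = 0.0
    return dS, dR


def rhs_logistic(state: TrajectoryState, p: ParameterSet, C: float, spec: "ModelSpec") -> tuple[float, float]:
    if spec.growth_law != "logistic":
        raise ConfigurationError("spec.growth_law must be 'logistic'")
    return two_population_rhs("logistic", spec.drug_model, state.S, state.R, C, p)


def rhs_gompertz(state: TrajectoryState, p: ParameterSet, C: float, spec: "ModelSpec") -> tuple[float, float]:
    if spec.growth_law != "gompertz":
        raise ConfigurationError("spec.growth_law must be 'gompertz'")
    return two_population_rhs("gompertz", spec.drug_model, state.S, state.R, C, p)


def rhs_von_bertalanffy(state: TrajectoryState, p: ParameterSet, C: float, spec: "ModelSpec") -> tuple[float, float]:
    if spec.growth_law != "von_bertalanffy":
        raise ConfigurationError("spec.growth_law must be 'von_bertalanffy'")
    return two_population_rhs("von_bertalanffy", spec.drug_model, state.S, state.R, C, p)


# ---------------------------------------------------------------------------
# model specifications

_VARIANT_FREE = {
    1: ("rho", "K"),
    2: ("rho1", "rho2", "K"),
    3: ("rho", "K", "alpha_sr"),
    4: ("rho", "K", "alpha_rs"),
    5: ("rho", "K", "alpha_sr", "alpha_rs"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A growth law × drug-efficacy term × parameter-sharing variant.

    ``variant`` encodes the stepwise sharing pattern used for model
    comparison:

    1. shared rho, shared K, both alphas fixed at 1
    2. distinct rho1 != rho2, shared K, alphas fixed at 1
    3. shared rho and K, alpha_sr free, alpha_rs fixed at 1
    4. shared rho and K, alpha_rs free, alpha_sr fixed at 1
    5. shared rho and K, both alphas free

    ``variant=None`` is the unconstrained model with all seven parameters
    distinct, used by the staged protocol.  ``population`` restricts the
    model to a single channel for monoculture fits ("sensitive" carries the
    drug term, "resistant" never does).
    """

    growth_law: str = "logistic"
    drug_model: str = "ratio_dependent"
    variant: int | None = None
    population: str = "both"

    def __post_init__(self) -> None:
        if self.growth_law not in GROWTH_LAWS:
            raise ConfigurationError(f"unknown growth law {self.growth_law!r}")
        if self.drug_model not in DRUG_MODELS:
            raise ConfigurationError(f"unknown drug model {self.drug_model!r}")
        if self.variant is not None and self.variant not in _VARIANT_FREE:
            raise ConfigurationError(f"variant must be 1..5 or None, got {self.variant!r}")
        if self.population not in ("both", "sensitive", "resistant"):
            raise ConfigurationError(f"unknown population {self.population!r}")
        if self.population != "both" and self.variant is not None:
            raise ConfigurationError("sharing variants apply only to two-population models")

    # -- free-parameter bookkeeping -------------------------------------

    def free_params(self, drug_present: bool) -> tuple[str, ...]:
        """Ordered names of the parameters this spec leaves free to fit.

        ``lam`` is free only when the drug is present and the spec models the
        sensitive population (the resistant equation never carries a drug
        term).
        """
        if self.variant is not None:
            names = _VARIANT_FREE[self.variant]
        elif self.population == "sensitive":
            names = ("rho1", "K1")
        elif self.population == "resistant":
            return ("rho2", "K2")
        else:
            names = ("rho1", "rho2", "K1", "K2", "alpha_sr", "alpha_rs")
        if drug_present:
            names = names + ("lam",)
        return names

    def build_parameters(self, values: Mapping[str, float]) -> ParameterSet:
        """Resolve shared/fixed parameters into a full :class:`ParameterSet`.

        ``values`` maps free (and optionally fixed) parameter names — shared
        names ``rho``/``K`` are accepted for the tied variants — to values.
        Monoculture specs decouple the unused channel (alphas set to 0 and
        neutral placeholders for the absent population's rho/K).
        """
        v = dict(values)
        out: dict[str, float] = {}
        if "rho" in v:
            out["rho1"] = out["rho2"] = v.pop("rho")
        if "K" in v:
            out["K1"] = out["K2"] = v.pop("K")
        for name, val in v.items():
            if name not in PARAM_NAMES:
                raise ConfigurationError(f"unknown parameter {name!r}")
            out[name] = val
        if self.variant in (1, 2):
            out.setdefault("alpha_sr", 1.0)
            out.setdefault("alpha_rs", 1.0)
        elif self.variant == 3:
            out.setdefault("alpha_rs", 1.0)
        elif self.variant == 4:
            out.setdefault("alpha_sr", 1.0)
        if self.population != "both":
            out["alpha_sr"] = 0.0
            out["alpha_rs"] = 0.0
            if self.population == "sensitive":
                out.setdefault("rho2", 1.0)
                out.setdefault("K2", 1.0)
            else:
                out.setdefault("rho1", 1.0)
                out.setdefault("K1", 1.0)
                out.setdefault("lam", 0.0)
        out.setdefault("lam", 0.0)
        missing = [n for n in PARAM_NAMES if n not in out]
        if missing:
            raise ConfigurationError(f"missing parameter values: {missing}")
        return ParameterSet(**out)

    def rhs(self, S: float, R: float, C: float, p: ParameterSet) -> tuple[float, float]:
        return two_population_rhs(self.growth_law, self.drug_model, S, R, C, p)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        d: dict[str, object] = {
            "growth_law": self.growth_law,
            "drug_model": self.drug_model,
            "variant": self.variant,
        }
        if self.population != "both":
            d["population"] = self.population
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        return cls(
            growth_law=d["growth_law"],
            drug_model=d["drug_model"],
            variant=d.get("variant"),
            population=d.get("population", "both"),
        )

    def label(self) -> str:
        v = "full" if self.variant is None else str(self.variant)
        tail = "" if self.population == "both" else f":{self.population}"
        return f"{self.growth_law}-{v}{tail}"


def enumerate_model_family(drug_model: str = "norton_simon") -> list[ModelSpec]:
    """The fifteen stepwise two-population models used for model comparison.

    Five parameter-sharing variants applied to each of the three growth laws,
    in deterministic order (logistic 1–5, gompertz 1–5, von_bertalanffy 1–5).
    The growth-law comparison in the source design couples each law with the
    Norton-Simon multiplier; the drug model can be overridden.
    """
    return [
        ModelSpec(growth_law=law, drug_model=drug_model, variant=v)
        for law in GROWTH_LAWS
        for v in sorted(_VARIANT_FREE)
    ]


def monoculture_models() -> tuple[ModelSpec, ModelSpec]:
    """The one-population models used to seed the staged protocol.

    Sensitive: dS/dt = rho1*S*(1 - S/K1) - lam*C*S (logistic growth with a
    ratio-dependent kill term).  Resistant: dR/dt = rho2*R*(1 - R/K2), with
    no drug term at all.
    """
    sensitive = ModelSpec(growth_law="logistic", drug_model="ratio_dependent",
                          variant=None, population="sensitive")
    resistant = ModelSpec(growth_law="logistic", drug_model="ratio_dependent",
                          variant=None, population="resistant")
    return sensitive, resistant
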