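"""Synthetic microplate generator emulating the co-culture competition assay.

The emulated experiment follows two fluorescently labeled NSCLC lines —
drug-sensitive (GFP channel) and Alectinib-resistant (mCherry channel) —
across four environments (DMSO control, CAF co-culture, drug, CAF+drug),
eight seeding ratios of sensitive to total, six replicates per cell, with
fluorescence read every 4 h from 0 to 120 h and a single constant drug dose
introduced at 20 h.

Wells are simulated by integrating a ground-truth model per environment from
a lognormally dispersed initial total population split by the seeding ratio,
then applying per-channel gain and multiplicative lognormal measurement
noise.  Everything is reproducible from the design's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .integrate import integrate
from .models import (
    ConfigurationError,
    DrugSchedule,
    ModelSpec,
    ParameterSet,
    TrajectoryState,
)

__all__ = [
    "ENVIRONMENTS",
    "PlateDesign",
    "WellRecord",
    "environment_flags",
    "environment_label",
    "default_truth",
    "generate_plate",
]

ENVIRONMENTS = ("DMSO", "CAF", "DRUG", "CAF+DRUG")

_ENV_FLAGS = {
    "DMSO": (False, False),
    "CAF": (True, False),
    "DRUG": (False, True),
    "CAF+DRUG": (True, True),
}


def environment_flags(env: str) -> tuple[bool, bool]:
    """(caf_present, drug_present) for an environment label."""
    try:
        return _ENV_FLAGS[env]
    except KeyError:
        raise ConfigurationError(f"unknown environment {env!r}") from None


def environment_label(caf: bool, drug: bool) -> str:
    for name, flags in _ENV_FLAGS.items():
        if flags == (bool(caf), bool(drug)):
            return name
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class WellRecord:
    """One well's measured two-channel time series plus design metadata."""

    well_id: str
    caf: bool
    drug: bool
    seeding_ratio: float
    replicate: int
    times: np.ndarray
    sensitive: np.ndarray
    resistant: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "sensitive", np.asarray(self.sensitive, dtype=float))
        object.__setattr__(self, "resistant", np.asarray(self.resistant, dtype=float))
        n = len(self.times)
        if len(self.sensitive) != n or len(self.resistant) != n:
            raise ValueError("channel series must match the time grid length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("sensitive", "resistant"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} intensities must be finite and nonnegative")
        if not 0.0 <= self.seeding_ratio <= 1.0:
            raise ValueError("seeding_ratio must lie in [0, 1]")

    @property
    def environment(self) -> str:
        return environment_label(self.caf, self.drug)

    def channel(self, name: str) -> np.ndarray:
        if name == "sensitive":
            return self.sensitive
        if name == "resistant":
            return self.resistant
        raise KeyError(name)

    def values_at(self, grid: np.ndarray, channel: str) -> np.ndarray:
        """Measured intensities at the requested times (must all be sampled)."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid)
        ok = (idx < len(self.times)) & np.isclose(self.times[np.minimum(idx, len(self.times) - 1)], grid)
        if not ok.all():
            missing = grid[~ok]
            raise ValueError(f"well {self.well_id} does not sample times {missing}")
        return self.channel(channel)[idx]


@dataclass(frozen=True)
class PlateDesign:
    """Design of the synthetic plate; defaults mirror the emulated assay."""

    environments: tuple[str, ...] = ENVIRONMENTS
    seeding_ratios: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0)
    replicates: int = 6
    sample_times: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 4))
    drug_onset_h: float = 20.0
    dose: float = 1.0
    init_total_mean: float = 500.0
    init_total_cv: float = 0.2
    noise_sigma: float = 0.05
    gain_sensitive: float = 1.0
    gain_resistant: float = 1.0
    noise_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for env in self.environments:
            environment_flags(env)
        if any(not 0.0 <= r <= 1.0 for r in self.seeding_ratios):
            raise ValueError("seeding ratios must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")


# Ground-truth defaults.  Competition coefficients are the drug-stratified
# co-culture medians reported for this assay (alpha_rs 0.576 / 2.144 and
# alpha_sr 0.519 / 0.961 without / with drug).  Growth rates, carrying
# capacities and drug efficacies are not printed for the original data, so
# the defaults are chosen to be realistic for these cell lines: doubling
# times near 14 h, resistant carrying capacity above the sensitive one, and
# drug kill rates exceeding the sensitive growth rate so drug wells decline
# within the 120 h window, with CAFs attenuating the kill rate.
_TRUTH_DEFAULTS = dict(rho1=0.05, rho2=0.055, K1=6000.0, K2=9000.0)
_ALPHA_NO_DRUG = dict(alpha_sr=0.519, alpha_rs=0.576)
_ALPHA_DRUG = dict(alpha_sr=0.961, alpha_rs=2.144)
_LAM_BY_ENV = {"DMSO": 0.0, "CAF": 0.0, "DRUG": 0.09, "CAF+DRUG": 0.06}


def default_truth(**overrides: float) -> dict[str, tuple[ModelSpec, ParameterSet]]:
    """Ground truth per environment: logistic growth, ratio-dependent kill.

    Keyword overrides replace the shared growth defaults (``rho1``, ``rho2``,
    ``K1``, ``K2``) in every environment.
    """
    base = {**_TRUTH_DEFAULTS, **overrides}
    spec = ModelSpec(growth_law="logistic", drug_model="ratio_dependent", variant=None)
    truth = {}
    for env in ENVIRONMENTS:
        _, drug = environment_flags(env)
        alphas = _ALPHA_DRUG if drug else _ALPHA_NO_DRUG
        truth[env] = (spec, ParameterSet(**base, **alphas, lam=_LAM_BY_ENV[env]))
    return truth


def generate_plate(
    design: PlateDesign,
    truth: Mapping[str, tuple[ModelSpec, ParameterSet]] | None = None,
    rtol: float = 1e-8,
) -> list[WellRecord]:
    """Simulate every well of the design under the given ground truth.

    For each environment × seeding ratio × replicate the initial total
    population is drawn lognormally around ``init_total_mean`` (the mean of
    the distribution, with coefficient of variation ``init_total_cv``), split
    by the seeding ratio, integrated under the environment's truth model,
    and measured with per-channel gain and multiplicative lognormal noise
    ``exp(sigma * Z)`` plus an optional additive noise floor.
    """
    truth = default_truth() if truth is None else truth
    for env in design.environments:
        if env not in truth:
            raise ConfigurationError(f"no ground truth for environment {env!r}")

    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sample_times, dtype=float)
    cv = design.init_total_cv
    sigma0 = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    wells: list[WellRecord] = []
    for env in design.environments:
        caf, drug = environment_flags(env)
        spec, params = truth[env]
        schedule = DrugSchedule(drug_present=drug, onset_h=design.drug_onset_h, dose=design.dose)
        for ratio in design.seeding_ratios:
            for rep in range(design.replicates):
                # mean-preserving lognormal draw of the initial total
                n0 = design.init_total_mean * math.exp(
                    sigma0 * rng.standard_normal() - 0.5 * sigma0 * sigma0
                )
                s0, r0 = ratio * n0, (1.0 - ratio) * n0
                traj = integrate(
                    spec, params, TrajectoryState(S=s0, R=r0, t=times[0]),
                    times, schedule, rtol=rtol,
                )
                noise_s = np.exp(design.noise_sigma * rng.standard_normal(len(times)))
                noise_r = np.exp(design.noise_sigma * rng.standard_normal(len(times)))
                meas_s = design.gain_sensitive * traj.S * noise_s + design.noise_floor
                meas_r = design.gain_resistant * traj.R * noise_r + design.noise_floor
                wells.append(
                    WellRecord(
                        well_id=f"{env}_r{ratio:g}_rep{rep}",
                        caf=caf,
                        drug=drug,
                        seeding_ratio=float(ratio),
                        replicate=rep,
                        times=times,
                        sensitive=meas_s,
                        resistant=meas_r,
                    )
                )
    return wells
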