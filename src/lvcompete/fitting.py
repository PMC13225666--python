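"""Weighted least-squares fitting, model comparison, and the staged protocol.

Each well is fit independently by minimizing the weighted cost

    J_w = sum_{i in {S,R}} sum_{t in {12,16,...,116}}
          ((d_it_measured - d_it_model) / max_t d_i_measured)^2,

where each channel's residuals are normalized by that channel's maximum
measured intensity so that the minority population is not swamped.  A channel
whose measured maximum is zero (the unseeded channel of a monoculture) is
excluded from the sum and from the data-point count N.  The chi-square error
is identified with J_w, and AIC = N*ln(chi2/N) + 2*N_varys.

The initial ODE state is pinned to the measured values at t = 12 h (the first
12 h let cells settle), so only model parameters are optimized.  Optimization
is bounded multi-start local least squares with starts drawn log-uniformly
within the bounds from a seeded generator; results are deterministic given
the seed.

Three higher-level analyses are built on the per-well fit:

* :func:`compare_growth_models` — the fifteen-model comparison table
  (median chi-square and AIC per growth law × sharing variant);
* :func:`compare_drug_models` — Norton-Simon vs linear vs ratio-dependent
  drug efficacy on drug-treated sensitive monocultures;
* :func:`run_staged_protocol` — monoculture medians (rho, K) → drug efficacy
  medians by CAF status → per-well competition coefficients, the only free
  parameters in co-culture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .integrate import IntegrationError, Trajectory, integrate
from .models import (
    DRUG_MODELS,
    DrugSchedule,
    ModelSpec,
    ParameterSet,
    TrajectoryState,
    monoculture_models,
    enumerate_model_family,
)
from .plates import WellRecord

__all__ = [
    "FIT_GRID",
    "DEFAULT_BOUNDS",
    "FitResult",
    "StagedEstimates",
    "StagedProtocolError",
    "GrowthCurveFit",
    "weighted_cost",
    "chi_square",
    "aic",
    "fit_well",
    "compare_growth_models",
    "compare_drug_models",
    "run_staged_protocol",
]

#: the fit grid: every 4 h from 12 h to 116 h inclusive (27 points)
FIT_GRID = np.arange(12.0, 117.0, 4.0)

#: default optimizer bounds by parameter class — generous, strictly positive
#: for rates and capacities, covering competition coefficients above 2
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rho": (1e-3, 2.0),
    "K": (10.0, 1e6),
    "alpha": (0.0, 10.0),
    "lam": (0.0, 10.0),
}

_PENALTY = 1e3  # residual magnitude assigned when integration fails


class StagedProtocolError(RuntimeError):
    """A stage of the protocol has no usable wells."""


def _bounds_for(name: str) -> tuple[float, float]:
    if name.startswith("rho"):
        return DEFAULT_BOUNDS["rho"]
    if name.startswith("K"):
        return DEFAULT_BOUNDS["K"]
    if name.startswith("alpha"):
        return DEFAULT_BOUNDS["alpha"]
    if name == "lam":
        return DEFAULT_BOUNDS["lam"]
    raise KeyError(name)


@dataclass
class FitResult:
    """A per-well optimization result with goodness-of-fit measures."""

    spec: ModelSpec
    params: ParameterSet
    free_names: tuple[str, ...]
    fixed: dict[str, float]
    jw: float
    chi2: float
    aic: float
    n_points: int
    n_varys: int
    converged: bool
    n_starts: int
    best_start: int
    start_spread: float  # max - min cost over converged starts
    well_id: str = ""
    message: str = ""

    def free_values(self) -> dict[str, float]:
        d = self.params.as_dict()
        out = {}
        for name in self.free_names:
            if name == "rho":
                out[name] = d["rho1"]
            elif name == "K":
                out[name] = d["K1"]
            else:
                out[name] = d[name]
        return out

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "spec": self.spec.to_json(),
            "params": self.params.as_dict(),
            "free": list(self.free_names),
            "fixed": self.fixed,
            "jw": self.jw,
            "chi2": self.chi2,
            "aic": self.aic,
            "n_points": self.n_points,
            "n_varys": self.n_varys,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_start": self.best_start,
            "start_spread": self.start_spread,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# cost and information criteria


def _channel_weights(well: WellRecord, grid: np.ndarray) -> dict[str, float]:
    """Per-channel normalizers max_t d_i_measured on the fit grid (0 ⇒ excluded)."""
    return {
        ch: float(np.max(well.values_at(grid, ch))) for ch in ("sensitive", "resistant")
    }


def weighted_cost(well: WellRecord, traj: Trajectory, grid: np.ndarray | None = None) -> float:
    """The weighted sum of squared errors J_w between a well and a trajectory.

    Both must cover the fit grid.  Channels with zero measured maximum are
    excluded.
    """
    grid = FIT_GRID if grid is None else np.asarray(grid, dtype=float)
    idx = np.searchsorted(traj.times, grid)
    ok = (idx < len(traj.times)) & np.isclose(traj.times[np.minimum(idx, len(traj.times) - 1)], grid)
    if not ok.all():
        raise ValueError("trajectory does not cover the fit grid")
    total = 0.0
    weights = _channel_weights(well, grid)
    for ch, w in weights.items():
        if w <= 0:
            continue
        meas = well.values_at(grid, ch)
        model = traj.channel(ch)[idx]
        total += float(np.sum(((meas - model) / w) ** 2))
    return total


def chi_square(jw: float, convention: str = "identity") -> float:
    """Chi-square error from the weighted cost.

    The default identifies chi2 with J_w; ``convention='sqrt'`` is provided
    for comparison with the alternative reading chi2 = sqrt(J_w).
    """
    if convention == "identity":
        return jw
    if convention == "sqrt":
        return math.sqrt(jw)
    raise ValueError(f"unknown convention {convention!r}")


def aic(chi2: float, n: int, n_varys: int) -> float:
    """Akaike information criterion: N*ln(chi2/N) + 2*N_varys."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    if chi2 == 0:
        warnings.warn("chi2 is exactly 0 (perfect fit); AIC is -inf", RuntimeWarning)
        return float("-inf")
    return n * math.log(chi2 / n) + 2 * n_varys


# ---------------------------------------------------------------------------
# per-well fit


def _fit_series(
    times: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    drug_present: bool,
    fixed: Mapping[str, float] | None,
    bounds: Mapping[str, tuple[float, float]] | None,
    n_starts: int,
    seed: int,
    onset_h: float,
    dose: float,
    rtol: float,
    well_id: str = "",
) -> FitResult:
    """Core multi-start bounded least-squares fit on a two-channel series."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (len(times), 2):
        raise ValueError("y must have shape (n_times, 2): sensitive, resistant")

    grid = FIT_GRID
    idx = np.searchsorted(times, grid)
    ok = (idx < len(times)) & np.isclose(times[np.minimum(idx, len(times) - 1)], grid)
    if not ok.all():
        raise ValueError("series does not cover the fit grid 12..116 h")
    meas = y[idx]  # (27, 2)

    weights = np.max(meas, axis=0)  # per-channel max over the fit grid
    include = weights > 0
    if not include.any():
        raise ValueError("both channels have zero measured maximum")
    n_points = int(27 * include.sum())

    fixed = dict(fixed or {})
    free = tuple(n for n in spec.free_params(drug_present) if n not in fixed)
    schedule = DrugSchedule(drug_present=drug_present, onset_h=onset_h, dose=dose)
    init = TrajectoryState(S=float(meas[0, 0]), R=float(meas[0, 1]), t=float(grid[0]))

    bmap = dict(bounds or {})
    lo = np.array([bmap.get(n, _bounds_for(n))[0] for n in free])
    hi = np.array([bmap.get(n, _bounds_for(n))[1] for n in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        values = {**fixed, **dict(zip(free, x))}
        try:
            p = spec.build_parameters(values)
            traj = integrate(spec, p, init, grid, schedule, rtol=rtol)
        except (IntegrationError, ValueError):
            return np.full(n_points, _PENALTY)
        model = np.column_stack([traj.S, traj.R])
        r = (meas[:, include] - model[:, include]) / weights[include]
        return r.ravel()

    if not free:
        r = residuals(np.empty(0))
        jw = float(np.sum(r**2))
        c2 = chi_square(jw)
        return FitResult(
            spec=spec, params=spec.build_parameters(fixed), free_names=free,
            fixed=dict(fixed), jw=jw, chi2=c2,
            aic=aic(c2, n_points, 0) if c2 > 0 else float("-inf"),
            n_points=n_points, n_varys=0, converged=True, n_starts=0,
            best_start=-1, start_spread=0.0, well_id=well_id,
        )

    # log-uniform starts within the bounds (zero lower bounds floored)
    rng = np.random.default_rng(seed)
    lo_s = np.maximum(lo, 1e-3)
    starts = np.exp(rng.uniform(np.log(lo_s), np.log(hi), size=(max(n_starts, 1), len(free))))

    best = None
    best_idx = -1
    costs = []
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
            )
        except Exception:  # numerical failure of a single start is tolerated
            continue
        cost = float(np.sum(sol.fun**2))
        costs.append(cost)
        if best is None or cost < best_cost:
            best, best_cost, best_idx = sol, cost, i

    if best is None:
        params = spec.build_parameters({**fixed, **dict(zip(free, starts[0]))})
        return FitResult(
            spec=spec, params=params, free_names=free, fixed=dict(fixed),
            jw=float("nan"), chi2=float("nan"), aic=float("nan"),
            n_points=n_points, n_varys=len(free), converged=False,
            n_starts=len(starts), best_start=-1, start_spread=float("nan"),
            well_id=well_id, message="all starts failed",
        )

    params = spec.build_parameters({**fixed, **dict(zip(free, best.x))})
    jw = best_cost
    c2 = chi_square(jw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = aic(c2, n_points, len(free))
    return FitResult(
        spec=spec, params=params, free_names=free, fixed=dict(fixed),
        jw=jw, chi2=c2, aic=a, n_points=n_points, n_varys=len(free),
        converged=bool(best.success), n_starts=len(starts), best_start=best_idx,
        start_spread=float(max(costs) - min(costs)), well_id=well_id,
        message=str(best.message),
    )


class GrowthCurveFit(BaseEstimator):
    """Scikit-learn style estimator fitting one well's two-channel series.

    ``fit(X, y)`` takes the sample times (h) as ``X`` of shape ``(n,)`` or
    ``(n, 1)`` and the measured intensities as ``y`` of shape ``(n, 2)``
    with columns (sensitive, resistant).  The series must cover the fit grid
    12–116 h at 4 h steps; the state at 12 h seeds the ODE.

    Parameters
    ----------
    spec : ModelSpec
        Growth law, drug model and sharing variant to fit.
    drug_present : bool
        Whether the drug schedule is active for this well.
    fixed : mapping, optional
        Parameter values held fixed (removed from the free set).
    bounds : mapping, optional
        Per-parameter ``(lo, hi)`` overrides of the default bounds.
    n_starts : int
        Number of log-uniform multi-starts.
    random_state : int
        Seed for the start generator.

    Attributes
    ----------
    result_ : FitResult
    params_ : ParameterSet
    jw_, chi2_, aic_ : float
    n_varys_ : int
    converged_ : bool
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        drug_present: bool = False,
        fixed: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        n_starts: int = 20,
        random_state: int = 0,
        onset_h: float = 20.0,
        dose: float = 1.0,
        rtol: float = 1e-7,
    ):
        self.spec = spec
        self.drug_present = drug_present
        self.fixed = fixed
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.onset_h = onset_h
        self.dose = dose
        self.rtol = rtol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        spec = self.spec if self.spec is not None else ModelSpec()
        y = np.asarray(y, dtype=float)
        self.result_ = _fit_series(
            X, y, spec, self.drug_present,
            self.fixed, self.bounds, self.n_starts, self.random_state,
            self.onset_h, self.dose, self.rtol,
        )
        i0 = int(np.argmin(np.abs(X - FIT_GRID[0])))
        self._fit_init = (float(y[i0, 0]), float(y[i0, 1]))
        self.params_ = self.result_.params
        self.jw_ = self.result_.jw
        self.chi2_ = self.result_.chi2
        self.aic_ = self.result_.aic
        self.n_varys_ = self.result_.n_varys
        self.converged_ = self.result_.converged
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        spec = self.result_.spec
        schedule = DrugSchedule(self.drug_present, self.onset_h, self.dose)
        # predict from the fitted parameters, seeding at the measured state
        # that anchored the fit (the 12 h observation)
        init = TrajectoryState(S=self._fit_init[0], R=self._fit_init[1], t=float(X[0]))
        traj = integrate(spec, self.params_, init, X, schedule, rtol=self.rtol)
        return np.column_stack([traj.S, traj.R])


def fit_well(
    well: WellRecord,
    spec: ModelSpec,
    fixed: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    onset_h: float = 20.0,
    dose: float = 1.0,
    rtol: float = 1e-7,
) -> FitResult:
    """Fit one well: bounded multi-start least squares on the weighted cost."""
    y = np.column_stack([well.sensitive, well.resistant])
    return _fit_series(
        well.times, y, spec, well.drug, fixed, bounds, n_starts, seed,
        onset_h, dose, rtol, well_id=well.well_id,
    )


# ---------------------------------------------------------------------------
# model comparison


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def compare_growth_models(
    wells: Sequence[WellRecord],
    seed: int = 0,
    n_starts: int = 5,
    drug_model: str = "norton_simon",
    onset_h: float = 20.0,
) -> pd.DataFrame:
    """Fit all fifteen stepwise models to every well; median chi2/AIC table.

    Returns one row per (growth law, variant) with median chi-square, median
    AIC, the free-parameter counts with and without drug, and the AIC rank
    (ties broken by fewer free parameters).  Non-converged fits become
    missing cells rather than aborting the table.
    """
    if not wells:
        raise ValueError("at least one well is required")
    specs = enumerate_model_family(drug_model=drug_model)
    seeds = _child_seeds(seed, len(specs) * len(wells))
    rows = []
    k = 0
    for s in specs:
        chi2s, aics = [], []
        for w in wells:
            res = fit_well(w, s, n_starts=n_starts, seed=int(seeds[k]), onset_h=onset_h)
            k += 1
            if res.converged and np.isfinite(res.chi2):
                chi2s.append(res.chi2)
                aics.append(res.aic)
        rows.append(
            {
                "growth_law": s.growth_law,
                "variant": s.variant,
                "n_wells": len(wells),
                "n_converged": len(chi2s),
                "median_chi2": float(np.median(chi2s)) if chi2s else float("nan"),
                "median_aic": float(np.median(aics)) if aics else float("nan"),
                "n_free_drug": len(s.free_params(True)),
                "n_free_no_drug": len(s.free_params(False)),
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(["median_aic", "n_free_drug"], kind="mergesort")
    table["aic_rank"] = 0
    table.loc[order.index, "aic_rank"] = np.arange(1, len(table) + 1)
    return table


def compare_drug_models(
    wells: Sequence[WellRecord],
    rho1: float,
    K1: float,
    seed: int = 0,
    n_starts: int = 5,
    onset_h: float = 20.0,
) -> pd.DataFrame:
    """Fit the drug-efficacy term of each candidate kill model per well.

    ``wells`` must be drug-treated sensitive monocultures; ``rho1`` and
    ``K1`` are fixed (staged from drug-free monocultures) so only ``lam``
    is free.  Returns a long table (well × drug model) with chi-square, plus
    the per-model medians accessible by grouping.
    """
    for w in wells:
        if not w.drug:
            raise ValueError(f"well {w.well_id} is not drug-treated")
    seeds = _child_seeds(seed, len(DRUG_MODELS) * len(wells))
    rows = []
    k = 0
    for dm in DRUG_MODELS:
        spec = ModelSpec(growth_law="logistic", drug_model=dm, variant=None,
                         population="sensitive")
        for w in wells:
            res = fit_well(
                w, spec, fixed={"rho1": rho1, "K1": K1},
                n_starts=n_starts, seed=int(seeds[k]), onset_h=onset_h,
            )
            k += 1
            rows.append(
                {
                    "drug_model": dm,
                    "well_id": w.well_id,
                    "caf": w.caf,
                    "chi2": res.chi2 if res.converged else float("nan"),
                    "lam": res.params.lam,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staged protocol


@dataclass
class StagedEstimates:
    """Outputs of the three-stage monoculture → co-culture protocol."""

    growth_medians: dict[str, float]  # rho1, K1, rho2, K2
    lam_by_caf: dict[bool, float]  # CAF status -> median lam (drug wells only)
    alpha_table: pd.DataFrame  # per co-culture well alpha_sr, alpha_rs
    stage1_results: list[FitResult] = field(default_factory=list)
    stage2_results: list[FitResult] = field(default_factory=list)
    stage3_results: list[FitResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def alpha_medians(self, drug: bool) -> dict[str, float]:
        sub = self.alpha_table[self.alpha_table["drug"] == drug]
        return {
            "alpha_sr": float(sub["alpha_sr"].median()),
            "alpha_rs": float(sub["alpha_rs"].median()),
        }


def _is_monoculture(well: WellRecord) -> bool:
    return well.seeding_ratio in (0.0, 1.0)


def run_staged_protocol(
    wells: Sequence[WellRecord],
    seed: int = 0,
    n_starts: int = 5,
    onset_h: float = 20.0,
    dose: float = 1.0,
) -> StagedEstimates:
    """The three-stage fitting protocol.

    Stage 1 fits the one-population logistic models to every drug-free
    monoculture well and pools the medians of (rho1, K1, rho2, K2) across
    DMSO and CAF environments.  Stage 2 fixes those medians and fits the
    drug efficacy ``lam`` per drug-treated sensitive monoculture well,
    taking medians separately by CAF status.  Stage 3 fixes everything and
    fits the competition coefficients (alpha_sr, alpha_rs) per co-culture
    well — the only free parameters in co-culture.
    """
    sens_spec, res_spec = monoculture_models()
    seeds = iter(_child_seeds(seed, 4 * len(wells)))
    notes: list[str] = []

    # stage 1: drug-free monocultures
    stage1: list[FitResult] = []
    rho1s, K1s, rho2s, K2s = [], [], [], []
    for w in wells:
        if w.drug or not _is_monoculture(w):
            continue
        if w.seeding_ratio == 1.0:
            res = fit_well(w, sens_spec, n_starts=n_starts, seed=int(next(seeds)),
                           onset_h=onset_h, dose=dose)
            if res.converged:
                rho1s.append(res.params.rho1)
                K1s.append(res.params.K1)
        else:
            res = fit_well(w, res_spec, n_starts=n_starts, seed=int(next(seeds)),
                           onset_h=onset_h, dose=dose)
            if res.converged:
                rho2s.append(res.params.rho2)
                K2s.append(res.params.K2)
        stage1.append(res)
    if not rho1s or not rho2s:
        raise StagedProtocolError(
            "stage 1 requires drug-free monocultures of both cell types "
            f"(got {len(rho1s)} sensitive, {len(rho2s)} resistant)"
        )
    growth_medians = {
        "rho1": float(np.median(rho1s)),
        "K1": float(np.median(K1s)),
        "rho2": float(np.median(rho2s)),
        "K2": float(np.median(K2s)),
    }

    # stage 2: drug efficacy from drug-treated sensitive monocultures
    stage2: list[FitResult] = []
    lam_vals: dict[bool, list[float]] = {False: [], True: []}
    for w in wells:
        if not (w.drug and w.seeding_ratio == 1.0):
            continue
        res = fit_well(
            w, sens_spec,
            fixed={"rho1": growth_medians["rho1"], "K1": growth_medians["K1"]},
            n_starts=n_starts, seed=int(next(seeds)), onset_h=onset_h, dose=dose,
        )
        stage2.append(res)
        if res.converged:
            lam_vals[w.caf].append(res.params.lam)
    lam_by_caf = {caf: float(np.median(v)) for caf, v in lam_vals.items() if v}
    if not lam_by_caf:
        notes.append("stage 2 empty: no drug-treated sensitive monocultures")

    # stage 3: competition coefficients, the only free co-culture parameters
    stage3: list[FitResult] = []
    rows = []
    for w in wells:
        if _is_monoculture(w):
            continue
        fixed = dict(growth_medians)
        if w.drug:
            if w.caf not in lam_by_caf:
                notes.append(
                    f"no stage-2 lam median for caf={w.caf}; skipping well {w.well_id}"
                )
                continue
            fixed["lam"] = lam_by_caf[w.caf]
        spec = ModelSpec(growth_law="logistic", drug_model="ratio_dependent", variant=None)
        res = fit_well(w, spec, fixed=fixed, n_starts=n_starts,
                       seed=int(next(seeds)), onset_h=onset_h, dose=dose)
        stage3.append(res)
        rows.append(
            {
                "well_id": w.well_id,
                "environment": w.environment,
                "caf": w.caf,
                "drug": w.drug,
                "seeding_ratio": w.seeding_ratio,
                "replicate": w.replicate,
                "alpha_sr": res.params.alpha_sr,
                "alpha_rs": res.params.alpha_rs,
                "jw": res.jw,
                "converged": res.converged,
            }
        )
    alpha_table = pd.DataFrame(
        rows,
        columns=[
            "well_id", "environment", "caf", "drug", "seeding_ratio",
            "replicate", "alpha_sr", "alpha_rs", "jw", "converged",
        ],
    )
    if alpha_table.empty:
        notes.append("stage 3 empty: no co-culture wells")

    return StagedEstimates(
        growth_medians=growth_medians,
        lam_by_caf=lam_by_caf,
        alpha_table=alpha_table,
        stage1_results=stage1,
        stage2_results=stage2,
        stage3_results=stage3,
        warnings=notes,
    )
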