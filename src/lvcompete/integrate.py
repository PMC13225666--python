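"""Deterministic numerical integration of the two-population models.

The drug enters as a right-continuous step in C(t), so integration is split
at the onset time and each segment is solved with a constant drug level —
the adaptive stepper never straddles the discontinuity.  States are clamped
to be nonnegative at segment boundaries and on output (extinction is
absorbing; see :mod:`lvcompete.models`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .models import DrugSchedule, ModelSpec, ParameterSet, TrajectoryState

__all__ = ["Trajectory", "IntegrationError", "integrate"]


@dataclass
class Trajectory:
    """Model-predicted populations on a requested time grid."""

    times: np.ndarray
    S: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not (len(self.times) == len(self.S) == len(self.R)):
            raise ValueError("times, S and R must have equal lengths")

    def channel(self, name: str) -> np.ndarray:
        if name == "sensitive":
            return self.S
        if name == "resistant":
            return self.R
        raise KeyError(name)


class IntegrationError(RuntimeError):
    """Integration failed (stiffness or blow-up); carries the last good time."""

    def __init__(self, message: str, last_good_time: float):
        super().__init__(message)
        self.last_good_time = last_good_time


#: state magnitude treated as divergence; the Norton-Simon term with
#: lam*C > 1 above carrying capacity blows up in finite time, so runaway
#: trajectories are cut off early instead of ground through
BLOWUP_LIMIT = 1e12


def _blowup_event(t: float, y: np.ndarray) -> float:
    return BLOWUP_LIMIT - max(y[0], y[1])


_blowup_event.terminal = True


def integrate(
    spec: ModelSpec,
    p: ParameterSet,
    init: TrajectoryState,
    times: np.ndarray,
    schedule: DrugSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``spec`` with parameters ``p`` and report the state at ``times``.

    ``times`` must be strictly increasing with ``times[0] == init.t``.
    """
    schedule = schedule or DrugSchedule(drug_present=False)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-d array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.isclose(times[0], init.t):
        raise ValueError(f"times[0]={times[0]} must equal init.t={init.t}")

    t0, t_end = float(times[0]), float(times[-1])
    onset = float(schedule.onset_h)

    # segment boundaries: split at the dose onset if it falls inside the span
    if schedule.drug_present and t0 < onset < t_end:
        segments = [(t0, onset, 0.0), (onset, t_end, float(schedule.dose))]
    else:
        c0 = float(schedule.dose) if (schedule.drug_present and t0 >= onset) else 0.0
        segments = [(t0, t_end, c0)]

    y = np.array([max(init.S, 0.0), max(init.R, 0.0)], dtype=float)
    out_S = np.empty_like(times)
    out_R = np.empty_like(times)
    filled = np.zeros(len(times), dtype=bool)
    # the first requested time is the initial state
    out_S[0], out_R[0] = y
    filled[0] = True

    for a, b, C in segments:
        mask = (times > a) & (times <= b)
        t_eval = times[mask]
        # always evaluate the segment endpoint so the state carries forward
        need_endpoint = len(t_eval) == 0 or not np.isclose(t_eval[-1], b)
        te = np.append(t_eval, b) if need_endpoint else t_eval

        def f(t: float, y: np.ndarray, _C: float = C) -> list[float]:
            return list(spec.rhs(y[0], y[1], _C, p))

        sol = solve_ivp(f, (a, b), y, method=method, t_eval=te, rtol=rtol,
                        atol=atol, events=_blowup_event)
        if sol.status == 1:
            last = float(sol.t_events[0][0]) if len(sol.t_events[0]) else a
            raise IntegrationError(f"state diverged in [{a}, {b}]", last)
        if not sol.success:
            last = float(sol.t[-1]) if len(sol.t) else a
            raise IntegrationError(f"integration failed in [{a}, {b}]: {sol.message}", last)
        if len(t_eval):
            out_S[mask] = np.maximum(sol.y[0, : len(t_eval)], 0.0)
            out_R[mask] = np.maximum(sol.y[1, : len(t_eval)], 0.0)
            filled |= mask
        y = np.maximum(sol.y[:, -1], 0.0)

    if not filled.all():
        raise IntegrationError("requested times not covered by integration", t0)
    if not (np.all(np.isfinite(out_S)) and np.all(np.isfinite(out_R))):
        raise IntegrationError("non-finite state encountered", t0)
    return Trajectory(times=times, S=out_S, R=out_R)
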