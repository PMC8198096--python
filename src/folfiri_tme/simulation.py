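"""Integration of the treated/untreated system and the experiment families.

The infusion forcing is piecewise constant, so integration is restarted at
every infusion breakpoint with the injection rates held constant inside each
segment; a stiff-capable solver (LSODA) with tight tolerances integrates each
smooth piece and dense output provides interpolation at arbitrary days.

Experiment families: drug-combination arms, treatment start-time scans, dose
multiplier scans and treatment-parameter multiplier scans, each summarized by
cancer and total-cell densities at named evaluation days.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DrugScaling, Regimen, dimensionless_injection
from .model import (N_STATE, STATE_NAMES, BaselineParams, StateVector,
                    TreatmentParams, _rhs_unchecked, cancer_death_rate,
                    total_cells, zero_treatment_params)
from .parameterization import default_scaling

__all__ = [
    "DEFAULT_EVAL_DAYS",
    "IntegrationError",
    "Trajectory",
    "ScanResult",
    "simulate",
    "combination_scan",
    "start_time_scan",
    "dose_scan",
    "parameter_scan",
]

#: Named summary days: right after the 12-cycle course ends (169 d) and
#: years 1, 2, 3, 5 and 9.
DEFAULT_EVAL_DAYS = (169.0, 365.0, 730.0, 1095.0, 1825.0, 3285.0)

C_IDX = STATE_NAMES.index("C")
TR_IDX = STATE_NAMES.index("Tr")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last good time/state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass
class Trajectory:
    """Time-stamped solution of the 17-variable system."""

    t: np.ndarray                      # days, strictly increasing
    y: np.ndarray                      # (17, len(t))
    regimen: Regimen | None
    fingerprint: str
    eval_days: dict = field(default_factory=dict)   # day -> 17-state
    _segments: list = field(default_factory=list, repr=False)

    def state_at(self, day: float) -> np.ndarray:
        """Dense-interpolated full state at ``day``."""
        for t0, t1, sol in self._segments:
            if t0 <= day <= t1:
                return np.asarray(sol(day), dtype=float)
        raise ValueError(f"day {day} outside the integrated range "
                         f"[{self._segments[0][0]}, {self._segments[-1][1]}]")

    def series(self, name: str) -> np.ndarray:
        return self.y[STATE_NAMES.index(name)]

    def cancer_at(self, day: float) -> float:
        return float(self.state_at(day)[C_IDX])

    def total_cells_at(self, day: float) -> float:
        return total_cells(self.state_at(day))

    def final_state(self) -> np.ndarray:
        return self.y[:, -1]

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        """Tidy long-format table (time_days, variable, value, scenario)."""
        frames = []
        for i, name in enumerate(STATE_NAMES):
            frames.append(pd.DataFrame({
                "time_days": self.t, "variable": name, "value": self.y[i],
                "scenario": scenario,
            }))
        return pd.concat(frames, ignore_index=True)


def _fingerprint(baseline: BaselineParams, treatment: TreatmentParams,
                 regimen: Regimen | None) -> str:
    payload = repr(sorted(baseline.to_dict().items()))
    payload += repr(sorted(treatment.to_dict().items()))
    if regimen is not None:
        payload += repr((regimen.dose_5fu, regimen.dose_lv, regimen.dose_ir,
                         regimen.n_cycles, regimen.cycle_length, regimen.start_day))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate(initial, baseline: BaselineParams,
             treatment: TreatmentParams | None = None,
             regimen: Regimen | None = None,
             scaling: DrugScaling | None = None,
             horizon: float = 365.0,
             eval_days=(),
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA",
             grid_step: float = 1.0) -> Trajectory:
    """Integrate the system from ``initial`` over ``[0, horizon]`` days.

    ``regimen=None`` (or a zero-dose regimen) gives untreated dynamics.  The
    solver is restarted at every infusion breakpoint so the discontinuous
    forcing never crosses a step.  ``eval_days`` are evaluated from the dense
    solution and returned in ``Trajectory.eval_days``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    eval_days = tuple(float(d) for d in eval_days)
    if any(d < 0 or d > horizon for d in eval_days):
        raise ValueError("eval_days must lie within [0, horizon]")

    y0 = initial.values.copy() if isinstance(initial, StateVector) else \
        np.asarray(initial, dtype=float).copy()
    if y0.shape == (14,):
        y0 = np.concatenate([y0, np.zeros(3)])
    if y0.shape != (N_STATE,):
        raise ValueError(f"initial state must have 14 or 17 components")

    tp = treatment if treatment is not None else zero_treatment_params()
    if regimen is not None and (regimen.dose_5fu or regimen.dose_lv or regimen.dose_ir):
        scal = scaling or default_scaling()
        inj_fns = dimensionless_injection(regimen, scal)
        bps = regimen.breakpoints()
        bps = bps[(bps > 0) & (bps < horizon)]
    else:
        inj_fns = None
        bps = np.array([])

    edges = np.unique(np.concatenate([[0.0], bps, [horizon]]))
    grid = np.unique(np.concatenate([
        np.arange(0.0, horizon, grid_step), [horizon], edges, np.array(eval_days)
    ]))

    ts, ys, segments = [], [], []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        if inj_fns is not None:
            mid = 0.5 * (a + b)
            inj = (inj_fns[0](mid), inj_fns[1](mid), inj_fns[2](mid))
        else:
            inj = (0.0, 0.0, 0.0)

        def rhs(t, yy, _inj=inj):
            return _rhs_unchecked(yy, baseline, tp, _inj)

        t_eval = grid[(grid >= a) & (grid <= b)]
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, dense_output=True)
        if not sol.success:
            t_last = sol.t[-1] if sol.t.size else a
            y_last = sol.y[:, -1] if sol.t.size else y
            raise IntegrationError(
                f"integration failed in [{a}, {b}]: {sol.message}", t_last, y_last)
        segments.append((a, b, sol.sol))
        y = np.asarray(sol.sol(b), dtype=float)
        if ts:
            ts.append(sol.t[1:])
            ys.append(sol.y[:, 1:])
        else:
            ts.append(sol.t)
            ys.append(sol.y)

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)

    floor = -10.0 * atol
    if Y.min() < floor:
        i = int(np.argmin(Y.min(axis=1)))
        raise IntegrationError(
            f"component {STATE_NAMES[i]} went below the negativity tolerance "
            f"({Y.min():.3e} < {floor:.3e})", float(t[-1]), Y[:, -1])

    traj = Trajectory(t=t, y=Y, regimen=regimen,
                      fingerprint=_fingerprint(baseline, tp, regimen),
                      _segments=segments)
    for d in eval_days:
        traj.eval_days[d] = traj.state_at(d)

    _warn_negative_bracket(traj, baseline, tp)
    return traj


def _warn_negative_bracket(traj: Trajectory, baseline, tp) -> None:
    """The macrophage shielding term enters the cancer death bracket with a
    minus sign; flag trajectories where the net bracket is negative on more
    than 1% of the evaluation grid."""
    if tp.delta_5fuM == 0:
        return
    neg = 0
    for k in range(traj.y.shape[1]):
        if cancer_death_rate(traj.y[:, k], baseline, tp) < 0:
            neg += 1
    frac = neg / traj.y.shape[1]
    if frac > 0.01:
        warnings.warn(
            f"cancer death bracket negative on {100 * frac:.1f}% of grid points "
            "(macrophage shielding exceeds total kill)", RuntimeWarning)


@dataclass
class ScanResult:
    """Per-point trajectories and evaluation-day summaries of one scan."""

    axis_name: str
    axis: list
    trajectories: dict
    eval_days: tuple

    def summary(self) -> pd.DataFrame:
        rows = []
        for label in self.axis:
            traj = self.trajectories[label]
            for d in self.eval_days:
                if d > traj.t[-1]:
                    continue
                state = traj.state_at(d)
                rows.append({self.axis_name: label, "day": d,
                             "cancer": float(state[C_IDX]),
                             "total_cells": total_cells(state)})
        return pd.DataFrame(rows)


def combination_scan(initial, baseline, treatment, regimen=None, scaling=None,
                     horizon=None, eval_days=DEFAULT_EVAL_DAYS, **kw) -> ScanResult:
    """The four drug-combination arms {5FU}, {5FU+LV}, {5FU+Ir}, {5FU+LV+Ir}.

    Arms differ only in which doses are zeroed; solver settings are shared.
    """
    reg = regimen or Regimen()
    if horizon is None:
        horizon = reg.course_end_day + 730.0
    arms = {
        "5FU": reg.with_doses(dose_lv=0.0, dose_ir=0.0),
        "5FU+LV": reg.with_doses(dose_ir=0.0),
        "5FU+Ir": reg.with_doses(dose_lv=0.0),
        "5FU+LV+Ir": reg,
    }
    trajs = {
        label: simulate(initial, baseline, treatment, r, scaling,
                        horizon=horizon, eval_days=[d for d in eval_days if d <= horizon],
                        **kw)
        for label, r in arms.items()
    }
    return ScanResult("combination", list(arms), trajs,
                      tuple(d for d in eval_days if d <= horizon))


def start_time_scan(initial, baseline, treatment, regimen=None, scaling=None,
                    start_years=(1, 3, 5, 7), horizon=None,
                    eval_days=(), **kw) -> ScanResult:
    """Treatment delayed by 1, 3, 5 or 7 years; untreated dynamics before."""
    reg = regimen or Regimen()
    trajs = {}
    for yr in start_years:
        r = reg.with_start(365.0 * yr)
        h = horizon or (r.course_end_day + 730.0)
        trajs[yr] = simulate(initial, baseline, treatment, r, scaling,
                             horizon=h, eval_days=eval_days, **kw)
    return ScanResult("start_year", list(start_years), trajs, tuple(eval_days))


def dose_scan(patient_regimen: Regimen, baseline, treatment, initial,
              multipliers, target_drug: str, scaling=None,
              horizon=None, eval_days=DEFAULT_EVAL_DAYS, **kw) -> ScanResult:
    """Scale one drug's dose by each multiplier, keeping the others fixed."""
    if target_drug not in ("FU", "LV", "Ir"):
        raise ValueError("target_drug must be one of 'FU', 'LV', 'Ir'")
    mults = sorted(float(m) for m in multipliers)
    if any(m < 0 for m in mults):
        raise ValueError("multipliers must be non-negative")
    if horizon is None:
        horizon = patient_regimen.course_end_day + 730.0
    field_name = {"FU": "dose_5fu", "LV": "dose_lv", "Ir": "dose_ir"}[target_drug]
    trajs = {}
    for mult in mults:
        r = patient_regimen.with_doses(
            **{field_name: mult * getattr(patient_regimen, field_name)})
        trajs[mult] = simulate(initial, baseline, treatment, r, scaling,
                               horizon=horizon,
                               eval_days=[d for d in eval_days if d <= horizon], **kw)
    return ScanResult(f"{target_drug}_dose_multiplier", mults, trajs,
                      tuple(d for d in eval_days if d <= horizon))


SCANNABLE_PARAMS = TreatmentParams.RATE_NAMES


def parameter_scan(param_name: str, baseline, treatment, multipliers,
                   regimen=None, scaling=None, initial=None,
                   eval_days=DEFAULT_EVAL_DAYS, horizon=None, **kw) -> ScanResult:
    """Scale one treatment parameter by each multiplier (steady-state ICs)."""
    if param_name not in SCANNABLE_PARAMS:
        raise ValueError(
            f"unknown parameter {param_name!r}; valid names: "
            + ", ".join(SCANNABLE_PARAMS))
    mults = sorted(float(m) for m in multipliers)
    reg = regimen or Regimen()
    init = initial if initial is not None else StateVector.ones()
    if horizon is None:
        horizon = max(eval_days) if eval_days else reg.course_end_day + 730.0
    trajs = {}
    for mult in mults:
        tp = treatment.replace(**{param_name: mult * getattr(treatment, param_name)})
        trajs[mult] = simulate(init, baseline, tp, reg, scaling, horizon=horizon,
                               eval_days=[d for d in eval_days if d <= horizon], **kw)
    return ScanResult(f"{param_name}_multiplier", mults, trajs,
                      tuple(d for d in eval_days if d <= horizon))
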