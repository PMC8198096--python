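"""Time-dependent forward sensitivity analysis.

For the system ``dX/dt = F(X, theta, t)`` the sensitivity of the solution to
one parameter, ``S_i = dX/d theta_i``, satisfies the forward equation

    dS_i/dt = dF/d theta_i + (dF/dX) S_i,   S_i(0) = 0,

which is integrated alongside the state (17 + 17 components, one parameter
at a time).  The relative sensitivity ``Sbar_i(t) = S_i(t) * theta_i / X(t)``
and the time averages ``(1/T) int_0^T . dt`` of both quantities summarize a
parameter's influence; parameters are ranked by the magnitude of the
time-averaged sensitivity of a chosen output (cancer or total cells).

Both ``dF/dX`` (the Jacobian) and ``dF/d theta`` use the same central
finite-difference stepping rule as :func:`folfiri_tme.model.jacobian`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DrugScaling, Regimen, dimensionless_injection
from .model import (CELL_INDICES, N_STATE, STATE_NAMES, BaselineParams,
                    StateVector, TreatmentParams, _rhs_unchecked, jacobian,
                    zero_treatment_params)
from .parameterization import default_scaling

__all__ = [
    "RELATIVE_MASK_THRESHOLD",
    "IMMUNE_TREATMENT_PARAMS",
    "SensitivityResult",
    "forward_sensitivity",
    "relative_sensitivity",
    "time_average",
    "rank_parameters",
    "augmented_sensitivity_solve",
]

#: Relative sensitivities are masked (NaN) where |X(t)| falls below this.
RELATIVE_MASK_THRESHOLD = 1e-8

#: Treatment parameters coupling a drug to an immune cell population.
IMMUNE_TREATMENT_PARAMS = (
    "delta_5fuM", "delta_TrIr", "lam_ThD5fu", "lam_TCD5fu", "delta_5fuD",
)


@dataclass
class SensitivityResult:
    """Sensitivity curves of all 17 variables with respect to one parameter."""

    theta_name: str
    theta_value: float
    t: np.ndarray                 # days
    X: np.ndarray                 # (17, n) state trajectory
    S: np.ndarray                 # (17, n) dX/dtheta
    horizon_T: float              # averaging horizon, days
    S_rel: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.S_rel is None:
            self.S_rel = relative_sensitivity(self)

    def average(self, relative: bool = False) -> np.ndarray:
        """Per-variable time average over [0, T]; NaN where masked."""
        curves = self.S_rel if relative else self.S
        return time_average(curves, self.t, self.horizon_T)

    def output_average(self, output: str = "C", relative: bool = False) -> float:
        """Time-averaged sensitivity of one output (a variable name or
        'total_cells', the sum of the nine cell types)."""
        if output == "total_cells":
            s_out = self.S[list(CELL_INDICES)].sum(axis=0)
            if relative:
                x_out = self.X[list(CELL_INDICES)].sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    s_out = np.where(np.abs(x_out) < RELATIVE_MASK_THRESHOLD,
                                     np.nan, s_out * self.theta_value / x_out)
        else:
            i = STATE_NAMES.index(output)
            s_out = (self.S_rel if relative else self.S)[i]
        return float(time_average(s_out[None, :], self.t, self.horizon_T)[0])


def relative_sensitivity(result: SensitivityResult) -> np.ndarray:
    """``Sbar(t) = S(t) * theta / X(t)`` elementwise, masked to NaN where
    ``|X| < RELATIVE_MASK_THRESHOLD``."""
    mask = np.abs(result.X) < RELATIVE_MASK_THRESHOLD
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = result.S * result.theta_value / result.X
    if mask.any():
        warnings.warn(
            f"relative sensitivity of {result.theta_name}: "
            f"{int(mask.sum())} grid values masked (|X| below threshold)",
            RuntimeWarning, stacklevel=2)
    rel[mask] = np.nan
    return rel


def time_average(curves: np.ndarray, t: np.ndarray, T: float) -> np.ndarray:
    """Trapezoidal time averages ``(1/T) int_0^T curve dt`` per row.

    Rows containing masked (NaN) values inside [0, T] average to NaN.
    """
    if T <= 0:
        raise ValueError("averaging horizon T must be positive")
    if T > t[-1] + 1e-9:
        raise ValueError(f"T = {T} exceeds the integrated horizon {t[-1]}")
    sel = t <= T + 1e-12
    tt = t[sel]
    cc = np.atleast_2d(curves)[:, sel]
    out = np.trapezoid(cc, tt, axis=1) / T
    out[np.isnan(cc).any(axis=1)] = np.nan
    return out


def _param_home(name: str, baseline: BaselineParams, tp: TreatmentParams):
    if name in BaselineParams.names():
        return "baseline", getattr(baseline, name)
    if name in TreatmentParams.RATE_NAMES:
        return "treatment", getattr(tp, name)
    raise ValueError(
        f"unknown parameter {name!r}; valid names are the 59 baseline and "
        "16 treatment rate parameters")


def augmented_sensitivity_solve(rhs, jac, dfdth, x0, edges, grid,
                                rtol=1e-8, atol=1e-10, method="LSODA"):
    """Integrate state + sensitivity for a generic system.

    ``rhs(t, x)``, ``jac(t, x)`` (n x n) and ``dfdth(t, x)`` (n,) define the
    augmented system; ``edges`` are restart points (discontinuous forcing) and
    ``grid`` the output times.  Returns ``(t, X (n,m), S (n,m))`` with
    ``S(edges[0]) = 0``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    z = np.concatenate([x0, np.zeros(n)])

    def aug(t, zz):
        x, s = zz[:n], zz[n:]
        return np.concatenate([rhs(t, x), dfdth(t, x) + jac(t, x) @ s])

    ts, xs, ss = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = grid[(grid >= a) & (grid <= b)]
        sol = solve_ivp(aug, (a, b), z, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, dense_output=True)
        if not sol.success:
            raise RuntimeError(
                f"sensitivity integration failed in [{a}, {b}]: {sol.message}")
        z = np.asarray(sol.sol(b), dtype=float)
        lo = 1 if ts else 0
        ts.append(sol.t[lo:])
        xs.append(sol.y[:n, lo:])
        ss.append(sol.y[n:, lo:])
    return np.concatenate(ts), np.concatenate(xs, axis=1), np.concatenate(ss, axis=1)


def forward_sensitivity(baseline: BaselineParams, treatment: TreatmentParams | None,
                        initial, regimen: Regimen | None, theta_names,
                        horizon: float, scaling: DrugScaling | None = None,
                        T: float | None = None,
                        rtol: float = 1e-8, atol: float = 1e-10,
                        grid_step: float = 1.0) -> list[SensitivityResult]:
    """Forward sensitivities of the model with respect to each named parameter.

    One augmented (17 + 17)-state integration per parameter, sharing the
    breakpoint-restart scheme of :func:`folfiri_tme.simulation.simulate`.
    The default averaging horizon ``T`` is the treatment course plus two
    years, capped by ``horizon``.
    """
    if isinstance(theta_names, str):
        theta_names = [theta_names]
    tp = treatment if treatment is not None else zero_treatment_params()
    y0 = initial.values if isinstance(initial, StateVector) else \
        np.asarray(initial, dtype=float)
    if y0.shape == (14,):
        y0 = np.concatenate([y0, np.zeros(3)])

    if regimen is not None and (regimen.dose_5fu or regimen.dose_lv or regimen.dose_ir):
        scal = scaling or default_scaling()
        inj_fns = dimensionless_injection(regimen, scal)
        bps = regimen.breakpoints()
        bps = bps[(bps > 0) & (bps < horizon)]
        course_end = regimen.course_end_day
    else:
        inj_fns = None
        bps = np.array([])
        course_end = 0.0

    if T is None:
        T = min(horizon, course_end + 730.0) if course_end else horizon

    edges = np.unique(np.concatenate([[0.0], bps, [horizon]]))
    grid = np.unique(np.concatenate([np.arange(0.0, horizon, grid_step),
                                     [horizon], edges]))

    results = []
    for name in theta_names:
        home, value = _param_home(name, baseline, tp)

        h = 1e-6 * max(1.0, abs(value))
        if home == "baseline":
            bp_p, bp_m = baseline.replace(**{name: value + h}), \
                baseline.replace(**{name: max(value - h, 0.0) if value - h < 0 else value - h})
            tp_p = tp_m = tp
        else:
            tp_p, tp_m = tp.replace(**{name: value + h}), \
                tp.replace(**{name: value - h if value - h >= 0 else 0.0})
            bp_p = bp_m = baseline
        # keep the step symmetric even when clamping at zero
        h_minus = value - (getattr(bp_m, name) if home == "baseline" else getattr(tp_m, name))
        denom = h + h_minus

        def make_fns(inj_const):
            def rhs(t, x):
                return _rhs_unchecked(x, baseline, tp, inj_const)

            def jac(t, x):
                return jacobian(x, baseline, tp, inj_const)

            def dfdth(t, x):
                f_p = _rhs_unchecked(x, bp_p, tp_p, inj_const)
                f_m = _rhs_unchecked(x, bp_m, tp_m, inj_const)
                return (f_p - f_m) / denom

            return rhs, jac, dfdth

        # piecewise integration with constant injection per segment
        ts, xs, ss = [], [], []
        z_x, z_s = y0.copy(), np.zeros(N_STATE)
        for a, b in zip(edges[:-1], edges[1:]):
            if inj_fns is not None:
                mid = 0.5 * (a + b)
                inj = (inj_fns[0](mid), inj_fns[1](mid), inj_fns[2](mid))
            else:
                inj = (0.0, 0.0, 0.0)
            rhs, jac, dfdth = make_fns(inj)

            def aug(t, zz):
                x, s = zz[:N_STATE], zz[N_STATE:]
                return np.concatenate([rhs(t, x), dfdth(t, x) + jac(t, x) @ s])

            t_eval = grid[(grid >= a) & (grid <= b)]
            sol = solve_ivp(aug, (a, b), np.concatenate([z_x, z_s]),
                            method="LSODA", rtol=rtol, atol=atol,
                            t_eval=t_eval, dense_output=True)
            if not sol.success:
                raise RuntimeError(
                    f"sensitivity for {name} failed in [{a}, {b}]: {sol.message}")
            zb = np.asarray(sol.sol(b), dtype=float)
            z_x, z_s = zb[:N_STATE], zb[N_STATE:]
            lo = 1 if ts else 0
            ts.append(sol.t[lo:])
            xs.append(sol.y[:N_STATE, lo:])
            ss.append(sol.y[N_STATE:, lo:])

        t = np.concatenate(ts)
        X = np.concatenate(xs, axis=1)
        S = np.concatenate(ss, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results.append(SensitivityResult(
                theta_name=name, theta_value=value, t=t, X=X, S=S, horizon_T=T))
    return results


def rank_parameters(results: list[SensitivityResult],
                    output: str = "C") -> pd.DataFrame:
    """Rank parameters by |time-averaged sensitivity| of one output.

    The primary ordering uses the absolute (non-normalized) time-averaged
    sensitivity; the relative variant is reported alongside.
    """
    if len(results) < 2:
        raise ValueError("ranking requires at least two analyzed parameters")
    if output not in ("C", "total_cells") and output not in STATE_NAMES:
        raise ValueError(f"unknown output {output!r}")
    rows = []
    for res in results:
        rows.append({
            "parameter": res.theta_name,
            "theta": res.theta_value,
            "avg_sensitivity": res.output_average(output, relative=False),
            "avg_rel_sensitivity": res.output_average(output, relative=True),
        })
    df = pd.DataFrame(rows)
    df["abs_avg"] = df["avg_sensitivity"].abs()
    df = df.sort_values("abs_avg", ascending=False, kind="mergesort")
    df = df.drop(columns="abs_avg").reset_index(drop=True)
    df.index.name = "rank"
    return df
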