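"""Right-hand sides of the colon-cancer tumor-microenvironment ODE system.

The baseline network couples nine cell populations (naive/helper/cytotoxic/
regulatory T-cells, naive and activated dendritic cells, macrophages, cancer
and necrotic cells) with five cytokine species (HMGB1, the carcinogenic
cytokine group mu1, the immunosuppressive group mu2, IFN-gamma and TGF-beta)
through mass-action kinetics.  The treatment extension adds the three FOLFIRI
agents (5-FU, leucovorin, irinotecan) as single-pool drug concentrations with
cytotoxic, synergistic and consumption terms.

Everything here works in the dimensionless scale: each cell/cytokine variable
is its density divided by the untreated steady-state value, so the untreated
fixed point is the all-ones vector; each drug is scaled by its natural decay
rate over the cohort daily-median injection rate, so a continuous median-rate
infusion equilibrates at 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "STATE_NAMES",
    "BASELINE_STATE_NAMES",
    "DRUG_STATE_NAMES",
    "N_BASELINE",
    "N_STATE",
    "StateVector",
    "BaselineParams",
    "TreatmentParams",
    "zero_treatment_params",
    "rhs_baseline",
    "rhs_treatment",
    "cancer_death_rate",
    "total_cells",
    "jacobian",
]

#: Fixed state ordering: the 14 baseline variables, then the three drugs.
BASELINE_STATE_NAMES: tuple[str, ...] = (
    "TN", "Th", "TC", "Tr", "DN", "D", "M", "C", "N",
    "H", "mu1", "mu2", "Igamma", "Gbeta",
)
DRUG_STATE_NAMES: tuple[str, ...] = ("FU", "LV", "Ir")
STATE_NAMES: tuple[str, ...] = BASELINE_STATE_NAMES + DRUG_STATE_NAMES

N_BASELINE = len(BASELINE_STATE_NAMES)   # 14
N_STATE = len(STATE_NAMES)               # 17

#: Cell-type components entering the "total cells" summary (no cytokines, no drugs).
CELL_NAMES: tuple[str, ...] = ("TN", "Th", "TC", "Tr", "DN", "D", "M", "C", "N")
CELL_INDICES: tuple[int, ...] = tuple(STATE_NAMES.index(n) for n in CELL_NAMES)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class StateVector:
    """Non-negative model state in the fixed 17-component ordering.

    Accepts either the 14 baseline components (drugs padded with zeros) or the
    full 17.  Components must be finite and >= 0.
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float] | np.ndarray):
        arr = np.asarray(values, dtype=float).copy()
        if arr.shape == (N_BASELINE,):
            arr = np.concatenate([arr, np.zeros(3)])
        if arr.shape != (N_STATE,):
            raise ValueError(
                f"state must have {N_BASELINE} or {N_STATE} components, got shape {arr.shape}"
            )
        for i, v in enumerate(arr):
            if not np.isfinite(v):
                raise ValueError(f"state component {STATE_NAMES[i]} is not finite")
            if v < 0:
                raise ValueError(f"state component {STATE_NAMES[i]} is negative ({v})")
        self.values = arr

    @classmethod
    def ones(cls) -> "StateVector":
        """Untreated steady state: all cells/cytokines at 1, drugs at 0."""
        return cls(np.concatenate([np.ones(N_BASELINE), np.zeros(3)]))

    @classmethod
    def from_dict(cls, d: dict) -> "StateVector":
        return cls([float(d.get(name, 0.0)) for name in STATE_NAMES])

    def to_dict(self) -> dict:
        return {name: float(v) for name, v in zip(STATE_NAMES, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[IDX[name]])

    def __len__(self) -> int:
        return N_STATE

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{n}={v:.4g}" for n, v in zip(STATE_NAMES, self.values))
        return f"StateVector({parts})"


def _check_nonnegative_fields(obj, kind: str) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if v is None or callable(v):
            continue
        if not np.isfinite(v):
            raise ValueError(f"{kind} parameter {f.name} is not finite")
        if v < 0:
            raise ValueError(f"{kind} parameter {f.name} is negative ({v})")


@dataclass
class BaselineParams:
    """The 59 rate/capacity parameters of the untreated network.

    ``lam_*`` are production/activation rates, ``delta_*`` removal/inhibition
    rates, ``A_TN``/``A_DN`` the naive-cell sources, ``M0``/``C0`` the
    macrophage and cancer capacities and ``alpha_NC`` the fraction of dying
    cancer cells that become necrotic.  All rates are per day in the
    dimensionless working scale.
    """

    # sources and capacities
    A_TN: float
    A_DN: float
    M0: float
    C0: float
    alpha_NC: float
    # activation / production rates
    lam_ThD: float
    lam_ThM: float
    lam_Thmu1: float
    lam_TCTh: float
    lam_TCD: float
    lam_TrTh: float
    lam_Trmu2: float
    lam_TrGb: float
    lam_DH: float
    lam_DC: float
    lam_Mmu2: float
    lam_MIg: float
    lam_MTh: float
    lam_C: float
    lam_Cmu1: float
    lam_HN: float
    lam_HM: float
    lam_HTh: float
    lam_HTC: float
    lam_HTr: float
    lam_mu1Th: float
    lam_mu1M: float
    lam_mu1D: float
    lam_mu2M: float
    lam_mu2D: float
    lam_mu2Tr: float
    lam_IgTh: float
    lam_IgTC: float
    lam_IgM: float
    lam_GbM: float
    lam_GbTr: float
    # removal / inhibition rates
    delta_TN: float
    delta_Thmu2: float
    delta_ThTr: float
    delta_Th: float
    delta_TCmu2: float
    delta_TCTr: float
    delta_TC: float
    delta_Trmu1: float
    delta_Tr: float
    delta_DH: float
    delta_D: float
    delta_DC: float
    delta_M: float
    delta_CGb: float
    delta_CIg: float
    delta_CTC: float
    delta_C: float
    delta_N: float
    delta_H: float
    delta_mu1: float
    delta_mu2: float
    delta_Ig: float
    delta_Gb: float

    def __post_init__(self):
        _check_nonnegative_fields(self, "baseline")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineParams":
        return cls(**{k: float(d[k]) for k in cls.names()})

    def replace(self, **kw) -> "BaselineParams":
        return dataclasses.replace(self, **kw)


@dataclass
class TreatmentParams:
    """The 19 FOLFIRI parameters: 16 numeric rates plus the three injection
    forcing functions (per-drug dimensionless injection rate vs. time, days).

    ``delta_C5fu``/``delta_CIr`` are direct cytotoxic rates, ``delta_C5fuIg``
    the IFN-gamma-potentiated 5-FU kill, ``delta_5fuM`` the macrophage
    shielding of cancer from 5-FU (entering the death bracket with a minus
    sign exactly as modeled), ``delta_CLV5fu`` the leucovorin-potentiated
    5-FU kill and ``delta_TrIr`` the irinotecan depletion of T-regs.  The
    ``alpha_*`` constants convert each kill interaction into drug consumption,
    and ``delta_5fu``/``delta_LV``/``delta_Ir`` are natural decay rates.
    """

    delta_C5fu: float
    delta_C5fuIg: float
    delta_5fuM: float
    delta_CLV5fu: float
    delta_CIr: float
    delta_TrIr: float
    delta_5fuD: float
    lam_ThD5fu: float
    lam_TCD5fu: float
    alpha_5fu: float
    alpha_LV: float
    alpha_IrC: float
    alpha_IrTr: float
    delta_5fu: float
    delta_LV: float
    delta_Ir: float
    A_inj5fu: Callable[[float], float] | None = None
    A_injLV: Callable[[float], float] | None = None
    A_injIr: Callable[[float], float] | None = None

    def __post_init__(self):
        _check_nonnegative_fields(self, "treatment")

    RATE_NAMES = (
        "delta_C5fu", "delta_C5fuIg", "delta_5fuM", "delta_CLV5fu",
        "delta_CIr", "delta_TrIr", "delta_5fuD", "lam_ThD5fu", "lam_TCD5fu",
        "alpha_5fu", "alpha_LV", "alpha_IrC", "alpha_IrTr",
        "delta_5fu", "delta_LV", "delta_Ir",
    )

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def to_dict(self) -> dict:
        """Numeric rates only; injection functions are carried separately."""
        return {k: getattr(self, k) for k in self.RATE_NAMES}

    @classmethod
    def from_dict(cls, d: dict, injections=None) -> "TreatmentParams":
        kw = {k: float(d[k]) for k in cls.RATE_NAMES}
        if injections is not None:
            kw["A_inj5fu"], kw["A_injLV"], kw["A_injIr"] = injections
        return cls(**kw)

    def replace(self, **kw) -> "TreatmentParams":
        return dataclasses.replace(self, **kw)


def zero_treatment_params() -> TreatmentParams:
    """All treatment rates zero: the treated RHS reduces to the baseline one."""
    return TreatmentParams(*([0.0] * 16))


# ---------------------------------------------------------------------------
# Right-hand sides.
#
# The expressions below are written once over (possibly array-valued)
# components, so the same code evaluates a single state or a batch of states
# (used by the finite-difference Jacobian).  The treatment terms are inserted
# as separate additions: with all drugs at zero they contribute exact floating
# point zeros and the treated RHS equals the baseline RHS bitwise.
# ---------------------------------------------------------------------------

def _derivs(y, p: BaselineParams, tp: TreatmentParams, inj_fu, inj_lv, inj_ir):
    (TN, Th, TC, Tr, DN, D, M, C, N, H, mu1, mu2, Ig, Gb, FU, LV, Ir) = y

    # activation brackets (shared between the naive equation and its targets)
    act_Th = p.lam_ThD * D + tp.lam_ThD5fu * FU * D + p.lam_ThM * M + p.lam_Thmu1 * mu1
    act_TC = p.lam_TCTh * Th + p.lam_TCD * D + tp.lam_TCD5fu * FU * D
    act_Tr = p.lam_TrTh * Th + p.lam_Trmu2 * mu2 + p.lam_TrGb * Gb
    act_D = p.lam_DH * H + p.lam_DC * C

    # cancer death bracket, shared between the cancer and necrosis equations;
    # the macrophage term enters with a minus sign (5-FU shielding).
    death_C = (
        p.delta_CGb * Gb + p.delta_CIg * Ig + p.delta_CTC * TC + p.delta_C
        + tp.delta_C5fu * FU + tp.delta_C5fuIg * FU * Ig
        - tp.delta_5fuM * FU * M
        + tp.delta_CLV5fu * FU * LV + tp.delta_CIr * Ir
    )

    dTN = p.A_TN - (act_Th + act_TC + act_Tr) * TN - p.delta_TN * TN
    dTh = act_Th * TN - (p.delta_Thmu2 * mu2 + p.delta_ThTr * Tr + p.delta_Th) * Th
    dTC = act_TC * TN - (p.delta_TCmu2 * mu2 + p.delta_TCTr * Tr + p.delta_TC) * TC
    dTr = act_Tr * TN - (p.delta_Trmu1 * mu1 + p.delta_Tr + tp.delta_TrIr * Ir) * Tr
    dDN = p.A_DN - act_D * DN - (p.delta_DH * H + p.delta_D) * DN
    dD = act_D * DN - (p.delta_DH * H + p.delta_DC * C + p.delta_D) * D
    dM = (p.lam_Mmu2 * mu2 + p.lam_MIg * Ig + p.lam_MTh * Th) * (p.M0 - M) - p.delta_M * M
    dC = (p.lam_C + p.lam_Cmu1 * mu1) * C * (1.0 - C / p.C0) - death_C * C
    dN = p.alpha_NC * death_C * C - p.delta_N * N
    dH = (p.lam_HN * N + p.lam_HM * M + p.lam_HTh * Th + p.lam_HTC * TC
          + p.lam_HTr * Tr - p.delta_H * H)
    dmu1 = p.lam_mu1Th * Th + p.lam_mu1M * M + p.lam_mu1D * D - p.delta_mu1 * mu1
    dmu2 = p.lam_mu2M * M + p.lam_mu2D * D + p.lam_mu2Tr * Tr - p.delta_mu2 * mu2
    dIg = p.lam_IgTh * Th + p.lam_IgTC * TC + p.lam_IgM * M - p.delta_Ig * Ig
    dGb = p.lam_GbM * M + p.lam_GbTr * Tr - p.delta_Gb * Gb

    # drug consumption: 5-FU spent on cancer kill (alpha-scaled bracket),
    # on dendritic-cell mediated T-cell activation, and natural elimination.
    fu_bracket = (
        tp.delta_C5fu * FU + tp.delta_C5fuIg * FU * Ig
        - tp.delta_5fuM * FU * M + tp.delta_CLV5fu * FU * LV
    )
    dFU = inj_fu - tp.alpha_5fu * fu_bracket * C - tp.delta_5fuD * FU * D - tp.delta_5fu * FU
    dLV = inj_lv - tp.delta_LV * LV - tp.alpha_LV * tp.delta_CLV5fu * C * FU * LV
    dIr = (inj_ir - tp.alpha_IrC * tp.delta_CIr * C * Ir
           - tp.alpha_IrTr * tp.delta_TrIr * Ir * Tr - tp.delta_Ir * Ir)

    return (dTN, dTh, dTC, dTr, dDN, dD, dM, dC, dN, dH,
            dmu1, dmu2, dIg, dGb, dFU, dLV, dIr)


_ZERO_TP = zero_treatment_params()


def _as_state_array(state, n: int) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.values[:n] if n == N_BASELINE else state.values
    arr = np.asarray(state, dtype=float)
    if n == N_STATE and arr.shape == (N_BASELINE,):
        arr = np.concatenate([arr, np.zeros(3)])
    if arr.shape != (n,):
        raise ValueError(f"expected state of length {n}, got shape {arr.shape}")
    return arr


def _validate_state(arr: np.ndarray) -> None:
    if np.any(arr < 0):
        i = int(np.argmin(arr))
        raise ValueError(f"state component {STATE_NAMES[i]} is negative ({arr[i]})")


def rhs_baseline(state, params: BaselineParams) -> np.ndarray:
    """Time derivative of the 14 untreated variables (per day)."""
    y = _as_state_array(state, N_BASELINE)
    _validate_state(y)
    full = tuple(y) + (0.0, 0.0, 0.0)
    d = _derivs(full, params, _ZERO_TP, 0.0, 0.0, 0.0)
    return np.array(d[:N_BASELINE], dtype=float)


def rhs_treatment(state, params: BaselineParams, treatment: TreatmentParams,
                  infusion=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Time derivative of the full 17-variable treated system (per day).

    ``infusion`` is the triple of dimensionless injection rates
    (5-FU, LV, Ir) at the current time.
    """
    y = _as_state_array(state, N_STATE)
    _validate_state(y)
    inj_fu, inj_lv, inj_ir = infusion
    if inj_fu < 0 or inj_lv < 0 or inj_ir < 0:
        raise ValueError("infusion rates must be non-negative")
    d = _derivs(tuple(y), params, treatment, inj_fu, inj_lv, inj_ir)
    return np.array(d, dtype=float)


def _rhs_unchecked(y: np.ndarray, params, treatment, inj) -> np.ndarray:
    """Fast path for the integrator: no validation, plain tuple unpack."""
    d = _derivs(tuple(y), params, treatment, inj[0], inj[1], inj[2])
    return np.asarray(d, dtype=float)


def _rhs_batch(Y: np.ndarray, params, treatment, inj) -> np.ndarray:
    """Vectorized RHS over a (17, k) batch of states."""
    d = _derivs(tuple(Y), params, treatment, inj[0], inj[1], inj[2])
    out = np.empty_like(Y)
    for i, di in enumerate(d):
        out[i] = di
    return out


def cancer_death_rate(state, params: BaselineParams,
                      treatment: TreatmentParams | None = None) -> float:
    """Per-capita cancer death bracket; the necrosis source is
    ``alpha_NC * cancer_death_rate * C`` by construction."""
    tp = treatment if treatment is not None else _ZERO_TP
    y = _as_state_array(state, N_STATE)
    (TN, Th, TC, Tr, DN, D, M, C, N, H, mu1, mu2, Ig, Gb, FU, LV, Ir) = y
    p = params
    return float(
        p.delta_CGb * Gb + p.delta_CIg * Ig + p.delta_CTC * TC + p.delta_C
        + tp.delta_C5fu * FU + tp.delta_C5fuIg * FU * Ig
        - tp.delta_5fuM * FU * M
        + tp.delta_CLV5fu * FU * LV + tp.delta_CIr * Ir
    )


def total_cells(state) -> float:
    """Sum of the nine cell-type densities (cytokines and drugs excluded)."""
    y = _as_state_array(state, N_STATE)
    return float(sum(y[i] for i in CELL_INDICES))


def jacobian(state, params: BaselineParams,
             treatment: TreatmentParams | None = None,
             infusion=(0.0, 0.0, 0.0)) -> np.ndarray:
    """17x17 matrix dF/dX by central finite differences.

    Column j uses a relative step ``h = 1e-6 * max(1, |x_j|)``; the batch of
    perturbed states is evaluated in one vectorized RHS call.
    """
    tp = treatment if treatment is not None else _ZERO_TP
    x = _as_state_array(state, N_STATE).astype(float)
    h = 1e-6 * np.maximum(1.0, np.abs(x))
    plus = x[:, None] + np.diag(h)
    minus = x[:, None] - np.diag(h)
    batch = np.concatenate([plus, minus], axis=1)          # (17, 34)
    F = _rhs_batch(batch, params, tp, infusion)
    J = (F[:, :N_STATE] - F[:, N_STATE:]) / (2.0 * h[None, :])
    if not np.all(np.isfinite(J)):
        bad = np.argwhere(~np.isfinite(J))
        i, j = bad[0]
        raise ValueError(
            f"non-finite Jacobian entry d(d{STATE_NAMES[i]}/dt)/d{STATE_NAMES[j]}"
        )
    return J
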