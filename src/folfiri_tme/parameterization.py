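"""Steady-state derivation of the baseline and treatment parameters.

The baseline network is parameterized so that the dimensionless untreated
steady state is the all-ones vector: for each variable the configured total
turnover (per day) fixes its steady-state removal flux, removal weights
allocate that flux among the removal terms, production is set equal to
removal and allocated by production weights, and the naive-cell sources
absorb the residual production of their equations.  The necrosis fraction
``alpha_NC`` is then whatever balances the necrosis equation.

Treatment kill rates are calibrated on per-cycle drug exposures under the
cohort-median regimen: a drug configured to be ``e`` efficient against its
target removes the fraction ``e`` of that target per cycle when acting
alone, giving ``delta = -ln(1 - e) / E`` with ``E`` the integral of the
dimensionless concentration (or concentration product, for the
leucovorin/5-FU synergy) over one cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .dosing import (DEFAULT_CYCLE_LENGTH_DAYS, MEDIAN_DOSES_MG, DrugScaling,
                     Regimen, decay_only_profiles, dimensionless_injection)
from .model import BaselineParams, TreatmentParams, rhs_baseline

__all__ = [
    "DrugAssumptions",
    "AssumptionSet",
    "SteadyStateProfile",
    "default_assumptions",
    "default_scaling",
    "derive_baseline_params",
    "derive_treatment_params",
    "derive_all",
    "cycle_exposures",
    "verify_equilibrium",
]


@dataclass
class SteadyStateProfile:
    """Dimensional anchors around the all-ones dimensionless steady state."""

    steady_state: dict = field(default_factory=dict)  # variable -> value (default 1)
    alpha_dim: float = 7.5e4                          # cells/cm^3 density scale
    necrosis_fraction: float = 0.1
    composition: tuple = (0.3, 0.6, 0.1)              # immune : cancer : necrotic

    def __post_init__(self):
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if not 0.0 <= self.necrosis_fraction < 1.0:
            raise ValueError("necrosis_fraction must be in [0, 1)")


@dataclass
class DrugAssumptions:
    """Pharmacological assumptions behind the 19 treatment parameters.

    Efficiencies are per-cycle kill fractions of the target under the median
    regimen acting alone; irinotecan is taken to be 40% efficient against
    cancer cells, distinctly higher than 5-FU and the incremental leucovorin
    effect.  About 80% of 5-FU elimination is hepatic; half-lives set the
    natural decay rates (delta = ln 2 / t_half).
    """

    irinotecan_kill_efficiency: float = 0.40
    fu_kill_efficiency: float = 0.25
    lv_incremental_efficiency: float = 0.15
    treg_depletion_efficiency: float = 0.30
    hepatic_elimination_fraction_5fu: float = 0.80
    half_life_5fu_hours: float = 0.35
    half_life_lv_hours: float = 6.0
    half_life_ir_hours: float = 12.0
    ifng_synergy_fraction: float = 0.10          # delta_C5fuIg / delta_C5fu
    macrophage_shielding_fraction: float = 0.25  # delta_5fuM / delta_C5fu
    tcell_activation_fraction: float = 0.20      # lam_*D5fu / lam_*D
    consumption_fraction: float = 0.05           # interaction loss vs natural decay
    dendritic_consumption_fraction: float = 0.05  # delta_5fuD / delta_5fu

    def __post_init__(self):
        for name in ("irinotecan_kill_efficiency", "fu_kill_efficiency",
                     "lv_incremental_efficiency", "treg_depletion_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("half_life_5fu_hours", "half_life_lv_hours", "half_life_ir_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _equal_weights(names: tuple[str, ...]) -> dict:
    w = 1.0 / len(names)
    return {n: w for n in names}


#: Production-term parameter groups per variable (state factor 1 at the
#: all-ones steady state unless noted).
PRODUCTION_GROUPS = {
    "Th": ("lam_ThD", "lam_ThM", "lam_Thmu1"),
    "TC": ("lam_TCTh", "lam_TCD"),
    "Tr": ("lam_TrTh", "lam_Trmu2", "lam_TrGb"),
    "D": ("lam_DH", "lam_DC"),
    "M": ("lam_Mmu2", "lam_MIg", "lam_MTh"),      # factor (M0 - 1)
    "C": ("lam_C", "lam_Cmu1"),                    # factor (1 - 1/C0)
    "H": ("lam_HN", "lam_HM", "lam_HTh", "lam_HTC", "lam_HTr"),
    "mu1": ("lam_mu1Th", "lam_mu1M", "lam_mu1D"),
    "mu2": ("lam_mu2M", "lam_mu2D", "lam_mu2Tr"),
    "Igamma": ("lam_IgTh", "lam_IgTC", "lam_IgM"),
    "Gbeta": ("lam_GbM", "lam_GbTr"),
}

#: Removal-term parameter groups per variable.
REMOVAL_GROUPS = {
    "TN": ("delta_TN",),
    "Th": ("delta_Thmu2", "delta_ThTr", "delta_Th"),
    "TC": ("delta_TCmu2", "delta_TCTr", "delta_TC"),
    "Tr": ("delta_Trmu1", "delta_Tr"),
    "D": ("delta_DH", "delta_DC", "delta_D"),
    "M": ("delta_M",),
    "C": ("delta_CGb", "delta_CIg", "delta_CTC", "delta_C"),
    "N": ("delta_N",),
    "H": ("delta_H",),
    "mu1": ("delta_mu1",),
    "mu2": ("delta_mu2",),
    "Igamma": ("delta_Ig",),
    "Gbeta": ("delta_Gb",),
}

#: Default total turnover rates, per day.  Cell populations turn over on a
#: days-to-weeks scale, cytokines within hours.  These are engineering
#: defaults; absolute timescales are configuration, not data.
DEFAULT_TURNOVER = {
    "TN": 0.1, "Th": 0.1, "TC": 0.1, "Tr": 0.1,
    "D": 0.2, "M": 0.05, "C": 0.02, "N": 0.01,
    "H": 4.0, "mu1": 3.0, "mu2": 3.0, "Igamma": 4.0, "Gbeta": 3.0,
}


@dataclass
class AssumptionSet:
    """Turnover rates, flux-allocation weights and drug assumptions."""

    turnover: dict = field(default_factory=lambda: dict(DEFAULT_TURNOVER))
    production_weights: dict = field(default_factory=lambda: {
        var: _equal_weights(names) for var, names in PRODUCTION_GROUPS.items()
    })
    removal_weights: dict = field(default_factory=lambda: {
        var: _equal_weights(names) for var, names in REMOVAL_GROUPS.items()
    })
    M0: float = 2.0
    C0: float = 2.0
    drugs: DrugAssumptions = field(default_factory=DrugAssumptions)

    def __post_init__(self):
        if isinstance(self.drugs, dict):
            self.drugs = DrugAssumptions(**self.drugs)
        for var, rate in self.turnover.items():
            if rate <= 0:
                raise ValueError(f"turnover rate for {var} must be positive")
        for label, groups in (("production", self.production_weights),
                              ("removal", self.removal_weights)):
            for var, weights in groups.items():
                total = sum(weights.values())
                if any(w < 0 for w in weights.values()):
                    raise ValueError(f"negative {label} weight for {var}")
                if abs(total - 1.0) > 1e-12:
                    raise ValueError(
                        f"{label} weights for {var} sum to {total}, expected 1"
                    )

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AssumptionSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def default_assumptions() -> AssumptionSet:
    return AssumptionSet()


def default_scaling(assumptions: AssumptionSet | None = None) -> DrugScaling:
    """Drug scaling from the configured half-lives and Table-style medians."""
    a = assumptions or AssumptionSet()
    return DrugScaling.from_half_lives({
        "FU": a.drugs.half_life_5fu_hours,
        "LV": a.drugs.half_life_lv_hours,
        "Ir": a.drugs.half_life_ir_hours,
    })


def derive_baseline_params(profile: SteadyStateProfile | None = None,
                           assumptions: AssumptionSet | None = None) -> BaselineParams:
    """Derive the 59 baseline parameters from the steady-state balance.

    The returned set satisfies ``rhs_baseline(all-ones) == 0`` to rounding.
    """
    a = assumptions or AssumptionSet()
    if profile is not None:
        for var, val in profile.steady_state.items():
            if val != 1.0:
                raise ValueError(
                    "only the all-ones dimensionless steady state is supported; "
                    f"got {var} = {val}"
                )

    factors = {var: 1.0 for var in PRODUCTION_GROUPS}
    factors["M"] = a.M0 - 1.0
    factors["C"] = 1.0 - 1.0 / a.C0
    for var, fac in factors.items():
        if fac <= 0 and any(w > 0 for w in a.production_weights[var].values()):
            raise ValueError(
                f"steady-state factor for {var} production is {fac}; "
                "flux cannot be allocated (check M0/C0 > 1)"
            )

    values: dict[str, float] = {"M0": a.M0, "C0": a.C0}

    for var, names in PRODUCTION_GROUPS.items():
        turn = a.turnover[var]
        for name in names:
            values[name] = a.production_weights[var][name] * turn / factors[var]
    for var, names in REMOVAL_GROUPS.items():
        turn = a.turnover[var]
        for name in names:
            values[name] = a.removal_weights[var][name] * turn

    # necrosis balance: alpha_NC * (cancer death flux at equilibrium) = delta_N
    values["alpha_NC"] = a.turnover["N"] / a.turnover["C"]

    # naive-cell sources absorb the residual removal of their equations
    values["A_TN"] = (a.turnover["Th"] + a.turnover["TC"] + a.turnover["Tr"]
                      + values["delta_TN"])
    values["A_DN"] = a.turnover["D"] + values["delta_DH"] + values["delta_D"]

    return BaselineParams.from_dict(values)


def cycle_exposures(scaling: DrugScaling,
                    regimen: Regimen | None = None,
                    n_points: int = 140_001) -> dict:
    """Per-cycle dimensionless drug exposures under injection + decay only.

    Returns integrals over one cycle of FU, LV, Ir and of the FU*LV product,
    evaluated on the analytic decay-only concentration profiles.  At the
    median dose each single-drug exposure equals the cycle length in days
    (up to the end-of-cycle decay tail).
    """
    reg = regimen or Regimen()
    one_cycle = Regimen(
        dose_5fu=reg.dose_5fu, dose_lv=reg.dose_lv, dose_ir=reg.dose_ir,
        n_cycles=1, cycle_length=reg.cycle_length, start_day=0.0,
        ir_hours=reg.ir_hours, lv_hours=reg.lv_hours, fu_hours=reg.fu_hours,
    )
    tgrid = np.linspace(0.0, reg.cycle_length, n_points)
    prof = decay_only_profiles(one_cycle, scaling, tgrid)
    return {
        "FU": float(np.trapezoid(prof["FU"], tgrid)),
        "LV": float(np.trapezoid(prof["LV"], tgrid)),
        "Ir": float(np.trapezoid(prof["Ir"], tgrid)),
        "FU*LV": float(np.trapezoid(prof["FU"] * prof["LV"], tgrid)),
    }


def _kill_rate(efficiency: float, exposure: float) -> float:
    if efficiency >= 1.0:
        raise ValueError("kill efficiency of 1 implies an infinite rate")
    if efficiency == 0.0:
        return 0.0
    return -math.log(1.0 - efficiency) / exposure


def derive_treatment_params(assumptions: AssumptionSet | None = None,
                            regimen: Regimen | None = None,
                            scaling: DrugScaling | None = None,
                            baseline: BaselineParams | None = None) -> TreatmentParams:
    """Derive the 19 treatment parameters.

    Kill rates are calibrated on median-regimen per-cycle exposures; synergy
    and auxiliary rates are configured fractions of their parent rates;
    consumption constants make each interaction's drug loss a configured
    fraction of natural decay at the reference (all-ones, unit-drug) state.
    The injection functions of ``regimen`` (default: the median regimen) are
    attached as the three forcing entries.
    """
    a = assumptions or AssumptionSet()
    scal = scaling or default_scaling(a)
    reg = regimen or Regimen()
    base = baseline or derive_baseline_params(assumptions=a)
    d = a.drugs

    median_reg = Regimen(cycle_length=reg.cycle_length, n_cycles=reg.n_cycles,
                         ir_hours=reg.ir_hours, lv_hours=reg.lv_hours,
                         fu_hours=reg.fu_hours)
    E = cycle_exposures(scal, median_reg)

    delta_5fu = scal.decay["FU"]
    delta_LV = scal.decay["LV"]
    delta_Ir = scal.decay["Ir"]

    delta_C5fu = _kill_rate(d.fu_kill_efficiency, E["FU"])
    delta_CLV5fu = _kill_rate(d.lv_incremental_efficiency, E["FU*LV"])
    delta_CIr = _kill_rate(d.irinotecan_kill_efficiency, E["Ir"])
    delta_TrIr = _kill_rate(d.treg_depletion_efficiency, E["Ir"])

    delta_C5fuIg = d.ifng_synergy_fraction * delta_C5fu
    delta_5fuM = d.macrophage_shielding_fraction * delta_C5fu
    lam_ThD5fu = d.tcell_activation_fraction * base.lam_ThD
    lam_TCD5fu = d.tcell_activation_fraction * base.lam_TCD
    delta_5fuD = d.dendritic_consumption_fraction * delta_5fu

    f = d.consumption_fraction
    fu_bracket = delta_C5fu + delta_C5fuIg - delta_5fuM + delta_CLV5fu
    alpha_5fu = f * delta_5fu / fu_bracket if fu_bracket > 0 else 0.0
    alpha_LV = f * delta_LV / delta_CLV5fu if delta_CLV5fu > 0 else 0.0
    alpha_IrC = f * delta_Ir / delta_CIr if delta_CIr > 0 else 0.0
    alpha_IrTr = f * delta_Ir / delta_TrIr if delta_TrIr > 0 else 0.0

    inj_fu, inj_lv, inj_ir = dimensionless_injection(reg, scal)
    return TreatmentParams(
        delta_C5fu=delta_C5fu, delta_C5fuIg=delta_C5fuIg, delta_5fuM=delta_5fuM,
        delta_CLV5fu=delta_CLV5fu, delta_CIr=delta_CIr, delta_TrIr=delta_TrIr,
        delta_5fuD=delta_5fuD, lam_ThD5fu=lam_ThD5fu, lam_TCD5fu=lam_TCD5fu,
        alpha_5fu=alpha_5fu, alpha_LV=alpha_LV, alpha_IrC=alpha_IrC,
        alpha_IrTr=alpha_IrTr, delta_5fu=delta_5fu, delta_LV=delta_LV,
        delta_Ir=delta_Ir, A_inj5fu=inj_fu, A_injLV=inj_lv, A_injIr=inj_ir,
    )


def derive_all(assumptions: AssumptionSet | None = None,
               regimen: Regimen | None = None):
    """Convenience: (BaselineParams, TreatmentParams, DrugScaling) from config."""
    a = assumptions or AssumptionSet()
    scal = default_scaling(a)
    base = derive_baseline_params(assumptions=a)
    treat = derive_treatment_params(a, regimen=regimen, scaling=scal, baseline=base)
    return base, treat, scal


def verify_equilibrium(params: BaselineParams) -> float:
    """Max-norm of the baseline RHS at the all-ones state."""
    ones = np.ones(14)
    return float(np.max(np.abs(rhs_baseline(ones, params))))
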