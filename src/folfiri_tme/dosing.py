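"""FOLFIRI administration schedule and drug non-dimensionalization.

A treatment cycle delivers a one-hour irinotecan drip, then a one-hour
leucovorin drip, then a 46-hour continuous 5-FU infusion; the cycle repeats
every ``cycle_length`` days for ``n_cycles`` cycles.  Injection rates are
piecewise-constant in mg/day with half-open infusion windows (a breakpoint
belongs to the interval it starts).

Each drug concentration [D] (mg-scale) is rescaled to
``Dbar = delta_D * [D] / A_daily_median`` where ``delta_D`` is the natural
decay rate (per day) and ``A_daily_median`` the cohort daily-median dose rate
(median dose per cycle / cycle length, mg/day).  Under a hypothetical
continuous infusion at exactly the daily-median rate with no consumption,
``Dbar`` equilibrates at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MEDIAN_DOSES_MG",
    "MIN_DOSES_MG",
    "DEFAULT_N_CYCLES",
    "DEFAULT_CYCLE_LENGTH_DAYS",
    "Regimen",
    "DrugScaling",
    "infusion_rates",
    "dimensionless_injection",
    "decay_only_profiles",
]

#: Cohort median / minimum doses per cycle, mg (5-FU, leucovorin, irinotecan).
MEDIAN_DOSES_MG = {"FU": 770.0, "LV": 725.0, "Ir": 300.0}
MIN_DOSES_MG = {"FU": 598.0, "LV": 75.0, "Ir": 208.0}
DEFAULT_N_CYCLES = 12
DEFAULT_CYCLE_LENGTH_DAYS = 14.0

HOUR = 1.0 / 24.0


@dataclass
class Regimen:
    """Doses per cycle (mg), cycle structure and treatment start day."""

    dose_5fu: float = MEDIAN_DOSES_MG["FU"]
    dose_lv: float = MEDIAN_DOSES_MG["LV"]
    dose_ir: float = MEDIAN_DOSES_MG["Ir"]
    n_cycles: int = DEFAULT_N_CYCLES
    cycle_length: float = DEFAULT_CYCLE_LENGTH_DAYS
    start_day: float = 0.0
    ir_hours: float = 1.0
    lv_hours: float = 1.0
    fu_hours: float = 46.0

    def __post_init__(self):
        for name in ("dose_5fu", "dose_lv", "dose_ir"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        if self.start_day < 0:
            raise ValueError("start_day must be non-negative")
        total_infusion = (self.ir_hours + self.lv_hours + self.fu_hours) * HOUR
        if self.n_cycles > 0 and self.cycle_length <= total_infusion:
            raise ValueError("cycle_length must exceed the total infusion duration")

    @property
    def end_day(self) -> float:
        """Day the last cycle's infusions end (start of post-treatment phase)."""
        if self.n_cycles == 0:
            return self.start_day
        last_start = self.start_day + (self.n_cycles - 1) * self.cycle_length
        return last_start + (self.ir_hours + self.lv_hours + self.fu_hours) * HOUR

    @property
    def course_end_day(self) -> float:
        """Day the full course (all cycles, incl. rest periods) completes."""
        return self.start_day + self.n_cycles * self.cycle_length

    def with_doses(self, dose_5fu=None, dose_lv=None, dose_ir=None) -> "Regimen":
        return Regimen(
            dose_5fu=self.dose_5fu if dose_5fu is None else dose_5fu,
            dose_lv=self.dose_lv if dose_lv is None else dose_lv,
            dose_ir=self.dose_ir if dose_ir is None else dose_ir,
            n_cycles=self.n_cycles, cycle_length=self.cycle_length,
            start_day=self.start_day, ir_hours=self.ir_hours,
            lv_hours=self.lv_hours, fu_hours=self.fu_hours,
        )

    def with_start(self, start_day: float) -> "Regimen":
        return Regimen(
            dose_5fu=self.dose_5fu, dose_lv=self.dose_lv, dose_ir=self.dose_ir,
            n_cycles=self.n_cycles, cycle_length=self.cycle_length,
            start_day=start_day, ir_hours=self.ir_hours,
            lv_hours=self.lv_hours, fu_hours=self.fu_hours,
        )

    def breakpoints(self) -> np.ndarray:
        """All infusion-rate discontinuity times (days), sorted."""
        pts = []
        for k in range(self.n_cycles):
            s = self.start_day + k * self.cycle_length
            t1 = s + self.ir_hours * HOUR
            t2 = t1 + self.lv_hours * HOUR
            t3 = t2 + self.fu_hours * HOUR
            pts.extend([s, t1, t2, t3])
        return np.array(sorted(set(pts)))


@dataclass
class DrugScaling:
    """Natural decay rates (per day) and daily-median dose rates (mg/day)."""

    decay: dict = field(default_factory=dict)          # drug -> per day
    daily_median: dict = field(default_factory=dict)   # drug -> mg/day

    def __post_init__(self):
        for drug in ("FU", "LV", "Ir"):
            if drug not in self.decay or self.decay[drug] <= 0:
                raise ValueError(f"decay rate for {drug} must be positive")
            if drug not in self.daily_median or self.daily_median[drug] <= 0:
                raise ValueError(f"daily median dose for {drug} must be positive")

    @classmethod
    def from_half_lives(cls, half_life_hours: dict,
                        median_doses_mg: dict = MEDIAN_DOSES_MG,
                        cycle_length_days: float = DEFAULT_CYCLE_LENGTH_DAYS) -> "DrugScaling":
        """delta = ln 2 / half-life; daily median = median dose / cycle length."""
        decay = {d: math.log(2.0) * 24.0 / half_life_hours[d] for d in ("FU", "LV", "Ir")}
        daily = {d: median_doses_mg[d] / cycle_length_days for d in ("FU", "LV", "Ir")}
        return cls(decay=decay, daily_median=daily)

    def scale_factor(self, drug: str) -> float:
        """delta_D / A_daily_median: multiplies mg-scale quantities."""
        return self.decay[drug] / self.daily_median[drug]


def _window_rate(t: float, regimen: Regimen, offset_h: float, dur_h: float,
                 dose: float) -> float:
    """Piecewise-constant rate (mg/day) for one drug's infusion window."""
    if regimen.n_cycles == 0 or dose == 0.0:
        return 0.0
    rel = t - regimen.start_day
    if rel < 0:
        return 0.0
    k = math.floor(rel / regimen.cycle_length)
    if k >= regimen.n_cycles:
        return 0.0
    tau = rel - k * regimen.cycle_length
    lo = offset_h * HOUR
    hi = (offset_h + dur_h) * HOUR
    if lo <= tau < hi:
        return dose * 24.0 / dur_h
    return 0.0


def infusion_rates(t: float, regimen: Regimen) -> tuple[float, float, float]:
    """(rate_ir, rate_lv, rate_5fu) in mg/day at time ``t`` (days).

    Within each cycle: irinotecan on [0, 1 h), leucovorin on [1 h, 2 h),
    5-FU on [2 h, 48 h), relative to the cycle start; zero elsewhere.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    r = regimen
    rate_ir = _window_rate(t, r, 0.0, r.ir_hours, r.dose_ir)
    rate_lv = _window_rate(t, r, r.ir_hours, r.lv_hours, r.dose_lv)
    rate_fu = _window_rate(t, r, r.ir_hours + r.lv_hours, r.fu_hours, r.dose_5fu)
    return rate_ir, rate_lv, rate_fu


def dimensionless_injection(regimen: Regimen, scaling: DrugScaling):
    """Per-drug dimensionless injection-rate functions ``t -> units/day``.

    Returns ``(inj_fu, inj_lv, inj_ir)``; each is ``scale_factor(drug) *``
    the mg/day infusion rate.
    """
    for drug, dose in (("FU", regimen.dose_5fu), ("LV", regimen.dose_lv),
                       ("Ir", regimen.dose_ir)):
        if dose > 0 and scaling.daily_median[drug] <= 0:
            raise ValueError(f"zero daily-median dose for {drug} with nonzero prescription")
    s_fu = scaling.scale_factor("FU")
    s_lv = scaling.scale_factor("LV")
    s_ir = scaling.scale_factor("Ir")

    def inj_fu(t: float) -> float:
        return s_fu * infusion_rates(t, regimen)[2]

    def inj_lv(t: float) -> float:
        return s_lv * infusion_rates(t, regimen)[1]

    def inj_ir(t: float) -> float:
        return s_ir * infusion_rates(t, regimen)[0]

    return inj_fu, inj_lv, inj_ir


def decay_only_profiles(regimen: Regimen, scaling: DrugScaling,
                        tgrid: np.ndarray) -> dict:
    """Analytic dimensionless concentrations under injection + natural decay.

    Ignores all consumption by the tumor microenvironment; used for
    exposure-based calibration of the kill rates.  Returns
    ``{"FU": array, "LV": array, "Ir": array}`` on ``tgrid`` (days, sorted,
    starting at or after 0 with zero initial drug).
    """
    tgrid = np.asarray(tgrid, dtype=float)
    bps = regimen.breakpoints()
    edges = np.unique(np.concatenate([[tgrid[0]], bps[(bps > tgrid[0]) & (bps < tgrid[-1])],
                                      [tgrid[-1]]]))
    inj_fns = dimensionless_injection(regimen, scaling)
    out = {}
    for drug, inj in zip(("FU", "LV", "Ir"), inj_fns):
        delta = scaling.decay[drug]
        conc = np.empty_like(tgrid)
        c0 = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            a = inj(0.5 * (lo + hi))  # constant within the segment
            mask = (tgrid >= lo) & (tgrid <= hi)
            dt = tgrid[mask] - lo
            conc[mask] = a / delta + (c0 - a / delta) * np.exp(-delta * dt)
            c0 = a / delta + (c0 - a / delta) * math.exp(-delta * (hi - lo))
        out[drug] = conc
    return out
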