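"""Synthetic patient cohorts and tumor-scalar arithmetic.

The cohort generator emulates the statistical shape of deconvolution-derived
clinical records: per-patient fractions of 22 immune cell types (digital
cytometry convention) clustered around five centroid profiles, tumor longest/
shortest dimensions, necrosis percentage near 10%, prescribed FOLFIRI doses
near the cohort dosage table, cycle counts and follow-up days.  It produces
tabular records only — no expression data and no deconvolution.

Tumor scalars convert a patient's tumor size (longest x shortest dimension,
cm^2) and necrosis percentage Np into cell densities: total cell density
TCD = alpha_dim * size / mean size, necrotic N = TCD * Np, cancer
C = (2/3) * TCD * (1 - Np) and total immune cells TIC = 0.5 * C, which at
Np = 0.1 gives the immune : cancer : necrotic composition 0.3 : 0.6 : 0.1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosing import (DEFAULT_CYCLE_LENGTH_DAYS, DEFAULT_N_CYCLES,
                     MEDIAN_DOSES_MG, MIN_DOSES_MG, Regimen)
from .model import BASELINE_STATE_NAMES, StateVector

__all__ = [
    "LM22_CELL_TYPES",
    "CohortConfig",
    "load_initial_condition_table",
    "load_dosage_table",
    "cluster_initial_conditions",
    "cluster_centroids",
    "tumor_scalars",
    "generate_cohort",
    "assign_followup",
    "regimen_from_record",
    "refit_clusters",
]

#: The 22 immune cell types of the digital-cytometry signature carried on
#: each record.  Only aggregated classes feed the dynamical model.
LM22_CELL_TYPES = (
    "B_cells_naive", "B_cells_memory", "Plasma_cells",
    "T_cells_CD8", "T_cells_CD4_naive", "T_cells_CD4_memory_resting",
    "T_cells_CD4_memory_activated", "T_cells_follicular_helper",
    "T_cells_regulatory_Tregs", "T_cells_gamma_delta",
    "NK_cells_resting", "NK_cells_activated", "Monocytes",
    "Macrophages_M0", "Macrophages_M1", "Macrophages_M2",
    "Dendritic_cells_resting", "Dendritic_cells_activated",
    "Mast_cells_resting", "Mast_cells_activated",
    "Eosinophils", "Neutrophils",
)

_TREG = LM22_CELL_TYPES.index("T_cells_regulatory_Tregs")
_TH = LM22_CELL_TYPES.index("T_cells_CD4_memory_activated")


def _data_path(name: str):
    return importlib.resources.files("folfiri_tme.data") / name


def load_initial_condition_table(as_strings: bool = False) -> pd.DataFrame:
    """Smallest-tumor dimensionless initial conditions, one row per cluster.

    With ``as_strings=True`` the printed decimal strings are preserved
    verbatim (bit-exact CSV round-trips)."""
    path = _data_path("smallest_tumor_initial_conditions.csv")
    if as_strings:
        return pd.read_csv(path, dtype=str)
    return pd.read_csv(path).set_index("cluster")


def load_dosage_table() -> pd.DataFrame:
    """Cohort drug dosage statistics (mg) and cycle structure."""
    return pd.read_csv(_data_path("drug_dosages.csv")).set_index("quantity")


def cluster_initial_conditions(cluster_id: int, ic_kind: str = "smallest") -> StateVector:
    """Initial state for one cluster: the smallest-tumor record or the
    (all-ones) steady state, with zero drug concentrations."""
    if cluster_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown cluster {cluster_id}; expected 1..5")
    if ic_kind == "steady":
        return StateVector.ones()
    if ic_kind != "smallest":
        raise ValueError("ic_kind must be 'smallest' or 'steady'")
    table = load_initial_condition_table()
    row = table.loc[cluster_id]
    return StateVector([float(row[name]) for name in BASELINE_STATE_NAMES])


def cluster_centroids() -> pd.DataFrame:
    """Centroid immune fractions for the five clusters (22 cell types).

    Synthetic profiles: a common colonic-tumor baseline with cluster-specific
    T-reg / T-helper shifts so that cluster 3 has the highest and cluster 2
    the lowest T-reg/T-helper ratio.  These are configuration defaults, not
    measured values.
    """
    base = {
        "B_cells_naive": 0.04, "B_cells_memory": 0.02, "Plasma_cells": 0.08,
        "T_cells_CD8": 0.10, "T_cells_CD4_naive": 0.03,
        "T_cells_CD4_memory_resting": 0.14, "T_cells_CD4_memory_activated": 0.06,
        "T_cells_follicular_helper": 0.05, "T_cells_regulatory_Tregs": 0.05,
        "T_cells_gamma_delta": 0.01, "NK_cells_resting": 0.03,
        "NK_cells_activated": 0.02, "Monocytes": 0.04, "Macrophages_M0": 0.10,
        "Macrophages_M1": 0.05, "Macrophages_M2": 0.08,
        "Dendritic_cells_resting": 0.02, "Dendritic_cells_activated": 0.01,
        "Mast_cells_resting": 0.04, "Mast_cells_activated": 0.01,
        "Eosinophils": 0.01, "Neutrophils": 0.01,
    }
    # (treg multiplier, Th-activated multiplier) per cluster
    shifts = {1: (1.0, 1.0), 2: (0.4, 1.6), 3: (2.2, 0.6), 4: (1.4, 0.9),
              5: (0.8, 1.2)}
    rows = {}
    for cluster, (f_treg, f_th) in shifts.items():
        prof = dict(base)
        prof["T_cells_regulatory_Tregs"] *= f_treg
        prof["T_cells_CD4_memory_activated"] *= f_th
        total = sum(prof.values())
        rows[cluster] = {k: v / total for k, v in prof.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(LM22_CELL_TYPES)]
    df.index.name = "cluster"
    return df


def tumor_scalars(longest_cm: float, shortest_cm: float, necrosis_fraction: float,
                  cohort_mean_size: float, alpha_dim: float = 7.5e4) -> dict:
    """Cell densities (cells/cm^3) from tumor dimensions and necrosis.

    size = longest x shortest; TCD = alpha_dim * size / cohort mean size;
    N = TCD * Np; C = (2/3) TCD (1 - Np); TIC = 0.5 C.
    """
    if longest_cm <= 0 or shortest_cm <= 0:
        raise ValueError("tumor dimensions must be positive")
    if cohort_mean_size <= 0:
        raise ValueError("cohort_mean_size must be positive")
    if not 0.0 <= necrosis_fraction <= 1.0:
        raise ValueError("necrosis_fraction must be in [0, 1]")
    size = longest_cm * shortest_cm
    tcd = alpha_dim * size / cohort_mean_size
    n = tcd * necrosis_fraction
    c = (2.0 / 3.0) * tcd * (1.0 - necrosis_fraction)
    tic = 0.5 * c
    return {"TCD": tcd, "N": n, "C": c, "TIC": tic}


@dataclass
class CohortConfig:
    """Sampling parameters of the synthetic cohort generator."""

    dirichlet_concentration: float = 200.0    # around the cluster centroid
    longest_median_cm: float = 5.0
    longest_sigma: float = 0.35               # log-scale sd
    shortest_median_cm: float = 3.2
    shortest_sigma: float = 0.35
    necrosis_mean: float = 0.1
    necrosis_concentration: float = 50.0      # Beta(a, b), a + b
    dose_min: dict = field(default_factory=lambda: dict(MIN_DOSES_MG))
    dose_median: dict = field(default_factory=lambda: dict(MEDIAN_DOSES_MG))
    n_cycles: int = DEFAULT_N_CYCLES
    cycle_length: float = DEFAULT_CYCLE_LENGTH_DAYS
    start_day: float = 0.0
    # follow-up offsets (days after treatment start) span late treatment
    # through post-recurrence so cohorts contain both tumor statuses
    followup_day_range: tuple = (150.0, 1200.0)


def generate_cohort(n: int, cluster_mix=(0.2, 0.2, 0.2, 0.2, 0.2),
                    seed: int | None = None,
                    config: CohortConfig | None = None) -> pd.DataFrame:
    """Sample ``n`` synthetic patient records (one row each).

    Immune fractions are Dirichlet-distributed around the assigned cluster's
    centroid; dimensions are log-normal; necrosis is Beta with mean ~0.1;
    per-cycle doses are uniform between the cohort minimum and twice the
    median.  Deterministic in ``(n, cluster_mix, seed, config)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(cluster_mix, dtype=float)
    if mix.shape != (5,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("cluster_mix must be five non-negative fractions summing to 1")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    centroids = cluster_centroids()

    clusters = rng.choice(np.arange(1, 6), size=n, p=mix)
    rows = []
    for i in range(n):
        cl = int(clusters[i])
        alpha = cfg.dirichlet_concentration * centroids.loc[cl].to_numpy()
        fracs = rng.dirichlet(alpha)
        longest = float(cfg.longest_median_cm * np.exp(rng.normal(0, cfg.longest_sigma)))
        shortest = float(cfg.shortest_median_cm * np.exp(rng.normal(0, cfg.shortest_sigma)))
        if shortest > longest:
            longest, shortest = shortest, longest
        a = cfg.necrosis_mean * cfg.necrosis_concentration
        b = (1.0 - cfg.necrosis_mean) * cfg.necrosis_concentration
        necrosis = float(rng.beta(a, b))
        doses = {d: float(rng.uniform(cfg.dose_min[d], 2.0 * cfg.dose_median[d]))
                 for d in ("FU", "LV", "Ir")}
        followup = cfg.start_day + float(rng.uniform(*cfg.followup_day_range))
        row = {
            "patient_id": f"SYN-{i:04d}", "cluster": cl,
            "longest_cm": longest, "shortest_cm": shortest,
            "necrosis_pct": necrosis,
            "dose_5fu_mg": doses["FU"], "dose_lv_mg": doses["LV"],
            "dose_ir_mg": doses["Ir"],
            "n_cycles": cfg.n_cycles, "cycle_length_days": cfg.cycle_length,
            "start_day": cfg.start_day, "followup_day": followup, "status": "",
        }
        for name, f in zip(LM22_CELL_TYPES, fracs):
            row[f"frac_{name}"] = float(f)
        rows.append(row)
    return pd.DataFrame(rows)


def regimen_from_record(record) -> Regimen:
    """Build the prescribed regimen from one cohort row (Series or dict)."""
    return Regimen(
        dose_5fu=float(record["dose_5fu_mg"]),
        dose_lv=float(record["dose_lv_mg"]),
        dose_ir=float(record["dose_ir_mg"]),
        n_cycles=int(record["n_cycles"]),
        cycle_length=float(record["cycle_length_days"]),
        start_day=float(record["start_day"]),
    )


def assign_followup(record, trajectory, label_noise: float = 0.0,
                    rng=None) -> dict:
    """Model-generated tumor status at the record's follow-up day.

    The ground-truth label applies the tumor-status rule (tumor-free iff the
    simulated cancer is below the initial value, or half of it for large
    tumors) and is flipped with probability ``label_noise``.  Records whose
    follow-up precedes the end of treatment are flagged excluded.
    """
    from .validation import expected_tumor_free, size_class  # no cycle: validation does not import cohort

    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must be in [0, 1]")
    day = float(record["followup_day"])
    if day > trajectory.t[-1]:
        raise ValueError(f"follow-up day {day} outside the simulated horizon")
    regimen = regimen_from_record(record)
    excluded = day < regimen.end_day

    c0 = trajectory.cancer_at(0.0)
    cf = trajectory.cancer_at(day)
    label = "tumor_free" if expected_tumor_free(c0, cf, size_class(c0)) else "with_tumor"
    if label_noise > 0:
        if rng is None:
            raise ValueError("label_noise > 0 requires an rng (or seed)")
        if not hasattr(rng, "random"):
            rng = np.random.default_rng(rng)
        if rng.random() < label_noise:
            label = "with_tumor" if label == "tumor_free" else "tumor_free"
    return {"status": label, "excluded": bool(excluded),
            "cancer_at_followup": cf, "cancer_initial": c0}


def refit_clusters(cohort: pd.DataFrame, k: int = 5, seed: int = 0) -> np.ndarray:
    """Optional k-means re-clustering of the immune fractions (plumbing)."""
    from sklearn.cluster import KMeans

    cols = [f"frac_{name}" for name in LM22_CELL_TYPES]
    X = cohort[cols].to_numpy()
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)
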