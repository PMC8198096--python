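"""Flat key-value serialization of parameter sets and tidy CSV outputs."""

from __future__ import annotations

import pandas as pd

from .model import BaselineParams, TreatmentParams

__all__ = ["write_params", "read_params", "write_trajectory_csv"]


def write_params(path, baseline: BaselineParams,
                 treatment: TreatmentParams | None = None) -> None:
    """One ``name = value`` line per parameter symbol (injection functions
    are regimen-derived and not serialized)."""
    with open(path, "w") as fh:
        for name, value in baseline.to_dict().items():
            fh.write(f"{name} = {value!r}\n")
        if treatment is not None:
            for name, value in treatment.to_dict().items():
                fh.write(f"{name} = {value!r}\n")


def read_params(path):
    """Inverse of :func:`write_params`; returns (BaselineParams,
    TreatmentParams or None)."""
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = float(raw)
    baseline = BaselineParams.from_dict(values)
    has_treatment = all(k in values for k in TreatmentParams.RATE_NAMES)
    treatment = TreatmentParams.from_dict(values) if has_treatment else None
    return baseline, treatment


def write_trajectory_csv(path, trajectory, scenario: str = "") -> None:
    """Tidy long-format trajectory (time_days, variable, value, scenario)."""
    trajectory.to_frame(scenario).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)
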