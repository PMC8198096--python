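"""Tumor-status prediction and ROC validation.

Each patient's regimen is simulated from their cluster's initial conditions,
the cancer density is read at the recorded follow-up day, and the cohort of
(prediction, observed status) pairs is scored by a threshold-sweep ROC curve
with *tumor free* as the positive class: a patient is called tumor free when
the predicted cancer value falls below the threshold.

The per-patient matching rule compares the follow-up cancer value with the
initial one (or half of it for large tumors); the regulatory T-cell summary
contrasts pre- and post-treatment T-reg levels in high- and low-T-reg groups
with a paired location test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import cluster_initial_conditions, regimen_from_record
from .model import STATE_NAMES, StateVector
from .simulation import Trajectory, simulate

__all__ = [
    "LARGE_TUMOR_CUTOFF",
    "RocCurve",
    "size_class",
    "expected_tumor_free",
    "predict_at_followup",
    "predict_cohort",
    "roc_auc",
    "status_match",
    "treg_pre_post",
]

#: A tumor counts as "large" when its initial dimensionless cancer density is
#: at least half the steady-state value.  Config-overridable via the
#: ``cutoff`` arguments below.
LARGE_TUMOR_CUTOFF = 0.5

C_IDX = STATE_NAMES.index("C")
TR_IDX = STATE_NAMES.index("Tr")


def size_class(initial_cancer: float, cutoff: float = LARGE_TUMOR_CUTOFF) -> str:
    """'large' for initial cancer >= cutoff, else 'small_medium'."""
    return "large" if initial_cancer >= cutoff else "small_medium"


def expected_tumor_free(c0: float, c_followup: float, klass: str) -> bool:
    """Tumor-free expectation: cancer below the initial value (small/medium)
    or below half the initial value (large)."""
    if klass == "large":
        return c_followup < 0.5 * c0
    return c_followup < c0


def predict_at_followup(record, baseline, treatment, scaling=None,
                        ic_kind: str = "smallest",
                        rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate one patient's regimen; return (cancer at follow-up, Trajectory)."""
    day = float(record["followup_day"])
    regimen = regimen_from_record(record)
    initial = cluster_initial_conditions(int(record["cluster"]), ic_kind)
    horizon = max(day, regimen.course_end_day) + 1.0
    traj = simulate(initial, baseline, treatment, regimen, scaling,
                    horizon=horizon, eval_days=[day], rtol=rtol, atol=atol)
    return float(traj.eval_days[day][C_IDX]), traj


def predict_cohort(cohort: pd.DataFrame, baseline, treatment, scaling=None,
                   ic_kind: str = "smallest", cutoff: float = LARGE_TUMOR_CUTOFF,
                   rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Prediction table: one row per record with predicted cancer at
    follow-up, size class, inclusion flag and T-reg pre/post values."""
    rows = []
    for _, rec in cohort.iterrows():
        regimen = regimen_from_record(rec)
        pred, traj = predict_at_followup(rec, baseline, treatment, scaling,
                                         ic_kind, rtol=rtol, atol=atol)
        c0 = traj.cancer_at(0.0)
        rows.append({
            "patient_id": rec["patient_id"],
            "cluster": int(rec["cluster"]),
            "followup_day": float(rec["followup_day"]),
            "prediction": pred,
            "cancer_initial": c0,
            "size_class": size_class(c0, cutoff),
            "observed_status": rec.get("status", ""),
            "included": bool(rec["followup_day"] >= regimen.end_day),
            "treg_pre": float(traj.state_at(regimen.start_day)[TR_IDX]),
            "treg_post": float(traj.state_at(min(regimen.end_day, traj.t[-1]))[TR_IDX]),
        })
    return pd.DataFrame(rows)


@dataclass
class RocCurve:
    """Threshold sweep with tumor_free as the positive class."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(predictions, labels, n_thresholds: int = 101) -> RocCurve:
    """ROC curve over a uniform threshold grid spanning the predictions.

    A record is classified tumor free when its prediction is strictly below
    the threshold.  TPR/FPR are computed per threshold with tumor_free
    positive; the standard (0,0) and (1,1) anchors complete the sweep and the
    AUC is the trapezoid over the sorted (FPR, TPR) sequence.
    """
    preds = np.asarray(predictions, dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ValueError("predictions must be finite")
    y = np.asarray([1 if lab == "tumor_free" else 0 for lab in labels])
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both tumor_free and with_tumor labels are required")
    thresholds = np.linspace(preds.min(), preds.max(), n_thresholds)
    tpr = np.array([(preds[y == 1] < th).mean() for th in thresholds])
    fpr = np.array([(preds[y == 0] < th).mean() for th in thresholds])
    # anchor the sweep endpoints: no record called positive / all called positive
    fpr_full = np.concatenate([[0.0], fpr, [1.0]])
    tpr_full = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr_full, fpr_full))
    auc = float(np.trapezoid(tpr_full[order], fpr_full[order]))
    return RocCurve(thresholds=thresholds, fpr=fpr_full[order],
                    tpr=tpr_full[order], auc=auc)


def status_match(record, trajectory: Trajectory,
                 cutoff: float = LARGE_TUMOR_CUTOFF) -> bool:
    """Whether the simulated trajectory agrees with the observed status.

    Expected tumor free iff C(follow-up) < C(0) for small/medium tumors or
    < C(0)/2 for large; a with-tumor observation matches the negation.
    """
    observed = record.get("status", "") if hasattr(record, "get") else record["status"]
    if observed not in ("tumor_free", "with_tumor"):
        raise ValueError(f"record has no usable tumor status ({observed!r})")
    c0 = trajectory.cancer_at(0.0)
    cf = trajectory.cancer_at(float(record["followup_day"]))
    expect_free = expected_tumor_free(c0, cf, size_class(c0, cutoff))
    return expect_free == (observed == "tumor_free")


def treg_pre_post(table: pd.DataFrame, grouping_threshold: float | None = None,
                  test: str = "ttest") -> pd.DataFrame:
    """Paired pre/post-treatment T-reg comparison in high/low T-reg groups.

    ``table`` needs columns ``treg_pre`` and ``treg_post``; the grouping
    threshold defaults to the median pre-treatment value.  ``test`` is
    'ttest' (paired t) or 'wilcoxon'.  Groups with no members are reported
    absent (NaN row); identical pre/post values give difference 0, p = 1.
    """
    pre = table["treg_pre"].to_numpy(dtype=float)
    post = table["treg_post"].to_numpy(dtype=float)
    thr = float(np.median(pre)) if grouping_threshold is None else grouping_threshold
    rows = []
    for name, mask in (("high_treg", pre >= thr), ("low_treg", pre < thr)):
        if not mask.any():
            rows.append({"group": name, "n": 0, "mean_pre": np.nan,
                         "mean_post": np.nan, "mean_diff": np.nan, "p_value": np.nan})
            continue
        a, b = pre[mask], post[mask]
        diff = b - a
        if np.allclose(diff, 0.0):
            p = 1.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(a, b).pvalue)
        elif test == "ttest":
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            raise ValueError(f"unknown paired test {test!r}")
        rows.append({"group": name, "n": int(mask.sum()),
                     "mean_pre": float(a.mean()), "mean_post": float(b.mean()),
                     "mean_diff": float(diff.mean()), "p_value": p})
    return pd.DataFrame(rows)
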