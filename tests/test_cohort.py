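"""Tests of tumor-scalar arithmetic and the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from folfiri_tme.cohort import (LM22_CELL_TYPES, CohortConfig, assign_followup,
                                cluster_centroids, cluster_initial_conditions,
                                generate_cohort, load_initial_condition_table,
                                load_dosage_table, refit_clusters,
                                regimen_from_record, tumor_scalars)
from folfiri_tme.dosing import Regimen
from folfiri_tme.model import BASELINE_STATE_NAMES, StateVector
from folfiri_tme.simulation import simulate


class TestTumorScalars:
    def test_average_size_tumor_reference_densities(self):
        out = tumor_scalars(2.0, 3.0, 0.1, cohort_mean_size=6.0, alpha_dim=7.5e4)
        assert out["TCD"] == pytest.approx(7.5e4)
        assert out["C"] == pytest.approx(4.5e4)
        assert out["N"] == pytest.approx(7.5e3)
        assert out["TIC"] == pytest.approx(2.25e4)

    def test_full_necrosis_leaves_no_cancer(self):
        out = tumor_scalars(2.0, 2.0, 1.0, cohort_mean_size=4.0)
        assert out["N"] == pytest.approx(out["TCD"])
        assert out["C"] == 0.0 and out["TIC"] == 0.0

    def test_composition_ratio_at_ten_percent_necrosis(self):
        out = tumor_scalars(1.7, 0.9, 0.1, cohort_mean_size=2.9)
        ratios = np.array([out["TIC"], out["C"], out["N"]]) / out["TCD"]
        np.testing.assert_allclose(ratios, [0.3, 0.6, 0.1], rtol=1e-12)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            tumor_scalars(0.0, 1.0, 0.1, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.99), st.floats(0.1, 20.0), st.floats(0.1, 20.0))
    def test_composition_identities(self, np_frac, a, b):
        """N/TCD = Np and C = 2 TIC for any necrosis fraction."""
        out = tumor_scalars(max(a, b), min(a, b), np_frac, cohort_mean_size=5.0)
        assert out["N"] / out["TCD"] == pytest.approx(np_frac, abs=1e-12)
        assert out["C"] == pytest.approx(2.0 * out["TIC"], rel=1e-12)
        assert out["TIC"] + out["C"] == pytest.approx(out["TCD"] * (1 - np_frac),
                                                      rel=1e-12)


class TestClusterInitialConditions:
    def test_cluster3_printed_values(self):
        sv = cluster_initial_conditions(3)
        assert sv["C"] == pytest.approx(1.83e-1)
        assert sv["N"] == 0.0
        assert sv["Gbeta"] == pytest.approx(3.87)

    def test_cluster4_printed_values(self):
        sv = cluster_initial_conditions(4)
        assert sv["H"] == pytest.approx(14.6)
        assert sv["Igamma"] == 0.0
        assert sv["mu2"] == pytest.approx(57.7)

    def test_steady_kind_is_all_ones(self):
        sv = cluster_initial_conditions(1, "steady")
        np.testing.assert_array_equal(sv.values[:14], 1.0)
        np.testing.assert_array_equal(sv.values[14:], 0.0)

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_initial_conditions(6)

    def test_drugs_start_at_zero_for_all_clusters(self):
        for cl in range(1, 6):
            assert np.all(cluster_initial_conditions(cl).values[14:] == 0.0)


class TestFixtureTables:
    def test_initial_condition_table_round_trips_bit_exactly(self, tmp_path):
        raw = load_initial_condition_table(as_strings=True)
        path = tmp_path / "copy.csv"
        raw.to_csv(path, index=False)
        again = pd.read_csv(path, dtype=str)
        assert raw.equals(again)

    def test_dosage_table_medians(self):
        tab = load_dosage_table()
        assert list(tab.loc["median"]) == [770, 725, 300]
        assert list(tab.loc["min"]) == [598, 75, 208]
        assert tab.loc["number_of_cycles", "Fluorouracil"] == 12
        assert tab.loc["cycle_length", "Irinotecan"] == 14


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        a = generate_cohort(25, seed=5)
        b = generate_cohort(25, seed=5)
        assert a.equals(b)
        c = generate_cohort(25, seed=6)
        assert not a.equals(c)

    def test_large_sample_statistics(self):
        cohort = generate_cohort(1000, seed=3)
        fracs = cohort[[f"frac_{n}" for n in LM22_CELL_TYPES]].to_numpy()
        np.testing.assert_allclose(fracs.sum(axis=1), 1.0, atol=1e-9)
        assert abs(cohort["necrosis_pct"].mean() - 0.1) < 0.02
        centroids = cluster_centroids()
        for cl in range(1, 6):
            sub = cohort[cohort["cluster"] == cl]
            mean_fracs = sub[[f"frac_{n}" for n in LM22_CELL_TYPES]].mean()
            np.testing.assert_allclose(mean_fracs.to_numpy(),
                                       centroids.loc[cl].to_numpy(), atol=0.01)

    def test_doses_within_configured_bounds(self):
        cohort = generate_cohort(300, seed=9)
        assert cohort["dose_5fu_mg"].between(598, 1540).all()
        assert cohort["dose_lv_mg"].between(75, 1450).all()
        assert cohort["dose_ir_mg"].between(208, 600).all()

    def test_pure_cluster_mix(self):
        cohort = generate_cohort(50, (1, 0, 0, 0, 0), seed=2)
        assert (cohort["cluster"] == 1).all()

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(10, (0.5, 0.5, 0.5, 0, 0), seed=1)

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(10)

    def test_treg_th_ratio_ordering_of_centroids(self):
        """Cluster 3 highest, cluster 2 lowest T-reg/T-helper ratio."""
        c = cluster_centroids()
        ratio = (c["T_cells_regulatory_Tregs"]
                 / c["T_cells_CD4_memory_activated"])
        assert ratio.idxmax() == 3
        assert ratio.idxmin() == 2


@pytest.fixture(scope="module")
def setup(derived):
    base, treat, scal = derived
    cohort = generate_cohort(4, (1, 0, 0, 0, 0), seed=13)
    rec = cohort.iloc[0].copy()
    reg = regimen_from_record(rec)
    init = cluster_initial_conditions(1)
    traj = simulate(init, base, treat, reg, scal,
                    horizon=max(rec["followup_day"], reg.course_end_day) + 1)
    return rec, traj


class TestAssignFollowup:
    def test_noise_free_label_follows_threshold_rule(self, setup):
        rec, traj = setup
        out = assign_followup(rec, traj, 0.0)
        c0, cf = out["cancer_initial"], out["cancer_at_followup"]
        expected = "tumor_free" if cf < c0 else "with_tumor"  # small tumor
        assert out["status"] == expected

    def test_early_followup_flagged_excluded(self, setup):
        rec, traj = setup
        early = rec.copy()
        early["followup_day"] = 100.0  # before the 168-day course ends
        out = assign_followup(early, traj, 0.0)
        assert out["excluded"] is True

    def test_half_noise_labels_are_coin_flips(self, derived):
        """At label_noise 0.5 the labels are independent of the trajectory."""
        base, treat, scal = derived
        cfg = CohortConfig(followup_day_range=(170.0, 1200.0))
        cohort = generate_cohort(500, (1, 0, 0, 0, 0), seed=21, config=cfg)
        reg = Regimen()
        traj = simulate(cluster_initial_conditions(1), base, treat, reg, scal,
                        horizon=1401.0)
        rng = np.random.default_rng(77)
        noisy, clean = [], []
        for _, rec in cohort.iterrows():
            rec = rec.copy()
            for col, val in (("dose_5fu_mg", 770.0), ("dose_lv_mg", 725.0),
                             ("dose_ir_mg", 300.0)):
                rec[col] = val  # all records share the simulated regimen
            noisy.append(assign_followup(rec, traj, 0.5, rng)["status"])
            clean.append(assign_followup(rec, traj, 0.0)["status"])
        noisy = np.array([s == "tumor_free" for s in noisy])
        clean = np.array([s == "tumor_free" for s in clean])
        # agreement rate should be ~0.5 under independence (binomial, n=500)
        agreement = (noisy == clean).mean()
        assert 0.43 < agreement < 0.57

    def test_followup_outside_horizon_rejected(self, setup, derived):
        rec, traj = setup
        far = rec.copy()
        far["followup_day"] = traj.t[-1] + 100.0
        with pytest.raises(ValueError):
            assign_followup(far, traj, 0.0)


def test_refit_clusters_recovers_groupings():
    """k-means on well-separated synthetic fractions is deterministic
    plumbing: same seed, same labels, five groups."""
    cohort = generate_cohort(200, seed=31)
    labels = refit_clusters(cohort, k=5, seed=0)
    labels2 = refit_clusters(cohort, k=5, seed=0)
    np.testing.assert_array_equal(labels, labels2)
    assert len(np.unique(labels)) == 5
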