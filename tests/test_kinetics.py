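"""Leaflet assignment, event detection, rate statistics, and kinetics math."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scramblekit as sk
from scramblekit.constants import R_KJ
from scramblekit.kinetics import FlipFlopEvent


def _scripted_trajectory(dz_series, box_z=12.0):
    """One lipid whose head-tail z separation follows dz_series."""
    nf = len(dz_series)
    pos = np.zeros((nf, 2, 3), dtype=float)
    zc = box_z / 2
    pos[:, 0, 2] = zc + np.asarray(dz_series) / 2  # head
    pos[:, 1, 2] = zc - np.asarray(dz_series) / 2  # tail
    pos[:, :, 0] = 5.0
    pos[:, :, 1] = 5.0
    traj = sk.Trajectory(
        times=np.arange(nf, dtype=float),
        positions=pos,
        box=np.tile([10.0, 10.0, box_z], (nf, 1)),
        names=np.array(["PO4", "C4B"]),
        resnames=np.array(["POPC", "POPC"]),
        resids=np.array([1, 1]),
    )
    lipids = sk.LipidSet(
        lipid_ids=np.array([1]), lipid_types=np.array(["POPC"]),
        head_indices=np.array([0]), tail_indices=np.array([1]),
    )
    return traj, lipids


class TestAssignLeaflets:
    def test_zero_separation_stays_undetermined_and_assignment_frozen(self):
        traj, lipids = _scripted_trajectory([0.0] * 20)
        states = sk.assign_leaflets(traj, lipids, threshold=2.1)
        assert np.all(states.instantaneous == 0)
        assert np.all(states.assigned == states.assigned[0, 0])

    def test_sign_convention_switch_inverts_labels_not_counts(self):
        dz = [3.0] * 5 + [0.0] * 3 + [-3.0] * 5
        traj, lipids = _scripted_trajectory(dz)
        s_nat = sk.assign_leaflets(traj, lipids, leaflet_sign=1)
        s_inv = sk.assign_leaflets(traj, lipids, leaflet_sign=-1)
        assert np.array_equal(s_nat.instantaneous, -s_inv.instantaneous)
        n_nat = len(sk.detect_events(s_nat, traj, lipids))
        n_inv = len(sk.detect_events(s_inv, traj, lipids))
        assert n_nat == n_inv == 1

    def test_rate_zero_system_has_constant_assignments(self, quiet_system):
        _spec, traj, lipids, _sites, _log = quiet_system
        states = sk.assign_leaflets(traj, lipids)
        assert np.all(states.assigned == states.assigned[0])


class TestDetectEvents:
    def test_single_scripted_crossing(self):
        dz = [3.0] * 10 + list(np.linspace(3, -3, 20)) + [-3.0] * 10
        traj, lipids = _scripted_trajectory(dz)
        states = sk.assign_leaflets(traj, lipids)
        events = sk.detect_events(states, traj, lipids)
        assert len(events) == 1
        assert events[0].direction == "upper->lower"

    def test_hysteresis_suppresses_midplane_excursion(self):
        # dip into the undetermined band and return: no event
        dz = [3.0] * 10 + [0.5] * 10 + [3.0] * 10
        traj, lipids = _scripted_trajectory(dz)
        states = sk.assign_leaflets(traj, lipids)
        assert len(sk.detect_events(states, traj, lipids)) == 0

    def test_detected_events_match_generator_truth(self, small_system):
        spec, traj, lipids, _sites, log = small_system
        states = sk.assign_leaflets(traj, lipids)
        events = sk.detect_events(states, traj, lipids)
        assert len(events) == len(log)
        # each detected event lies within the transit window of a true event
        det = sk.events_to_dataframe(events).sort_values(["lipid_id", "time_ns"])
        tru = log.to_dataframe().sort_values(["lipid_id", "t_start_ns"])
        for (_, d), (_, t) in zip(det.iterrows(), tru.iterrows()):
            assert d["lipid_id"] == t["lipid_id"]
            assert (
                t["t_start_ns"] - spec.dt_ns
                <= d["time_ns"]
                <= t["t_start_ns"] + spec.transit_time_ns + spec.dt_ns
            )

    def test_directions_alternate_per_lipid(self, small_system):
        _spec, traj, lipids, _sites, _log = small_system
        states = sk.assign_leaflets(traj, lipids)
        df = sk.events_to_dataframe(sk.detect_events(states, traj, lipids))
        for _lid, grp in df.groupby("lipid_id"):
            dirs = grp.sort_values("time_ns")["direction"].tolist()
            assert all(a != b for a, b in zip(dirs, dirs[1:]))


class TestSiteAssignment:
    def test_no_sites_means_bulk(self, small_system):
        _spec, traj, lipids, _sites, _log = small_system
        states = sk.assign_leaflets(traj, lipids)
        events = sk.detect_events(states, traj, lipids)
        empty = sk.ProteinSites(sites={}, reference_indices=np.array([0]))
        labelled = sk.assign_events_to_sites(events, empty, traj)
        assert all(e.site == "bulk" for e in labelled)

    def test_site_localized_flips_labelled_with_true_site(self, small_system):
        _spec, traj, lipids, sites, log = small_system
        states = sk.assign_leaflets(traj, lipids)
        events = sk.assign_events_to_sites(
            sk.detect_events(states, traj, lipids), sites, traj, cutoff=2.0
        )
        det = sk.events_to_dataframe(events).sort_values(["lipid_id", "time_ns"])
        tru = log.to_dataframe().sort_values(["lipid_id", "t_start_ns"])
        matches = np.mean(det["site"].to_numpy() == tru["site"].to_numpy())
        assert matches >= 0.95

    def test_event_beyond_cutoff_is_bulk(self, small_system):
        _spec, traj, lipids, sites, _log = small_system
        ev = FlipFlopEvent(
            lipid_id=1, lipid_type="POPC", time_ns=0.0,
            direction="upper->lower",
            head_position=np.array([1.0, 1.0, 6.0]),  # far from both sites
        )
        out = sk.assign_events_to_sites([ev], sites, traj, cutoff=2.0)
        assert out[0].site == "bulk"


def _fake_events(n, site="Sec61", ltype="POPC"):
    return [
        FlipFlopEvent(
            lipid_id=i + 1, lipid_type=ltype, time_ns=float(i),
            direction="upper->lower", head_position=np.zeros(3), site=site,
        )
        for i in range(n)
    ]


class TestComputeRates:
    def test_zero_events_format_matches_zero_row(self):
        table = sk.compute_rates([[], [], [], [], []], [20.0] * 5)
        fmt = table.formatted()
        assert (fmt["rate"] == "0.0 ± 0.0").all()

    def test_exact_replica_counts_give_exact_rate(self):
        reps = [_fake_events(154) for _ in range(5)]
        table = sk.compute_rates(reps, [20.0] * 5)
        rate, se = table.lookup("Sec61", "POPC")
        assert rate == pytest.approx(7.7)
        assert se == pytest.approx(0.0)
        assert table.formatted()["rate"].iloc[0] == "7.7 ± 0.0"

    def test_total_row_sums_types(self):
        reps = [
            _fake_events(10, ltype="POPC") + _fake_events(6, ltype="POPE")
            for _ in range(3)
        ]
        table = sk.compute_rates(reps, [10.0] * 3)
        tot, _ = table.lookup("Sec61", "total")
        assert tot == pytest.approx(1.6)

    def test_synthetic_rate_recovered_within_three_se(self):
        spec = sk.SyntheticSpec(
            n_per_leaflet={"POPC": 60}, n_frames=5001, dt_ns=2.0,
            flip_rates={"POPC": {"Sec61": 2.2}}, seed=21,
        )
        per_rep, durations = [], []
        for r in range(5):
            s = sk.SyntheticSpec(**{**spec.__dict__, "seed": 100 + r})
            traj, lipids, sites, _log = sk.generate_trajectory(s)
            states = sk.assign_leaflets(traj, lipids)
            evs = sk.assign_events_to_sites(
                sk.detect_events(states, traj, lipids), sites, traj
            )
            per_rep.append(evs)
            durations.append(s.duration_us)
        table = sk.compute_rates(per_rep, durations)
        rate, se = table.lookup("Sec61", "POPC")
        assert abs(rate - 2.2) <= 3 * max(se, 1e-6)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            sk.compute_rates([[]], [0.0])


class TestThresholdScan:
    def test_monotone_and_plateau(self, small_system):
        _spec, traj, lipids, _sites, log = small_system
        thresholds = [1.6, 1.8, 2.0, 2.1, 2.2, 2.4, 2.6]
        scan = sk.threshold_scan(traj, lipids, thresholds)
        n = scan["n_events"].to_numpy()
        assert np.all(np.diff(n) <= 0)
        lo, hi = sk.plateau_window(scan, tol=0.10)
        assert lo <= 1.8 and hi >= 2.6  # clean data: flat across the band
        assert set(scan[scan["threshold_nm"].between(1.8, 2.6)]["n_events"]) == {len(log)}

    def test_threshold_beyond_max_separation_gives_zero(self, small_system):
        _spec, traj, lipids, _sites, _log = small_system
        scan = sk.threshold_scan(traj, lipids, [5.0])
        assert scan["n_events"].iloc[0] == 0


class TestArrhenius:
    def test_constant_rates_give_zero_activation_energy(self):
        fit = sk.fit_arrhenius([290, 310, 330], [2.0, 2.0, 2.0])
        assert fit.e_a == pytest.approx(0.0, abs=1e-12)

    def test_exact_arrhenius_rates_recovered(self):
        temps = [290.0, 300, 310, 320, 330]
        k = [sk.arrhenius_true_rate(40.0, 18.0, t) for t in temps]
        fit = sk.fit_arrhenius(temps, k)
        assert fit.e_a == pytest.approx(40.0, abs=1e-9)
        assert np.allclose(fit.predict(np.array(temps)), k)

    def test_zero_rate_rejected_with_advice(self):
        with pytest.raises(ValueError, match="exclude"):
            sk.fit_arrhenius([290, 310, 330], [0.0, 1.0, 2.0])

    def test_two_temperatures_rejected(self):
        with pytest.raises(ValueError):
            sk.fit_arrhenius([300, 320], [1.0, 2.0])

    def test_weighted_mode_runs_and_differs(self):
        temps = [290.0, 300, 310, 320, 330]
        k = [1.7, 3.3, 7.7, 14.3, 26.0]
        se = [0.4, 0.6, 0.7, 1.1, 1.0]
        fw = sk.fit_arrhenius(temps, k, errors=se, weighted=True)
        fu = sk.fit_arrhenius(temps, k)
        assert fw.e_a != fu.e_a
        assert 45 < fw.e_a < 60


class TestEyring:
    def test_equal_barriers_give_unity(self):
        assert sk.eyring_speedup(59.2, 59.2, 310.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        g_ref=st.floats(1.0, 80.0),
        g_new=st.floats(1.0, 80.0),
        temp=st.floats(250.0, 400.0),
    )
    def test_fold_equals_rate_ratio(self, g_ref, g_new, temp):
        fold = sk.eyring_speedup(g_ref, g_new, temp)
        ratio = sk.eyring_rate(g_new, temp) / sk.eyring_rate(g_ref, temp)
        assert fold == pytest.approx(ratio, rel=1e-9)

    def test_fold_strictly_decreasing_in_new_barrier(self):
        folds = [sk.eyring_speedup(59.2, g, 310.0) for g in (5.0, 10.0, 20.0, 40.0)]
        assert all(a > b for a, b in zip(folds, folds[1:]))

    def test_half_life_scaling(self):
        month_s = 30 * 24 * 3600.0
        fold = sk.eyring_speedup(59.2, 10.8, 310.0)
        assert sk.scaled_half_life(month_s, fold) < 1.0  # sub-second


class TestCompareRates:
    def test_identical_groups_p_one(self):
        assert sk.compare_rates([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_separated_groups_significant(self):
        a = [6.5, 6.3, 6.8, 6.4, 6.6]
        b = [2.2, 2.1, 2.4, 2.2, 2.3]
        assert sk.compare_rates(a, b) < 0.01

    def test_type_one_error_near_alpha(self, rng):
        # both groups from the same Poisson counting process
        n_sim, alpha = 1000, 0.05
        false_pos = 0
        for _ in range(n_sim):
            a = rng.poisson(40, size=5) / 20.0
            b = rng.poisson(40, size=5) / 20.0
            try:
                if sk.compare_rates(a, b) < alpha:
                    false_pos += 1
            except ValueError:
                pass
        rate = false_pos / n_sim
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_sim)

    def test_too_few_replicas_rejected(self):
        with pytest.raises(ValueError):
            sk.compare_rates([1.0], [2.0, 3.0])
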