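"""Geometric detectors against brute-force oracles and planted truth."""

import numpy as np
import pytest

from clcpipe import synthetic_data as sd, trajectory_analysis as ta
from clcpipe.core_io import AnalysisConfig

from conftest import make_water_frame


def brute_force_pairs(traj, frame, cutoff, angle_min):
    """Independent O(n^2) hydrogen-bond oracle over water oxygens."""
    xyz = traj.coords[frame]
    o_idx = traj.indices_by_role("water_O")
    h_by_o = traj.water_hydrogens()
    pairs = set()
    for a in o_idx:
        for b in o_idx:
            if a >= b or np.linalg.norm(xyz[a] - xyz[b]) > cutoff:
                continue
            for donor, acc in ((a, b), (b, a)):
                for h in h_by_o.get(donor, []):
                    u = xyz[donor] - xyz[h]
                    v = xyz[acc] - xyz[h]
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                        pairs.add((min(a, b), max(a, b)))
    return pairs


class TestHBondGraph:
    def test_two_waters_within_cutoff_and_angle(self, config):
        traj = make_water_frame([(0, 0, 0), (2.8, 0, 0)],
                                h_directions=[(1, 0, 0), (0, 1, 0)])
        g = ta.build_hbond_graph(traj, 0, config).graph
        water_edges = [(u, v) for u, v in g.edges
                       if isinstance(u, int) and isinstance(v, int)]
        assert len(water_edges) == 1

    def test_two_waters_beyond_cutoff(self, config):
        traj = make_water_frame([(0, 0, 0), (5.0, 0, 0)])
        g = ta.build_hbond_graph(traj, 0, config).graph
        assert g.number_of_edges() == 0

    def test_bad_angle_rejected(self, config):
        # donor hydrogens point away from the acceptor: distance passes,
        # angle fails both ways
        traj = make_water_frame([(0, 0, 0), (3.0, 0, 0)],
                                h_directions=[(-1, 0, 0), (1, 0, 0)])
        g = ta.build_hbond_graph(traj, 0, config).graph
        assert g.number_of_edges() == 0

    def test_three_collinear_waters_form_path(self, config):
        traj = make_water_frame([(0, 0, 0), (2.8, 0, 0), (5.6, 0, 0)],
                                h_directions=[(1, 0, 0), (1, 0, 0),
                                              (-1, 0, 0)])
        g = ta.build_hbond_graph(traj, 0, config).graph
        water_edges = [(u, v) for u, v in g.edges
                       if isinstance(u, int) and isinstance(v, int)]
        assert len(water_edges) == 2
        assert brute_force_pairs(traj, 0, 3.5, 150.0) == {
            (i, j) for i, j in [(0, 3), (3, 6)]}

    def test_matches_brute_force_oracle_on_random_frames(self, config):
        """Detector edges equal the exhaustive pairwise oracle on frames
        of <= 20 waters."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(5, 20))
            pos = rng.uniform(-6, 6, (n, 3))
            dirs = rng.normal(size=(n, 3))
            traj = make_water_frame(pos, h_directions=dirs)
            g = ta.build_hbond_graph(traj, 0, config).graph
            id2idx = {row.atom_id: i for i, row in
                      enumerate(traj.topology.itertuples())}
            got = {tuple(sorted((id2idx[u], id2idx[v])))
                   for u, v in g.edges
                   if isinstance(u, int) and isinstance(v, int)}
            assert got == brute_force_pairs(traj, 0, 3.5, 150.0)


class TestWireDetection:
    def test_planted_class2_recovered_on_exact_frames(self, config):
        spec = sd.TrajectorySpec(
            n_frames=30, wire_episodes=[sd.WireEpisode("A", 2, 10, 20)])
        recs = ta.detect_wires_trajectory(sd.gen_trajectory(spec), config)
        frames = sorted({r.frame_index for r in recs if r.wire_class == 2})
        assert frames == list(range(10, 21))
        assert not any(r.wire_class != 2 or r.subunit != "A" for r in recs)

    def test_no_waters_no_wires(self, config):
        spec = sd.TrajectorySpec(n_frames=5, n_bulk_waters=0)
        recs = ta.detect_wires_trajectory(sd.gen_trajectory(spec), config)
        assert recs == []

    def test_sink_mismatch_gives_no_record(self, config):
        spec = sd.TrajectorySpec(
            n_frames=4, wire_episodes=[sd.WireEpisode("A", 2, 0, 3)])
        traj = sd.gen_trajectory(spec)
        recs = ta.detect_wires_trajectory(traj, config, sink="extracellular")
        assert recs == []

    def test_class_paths_end_at_sink(self, config):
        spec = sd.TrajectorySpec(
            n_frames=3, wire_episodes=[sd.WireEpisode("B", 1, 0, 2)])
        traj = sd.gen_trajectory(spec)
        recs = ta.detect_wires_trajectory(traj, config)
        assert recs and all(r.path[-1] == "intracellular" for r in recs)
        assert all(r.subunit == "B" for r in recs)


class TestIonDistance:
    def test_constant_single_ion(self, config):
        spec = sd.TrajectorySpec(n_frames=5)
        traj = sd.gen_trajectory(spec)
        series = ta.nearest_ion_distance(traj)
        for s in series:
            assert np.allclose(s.raw, s.raw[0])
            assert s.raw[0] < 12.0

    def test_min_of_two_ions_matches_bruteforce(self):
        traj = make_water_frame(
            [], extra_atoms=[
                ("CA", "TYR", 445, "C", (0, 0, 0)),
                ("CL", "CLA", 2000, "CL", (4, 0, 0)),
                ("CL", "CLA", 2001, "CL", (9, 0, 0)),
            ])
        s = ta.nearest_ion_distance(traj)[0]
        assert s.raw[0] == pytest.approx(4.0)

    def test_equals_exhaustive_minimum_on_random_frames(self):
        rng = np.random.default_rng(21)
        ions = [("CL", "CLA", 2000 + i, "CL", rng.uniform(-20, 20, 3))
                for i in range(6)]
        traj = make_water_frame(
            [], extra_atoms=[("CA", "TYR", 445, "C", (1.0, -2.0, 3.0))] + ions,
            n_frames=1)
        s = ta.nearest_ion_distance(traj)[0]
        ref = traj.coords[0][traj.atom_index("A", 445, "CA")]
        want = min(np.linalg.norm(traj.coords[0][i] - ref)
                   for i in traj.indices_by_role("chloride"))
        assert s.raw[0] == pytest.approx(want)

    def test_no_ions_flags_infinite_series(self, config):
        traj = make_water_frame(
            [(0, 0, 0)], extra_atoms=[("CA", "TYR", 445, "C", (5, 5, 5))])
        s = ta.nearest_ion_distance(traj)[0]
        assert np.isinf(s.raw).all()
        assert s.flagged_empty


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        t = np.arange(10.0)
        v = np.full(10, 3.3)
        assert np.allclose(ta.moving_average(v, t, 4.0), v)

    def test_single_frame_window_is_identity(self):
        t = np.arange(5.0)
        v = np.array([1.0, 5.0, 2.0, 8.0, 0.0])
        assert np.array_equal(ta.moving_average(v, t, 1.0), v)

    def test_step_series_hand_computed(self):
        t = np.arange(5.0)
        v = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        got = ta.moving_average(v, t, 3.0)   # 3-frame centered window
        assert np.allclose(got, [0.0, 1 / 3, 2 / 3, 1.0, 1.0])


class TestLeavingEvents:
    def test_walked_ion_crosses_threshold_once(self, config):
        # raw distance ramps 3 -> 20 over the run
        t = np.arange(0, 200) * 0.2
        raw = np.linspace(3, 20, 200)
        s = ta.IonDistanceSeries("A", t, raw, nearest_z=np.full(200, 15.0))
        s = ta.detect_leaving_events(s, AnalysisConfig(min_dwell_ns=10.0))
        assert s.verdict == "left"
        assert len(s.events) == 1
        crossings = np.diff((s.smoothed > 12).astype(int))
        assert (crossings == 1).sum() == 1

    def test_all_below_threshold_stays(self, config):
        spec = sd.TrajectorySpec(n_frames=300, condition="Egate_protonated")
        traj = sd.gen_trajectory(spec)
        verdicts = [ta.detect_leaving_events(s, config).verdict
                    for s in ta.nearest_ion_distance(traj)]
        assert verdicts == ["stayed", "stayed"]

    def test_single_spike_below_dwell_is_not_an_event(self):
        t = np.arange(0, 600) * 0.2   # 120 ns span > 50 ns dwell
        raw = np.full(600, 5.0)
        raw[300] = 40.0
        s = ta.IonDistanceSeries("A", t, raw, nearest_z=np.zeros(600),
                                 smoothed=raw.copy())   # unsmoothed spike
        s = ta.detect_leaving_events(s, AnalysisConfig())
        assert s.verdict == "stayed"

    def test_short_series_indeterminate(self):
        t = np.arange(0, 10) * 0.2    # 1.8 ns << 50 ns dwell
        s = ta.IonDistanceSeries("A", t, np.full(10, 20.0),
                                 nearest_z=np.zeros(10))
        s = ta.detect_leaving_events(s, AnalysisConfig())
        assert s.verdict == "indeterminate"

    def test_invariant_to_rigid_motion(self, config):
        spec = sd.TrajectorySpec(
            n_frames=400,
            leaving_episodes=[sd.LeavingEpisode("A", 60, "extracellular")])
        traj = sd.gen_trajectory(spec)
        s0 = ta.detect_leaving_events(
            ta.nearest_ion_distance(traj)[0], config)
        # rigid rotation + translation of every coordinate
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        traj.coords = traj.coords @ q.T + np.array([100.0, -50.0, 30.0])
        s1 = ta.detect_leaving_events(
            ta.nearest_ion_distance(traj)[0], config)
        assert s1.verdict == s0.verdict == "left"
        assert [e.onset_time_ns for e in s1.events] == \
               [e.onset_time_ns for e in s0.events]

    def test_aggregate_k_of_n(self, config):
        """8 of 10 replicate trajectories planted with leaving events."""
        series = []
        for rep in range(10):
            eps = ([sd.LeavingEpisode("A", 60, "extracellular")]
                   if rep < 8 else [])
            traj = sd.gen_trajectory(sd.TrajectorySpec(
                n_frames=400, chains=("A",), leaving_episodes=eps,
                replicate=rep, seed=rep))
            series.append(ta.detect_leaving_events(
                ta.nearest_ion_distance(traj)[0], config))
        agg = ta.aggregate_leaving(series)
        assert (agg["n_left"], agg["n"]) == (8, 10)
        assert set(agg["exit_sides"]) == {"extracellular"}


class TestGateState:
    def test_planted_open_episode_recovered(self, config):
        spec = sd.TrajectorySpec(
            n_frames=20, gate_episodes=[sd.GateEpisode("B", 5, 12)])
        states = {g.subunit: g for g in
                  ta.classify_gate_state(sd.gen_trajectory(spec), config)}
        open_frames = np.flatnonzero(states["B"].state == "open")
        assert open_frames.tolist() == list(range(5, 13))
        assert (states["A"].state == "closed").all()

    def test_infinite_cutoff_all_closed(self):
        cfg = AnalysisConfig(gate_open_cutoff=np.inf)
        spec = sd.TrajectorySpec(
            n_frames=6, gate_episodes=[sd.GateEpisode("A", 0, 5)])
        g = ta.classify_gate_state(sd.gen_trajectory(spec), cfg)[0]
        assert (g.state == "closed").all()


class TestOccupancySummary:
    def test_wire_every_frame_fraction_one(self, config):
        spec = sd.TrajectorySpec(
            n_frames=10, wire_episodes=[sd.WireEpisode("A", 1, 0, 9)])
        recs = ta.detect_wires_trajectory(sd.gen_trajectory(spec), config)
        assert ta.wire_fraction(recs, 10) == 1.0

    def test_planted_prevalence_recovered_exactly(self, config):
        rng = np.random.default_rng(3)
        frames = np.sort(rng.choice(200, size=60, replace=False))
        # group chosen frames into contiguous episodes
        episodes, start = [], frames[0]
        for a, b in zip(frames, frames[1:]):
            if b != a + 1:
                episodes.append(sd.WireEpisode("A", 1, int(start), int(a)))
                start = b
        episodes.append(sd.WireEpisode("A", 1, int(start), int(frames[-1])))
        spec = sd.TrajectorySpec(n_frames=200, wire_episodes=episodes)
        recs = ta.detect_wires_trajectory(sd.gen_trajectory(spec), config)
        assert ta.wire_fraction(recs, 200) == pytest.approx(0.3)

    def test_box_statistics_hand_computed(self):
        sims = []
        for f in np.arange(0.1, 1.05, 0.1):
            n_on = int(round(f * 10))
            sims.append([ta.WaterWireRecord(i, "A", 1, ["x"])
                         for i in range(n_on)])
        summ = ta.summarize_wire_occupancy(sims, 10)
        assert summ.median == pytest.approx(0.55)
        assert summ.q1 == pytest.approx(0.325)
        assert summ.q3 == pytest.approx(0.775)
        assert summ.whisker_low == pytest.approx(0.1)
        assert summ.whisker_high == pytest.approx(1.0)

    def test_occupancy_independent_of_chloride(self, config):
        """Identical wire plants with and without bound Cl- give the
        same occupancy fractions (wires do not depend on Cl- binding)."""
        wires = [sd.WireEpisode("A", 2, 5, 24)]
        bound = sd.TrajectorySpec(n_frames=40, wire_episodes=list(wires),
                                  condition="Egate_protonated")
        empty = sd.TrajectorySpec(
            n_frames=40, wire_episodes=list(wires),
            leaving_episodes=[sd.LeavingEpisode("A", 0, "extracellular",
                                                transit_frames=1)],
            condition="Egate_deprotonated")
        f_bound = ta.wire_fraction(ta.detect_wires_trajectory(
            sd.gen_trajectory(bound), config), 40)
        f_empty = ta.wire_fraction(ta.detect_wires_trajectory(
            sd.gen_trajectory(empty), config), 40)
        assert f_bound == f_empty == 0.5
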