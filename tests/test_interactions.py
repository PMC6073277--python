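"""Hydrogen bonds, salt bridges, water bridges, interface-water census."""

import numpy as np
import pytest

from mdcompare.core import Atom, Selection, Topology, Trajectory
from mdcompare.interactions import (brute_force_hbonds,
                                    brute_force_salt_bridge_pairs,
                                    detect_hbonds, detect_salt_bridges,
                                    detect_water_bridges,
                                    donor_hydrogen_pairs,
                                    interface_water_count)
from mdcompare.synthetic import (HBondPlan, SaltBridgePlan, SyntheticSpec,
                                 generate)


def _hbond_triple_traj(ha_dist, angle_deg):
    """SER O-H donor on chain A, carbonyl O acceptor on chain B, with the
    hydrogen...acceptor distance and A-H-D angle set explicitly."""
    atoms = [
        Atom(1, "CA", "C", "SER", 1, "A", float("nan"), 1.7),
        Atom(2, "OG", "O", "SER", 1, "A", float("nan"), 1.52),
        Atom(3, "HG", "H", "SER", 1, "A", float("nan"), 1.2),
        Atom(4, "O", "O", "GLY", 1, "B", float("nan"), 1.52),
    ]
    theta = np.radians(180.0 - angle_deg)
    acceptor = np.array([ha_dist * np.cos(theta),
                         ha_dist * np.sin(theta), 0.0]) + [1.96, 0, 0]
    coords = np.array([[[-3.0, 0, 0], [1.0, 0, 0], [1.96, 0, 0], acceptor]])
    return Trajectory(Topology(atoms), coords)


class TestHBonds:
    def test_linear_short_bond_detected(self):
        traj = _hbond_triple_traj(2.0, 180.0)
        found = detect_hbonds(traj, Selection.chain("A"),
                              Selection.chain("B"))
        assert len(found) == 1 and found[0].occupancy == 1.0

    def test_angle_gate_rejects_bent_geometry(self):
        traj = _hbond_triple_traj(2.0, 120.0)
        assert detect_hbonds(traj, Selection.chain("A"),
                             Selection.chain("B")) == []

    def test_distance_gate(self):
        traj = _hbond_triple_traj(3.6, 180.0)
        assert detect_hbonds(traj, Selection.chain("A"),
                             Selection.chain("B")) == []

    def test_distance_is_measured_to_hydrogen_not_donor(self):
        # H...A = 3.2 A passes even though donor...acceptor = 4.16 A
        traj = _hbond_triple_traj(3.2, 180.0)
        assert len(detect_hbonds(traj, Selection.chain("A"),
                                 Selection.chain("B"))) == 1
        assert detect_hbonds(traj, Selection.chain("A"),
                             Selection.chain("B"),
                             distance_mode="donor-acceptor") == []

    def test_threshold_monotonicity(self):
        """Loosening cutoffs never removes a bond; tightening never adds."""
        traj = _hbond_triple_traj(3.0, 150.0)

        def n_found(dist, angle):
            return len(detect_hbonds(traj, Selection.chain("A"),
                                     Selection.chain("B"),
                                     dist_cutoff=dist, angle_cutoff=angle))

        assert n_found(3.5, 135) >= n_found(3.1, 135) >= n_found(2.9, 135)
        assert n_found(3.5, 135) >= n_found(3.5, 145) >= n_found(3.5, 155)

    def test_missing_hydrogens_reported(self):
        atoms = [Atom(1, "OG", "O", "SER", 1, "A", float("nan"), 1.52),
                 Atom(2, "O", "O", "GLY", 1, "B", float("nan"), 1.52)]
        traj = Trajectory(Topology(atoms), np.zeros((1, 2, 3)) + [[0, 0, 0],
                                                                  [2, 0, 0]])
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(traj, Selection.chain("A"), Selection.chain("B"))

    def test_planted_persistence_recovered_as_occupancy(self):
        spec = SyntheticSpec(n_res_a=8, n_res_b=8, n_frames=2000,
                             hbond_plan=[HBondPlan(4, 4, persistence=0.6)],
                             seed=21)
        traj, truth = generate(spec, with_truth=True)
        found = detect_hbonds(traj, Selection.chain("L"),
                              Selection.chain("N"))
        assert len(found) == 1
        assert found[0].occupancy == pytest.approx(0.60, abs=0.05)
        # and exactly equal to the generator's realised per-frame truth
        assert found[0].occupancy == truth["hbonds"][0]["occupancy"]

    def test_occupancy_filter(self):
        spec = SyntheticSpec(n_res_a=8, n_res_b=8, n_frames=500,
                             hbond_plan=[HBondPlan(4, 4, persistence=0.3)],
                             seed=22)
        traj = generate(spec)
        assert detect_hbonds(traj, Selection.chain("L"),
                             Selection.chain("N"), min_occupancy=0.40) == []

    def test_water_hydrogens_map_to_water_oxygen(self, rich_system):
        traj, _ = rich_system
        pairs = donor_hydrogen_pairs(traj.topology, Selection(water=True))
        assert len(pairs) == 2 * 9
        for d, h in pairs:
            assert traj.topology.elements[d] == "O"


class TestSaltBridges:
    def test_bidentate_classification(self):
        spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=5,
                             saltbridge_plan=[SaltBridgePlan(3, 3)], seed=0)
        traj = generate(spec)
        found = detect_salt_bridges(traj, Selection.chain("L"),
                                    Selection.chain("N"))
        assert len(found) == 1
        assert found[0].bridge_class == "bidentate"
        assert found[0].occupancy == 1.0

    def test_single_classification(self):
        spec = SyntheticSpec(
            n_res_a=6, n_res_b=6, n_frames=5,
            saltbridge_plan=[SaltBridgePlan(3, 3, distance=3.8,
                                            bidentate=False)], seed=0)
        found = detect_salt_bridges(generate(spec), Selection.chain("L"),
                                    Selection.chain("N"))
        assert len(found) == 1 and found[0].bridge_class == "single"
        assert found[0].min_distance[0] == pytest.approx(3.8, abs=1e-9)

    def test_beyond_cutoff_not_reported(self):
        spec = SyntheticSpec(
            n_res_a=6, n_res_b=6, n_frames=5,
            saltbridge_plan=[SaltBridgePlan(3, 3, distance=4.2,
                                            bidentate=False)], seed=0)
        assert detect_salt_bridges(generate(spec), Selection.chain("L"),
                                   Selection.chain("N")) == []

    def test_intermittent_bridge_classified_half(self):
        spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=10,
                             saltbridge_plan=[SaltBridgePlan(3, 3)], seed=0)
        traj = generate(spec)
        coords = traj.coords.copy()
        top = traj.topology
        basic = [i for i in top.residue_atoms("N", 3)
                 if str(top.names[i]).startswith("NH")]
        coords[4:, basic, 1] += 10.0    # present in 4/10 frames only
        moved = Trajectory(top, coords, traj.times)
        found = detect_salt_bridges(moved, Selection.chain("L"),
                                    Selection.chain("N"))
        assert len(found) == 1 and found[0].bridge_class == "half"
        assert found[0].occupancy == pytest.approx(0.4)


class TestOracleEquivalence:
    """Randomised-frame exact agreement with naive scans (no spatial index,
    plain loops) for both detectors."""

    def _random_polar_system(self, rng, n_res=12):
        atoms = []
        for r in range(n_res):
            chain = "A" if r < n_res // 2 else "B"
            resid = r % (n_res // 2) + 1
            resname = ("SER", "ASP", "ARG", "GLN")[r % 4]
            names = {"SER": [("OG", "O"), ("HG", "H")],
                     "ASP": [("OD1", "O"), ("OD2", "O")],
                     "ARG": [("NH1", "N"), ("NH2", "N")],
                     "GLN": [("OE1", "O"), ("NE2", "N")]}[resname]
            atoms.append(Atom(len(atoms) + 1, "CA", "C", resname, resid,
                              chain, float("nan"), 1.7))
            for nm, el in names:
                atoms.append(Atom(len(atoms) + 1, nm, el, resname, resid,
                                  chain, float("nan"), 1.5))
        top = Topology(atoms)
        coords = rng.uniform(0, 10, size=(60, top.n_atoms, 3))
        return Trajectory(top, coords)

    def test_hbond_detector_matches_triple_loop(self):
        traj = self._random_polar_system(np.random.default_rng(5))
        ga, gb = Selection.chain("A"), Selection.chain("B")
        found = detect_hbonds(traj, ga, gb)
        for f in range(traj.n_frames):
            fast = {(hb.donor, hb.hydrogen, hb.acceptor)
                    for hb in found if hb.presence[f]}
            slow = brute_force_hbonds(traj, ga, gb, frame=f)
            assert fast == slow

    def test_salt_bridge_detector_matches_double_loop(self):
        traj = self._random_polar_system(np.random.default_rng(6))
        ga, gb = Selection.chain("A"), Selection.chain("B")
        found = detect_salt_bridges(traj, ga, gb)
        for f in range(traj.n_frames):
            fast_total = sum(int(sb.n_qualifying[f]) for sb in found)
            slow = brute_force_salt_bridge_pairs(traj, ga, gb, frame=f)
            assert fast_total == len(slow)


class TestWaterBridges:
    def test_planted_bridge_detected_with_high_occupancy(self, rich_system):
        traj, truth = rich_system
        bridges, relay = detect_water_bridges(traj, Selection.chain("L"),
                                              Selection.chain("N"))
        assert len(bridges) == 1
        assert bridges[0].occupancy >= 0.9
        assert bridges[0].occupancy == truth["water_bridges"][0]["occupancy"]

    def test_one_sided_water_is_not_a_bridge(self):
        spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=5,
                             n_bridge_waters=1, seed=0)
        traj = generate(spec)
        coords = traj.coords.copy()
        top = traj.topology
        waters = top.residue_atoms("W", 1000)
        coords[:, waters, 1] -= 2.0   # keep side A in range, push off side B
        moved = Trajectory(top, coords, traj.times)
        bridges, _ = detect_water_bridges(moved, Selection.chain("L"),
                                          Selection.chain("N"))
        assert bridges == []

    def test_alternating_waters_yield_any_water_relay(self):
        spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=10,
                             n_bridge_waters=1, bridge_persistence=1.0,
                             seed=0)
        traj = generate(spec)
        top = traj.topology
        # clone the bridge water into a second one, alternating frames
        w = top.residue_atoms("W", 1000)
        atoms = top.atoms
        for k, name in enumerate(("O", "H1", "H2")):
            atoms.append(Atom(len(atoms) + 1, name, name[0], "WAT", 1001,
                              "W", float("nan"), 1.2))
        new_top = Topology(atoms)
        coords = np.concatenate([traj.coords, traj.coords[:, w, :]], axis=1)
        odd = np.arange(10) % 2 == 1
        coords[np.ix_(odd, w)] += [0, 0, 50.0]        # water 1 off on odd
        coords[np.ix_(~odd, new_top.residue_atoms("W", 1001))] += \
            [0, 0, 50.0]                              # water 2 off on even
        moved = Trajectory(new_top, coords, traj.times)
        bridges, relay = detect_water_bridges(moved, Selection.chain("L"),
                                              Selection.chain("N"))
        occ = {b.water[1]: b.occupancy for b in bridges}
        assert occ[1000] == pytest.approx(0.5)
        assert occ[1001] == pytest.approx(0.5)
        assert list(relay.values()) == [pytest.approx(1.0)]

    def test_no_waters_rejected(self, static_traj):
        with pytest.raises(ValueError, match="water"):
            detect_water_bridges(static_traj, Selection.chain("L"),
                                 Selection.chain("N"))


class TestInterfaceWaterCount:
    def test_planted_waters_counted_every_sample(self):
        spec = SyntheticSpec(n_res_a=6, n_res_b=6, n_frames=8,
                             n_bridge_waters=2, n_bulk_waters=20, seed=0)
        traj = generate(spec)
        counts, mean, sampled = interface_water_count(
            traj, Selection.chain("L"), cutoff=4.0)
        assert np.all(counts == 2) and mean == 2.0
        assert sampled.size == 8

    def test_zero_cutoff_counts_nothing(self, rich_system):
        traj, _ = rich_system
        counts, mean, _ = interface_water_count(traj, Selection.chain("L"),
                                                cutoff=0.0, stride=100)
        assert mean == 0.0

    def test_monotone_in_cutoff(self, rich_system):
        traj, _ = rich_system
        prev = -1
        for cutoff in (2.0, 4.0, 8.0, 30.0, 100.0):
            counts, _, _ = interface_water_count(
                traj.slice_frames(0, 1), Selection.chain("L"), cutoff=cutoff)
            assert counts[0] >= prev
            prev = counts[0]

    def test_empty_region_rejected(self, rich_system):
        traj, _ = rich_system
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="region"):
                interface_water_count(traj, Selection(chains=frozenset("Z")))
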