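"""Occupancy counting, strength labels, and the helix contact census."""

import numpy as np
import pandas as pd
import pytest

import dimerdyn as dd
from dimerdyn import interactions as ia
from dimerdyn import structures as st
from dimerdyn.geometry import apply_transform

from conftest import random_rigid_transform
from oracles import (binom_ci, naive_hbond_occupancy,
                     naive_hydrophobic_occupancy, table_to_dict)


def _toy_hbond_topology():
    """One donor (N-H) in chain A, one acceptor (O) in chain B."""
    return st.Topology(names=["N", "H", "O"], elements=["N", "H", "O"],
                       chain_ids=["A", "A", "B"], res_local=[1, 1, 1],
                       res_names=["GLY", "GLY", "GLY"])


class TestHBondCriteria:
    @pytest.mark.parametrize("acceptor_x,counted", [
        (3.1, True),   # distance 3.1 <= 3.2, angle 180 >= 120
        (3.3, False),  # distance 3.3 > 3.2
    ])
    def test_distance_threshold_boundary(self, acceptor_x, counted):
        topo = _toy_hbond_topology()
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [acceptor_x, 0, 0]])
        traj = dd.Trajectory(frame[None], topo, 2.0)
        df = ia.hbond_occupancy(traj)
        if counted:
            assert len(df) == 1
            assert df.iloc[0]["occupancy"] == 100.0
            assert {df.iloc[0]["res1"], df.iloc[0]["res2"]} == {1, 914}
        else:
            assert len(df) == 0

    def test_angle_threshold(self):
        """D-H-A below 120 degrees is rejected even at short distance."""
        topo = _toy_hbond_topology()
        # acceptor placed so the D-H-A angle is ~90 degrees
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.5, 0]])
        traj = dd.Trajectory(frame[None], topo, 2.0)
        assert len(ia.hbond_occupancy(traj)) == 0

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ia.HBondCriteria(max_donor_acceptor_distance=-1.0)
        with pytest.raises(ValueError):
            ia.HBondCriteria(min_dha_angle=200.0)


class TestHydrophobicCriteria:
    def _two_cb_topology(self):
        return st.Topology(names=["CB", "CB"], elements=["C", "C"],
                           chain_ids=["A", "B"], res_local=[1, 1],
                           res_names=["ALA", "ALA"])

    @pytest.mark.parametrize("dist,counted", [
        (4.5, True),    # inside [3.5, 5.5]
        (3.4, False),   # clash regime below 3.5
        (5.6, False),   # beyond 5.5
    ])
    def test_distance_band(self, dist, counted):
        topo = self._two_cb_topology()
        frame = np.array([[0.0, 0, 0], [dist, 0, 0]])
        traj = dd.Trajectory(np.stack([frame] * 3), topo, 2.0)
        df = ia.hydrophobic_occupancy(traj)
        assert (len(df) == 1 and df.iloc[0]["occupancy"] == 100.0) == counted

    def test_sequence_adjacent_pairs_excluded(self):
        topo = st.Topology(names=["CB", "CB"], elements=["C", "C"],
                           chain_ids=["A", "A"], res_local=[1, 2],
                           res_names=["ALA", "ALA"])
        frame = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        traj = dd.Trajectory(frame[None], topo, 2.0)
        assert len(ia.hydrophobic_occupancy(traj)) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_module_equals_naive_recount(self, bundle, seed):
        """Vectorized occupancies equal the per-frame naive recount exactly."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=seed)
        traj, _ = dd.simulate_trajectory(topo, coords, man, 60, 100.0)
        hb = table_to_dict(ia.hbond_occupancy(traj))
        hb_naive = naive_hbond_occupancy(traj)
        assert hb == hb_naive
        hi = table_to_dict(ia.hydrophobic_occupancy(traj))
        hi_naive = naive_hydrophobic_occupancy(traj)
        assert hi == hi_naive

    def test_planted_occupancy_recovery(self, bundle):
        """Reported occupancy of the planted pair sits in the binomial CI."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=8,
                                  hbond_occupancies=(0.6,),
                                  contact_occupancies=(0.3,),
                                  unwound_fraction=0.0)
        n = 1000
        traj, log = dd.simulate_trajectory(topo, coords, man, n, 100.0)
        hb = table_to_dict(ia.hbond_occupancy(traj))
        pair = tuple(sorted((man.hbonds[0].donor_res,
                             man.hbonds[0].acceptor_res)))
        lo, hi = binom_ci(n, 0.6)
        assert 100.0 * lo / n <= hb[pair] <= 100.0 * hi / n
        hi_table = table_to_dict(ia.hydrophobic_occupancy(traj))
        cpair = tuple(sorted((man.contacts[0].res_a, man.contacts[0].res_b)))
        lo_c, hi_c = binom_ci(n, 0.3)
        assert 100.0 * lo_c / n <= hi_table[cpair] <= 100.0 * hi_c / n

    def test_rigid_transform_invariance(self, short_run):
        traj = short_run[0]
        small = dd.Trajectory(traj.coords[:30], traj.topology, 100.0)
        base_hb = table_to_dict(ia.hbond_occupancy(small))
        base_hi = table_to_dict(ia.hydrophobic_occupancy(small))
        rng = np.random.default_rng(4)
        moved = small.coords.copy()
        for t in range(len(moved)):
            rot, trans = random_rigid_transform(rng)
            moved[t] = apply_transform(moved[t], rot, trans)
        mtraj = dd.Trajectory(moved, traj.topology, 100.0)
        assert table_to_dict(ia.hbond_occupancy(mtraj)) == pytest.approx(base_hb)
        assert table_to_dict(ia.hydrophobic_occupancy(mtraj)) == pytest.approx(base_hi)


class TestStrengthLabel:
    @pytest.mark.parametrize("occ,label", [
        (71.9, "strong"), (50.0, "strong"), (49.99, "medium"),
        (20.0, "medium"), (19.99, "periodic"), (0.5, "periodic"),
        (0.0, "absent"), (100.0, "strong"),
    ])
    def test_vocabulary(self, occ, label):
        assert ia.strength_label(occ) == label

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                ia.strength_label(bad)


class TestContactCensus:
    def _helix_set(self):
        return st.HelixSet(A1=(1, 14), A2=(19, 32), B1=(914, 927),
                           B2=(932, 945))

    def test_empty_tables_all_zero(self):
        census = ia.contact_census(None, None, self._helix_set())
        assert census.total == 0
        assert census.intersubunit == 0
        assert census.a1_balance == "undefined"

    def test_hand_built_table_matches_enumeration(self):
        """7-row table counted by hand: per-pair, total, intersubunit."""
        hi = pd.DataFrame({
            "res1": [1, 2, 3, 20, 21, 5, 10],
            "res2": [914, 933, 21, 915, 934, 916, 11],
            "kind": ["HI"] * 7,
            "occupancy": [50.0, 40.0, 30.0, 25.0, 15.0, 5.0, 60.0],
            "label": ["strong", "medium", "medium", "medium", "periodic",
                      "periodic", "strong"]})
        census = ia.contact_census(None, hi, self._helix_set(),
                                   occupancy_threshold_percent=10.0)
        # rows >= 10%: (1,914) A1-B1, (2,933) A1-B2, (3,21) A1-A2,
        # (20,915) A2-B1, (21,934) A2-B2; (5,916) below threshold;
        # (10,11) both in A1 -> same segment, dropped
        assert census.pair_counts[("A1", "B1")] == 1
        assert census.pair_counts[("A1", "B2")] == 1
        assert census.pair_counts[("A1", "A2")] == 1
        assert census.pair_counts[("A2", "B1")] == 1
        assert census.pair_counts[("A2", "B2")] == 1
        assert census.pair_counts[("B1", "B2")] == 0
        assert census.total == 5
        assert census.intersubunit == 4
        assert census.a1_balance == "both"

    def test_a1_balance_single_target(self):
        hi = pd.DataFrame({
            "res1": [1, 2], "res2": [914, 915], "kind": ["HI", "HI"],
            "occupancy": [60.0, 30.0], "label": ["strong", "medium"]})
        census = ia.contact_census(None, hi, self._helix_set())
        assert census.a1_balance == "B1"

    def test_monotone_in_threshold(self, short_run):
        """Census counts never increase as the threshold rises."""
        traj, _, _, hs = short_run
        hb = ia.hbond_occupancy(traj)
        hi = ia.hydrophobic_occupancy(traj)
        totals = [ia.contact_census(hb, hi, hs, thr).total
                  for thr in (0.0, 5.0, 10.0, 25.0, 50.0, 90.0)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_window_required_nonempty(self, short_run):
        traj = short_run[0]
        with pytest.raises(ValueError):
            ia.hbond_occupancy(traj, dd.StableWindow(5, 400, 10.0))
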