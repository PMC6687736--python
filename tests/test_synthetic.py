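"""Generator contracts: geometry, planted ground truth, reproducibility."""

import numpy as np
import pytest

import dimerdyn as dd
from dimerdyn import secondary_structure as ss
from dimerdyn import synthetic
from dimerdyn.synthetic import (DriftSpec, GroundTruthManifest, OverlapError,
                                PlantedContact, PlantedHBond, UnwoundSegment)

from oracles import binom_ci, planted_hbond_recount


class TestBundleGeometry:
    def test_c2_symmetry(self, bundle):
        """Applying the C2 operator to chain A reproduces chain B."""
        topo, coords, _ = bundle
        a = coords[topo.chain_atoms("A")]
        b = coords[topo.chain_atoms("B")]
        np.testing.assert_allclose(a @ synthetic.ROT_C2_Z.T, b, atol=1e-6)

    def test_chain_b_dimer_numbering(self, bundle):
        topo, _, hs = bundle
        b_first = [r for r in topo.residues if r.chain_id == "B"][0]
        assert b_first.dimer_index == 914
        assert hs.B1[0] == 914

    def test_helical_assignment_of_built_bundle(self, bundle):
        """DSSP-style labels call >= (n-4)/n of helix residues H."""
        topo, coords, hs = bundle
        labels = ss.assign_frame(coords, topo)
        for seg in ("A1", "A2", "B1", "B2"):
            rids = [topo.residue_index(r) for r in hs.residues(seg)]
            n = len(rids)
            n_h = (labels[rids] == "H").sum()
            assert n_h >= n - 4

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(OverlapError):
            dd.build_ideal_bundle(inter_helix_spacing=3.0)

    def test_too_short_helix_rejected(self):
        with pytest.raises(ValueError):
            dd.build_ideal_bundle(n_res_per_helix=6)

    def test_phi_psi_in_helical_region(self, bundle):
        """Backbone rise of ~1.5 A/residue along the helix axis."""
        topo, coords, hs = bundle
        ca = [topo.atom_index(r, "CA") for r in hs.residues("A1")]
        rise = np.abs(np.diff(coords[ca][:, 2]))
        assert np.allclose(rise.mean(), 1.5, atol=0.15)


class TestManifest:
    def test_occupancy_validation(self, bundle):
        topo, coords, hs = bundle
        man = GroundTruthManifest(hbonds=[PlantedHBond(3, 916, 1.2)])
        with pytest.raises(ValueError, match="outside"):
            man.validate()
        with pytest.raises(ValueError):
            GroundTruthManifest(
                contacts=[PlantedContact(1, 932, -0.1)]).validate()

    def test_mode_orthonormality(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs)
        vecs = np.stack([v for v, _ in man.modes])
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(len(vecs)),
                                   atol=1e-8)

    def test_json_round_trip(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=7,
                                  drift=DriftSpec(50, 5.0))
        back = GroundTruthManifest.from_json(man.to_json())
        assert back.seed == 7
        assert back.drift == DriftSpec(50, 5.0)
        assert [vars(h) for h in back.hbonds] == [vars(h) for h in man.hbonds]
        np.testing.assert_allclose(
            np.stack([v for v, _ in back.modes]),
            np.stack([v for v, _ in man.modes]))


class TestSimulation:
    def test_bit_reproducibility(self, bundle):
        """Identical seed + manifest give bit-identical frames."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=42)
        t1, _ = dd.simulate_trajectory(topo, coords, man, 50, 100.0)
        t2, _ = dd.simulate_trajectory(topo, coords, man, 50, 100.0)
        assert np.array_equal(t1.coords, t2.coords)

    def test_zero_occupancy_gives_no_planted_bonds(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=1,
                                  hbond_occupancies=(0.0, 0.0),
                                  contact_occupancies=(0.0, 0.0),
                                  unwound_fraction=0.0)
        traj, log = dd.simulate_trajectory(topo, coords, man, 50, 100.0)
        assert not log.hbond_formed.any()
        assert not log.contact_formed.any()
        recounts = planted_hbond_recount(traj, log, man)
        for hits in recounts:
            assert not hits.any()

    def test_planted_mode_sample_variance(self, bundle):
        """Sample variance along mode 1 within 3 SE of the planted 4 A^2."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=5,
                                  hbond_occupancies=(), contact_occupancies=(),
                                  unwound_fraction=0.0)
        n = 2000
        traj, log = dd.simulate_trajectory(topo, coords, man, n, 100.0)
        v1 = man.modes[0][0]
        ca = topo.ca_indices
        disp = (traj.coords[:, ca] - coords[ca]).reshape(n, -1)
        proj = disp @ v1
        se = 4.0 * np.sqrt(2.0 / (n - 1))
        assert abs(proj.var(ddof=1) - 4.0) < 3 * se

    def test_planted_hbond_binomial_recovery(self, bundle):
        """Formed-geometry frame count lands in the Binomial 99% interval."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=9,
                                  hbond_occupancies=(0.6,),
                                  contact_occupancies=(),
                                  unwound_fraction=0.0)
        n = 1000
        traj, log = dd.simulate_trajectory(topo, coords, man, n, 100.0)
        hits = planted_hbond_recount(traj, log, man)[0]
        lo, hi = binom_ci(n, 0.6)
        assert lo <= hits.sum() <= hi

    def test_draw_log_matches_geometry_exactly(self, bundle):
        """Brute-force recount of formed frames equals the internal draw log."""
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=13)
        traj, log = dd.simulate_trajectory(topo, coords, man, 200, 100.0)
        recounts = planted_hbond_recount(traj, log, man)
        for bi, hits in enumerate(recounts):
            assert np.array_equal(hits, log.hbond_formed[:, bi])

    def test_contact_formed_distance_exact(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=3,
                                  unwound_fraction=0.0)
        traj, log = dd.simulate_trajectory(topo, coords, man, 100, 100.0)
        for ci, c in enumerate(man.contacts):
            a_i, b_i = synthetic._resolve_contact_atoms(topo, c)
            d = np.linalg.norm(traj.coords[:, a_i] - traj.coords[:, b_i],
                               axis=1)
            expect = np.where(log.contact_formed[:, ci], 4.5, 8.0)
            np.testing.assert_allclose(d, expect, atol=1e-9)

    def test_unwound_fraction_binomial(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs, seed=21,
                                  hbond_occupancies=(), contact_occupancies=(),
                                  unwound_fraction=0.3)
        n = 1000
        traj, log = dd.simulate_trajectory(topo, coords, man, n, 100.0)
        lo, hi = binom_ci(n, 0.3)
        assert lo <= log.unwound[:, 0].sum() <= hi

    def test_min_frames_precondition(self, bundle):
        topo, coords, hs = bundle
        man = dd.default_manifest(topo, coords, hs)
        with pytest.raises(ValueError):
            dd.simulate_trajectory(topo, coords, man, 5, 100.0)
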