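"""PCA schemes: eigen-spectra, projections, distance features."""

import numpy as np
import pandas as pd
import pytest

import dimerdyn as dd
from dimerdyn import essential_dynamics as ed
from dimerdyn import structures as st


def _planted_run(bundle, seed, n_frames=2500):
    topo, coords, hs = bundle
    man = dd.default_manifest(topo, coords, hs, seed=seed,
                              hbond_occupancies=(), contact_occupancies=(),
                              unwound_fraction=0.0)
    traj, log = dd.simulate_trajectory(topo, coords, man, n_frames, 100.0)
    return traj, man, log


class TestPcaCartesian:
    def test_static_trajectory_zero_eigenvalues(self, bundle):
        topo, coords, _ = bundle
        traj = dd.Trajectory(np.stack([coords] * 10), topo, 100.0)
        ms = ed.pca_cartesian(traj)
        np.testing.assert_allclose(ms.eigenvalues, 0.0, atol=1e-10)

    def test_planted_modes_recovered(self, bundle):
        """Top-2 eigenvalues near (4, 1) A^2; subspace overlap > 0.99."""
        traj, man, log = _planted_run(bundle, seed=23)
        ms = ed.pca_cartesian(traj)
        sample_var = log.mode_amplitudes.var(axis=0, ddof=1)
        np.testing.assert_allclose(ms.eigenvalues[:2], sample_var, rtol=0.02)
        for k, (v, _) in enumerate(man.modes):
            assert abs(v @ ms.eigenvectors[k]) > 0.99

    def test_orthonormality_and_trace(self, bundle):
        traj, _, _ = _planted_run(bundle, seed=3, n_frames=400)
        ms = ed.pca_cartesian(traj)
        gram = ms.eigenvectors @ ms.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        # trace conservation against per-coordinate variances
        sel = traj.topology.ca_indices
        fitted, mean = ed._superposed_stack(traj.coords[:, sel])
        x = (fitted - mean).reshape(len(fitted), -1)
        total_var = x.var(axis=0, ddof=1).sum()
        assert ms.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_cumulative_explained_is_one(self, bundle):
        traj, _, _ = _planted_run(bundle, seed=4, n_frames=300)
        ms = ed.pca_cartesian(traj)
        assert np.cumsum(ms.explained_fraction)[-1] == pytest.approx(1.0)

    def test_too_few_frames_errors(self, bundle):
        topo, coords, _ = bundle
        traj = dd.Trajectory(coords[None], topo, 100.0)
        with pytest.raises(ValueError):
            ed.pca_cartesian(traj)


class TestProject:
    def test_mean_structure_projects_to_zero(self, bundle):
        traj, _, _ = _planted_run(bundle, seed=5, n_frames=300)
        ms = ed.pca_cartesian(traj)
        full_mean = np.zeros((traj.topology.n_atoms, 3))
        full_mean[ms.selection] = ms.mean_structure
        out = ed.project(full_mean[None], ms, 0)
        assert abs(out[0]) < 1e-8

    def test_projection_variance_equals_eigenvalue(self, bundle):
        """PCA identity on the fitting frames themselves."""
        traj, _, _ = _planted_run(bundle, seed=6, n_frames=500)
        ms = ed.pca_cartesian(traj)
        assert ms.projections[:, 0].var(ddof=1) == pytest.approx(
            ms.eigenvalues[0], rel=1e-6)

    def test_reconstructed_frames_project_to_coefficient(self, bundle):
        traj, _, _ = _planted_run(bundle, seed=7, n_frames=300)
        ms = ed.pca_cartesian(traj)
        v = ms.eigenvectors[0].reshape(-1, 3)
        cs = np.array([-1.5, 0.0, 0.7, 2.0])
        frames = ms.mean_structure[None] + cs[:, None, None] * v[None]
        out = ed.project(frames, ms, 0, selection_applied=True)
        np.testing.assert_allclose(out, cs, atol=1e-6)

    def test_invalid_mode_index(self, bundle):
        traj, _, _ = _planted_run(bundle, seed=8, n_frames=200)
        ms = ed.pca_cartesian(traj)
        with pytest.raises(IndexError):
            ed.project(traj.coords[:2], ms, len(ms.eigenvalues))


class TestPcCorrelation:
    def test_self_and_negation_are_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(500)
        assert ed.pc_correlation(a, a) == pytest.approx(1.0)
        assert ed.pc_correlation(a, -a) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 400))
        assert ed.pc_correlation(a, b) == pytest.approx(
            ed.pc_correlation(b, a))

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        r2 = [ed.pc_correlation(rng.standard_normal(2500),
                                rng.standard_normal(2500))
              for _ in range(20)]
        # under independence r^2 ~ 1/n; 0.01 is a generous 99% bound
        assert np.median(r2) < 0.01

    def test_unequal_lengths_resampled(self):
        t_long = np.linspace(0, 1, 1000)
        t_short = np.linspace(0, 1, 400)
        assert ed.pc_correlation(np.sin(6 * t_long), np.sin(6 * t_short)) \
            == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_flagged(self):
        assert ed.pc_correlation(np.ones(100), np.arange(100.0)) is None


class TestDistanceFeatures:
    def test_rigid_bundle_constant_features(self, bundle):
        topo, coords, hs = bundle
        traj = dd.Trajectory(np.stack([coords] * 120), topo, 100.0)
        df = ed.helix_distance_features(traj, hs, stride=10)
        feats = df.drop(columns="frame")
        assert (feats.std() < 1e-10).all()
        assert (feats > 0).all().all()

    def test_translated_helix_bimodal_feature(self, bundle):
        """+2 A shift of B1 along the A1-B1 axis in half the frames."""
        topo, coords, hs = bundle
        frames = np.stack([coords] * 100)
        b1_atoms = np.concatenate([topo.residue_atoms(r)
                                   for r in hs.residues("B1")])
        a1_ca = [topo.atom_index(r, "CA") for r in hs.residues("A1")]
        b1_ca = [topo.atom_index(r, "CA") for r in hs.residues("B1")]
        axis = coords[b1_ca].mean(0) - coords[a1_ca].mean(0)
        axis /= np.linalg.norm(axis)
        frames[50:, b1_atoms] += 2.0 * axis
        traj = dd.Trajectory(frames, topo, 100.0)
        df = ed.helix_distance_features(traj, hs, stride=1)
        vals = np.sort(df["A1-B1"].unique())
        assert len(vals) == 2
        assert vals[1] - vals[0] == pytest.approx(2.0, abs=1e-9)

    def test_stride_beyond_length_gives_one_frame(self, bundle):
        topo, coords, hs = bundle
        traj = dd.Trajectory(np.stack([coords] * 30), topo, 100.0)
        df = ed.helix_distance_features(traj, hs, stride=100)
        assert len(df) == 1


class TestPcaFeatures:
    def _feature_frame(self, x):
        cols = [f"{a}-{b}" for a, b in ed.FEATURE_PAIRS]
        return pd.DataFrame(np.asarray(x), columns=cols)

    def test_planar_features_fully_explained(self):
        """Features in a 2D affine subspace: 2 components explain 100%."""
        rng = np.random.default_rng(3)
        latent = rng.standard_normal((500, 2))
        mix = rng.standard_normal((2, 6))
        feats = self._feature_frame(10.0 + latent @ mix)
        out = ed.pca_features({"sys": feats})
        assert out.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_dispersion_ratio_tracks_noise_ratio(self):
        """5x noisier system shows ~25x projection dispersion."""
        rng = np.random.default_rng(4)
        base = 12.0 + rng.standard_normal((2000, 6)) * 0.2
        noisy = 12.0 + rng.standard_normal((2000, 6)) * 1.0
        out = ed.pca_features({"tight": self._feature_frame(base),
                               "dispersed": self._feature_frame(noisy)})
        ratio = out.dispersion["dispersed"] / out.dispersion["tight"]
        assert 15.0 < ratio < 40.0

    def test_shifted_systems_separate_in_projection(self):
        rng = np.random.default_rng(5)
        a = 12.0 + rng.standard_normal((500, 6)) * 0.1
        b = a + np.array([2.0, -2.0, 1.0, 0.0, 0.5, -0.5])
        out = ed.pca_features({"a": self._feature_frame(a),
                               "b": self._feature_frame(b)})
        spread = max(np.sqrt(out.dispersion["a"]), np.sqrt(out.dispersion["b"]))
        assert out.centroid_separation("a", "b") > 5 * spread

    def test_iid_equal_variance_explained_near_third(self):
        """Six i.i.d. features: two components explain ~2/6 of variance."""
        rng = np.random.default_rng(6)
        feats = self._feature_frame(8.0 + rng.standard_normal((5000, 6)))
        out = ed.pca_features({"sys": feats})
        assert out.explained_variance_ratio.sum() == pytest.approx(1 / 3,
                                                                   abs=0.05)


class TestModeAnimation:
    def test_round_trip_displacements_match_mode(self, bundle, tmp_path):
        traj, man, _ = _planted_run(bundle, seed=9, n_frames=300)
        topo = traj.topology
        ms = ed.pca_cartesian(traj)
        pdb = tmp_path / "mode1.pdb"
        csv = tmp_path / "arrows.csv"
        amp = 3.0
        ed.export_mode_animation(ms, topo, traj.coords[0], 0, amp, 5, pdb, csv)
        back = st.read_trajectory(pdb, topo, 100.0)
        assert back.n_frames == 5
        delta = (back.coords[-1] - back.coords[0])[ms.selection]
        v = ms.eigenvectors[0].reshape(-1, 3)
        np.testing.assert_allclose(delta, 2 * amp * v, atol=5e-3)
        arrows = pd.read_csv(csv)
        np.testing.assert_allclose(arrows[["dx", "dy", "dz"]].to_numpy(), v,
                                   atol=1e-9)

    def test_zero_amplitude_all_models_equal(self, bundle, tmp_path):
        traj, _, _ = _planted_run(bundle, seed=10, n_frames=200)
        ms = ed.pca_cartesian(traj)
        pdb = tmp_path / "flat.pdb"
        ed.export_mode_animation(ms, traj.topology, traj.coords[0], 0, 0.0,
                                 4, pdb)
        back = st.read_trajectory(pdb, traj.topology, 100.0)
        for t in range(1, back.n_frames):
            np.testing.assert_allclose(back.coords[t], back.coords[0],
                                       atol=1e-9)
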