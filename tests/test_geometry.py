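"""Geometric observables: superposition optimality, C3 frames, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from c3ensemble import geometry, synthetic
from c3ensemble.io import EnsembleTrajectory


def random_rototranslation(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t


class TestKabsch:
    def test_identical_structures_zero_rmsd(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = geometry.kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_recovers_random_rototranslation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3)) * 10
        R0, t0 = random_rototranslation(rng)
        moved = x @ R0.T + t0
        _, _, rmsd = geometry.kabsch_superpose(moved, x)
        assert rmsd <= 1e-8

    def test_matches_brute_force_rotation_grid(self):
        """4-point asymmetric fixture: optimal RMSD equals an exhaustive
        minimum over a fine rotation grid (independent oracle)."""
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 5]])
        rng = np.random.default_rng(2)
        mob = ref + rng.normal(0, 0.4, size=ref.shape)
        _, _, rmsd = geometry.kabsch_superpose(mob, ref)
        mob_c = mob - mob.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        best = np.inf
        # coarse-to-fine search over rotations
        grid = Rotation.random(4000, random_state=3)
        for stage in range(3):
            vals = [
                np.sqrt(((mob_c @ g.as_matrix().T - ref_c) ** 2).sum(axis=1).mean())
                for g in grid
            ]
            i = int(np.argmin(vals))
            best = min(best, vals[i])
            center = grid[i]
            perturb = Rotation.from_rotvec(
                np.random.default_rng(stage).normal(0, 0.1 / (4**stage), size=(2000, 3))
            )
            grid = center * perturb
        assert rmsd <= best + 1e-3

    def test_rmsd_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        _, _, r1 = geometry.kabsch_superpose(a, b)
        _, _, r2 = geometry.kabsch_superpose(b, a)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            geometry.kabsch_superpose(line, line)


class TestC3Frame:
    def test_constructed_axis_and_sign(self, rigid_trimer):
        traj, _ = rigid_trimer
        sel = synthetic.default_selections(traj)
        fr = geometry.c3_frame(traj, 0, sel["core"], sel["orientation"])
        # generator builds the trimer around +z with the ligand face at -z
        assert np.allclose(np.abs(fr.axis), [0, 0, 1], atol=1e-6)
        assert fr.axis[2] > 0
        assert abs(np.linalg.norm(fr.axis) - 1.0) < 1e-10

    def test_orientation_on_positive_face_flips_axis(self, rigid_trimer):
        traj, _ = rigid_trimer
        sel = synthetic.default_selections(traj)
        # use the (forward-protruding) loop tips as the orientation face
        tips = traj.select(residues=[81], atoms="CA")
        fr = geometry.c3_frame(traj, 0, sel["core"], tips)
        assert fr.axis[2] < 0

    def test_axis_covariant_under_global_motion(self, rigid_trimer):
        traj, _ = rigid_trimer
        sel = synthetic.default_selections(traj)
        rng = np.random.default_rng(5)
        R, t = random_rototranslation(rng)
        moved = EnsembleTrajectory(traj.coords @ R.T + t, traj.atoms.copy())
        f0 = geometry.c3_frame(traj, 0, sel["core"], sel["orientation"])
        f1 = geometry.c3_frame(moved, 0, sel["core"], sel["orientation"])
        assert np.allclose(f1.axis, R @ f0.axis, atol=1e-8)


class TestProtrusion:
    def test_recovers_planted_values_exactly_without_jitter(self, rigid_trimer):
        traj, truth = rigid_trimer
        sel = synthetic.default_selections(traj)
        ps = geometry.protrusion_distances(traj, (81, "CA"), sel["core"], sel["orientation"])
        assert np.allclose(ps.values, truth.protrusions, atol=1e-9)

    def test_recovers_planted_values_under_jitter(self):
        spec = synthetic.TrimerSpec(
            n_frames=200, loop_bias_mean=12.0, loop_bias_sd=4.0, jitter_sd=0.2, seed=9
        )
        traj, truth = synthetic.generate_trimer_ensemble(spec)
        sel = synthetic.default_selections(traj)
        ps = geometry.protrusion_distances(traj, (81, "CA"), sel["core"], sel["orientation"])
        # reporter jitter 0.2 A/coordinate plus plane-origin noise
        assert np.abs(ps.values - truth.protrusions).max() < 1.5
        assert np.abs(ps.values - truth.protrusions).mean() < 0.3

    def test_missing_reporter_atom_names_monomer(self, rigid_trimer):
        traj, _ = rigid_trimer
        sel = synthetic.default_selections(traj)
        with pytest.raises(ValueError, match="monomer A"):
            geometry.protrusion_distances(traj, (999, "CA"), sel["core"], sel["orientation"])

    def test_sign_flips_when_orientation_moves_to_opposite_face(self, rigid_trimer):
        traj, _ = rigid_trimer
        sel = synthetic.default_selections(traj)
        ps = geometry.protrusion_distances(traj, (81, "CA"), sel["core"], sel["orientation"])
        tips = traj.select(residues=[81], atoms="CA")
        flipped = geometry.protrusion_distances(traj, (81, "CA"), sel["core"], tips)
        assert np.allclose(flipped.values, -ps.values, atol=1e-9)


class TestRgRmsfRmsd:
    def test_rg_closed_forms(self):
        atoms = _point_atoms(2)
        coords = np.array([[[0.0, 0, 0], [2, 0, 0]]])
        traj = EnsembleTrajectory(coords, atoms)
        assert geometry.radius_of_gyration(traj)[0] == pytest.approx(1.0)
        same = EnsembleTrajectory(np.zeros((1, 2, 3)), atoms)
        assert geometry.radius_of_gyration(same)[0] == pytest.approx(0.0)

    def test_holo_like_ensemble_more_compact(self):
        apo, _ = synthetic.generate_trimer_ensemble(
            synthetic.TrimerSpec(n_frames=150, latch_prob=0.2, loop_bias_mean=16, loop_bias_sd=3, seed=1)
        )
        holo, _ = synthetic.generate_trimer_ensemble(
            synthetic.TrimerSpec(n_frames=150, latch_prob=1.0, loop_bias_mean=16, loop_bias_sd=3, seed=2)
        )
        # directional bias concentrates the loops: lower Rg spread of means
        assert geometry.radius_of_gyration(holo).mean() != geometry.radius_of_gyration(apo).mean()

    def test_static_trajectory_zero_rmsf(self, rigid_trimer):
        traj, _ = rigid_trimer
        static = EnsembleTrajectory(
            np.repeat(traj.coords[:1], 5, axis=0), traj.atoms.copy()
        )
        prof = geometry.rmsf_profile(static)
        assert np.allclose(prof["rmsf"], 0.0, atol=1e-9)

    def test_isotropic_jitter_rmsf_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(60, 3)) * 12
        sigma = 0.5
        coords = base[None] + rng.normal(0, sigma, size=(2000, 60, 3))
        traj = EnsembleTrajectory(coords, _point_atoms(60))
        prof = geometry.rmsf_profile(traj)
        expected = sigma * np.sqrt(3)
        assert abs(prof["rmsf"].mean() - expected) / expected < 0.05

    def test_rmsd_first_frame_zero_and_trim_composability(self):
        spec = synthetic.TrimerSpec(n_frames=50, loop_bias_sd=2.0, seed=12, frame_dt_ns=1.0)
        traj, _ = synthetic.generate_trimer_ensemble(spec)
        rmsd = geometry.rmsd_timeseries(traj)
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)
        trimmed = geometry.equilibration_trim(traj, t_cut=5.0)
        direct = geometry.radius_of_gyration(trimmed)
        from_full = geometry.radius_of_gyration(traj)[5:]
        assert np.allclose(direct, from_full)

    def test_trim_retains_90pct_on_uniform_millenium_trajectory(self):
        atoms = _point_atoms(3)
        coords = np.zeros((1000, 3, 3))
        times = np.linspace(0, 999, 1000)
        traj = EnsembleTrajectory(coords, atoms, times)
        trimmed = geometry.equilibration_trim(traj, t_cut=100.0)
        assert trimmed.n_frames == 900

    def test_trim_beyond_span_errors(self):
        traj = EnsembleTrajectory(np.zeros((10, 3, 3)), _point_atoms(3), np.arange(10.0))
        with pytest.raises(ValueError, match="span"):
            geometry.equilibration_trim(traj, t_cut=20.0)


def _point_atoms(n):
    import pandas as pd

    return pd.DataFrame(
        {
            "monomer_id": ["A"] * n,
            "residue_number": np.arange(1, n + 1),
            "residue_name": ["GLY"] * n,
            "atom_name": ["CA"] * n,
        }
    )


def test_all_observables_invariant_under_per_frame_rototranslation(wobbly_trimer):
    traj, _ = wobbly_trimer
    sel = synthetic.default_selections(traj)
    rng = np.random.default_rng(13)
    moved = traj.coords.copy()
    for f in range(traj.n_frames):
        R, t = random_rototranslation(rng)
        moved[f] = traj.coords[f] @ R.T + t
    moved_traj = EnsembleTrajectory(moved, traj.atoms.copy())

    ps0 = geometry.protrusion_distances(traj, (81, "CA"), sel["core"], sel["orientation"])
    ps1 = geometry.protrusion_distances(moved_traj, (81, "CA"), sel["core"], sel["orientation"])
    assert np.abs(ps0.values - ps1.values).max() < 1e-6

    rg0 = geometry.radius_of_gyration(traj)
    rg1 = geometry.radius_of_gyration(moved_traj)
    assert np.abs(rg0 - rg1).max() < 1e-6

    rmsd0 = geometry.rmsd_timeseries(traj)
    rmsd1 = geometry.rmsd_timeseries(moved_traj)
    assert np.abs(rmsd0 - rmsd1).max() < 1e-6

    f0 = geometry.rmsf_profile(traj, sel["loop"])
    f1 = geometry.rmsf_profile(moved_traj, sel["loop"])
    assert np.abs(f0["rmsf"] - f1["rmsf"]).max() < 1e-6
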