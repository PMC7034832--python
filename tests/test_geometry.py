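"""Superposition, RMSD/RMSF conventions, replica QC, tails, distances, KDE."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from sranet.geometry import (DegenerateInputError, FittingError,
                             gaussian_kde, qc_replicas,
                             ring_distance_series, rmsd_series, rmsf_profile,
                             slice_tail, superpose)
from sranet.model_io import Trajectory, resolve_selection
from sranet.synthetic import harmonic_ensemble, make_replica_set

from conftest import static_trajectory


def oracle_min_rmsd(mobile, reference, n_starts=24, seed=0):
    """Independent minimum-RMSD oracle: numerical optimization over
    rotation vectors from many coarse starting orientations."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((x @ r.T - y) ** 2, axis=1)))

    best = np.inf
    starts = Rotation.random(n_starts, random_state=seed).as_rotvec()
    for start in starts:
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity_on_self(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_copy_rmsd_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        r = Rotation.random(random_state=5).as_matrix()
        moved = x @ r.T + np.array([4.0, -1.0, 7.0])
        _, _, rmsd = superpose(moved, x)
        assert rmsd < 1e-6

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar cloud, where an improper reflection would win
        x = rng.normal(size=(10, 3)) * np.array([1.0, 1.0, 0.05])
        y = rng.normal(size=(10, 3))
        rot, _, _ = superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("case_seed", [11, 12, 13])
    def test_agrees_with_orientation_search_oracle(self, case_seed):
        """Kabsch RMSD equals an exhaustive-orientation numerical oracle
        within 1e-4 Å on random 10-atom cases with nonzero residual."""
        rng = np.random.default_rng(case_seed)
        ref = rng.normal(size=(10, 3)) * 3.0
        mobile = ref + rng.normal(scale=0.4, size=(10, 3))
        r = Rotation.random(random_state=case_seed).as_matrix()
        mobile = mobile @ r.T + rng.normal(size=3) * 5.0
        _, _, rmsd = superpose(mobile, ref)
        assert abs(rmsd - oracle_min_rmsd(mobile, ref)) < 1e-4

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(FittingError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(FittingError):
            superpose(line, line)


class TestRMSDSeries:
    def test_identical_frames_all_zero(self, protein_dna):
        top, coords = protein_dna
        traj = static_trajectory(top, coords, 6)
        fit = resolve_selection(top, "protein and name CA")
        series = rmsd_series(traj, fit, fit)
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_planted_dna_shift_measured_after_protein_fit(self, protein_dna):
        """A rigid 5 Å DNA displacement shows as ≈5 Å DNA RMSD while the
        protein stays fitted."""
        top, coords = protein_dna
        dna = resolve_selection(top, "nucleic")
        fit = resolve_selection(top, "protein and name CA")
        shifted = coords.copy()
        shifted[dna.resolved] += np.array([5.0, 0.0, 0.0])
        traj = Trajectory(topology=top, coords=np.stack([coords, shifted]),
                          frame_times=np.arange(2.0))
        series = rmsd_series(traj, fit, dna)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert series.values[1] == pytest.approx(5.0, abs=1e-9)

    def test_calc_equals_fit_matches_superpose(self, protein_dna):
        top, coords = protein_dna
        rng = np.random.default_rng(9)
        frame = coords + rng.normal(scale=0.3, size=coords.shape)
        fit = resolve_selection(top, "protein and name CA")
        traj = Trajectory(topology=top, coords=frame[None],
                          frame_times=np.array([0.0]))
        series = rmsd_series(traj, fit, fit, reference=coords)
        _, _, direct = superpose(frame[fit.resolved], coords[fit.resolved])
        assert series.values[0] == pytest.approx(direct, abs=1e-12)


class TestRMSF:
    def test_static_trajectory_zero(self, protein_dna):
        top, coords = protein_dna
        traj = static_trajectory(top, coords, 5)
        fit = resolve_selection(top, "protein and name CA")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = rmsf_profile(traj, fit, resolve_selection(top, "all"))
        assert np.allclose(prof.atom_values, 0.0, atol=1e-9)

    def test_harmonic_calibration_sqrt3_sigma(self, protein_dna):
        """Isotropic per-coordinate σ=0.5 Å noise outside the fit region
        gives per-atom RMSF ≈ √3·σ within 5% at 2000 frames."""
        top, coords = protein_dna
        sigma = np.full(top.n_atoms, 0.5)
        protein = resolve_selection(top, "protein")
        sigma[protein.resolved] = 0.0
        traj = harmonic_ensemble(top, coords, sigma, 2000, seed=5)
        fit = resolve_selection(top, "protein and name CA")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = rmsf_profile(traj, fit, resolve_selection(top, "nucleic"))
        expected = np.sqrt(3) * 0.5
        assert np.all(np.abs(prof.atom_values - expected) / expected < 0.05)

    def test_doubling_displacements_doubles_rmsf(self, protein_dna):
        top, coords = protein_dna
        sigma = np.full(top.n_atoms, 0.3)
        protein = resolve_selection(top, "protein")
        sigma[protein.resolved] = 0.0
        fit = resolve_selection(top, "protein and name CA")
        nucleic = resolve_selection(top, "nucleic")
        t1 = harmonic_ensemble(top, coords, sigma, 400, seed=8)
        doubled = coords[None] + 2.0 * (t1.coords - coords[None])
        t2 = Trajectory(topology=top, coords=doubled,
                        frame_times=t1.frame_times)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = rmsf_profile(t1, fit, nucleic)
            p2 = rmsf_profile(t2, fit, nucleic)
        assert np.allclose(p2.atom_values, 2.0 * p1.atom_values, rtol=1e-6)

    def test_rigid_transform_invariance(self, protein_dna):
        top, coords = protein_dna
        sigma = np.full(top.n_atoms, 0.2)
        fit = resolve_selection(top, "protein and name CA")
        nucleic = resolve_selection(top, "nucleic")
        traj = harmonic_ensemble(top, coords, sigma, 200, seed=4)
        r = Rotation.random(random_state=3).as_matrix()
        moved = Trajectory(topology=top,
                           coords=traj.coords @ r.T + np.array([5.0, 1.0, -2.0]),
                           frame_times=traj.frame_times)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = rmsf_profile(traj, fit, nucleic)
            b = rmsf_profile(moved, fit, nucleic)
        assert np.allclose(a.atom_values, b.atom_values, atol=1e-9)


class TestReplicaQC:
    def test_all_static_pass(self, protein_dna):
        top, coords = protein_dna
        reps = [static_trajectory(top, coords, 10) for _ in range(3)]
        fit = resolve_selection(top, "protein and name CA")
        calc = resolve_selection(top, "nucleic")
        results = qc_replicas(reps, fit, calc, threshold=4.0, tail=5)
        assert all(r.passed for r in results)

    def test_divergent_member_excluded(self, protein_dna):
        """Exactly the 6 Å-displaced replica fails the 4 Å rule computed
        with protein-Cα fit and DNA calc over the tail window."""
        top, coords = protein_dna
        base = static_trajectory(top, coords, 40)
        reps = make_replica_set(base, 5, divergent={2}, displacement=6.0,
                                seed=7)
        fit = resolve_selection(top, "protein and name CA")
        calc = resolve_selection(top, "nucleic")
        results = qc_replicas(reps, fit, calc, threshold=4.0, tail=20)
        assert [r.passed for r in results] == [True, True, False, True, True]
        assert results[2].max_tail_rmsd > 4.0
        # order invariance
        rev = qc_replicas(reps[::-1], fit, calc, threshold=4.0, tail=20)
        assert [r.replica_id for r in rev if not r.passed] == ["r3"]

    def test_zero_threshold_excludes_all_nonidentical(self, protein_dna):
        top, coords = protein_dna
        base = static_trajectory(top, coords, 10)
        reps = make_replica_set(base, 3, divergent=set(), jitter_sigma=0.05,
                                seed=1)
        fit = resolve_selection(top, "protein and name CA")
        calc = resolve_selection(top, "nucleic")
        results = qc_replicas(reps, fit, calc, threshold=0.0, tail=5)
        assert not any(r.passed for r in results)


class TestSliceTail:
    def make(self, top, coords, n):
        return Trajectory(topology=top,
                          coords=np.repeat(coords[None], n, axis=0)
                          + np.arange(n)[:, None, None] * 0.0,
                          frame_times=np.arange(float(n)) * 100.0)

    def test_last_n_frames(self, protein_dna):
        top, coords = protein_dna
        traj = self.make(top, coords, 2000)
        tail = slice_tail(traj, last_n_frames=1000)
        assert tail.n_frames == 1000
        assert tail.frame_times[0] == traj.frame_times[1000]

    def test_keep_longer_than_trajectory_is_identity(self, protein_dna):
        top, coords = protein_dna
        traj = self.make(top, coords, 10)
        with pytest.warns(UserWarning, match="clip|keeping all"):
            tail = slice_tail(traj, last_n_frames=50)
        assert tail.n_frames == 10

    def test_last_half_by_time(self, protein_dna):
        """Keeping the last 100 ns of a 200 ns run at uniform stride keeps
        the second half of the frames."""
        top, coords = protein_dna
        traj = self.make(top, coords, 2000)   # dt 100 ps -> 200 ns total
        tail = slice_tail(traj, last_ns=100.0)
        assert tail.n_frames == 1000
        assert tail.replica_id == traj.replica_id


class TestRingDistances:
    def test_constant_separation(self, bdna_14):
        _, top, coords = bdna_14
        traj = static_trajectory(top, coords, 5)
        ring_a = resolve_selection(top, "chain A and resid 3 and not name P OP1 OP2")
        ring_b = resolve_selection(top, "chain A and resid 7 and not name P OP1 OP2")
        dist = ring_distance_series(traj, ring_a, ring_b)
        assert np.ptp(dist.samples) < 1e-9
        assert dist.kde is None  # degenerate: constant distances

    def test_kde_mode_matches_sampling_oracle(self):
        """Distances drawn from N(6, 0.3): KDE mode within 0.1 Å of 6."""
        rng = np.random.default_rng(14)
        samples = rng.normal(6.0, 0.3, size=4000)
        kde = gaussian_kde(samples)
        grid = np.linspace(4, 8, 2001)
        mode = grid[np.argmax(kde(grid))]
        assert abs(mode - 6.0) < 0.1


class TestKDE:
    def test_standard_normal_density_at_zero(self):
        samples = np.random.default_rng(0).standard_normal(10000)
        kde = gaussian_kde(samples)
        assert kde(0.0)[0] == pytest.approx(1.0 / np.sqrt(2 * np.pi),
                                            abs=0.02)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(5)
        for sample in (rng.standard_normal(500),
                       rng.exponential(2.0, 800),
                       rng.uniform(-3, 3, 300)):
            assert gaussian_kde(sample).integral() == pytest.approx(
                1.0, abs=1e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        samples = rng.standard_normal(1000)
        k0 = gaussian_kde(samples)
        k1 = gaussian_kde(samples + 2.5)
        grid = np.linspace(-3, 3, 50)
        assert np.allclose(k0(grid), k1(grid + 2.5), atol=1e-12)

    def test_fixed_bandwidth_respected(self):
        samples = np.random.default_rng(7).standard_normal(500)
        kde = gaussian_kde(samples, bandwidth=0.25)
        assert kde.bandwidth == pytest.approx(0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            gaussian_kde(np.ones(50))
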