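"""Energy/force consistency and Langevin integrator behaviour."""

import numpy as np
import pytest
import scipy.stats

import tailgate as tg
from tailgate.dynamics import CompiledSystem

from test_structure_io import make_structure


def finite_difference_forces(system, coords, h=1e-6):
    """Independent central-difference gradient oracle."""
    fd = np.zeros_like(coords)
    for a in range(coords.shape[0]):
        for ax in range(3):
            cp = coords.copy()
            cp[a, ax] += h
            cm = coords.copy()
            cm[a, ax] -= h
            fd[a, ax] = -(tg.energy_forces(system, cp).energy
                          - tg.energy_forces(system, cm).energy) / (2 * h)
    return fd


class TestEnergyForces:
    def test_bonded_pair_harmonic(self):
        s = make_structure([[0.0, 0.0, 0.0], [0.38, 0.0, 0.0]])
        cm = tg.ContactMap(np.zeros(0, int), np.zeros(0, int), np.zeros(0))
        pot = tg.build_potential(s, cm, tg.ForceFieldParams(k_bond=100.0))
        sys = tg.CompiledSystem(pot)
        delta = 0.05
        coords = np.array([[0.0, 0.0, 0.0], [0.38 + delta, 0.0, 0.0]])
        ev = tg.energy_forces(sys, coords)
        assert ev.energy == pytest.approx(0.5 * 100.0 * delta ** 2, rel=1e-12)
        assert ev.forces[1, 0] == pytest.approx(-100.0 * delta, rel=1e-12)
        assert ev.forces[0, 0] == pytest.approx(100.0 * delta, rel=1e-12)

    def test_reference_forces_vanish(self, full_bundle, full_system):
        ev = tg.energy_forces(full_system, full_bundle.post_structure.coords)
        mob = full_system.potential.mobile
        assert np.max(np.abs(ev.forces[mob])) < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_forces_match_finite_differences(self, seed, full_bundle,
                                             full_system):
        rng = np.random.default_rng(seed)
        coords = full_bundle.post_structure.coords.copy()
        mob = np.flatnonzero(full_system.potential.mobile)
        coords[mob] += 0.04 * rng.standard_normal((mob.size, 3))
        ev = tg.energy_forces(full_system, coords)
        fd = finite_difference_forces(full_system, coords)
        scale = np.maximum(1.0, np.abs(ev.forces[mob]))
        assert np.max(np.abs(fd[mob] - ev.forces[mob]) / scale) < 1e-6

    def test_overlapping_cores_diverge_cleanly(self):
        s = make_structure([[0.0, 0.0, 0.0], [1e-30, 0.0, 0.0]],
                           chains=["A", "B"])
        cm = tg.ContactMap(np.zeros(0, int), np.zeros(0, int), np.zeros(0))
        pot = tg.build_potential(s, cm, tg.ForceFieldParams())
        with pytest.raises(tg.DivergedError):
            tg.energy_forces(pot, s.coords)


class TestRunLangevin:
    def test_zero_temperature_limit_stationary(self, full_bundle,
                                               full_system):
        cfg = tg.SimConfig(temperature=1e-12, friction=1.0, timestep=0.002,
                           n_steps=10_000, output_stride=1000, seed=1)
        traj = tg.run_langevin(full_system, full_bundle.post_structure, cfg)
        idx = full_bundle.post_structure.index_of(full_bundle.tracked_atom_id)
        drift = np.linalg.norm(traj.frames[-1, idx] - traj.frames[0, idx])
        assert drift < 1e-3

    def test_bitwise_deterministic(self, full_bundle, full_system):
        cfg = tg.SimConfig(n_steps=5_000, output_stride=100, seed=42)
        t1 = tg.run_langevin(full_system, full_bundle.pre_structure, cfg)
        t2 = tg.run_langevin(full_system, full_bundle.pre_structure, cfg)
        assert np.array_equal(t1.frames, t2.frames)
        t3 = tg.run_langevin(full_system, full_bundle.pre_structure,
                             cfg.replace(seed=43))
        assert not np.array_equal(t1.frames, t3.frames)

    def test_immobile_atoms_never_move(self, full_bundle, full_system):
        cfg = tg.SimConfig(n_steps=2_000, output_stride=500, seed=3)
        traj = tg.run_langevin(full_system, full_bundle.pre_structure, cfg)
        frozen = ~full_system.potential.mobile
        ref = full_bundle.pre_structure.coords[frozen]
        for f in range(traj.n_frames):
            assert np.array_equal(traj.frames[f][frozen], ref)

    def test_frame_count_contract(self, full_bundle, full_system):
        cfg = tg.SimConfig(n_steps=1_234, output_stride=100, seed=0)
        traj = tg.run_langevin(full_system, full_bundle.pre_structure, cfg)
        assert traj.n_frames == 1_234 // 100 + 1
        assert traj.times[0] == 0.0

    def test_neighbor_list_matches_full_pair_evaluation(self, full_bundle,
                                                        forcefield):
        """With a huge skin the Verlet list holds every candidate pair;
        the default skin must reproduce the exact same dynamics."""
        sys_small = tg.translocation_potential(full_bundle, forcefield, 0.38)
        sys_big = CompiledSystem(sys_small.potential, skin=5.0)
        cfg = tg.SimConfig(n_steps=4_000, output_stride=200, seed=9)
        t_small = tg.run_langevin(sys_small, full_bundle.pre_structure, cfg)
        t_big = tg.run_langevin(sys_big, full_bundle.pre_structure, cfg)
        assert np.array_equal(t_small.frames, t_big.frames)

    def test_equipartition_variance(self):
        """Positional variance of a tethered bead equals T/k."""
        k, temp = 100.0, 1.0
        s, pot = tg.make_harmonic_system(k, 1)
        cfg = tg.SimConfig(temperature=temp, friction=2.0, timestep=0.002,
                           n_steps=300_000, output_stride=10, seed=11)
        traj = tg.run_langevin(pot, s, cfg)
        x = traj.frames[2_000:, 0, :] - s.coords[0]
        blocks = np.array_split(x, 20, axis=0)
        block_vars = np.array([b.var(axis=0).mean() for b in blocks])
        se = block_vars.std(ddof=1) / np.sqrt(len(block_vars))
        assert abs(x.var(axis=0).mean() - temp / k) < 3 * se + 1e-4

    def test_harmonic_samples_normal(self):
        """Equilibrium coordinates of the tether pass a normality check."""
        s, pot = tg.make_harmonic_system(50.0, 1)
        cfg = tg.SimConfig(temperature=0.5, friction=2.0, timestep=0.002,
                           n_steps=200_000, output_stride=400, seed=5)
        traj = tg.run_langevin(pot, s, cfg)
        x = traj.frames[50:, 0, 0]
        assert scipy.stats.normaltest(x).pvalue > 1e-3

    def test_velocity_verlet_limit_conserves_energy(self):
        """friction = 0 reduces BAOAB to velocity Verlet: no energy drift."""
        s, pot = tg.make_harmonic_system(100.0, 2)
        rng = np.random.default_rng(4)
        start = s.copy()
        start.coords = s.coords + 0.05 * rng.standard_normal(s.coords.shape)
        cfg = tg.SimConfig(temperature=0.5, friction=0.0, timestep=0.002,
                           n_steps=20_000, output_stride=20, seed=8)
        traj = tg.run_langevin(pot, start, cfg)
        pe = np.array([tg.energy_forces(pot, f).energy for f in traj.frames])
        etot = pe + traj.kinetic_energy
        n = etot.size
        drift = abs(etot[-n // 10:].mean() - etot[:n // 10].mean())
        assert drift / abs(etot.mean()) < 1e-4

    def test_invalid_config_rejected(self):
        with pytest.raises(tg.ValidationError):
            tg.SimConfig(temperature=0.0)
        with pytest.raises(tg.ValidationError):
            tg.SimConfig(n_steps=0)
        with pytest.raises(tg.ValidationError):
            tg.SimConfig(output_stride=0)
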