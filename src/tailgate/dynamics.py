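"""Langevin dynamics of a structure-based potential.

The integrator is BAOAB splitting of underdamped Langevin dynamics: two
half-kicks (B) and two half-drifts (A) around an exact Ornstein-Uhlenbeck
velocity update (O).  With friction = 0 the O step is the identity and the
scheme reduces to velocity Verlet, which is the basis of the zero-friction
energy-conservation check.  Bead masses are 1 in reduced units.

Runs are bitwise reproducible: all randomness (Maxwell-Boltzmann initial
velocities and thermostat noise) comes from one PCG64 generator seeded with
``cfg.seed``, and noise is drawn in fixed-size chunks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import DivergedError, ValidationError
from .forcefield import StructurePotential
from .structure import SimConfig, Structure, Trajectory

_CHUNK = 8192  # steps of noise drawn per kernel call (fixed for determinism)


@dataclass
class ForceEvaluation:
    """Energy and exact negative gradient of a potential at one configuration.

    Forces on immobile atoms are reported (they are part of the gradient)
    but the integrator never applies them.
    """

    energy: float
    forces: np.ndarray  # (N, 3)


class CompiledSystem:
    """Kernel-ready view of a StructurePotential.

    Precomputes the candidate excluded-volume pair list (pairs with at
    least one mobile atom) for the integrator and the full pair list (all
    atoms) for exact energy/force evaluation.
    """

    def __init__(self, p: StructurePotential, skin: float = 0.2):
        self.potential = p
        self.skin = float(skin)
        self.mobile_idx = np.flatnonzero(p.mobile).astype(np.int64)
        if self.mobile_idx.size == 0:
            raise ValidationError("no mobile atoms to integrate")
        self.cand_i, self.cand_j, self.cand_sig = p.ev_candidate_pairs()
        self.form = (_kernels.FORM_12_6 if p.contact_form == "12-6"
                     else _kernels.FORM_12_10)
        self.digest = hashlib.sha1(p.to_json().encode()).hexdigest()[:16]

    @property
    def n_atoms(self) -> int:
        return self.potential.n_atoms

    def term_args(self):
        p = self.potential
        return (p.bond_i, p.bond_j, p.bond_r0, p.k_bond,
                p.angle_i, p.angle_j, p.angle_k, p.angle_theta0, p.k_angle,
                p.dih_i, p.dih_j, p.dih_k, p.dih_l, p.dih_phi0, p.k_dihedral,
                p.contact_i, p.contact_j, p.contact_r0, p.contact_eps,
                self.form)



def _as_system(p) -> CompiledSystem:
    return p if isinstance(p, CompiledSystem) else CompiledSystem(p)


def energy_forces(p: StructurePotential | CompiledSystem,
                  coords: np.ndarray) -> ForceEvaluation:
    """Exact energy and forces of the full potential (no neighbour list)."""
    sys = _as_system(p)
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (sys.n_atoms, 3):
        raise ValidationError(
            f"coords shape {coords.shape} != ({sys.n_atoms}, 3)")
    pot = sys.potential
    f = np.zeros_like(coords)
    ev_i, ev_j, ev_sig = sys.cand_i, sys.cand_j, sys.cand_sig
    e = _kernels.forces_energy(coords, f, *sys.term_args(),
                               ev_i, ev_j, ev_sig, ev_i.shape[0], pot.eps_ev,
                               pot.restraint_idx,
                               pot.restraint_x0.reshape(-1, 3),
                               pot.restraint_k)
    if not (np.isfinite(e) and np.all(np.isfinite(f))):
        raise DivergedError("non-finite energy or force "
                            "(overlapping excluded-volume cores?)")
    return ForceEvaluation(energy=float(e), forces=f)


def run_langevin(p: StructurePotential | CompiledSystem, start: Structure,
                 cfg: SimConfig, v0: np.ndarray | None = None,
                 x0: np.ndarray | None = None, return_state: bool = False):
    """Integrate Langevin dynamics from ``start``; returns a Trajectory.

    Initial velocities are Maxwell-Boltzmann at cfg.temperature unless
    ``v0`` is given; ``x0`` overrides the start coordinates (both are used
    by the pipeline to continue a run in segments).  Frames (all atoms) are
    emitted every ``cfg.output_stride`` steps, frame 0 being the initial
    coordinates.  With ``return_state`` the final (coords, velocities) are
    returned alongside the trajectory.
    """
    sys = _as_system(p)
    pot = sys.potential
    coords = np.array(x0 if x0 is not None else start.coords,
                      dtype=np.float64)
    if coords.shape != (sys.n_atoms, 3):
        raise ValidationError("start coordinates do not match the potential")

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    vels = np.zeros_like(coords)
    n_mob = sys.mobile_idx.size
    if v0 is not None:
        vels[:] = v0
        vels[~pot.mobile] = 0.0
    else:
        vels[sys.mobile_idx] = (np.sqrt(cfg.temperature)
                                * rng.standard_normal((n_mob, 3)))

    c1 = float(np.exp(-cfg.friction * cfg.timestep))
    c2 = float(np.sqrt(cfg.temperature * max(0.0, 1.0 - c1 * c1)))

    n_frames = cfg.n_frames
    frames = np.empty((n_frames, sys.n_atoms, 3), dtype=np.float64)
    ke = np.empty(n_frames, dtype=np.float64)
    frames[0] = coords
    ke[0] = 0.5 * float(np.sum(vels[sys.mobile_idx] ** 2))

    cap = sys.cand_i.shape[0]
    act_i = np.empty(max(cap, 1), dtype=np.int64)
    act_j = np.empty(max(cap, 1), dtype=np.int64)
    act_sig = np.empty(max(cap, 1), dtype=np.float64)
    ref = np.array(coords, copy=True)
    n_act = _kernels.build_neighbor_list(coords, sys.cand_i, sys.cand_j,
                                         sys.cand_sig, sys.skin,
                                         act_i, act_j, act_sig)
    forces = np.zeros_like(coords)
    res_x0 = pot.restraint_x0.reshape(-1, 3)
    _kernels.forces_energy(coords, forces, *sys.term_args(),
                           act_i, act_j, act_sig, n_act, pot.eps_ev,
                           pot.restraint_idx, res_x0, pot.restraint_k)

    frame_count = 1
    step_offset = 0
    while step_offset < cfg.n_steps:
        chunk = min(_CHUNK, cfg.n_steps - step_offset)
        noise = rng.standard_normal((chunk, n_mob, 3))
        status, local, n_act, frame_count = _kernels.integrate_chunk(
            coords, vels, forces, sys.mobile_idx,
            cfg.timestep, c1, c2, noise,
            *sys.term_args(),
            sys.cand_i, sys.cand_j, sys.cand_sig, sys.skin, pot.eps_ev,
            act_i, act_j, act_sig, n_act, ref,
            pot.restraint_idx, res_x0, pot.restraint_k,
            frames, ke, cfg.output_stride, step_offset, frame_count)
        if status != 0:
            raise DivergedError(
                f"non-finite coordinates at step {step_offset + local}",
                step=step_offset + local)
        step_offset += chunk

    times = cfg.timestep * cfg.output_stride * np.arange(n_frames,
                                                         dtype=np.float64)
    digest = hashlib.sha1(
        f"{sys.digest}|{cfg.temperature}|{cfg.friction}|{cfg.timestep}|"
        f"{cfg.n_steps}|{cfg.output_stride}|{cfg.seed}".encode()
    ).hexdigest()[:16]
    traj = Trajectory(times=times, frames=frames, seed=cfg.seed,
                      config_digest=digest,
                      output_stride=cfg.output_stride,
                      kinetic_energy=ke).validate()
    if return_state:
        return traj, (coords, vels)
    return traj
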