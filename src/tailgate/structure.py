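"""Core in-memory containers: coordinates, simulation settings, trajectories.

Internal unit system is reduced throughout the package: lengths in nm,
energies in units of the native-contact well depth epsilon, masses of 1,
k_B = 1, and time in tau = nm * sqrt(mass / epsilon).  Angstrom appears only
at the PDB boundary (see :mod:`tailgate.pdbio`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class Structure:
    """A set of beads/atoms with identity, coordinates (nm) and mobility.

    Atoms are stored column-wise in file order.  ``mobile`` marks atoms that
    the integrator moves; immobile atoms form the rigid scaffold.
    """

    atom_id: np.ndarray        # (N,) int
    atom_name: np.ndarray      # (N,) str
    residue_index: np.ndarray  # (N,) int
    residue_name: np.ndarray   # (N,) str
    chain_id: np.ndarray       # (N,) str, single character
    coords: np.ndarray         # (N, 3) float, nm
    mobile: np.ndarray         # (N,) bool

    def __post_init__(self):
        self.atom_id = np.asarray(self.atom_id, dtype=np.int64)
        self.atom_name = np.asarray(self.atom_name, dtype="U4")
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype="U3")
        self.chain_id = np.asarray(self.chain_id, dtype="U1")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.mobile = np.asarray(self.mobile, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_id.shape[0])

    def validate(self) -> "Structure":
        n = self.n_atoms
        if n == 0:
            raise ValidationError("no atoms")
        for name, arr in (("atom_name", self.atom_name),
                          ("residue_index", self.residue_index),
                          ("residue_name", self.residue_name),
                          ("chain_id", self.chain_id),
                          ("mobile", self.mobile)):
            if arr.shape[0] != n:
                raise ValidationError(f"{name} length {arr.shape[0]} != {n}")
        if self.coords.shape != (n, 3):
            raise ValidationError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if np.unique(self.atom_id).shape[0] != n:
            raise ValidationError("duplicate atom ids")
        if n > 1 and not np.all(np.diff(self.atom_id) > 0):
            raise ValidationError("atom ids not strictly increasing")
        # chain contiguity: each chain id appears in one contiguous block
        seen = set()
        prev = None
        for c in self.chain_id:
            if c != prev:
                if c in seen:
                    raise ValidationError(f"chain {c!r} not contiguous")
                seen.add(c)
                prev = c
        return self

    def chains(self) -> list[str]:
        """Chain ids in file order."""
        out: list[str] = []
        for c in self.chain_id:
            if not out or out[-1] != c:
                out.append(str(c))
        return out

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_id == chain_id

    def index_of(self, atom_id: int) -> int:
        """Array index of the atom with the given id."""
        idx = np.searchsorted(self.atom_id, atom_id)
        if idx >= self.n_atoms or self.atom_id[idx] != atom_id:
            raise ValidationError(f"unknown atom id {atom_id}")
        return int(idx)

    def copy(self) -> "Structure":
        return Structure(*(np.array(getattr(self, f.name), copy=True)
                           for f in dataclasses.fields(self)))

    def subset(self, mask: np.ndarray) -> "Structure":
        """New Structure keeping atoms where ``mask`` is True (ids preserved)."""
        return Structure(*(np.array(getattr(self, f.name)[mask], copy=True)
                           for f in dataclasses.fields(self)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return all(np.array_equal(getattr(self, f.name), getattr(other, f.name))
                   for f in dataclasses.fields(self))


@dataclass
class SimConfig:
    """Langevin integration settings in reduced units.

    temperature: k_B T in units of epsilon (> 0)
    friction:    gamma in 1/tau
    timestep:    dt in tau
    """

    temperature: float = 0.5
    friction: float = 1.0
    timestep: float = 0.002
    n_steps: int = 100_000
    output_stride: int = 50
    seed: int = 0

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0")
        if not self.timestep > 0:
            raise ValidationError("timestep must be > 0")
        if self.friction < 0:
            raise ValidationError("friction must be >= 0")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.output_stride < 1:
            raise ValidationError("output_stride must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.output_stride + 1

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Trajectory:
    """Time-ordered frames (nm) from one Langevin run.

    ``kinetic_energy`` is an optional in-memory per-frame record used by the
    energy-conservation diagnostics; it is not part of the on-disk container.
    """

    times: np.ndarray    # (F,) tau, uniformly spaced starting at 0
    frames: np.ndarray   # (F, N, 3) nm
    seed: int
    config_digest: str
    output_stride: int = 1
    kinetic_energy: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.frames = np.asarray(self.frames)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def validate(self) -> "Trajectory":
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (F, N, 3)")
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValidationError("times/frames length mismatch")
        if self.n_frames >= 2:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValidationError("times not strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValidationError("times not uniformly spaced")
        return self

    def atom_positions(self, index: int) -> np.ndarray:
        """(F, 3) positions of the atom at array index ``index``."""
        return self.frames[:, index, :]
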