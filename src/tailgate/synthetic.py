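"""Synthetic scaled-down translocation systems.

The generator emulates the geometry of tmRNA-SmpB translocation on the
large ribosomal subunit with three components inside a cylindrical
corridor aligned with z:

* a rigid **scaffold** chain (``S``): corridor wall rings, a floor disk at
  the P-site end and a cap disk at the A-site end, all immobile — the
  stand-in for the ribosome body;
* a semi-rigid **ligand** chain (``L``): a gently helical bead chain
  mimicking the tmRNA tRNA-like-domain acceptor stem, whose leading bead
  (the tracked atom, analogous to the P atom of U9) sits at the P-site
  target in the post-translocation state and ``corridor_length`` away in
  the pre-translocation state;
* a flexible **tail** chain (``T``): a bead chain mimicking the bL27
  N-terminal tail, held near the corridor wall at ``bottleneck_position``
  (distance from the P-site target) by a stiff positional tether on its
  anchored end.  The tail carries no native contacts downstream — it is a
  purely steric, disordered obstacle.

The post-translocation structure is the reference (native) state for the
Go potential; translocation is spontaneous relaxation of the ligand from
the A-site start.  Attractive native contacts arise only where the ligand
touches the scaffold in the post state, i.e. at the P-site floor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, ValidationError
from .forcefield import StructurePotential
from .structure import Structure

#: spacing of wall rings along z, in units of bead_spacing
_WALL_RING_FACTOR = 1.3
#: ligand helix turn per bead (rad); keeps the chain away from exact
#: collinearity so bond angles and dihedrals are well-conditioned
_HELIX_TURN = 1.2


@dataclass
class GeometryParams:
    """Dimensions of the synthetic corridor system (lengths in nm).

    Defaults encode the documented translocation geometry: the tracked
    atom travels 3.0 nm from the A-site start to the P-site target, and
    the tail anchor sits at the steric bottleneck 2.2 nm from the target.
    """

    corridor_length: float = 3.0
    bottleneck_position: float = 2.2
    corridor_radius: float = 1.0
    tail_residues: int = 9
    ligand_beads: int = 12
    scaffold_beads: int = 400       # upper bound on generated scaffold beads
    bead_spacing: float = 0.38
    ligand_helix_radius: float = 0.17
    # the P site is a snug pocket: the corridor tapers from corridor_radius
    # at z = pocket_depth down to pocket_radius at the floor, funnelling the
    # ligand head onto the axis and giving it a basin of native contacts
    pocket_radius: float = 0.6
    pocket_depth: float = 1.5

    def __post_init__(self):
        for name in ("corridor_length", "bottleneck_position",
                     "corridor_radius", "bead_spacing", "pocket_radius",
                     "pocket_depth"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.bottleneck_position < self.corridor_length:
            raise ValidationError(
                "bottleneck_position must be < corridor_length")
        if self.tail_residues < 0:
            raise ValidationError("tail_residues must be >= 0")
        if self.ligand_beads < 2:
            raise ValidationError("ligand_beads must be >= 2")
        if not self.pocket_radius <= self.corridor_radius:
            raise ValidationError("pocket_radius must be <= corridor_radius")
        if self.pocket_radius < self.ligand_helix_radius + self.bead_spacing:
            raise ValidationError(
                "pocket_radius leaves no room for the ligand")
        if self.pocket_depth >= self.bottleneck_position:
            raise ValidationError(
                "pocket must end below the tail bottleneck")

    def replace(self, **kw) -> "GeometryParams":
        return dataclasses.replace(self, **kw)


@dataclass
class SystemBundle:
    """Matched pre/post-translocation endpoint structures plus metadata."""

    pre_structure: Structure
    post_structure: Structure
    tracked_atom_id: int
    target_position: np.ndarray
    labels: dict[str, str]
    anchors: list[tuple[int, np.ndarray]] = field(default_factory=list)
    geometry: GeometryParams | None = None
    seed: int = 0

    def validate(self) -> "SystemBundle":
        pre, post = self.pre_structure, self.post_structure
        pre.validate()
        post.validate()
        for name in ("atom_id", "atom_name", "residue_index",
                     "residue_name", "chain_id", "mobile"):
            if not np.array_equal(getattr(pre, name), getattr(post, name)):
                raise ValidationError(f"pre/post {name} mismatch")
        idx = post.index_of(self.tracked_atom_id)
        disp = np.linalg.norm(post.coords[idx] - pre.coords[idx])
        if self.geometry is not None and \
                abs(disp - self.geometry.corridor_length) > 1e-9:
            raise ValidationError(
                f"tracked-atom displacement {disp} != corridor_length")
        return self

    def to_json(self) -> str:
        return json.dumps({
            "tracked_atom_id": int(self.tracked_atom_id),
            "target_position": np.asarray(self.target_position).tolist(),
            "labels": self.labels,
            "anchors": [(int(a), np.asarray(p).tolist())
                        for a, p in self.anchors],
            "geometry": dataclasses.asdict(self.geometry)
            if self.geometry else None,
            "seed": int(self.seed),
        })

    def write(self, directory: str | Path, prefix: str = "system") -> None:
        """Emit pre/post PDB files plus the JSON metadata sidecar."""
        from .pdbio import write_structure
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{prefix}_pre.pdb").write_text(
            write_structure(self.pre_structure))
        (directory / f"{prefix}_post.pdb").write_text(
            write_structure(self.post_structure))
        (directory / f"{prefix}_meta.json").write_text(self.to_json())


def _ring(radius: float, n: int, z: float, phase: float) -> np.ndarray:
    th = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.full(n, z)])


def _disk(radius_max: float, spacing: float, z: float,
          phase: float) -> np.ndarray:
    rings = [np.array([[0.0, 0.0, z]])]
    r = spacing
    while r <= radius_max + 1e-9:
        n = max(int(np.floor(2.0 * np.pi * r / spacing)), 3)
        rings.append(_ring(r, n, z, phase))
        r += spacing
    return np.vstack(rings)


def _ligand_coords(g: GeometryParams, head_z: float) -> np.ndarray:
    """Helical ligand chain; bead 0 (the tracked atom) at z = head_z."""
    r = g.ligand_helix_radius
    chord_xy = 2.0 * r * np.sin(_HELIX_TURN / 2.0)
    if chord_xy >= g.bead_spacing:
        raise GeometryError("ligand helix radius too large for bead spacing")
    rise = np.sqrt(g.bead_spacing ** 2 - chord_xy ** 2)
    k = np.arange(g.ligand_beads)
    th = k * _HELIX_TURN
    return np.column_stack([r * np.cos(th), r * np.sin(th),
                            head_z + k * rise])


def make_translocation_system(g: GeometryParams, include_tail: bool = True,
                              seed: int = 0) -> SystemBundle:
    """Build the corridor + ligand (+ tail) system.

    Deterministic for fixed (g, seed); the seed sets a small global
    azimuthal phase so distinct replicate geometries are trivially
    available.  With ``include_tail=False`` the bundle differs from the
    tailed one only by the absence of the tail chain (scaffold and ligand
    coordinates are bit-identical and keep their atom ids because the tail
    chain is last in file order).
    """
    s = g.bead_spacing
    R = g.corridor_radius
    if include_tail and g.tail_residues > 0 and R < 2.0 * s:
        raise GeometryError(
            "corridor_radius leaves the tail anchor less than one "
            "bead_spacing from the axis; no room for the tail")

    phase = 2.0 * np.pi * ((seed % 997) / 997.0) / 16.0

    post_ligand = _ligand_coords(g, 0.0)
    ligand_extent = post_ligand[-1, 2]
    z_top = g.corridor_length + ligand_extent + 2.0 * s

    # corridor wall: rings on a z grid that passes exactly through the
    # bottleneck so the tail anchor aligns with a wall lattice site; the
    # wall tapers linearly into the P-site pocket below pocket_depth
    def wall_radius(z: float) -> float:
        if z >= g.pocket_depth:
            return R
        frac = max(z, 0.0) / g.pocket_depth
        return g.pocket_radius + (R - g.pocket_radius) * frac

    dz = _WALL_RING_FACTOR * s
    n_per_ring = max(int(np.floor(2.0 * np.pi * R / s)), 3)
    k_lo = int(np.ceil((-s - g.bottleneck_position) / dz))
    k_hi = int(np.floor((z_top - g.bottleneck_position) / dz))
    wall = []
    for k in range(k_lo, k_hi + 1):
        z = g.bottleneck_position + k * dz
        r_ring = wall_radius(z)
        n_ring = max(int(np.floor(2.0 * np.pi * r_ring / s)), 3)
        ring_phase = phase + (k % 2) * np.pi / n_ring
        wall.append(_ring(r_ring, n_ring, z, ring_phase))
    z_cap = g.bottleneck_position + (k_hi + 1) * dz
    scaffold = np.vstack(wall + [_disk(g.pocket_radius, s, -s, phase),
                                 _disk(R, s, z_cap, phase)])
    if scaffold.shape[0] > g.scaffold_beads:
        raise GeometryError(
            f"geometry requires {scaffold.shape[0]} scaffold beads, above "
            f"the scaffold_beads bound {g.scaffold_beads}")

    # tail: an arc at one bead_spacing inside the wall, in the bottleneck
    # plane; chain order runs tip -> anchored end, the anchored end aligned
    # with a wall bead
    tail = None
    anchor = None
    if include_tail and g.tail_residues > 0:
        rho = R - s
        dth = 2.0 * np.arcsin(min(s / (2.0 * rho), 1.0))
        p = np.arange(g.tail_residues)           # 0 = tip
        th = phase + (g.tail_residues - 1 - p) * dth
        tail = np.column_stack([rho * np.cos(th), rho * np.sin(th),
                                np.full(g.tail_residues,
                                        g.bottleneck_position)])
        anchor = tail[-1].copy()

    def assemble(ligand_xyz: np.ndarray) -> Structure:
        parts = [("S", "SCF", "SC", scaffold, False),
                 ("L", "U", "P", ligand_xyz, True)]
        if tail is not None:
            parts.append(("T", "GLY", "CA", tail, True))
        ids, names, ridx, rnames, chains, xyz, mobile = \
            [], [], [], [], [], [], []
        next_id = 1
        for chain, resname, name, coords, mob in parts:
            for r, pos in enumerate(coords, start=1):
                ids.append(next_id)
                next_id += 1
                names.append(name)
                ridx.append(r)
                rnames.append(resname)
                chains.append(chain)
                xyz.append(pos)
                mobile.append(mob)
        return Structure(np.array(ids), np.array(names), np.array(ridx),
                         np.array(rnames), np.array(chains),
                         np.array(xyz, dtype=np.float64),
                         np.array(mobile)).validate()

    post = assemble(post_ligand)
    pre_ligand = post_ligand + np.array([0.0, 0.0, g.corridor_length])
    pre = assemble(pre_ligand)

    tracked_id = int(scaffold.shape[0] + 1)      # first ligand bead
    labels = {"S": "scaffold", "L": "ligand"}
    anchors = []
    if tail is not None:
        labels["T"] = "tail"
        anchor_atom = int(scaffold.shape[0] + g.ligand_beads
                          + g.tail_residues)     # last tail bead
        anchors.append((anchor_atom, anchor))
    return SystemBundle(
        pre_structure=pre, post_structure=post,
        tracked_atom_id=tracked_id,
        target_position=post_ligand[0].copy(),
        labels=labels, anchors=anchors, geometry=g, seed=seed,
    ).validate()


def make_harmonic_system(spring_constant: float, n_atoms: int,
                         spacing: float = 2.0
                         ) -> tuple[Structure, StructurePotential]:
    """Independent harmonic tethers: the analytic validation fixture.

    Each atom is tied to its initial position by V = 1/2 k |x - x0|^2 and
    interacts with nothing else (atoms are spaced far outside the
    excluded-volume range), so equilibrium positional variance per
    coordinate is exactly T/k.
    """
    if not spring_constant > 0:
        raise ValidationError("spring_constant must be > 0")
    if n_atoms < 1:
        raise ValidationError("n_atoms must be >= 1")
    coords = np.column_stack([spacing * np.arange(n_atoms),
                              np.zeros(n_atoms), np.zeros(n_atoms)])
    s = Structure(np.arange(1, n_atoms + 1),
                  np.array(["CA"] * n_atoms),
                  np.arange(1, n_atoms + 1),
                  np.array(["GLY"] * n_atoms),
                  np.array(["H"] * n_atoms),
                  coords, np.ones(n_atoms, dtype=bool)).validate()
    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0, dtype=np.float64)
    pot = StructurePotential(
        atom_ids=np.array(s.atom_id), mobile=np.array(s.mobile),
        bond_i=empty_i, bond_j=empty_i, bond_r0=empty_f, k_bond=0.0,
        angle_i=empty_i, angle_j=empty_i, angle_k=empty_i,
        angle_theta0=empty_f, k_angle=0.0,
        dih_i=empty_i, dih_j=empty_i, dih_k=empty_i, dih_l=empty_i,
        dih_phi0=empty_f, k_dihedral=0.0,
        contact_i=empty_i, contact_j=empty_i, contact_r0=empty_f,
        contact_eps=empty_f, contact_form="12-6",
        sigma=np.full(n_atoms, 0.2), eps_ev=1.0,
        restraint_idx=np.arange(n_atoms, dtype=np.int64),
        restraint_x0=np.array(coords, copy=True),
        restraint_k=np.full(n_atoms, float(spring_constant)),
    )
    return s, pot
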