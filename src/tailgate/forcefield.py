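"""Structure-based (Go-type) potential construction.

The energy function is the classic single-basin native-centric form: the
reference structure is the global minimum by construction.

* bonds (consecutive beads in a chain):   V = 1/2 k_bond (r - r0)^2
* angles (consecutive triples):           V = 1/2 k_angle (theta - theta0)^2
* dihedrals (consecutive quadruples):     V = k_d [1 - cos(phi - phi0)]
                                            + k_d/2 [1 - cos 3(phi - phi0)]
* native contacts, "12-6" form:           V = eps [ (r0/r)^12 - 2 (r0/r)^6 ]
  or "12-10" form:                        V = eps [ 5 (r0/r)^12 - 6 (r0/r)^10 ]
  both with minimum exactly -eps at r = r0
* excluded volume (all other non-bonded pairs), truncated at r = sigma so
  that energy and force vanish there:
                                          V = eps_ev [ (s/r)^12 - 2 (s/r)^6 + 1 ]  for r < s
  with s the arithmetic mean of the two per-atom radii
* optional positional restraints:         V = 1/2 k (x - x0)^2

All reference values (r0, theta0, phi0, contact r0) are taken from the
reference structure, so the net force on every mobile atom vanishes there.

A fully immobile substructure is a rigid body with no internal energy:
bonded terms are generated only for chains containing at least one mobile
atom, and excluded volume acts only between pairs with at least one mobile
atom.  (Native contacts between two immobile atoms are permitted by the
generic contact-map contract; the experiment pipeline drops them, along
with every contact that touches the disordered tail chain, when building
the translocation potential.)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure import Structure

CONTACT_FORMS = ("12-6", "12-10")


@dataclass
class ForceFieldParams:
    """Force-field constants in reduced units (energies in eps_contact).

    Defaults are conventional coarse-grained Go-model magnitudes; none are
    dictated by experiment, so every one is config-exposed and recorded in
    the experiment report.
    """

    k_bond: float = 10000.0          # eps / nm^2
    k_angle: float = 40.0            # eps / rad^2
    k_dihedral: float = 1.0          # eps
    eps_contact: float = 1.0         # eps (defines the energy unit)
    eps_ev: float = 1.0              # eps
    sigma_ev: float = 0.38           # nm, default per-atom excluded-volume diameter
    cutoff: float = 0.55             # nm, native-contact cutoff
    min_seq_separation: int = 4      # residues, intra-chain contact exclusion
    contact_form: str = "12-6"
    rigid_chain_contact_scale: float = 3.0  # eps multiplier for intra-chain
                                            # contacts of semi-rigid chains

    def __post_init__(self):
        if self.contact_form not in CONTACT_FORMS:
            raise ValidationError(
                f"contact_form must be one of {CONTACT_FORMS}")
        for name in ("k_bond", "k_angle", "eps_contact", "eps_ev",
                     "sigma_ev", "cutoff"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    def replace(self, **kw) -> "ForceFieldParams":
        return dataclasses.replace(self, **kw)


@dataclass
class ContactMap:
    """Native contact pairs (atom ids, i < j) with reference distances r0 (nm)."""

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.r0 = np.asarray(self.r0, dtype=np.float64)

    @property
    def n_contacts(self) -> int:
        return int(self.i.shape[0])

    def validate(self) -> "ContactMap":
        if not (self.i.shape == self.j.shape == self.r0.shape):
            raise ValidationError("contact arrays must have equal length")
        if np.any(self.i >= self.j):
            raise ValidationError("contacts must satisfy i < j")
        if np.any(self.r0 <= 0):
            raise ValidationError("contact r0 must be > 0")
        pairs = set(zip(self.i.tolist(), self.j.tolist()))
        if len(pairs) != self.n_contacts:
            raise ValidationError("duplicate contact pairs")
        return self

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def subset(self, mask: np.ndarray) -> "ContactMap":
        return ContactMap(self.i[mask], self.j[mask], self.r0[mask])


def _bonded_index_pairs(s: Structure, include_immobile_chains: bool = False
                        ) -> list[tuple[int, int]]:
    """Array-index pairs of consecutive atoms within each chain.

    Unless ``include_immobile_chains`` is set, chains with no mobile atom
    (rigid scaffolds, whose internal energy is constant) contribute none.
    """
    live = {c for c in np.unique(s.chain_id)
            if include_immobile_chains or np.any(s.mobile[s.chain_id == c])}
    chain = s.chain_id
    return [(a, a + 1) for a in range(s.n_atoms - 1)
            if chain[a] == chain[a + 1] and chain[a] in live]


def compute_contact_map(s: Structure, cutoff: float = 0.55,
                        min_seq_separation: int = 4) -> ContactMap:
    """Native contacts of a reference structure.

    A pair (i, j), i < j by atom id, is a contact iff the reference distance
    is <= cutoff, the atoms are in different chains OR their residue indices
    differ by at least ``min_seq_separation``, and the pair is not bonded
    (consecutive in a chain).  r0 is the reference distance.
    """
    if not cutoff > 0:
        raise ValidationError("cutoff must be > 0")
    s.validate()
    tree = cKDTree(s.coords)
    cand = tree.query_pairs(cutoff, output_type="ndarray")  # index pairs a < b
    bonded = set(_bonded_index_pairs(s, include_immobile_chains=True))
    keep_i, keep_j, keep_r = [], [], []
    for a, b in cand:
        a, b = int(a), int(b)
        if (a, b) in bonded:
            continue
        if s.chain_id[a] == s.chain_id[b] and \
                abs(int(s.residue_index[a]) - int(s.residue_index[b])) \
                < min_seq_separation:
            continue
        r = float(np.linalg.norm(s.coords[a] - s.coords[b]))
        ia, ja = int(s.atom_id[a]), int(s.atom_id[b])
        if ia > ja:
            ia, ja = ja, ia
        keep_i.append(ia)
        keep_j.append(ja)
        keep_r.append(r)
    order = np.lexsort((np.array(keep_j, dtype=np.int64),
                        np.array(keep_i, dtype=np.int64))) \
        if keep_i else np.array([], dtype=np.int64)
    return ContactMap(np.array(keep_i, dtype=np.int64)[order],
                      np.array(keep_j, dtype=np.int64)[order],
                      np.array(keep_r, dtype=np.float64)[order]).validate()


@dataclass
class StructurePotential:
    """A structure-based energy function over a fixed atom ordering.

    All index arrays refer to positions in ``atom_ids`` (i.e. array indices
    of the originating Structure), not raw atom ids.
    """

    atom_ids: np.ndarray           # (N,) original atom ids
    mobile: np.ndarray             # (N,) bool
    # bonds
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    k_bond: float
    # angles
    angle_i: np.ndarray
    angle_j: np.ndarray
    angle_k: np.ndarray
    angle_theta0: np.ndarray
    k_angle: float
    # dihedrals
    dih_i: np.ndarray
    dih_j: np.ndarray
    dih_k: np.ndarray
    dih_l: np.ndarray
    dih_phi0: np.ndarray
    k_dihedral: float
    # native contacts
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_form: str
    # excluded volume
    sigma: np.ndarray              # (N,) per-atom radius (nm)
    eps_ev: float
    # positional restraints
    restraint_idx: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64))
    restraint_x0: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    restraint_k: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_atoms(self) -> int:
        return int(self.atom_ids.shape[0])

    @property
    def n_contacts(self) -> int:
        return int(self.contact_i.shape[0])

    def with_restraints(self, restraints) -> "StructurePotential":
        """Copy with positional restraints (array index, point, k) appended."""
        idx = np.concatenate([self.restraint_idx,
                              np.array([r[0] for r in restraints], dtype=np.int64)])
        x0 = np.concatenate([self.restraint_x0.reshape(-1, 3),
                             np.array([r[1] for r in restraints],
                                      dtype=np.float64).reshape(-1, 3)])
        k = np.concatenate([self.restraint_k,
                            np.array([r[2] for r in restraints], dtype=np.float64)])
        return dataclasses.replace(self, restraint_idx=idx, restraint_x0=x0,
                                   restraint_k=k)

    def with_chain_sigma(self, s: Structure, chain_id: str,
                         sigma: float) -> "StructurePotential":
        """Copy with the excluded-volume radius of one chain's atoms changed."""
        new = np.array(self.sigma, copy=True)
        new[s.chain_mask(chain_id)] = sigma
        return dataclasses.replace(self, sigma=new)

    # --- exclusion bookkeeping -------------------------------------------

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Index pairs excluded from excluded-volume interactions:
        1-2 (bond), 1-3 (angle), 1-4 (dihedral) and native-contact pairs."""
        excl: set[tuple[int, int]] = set()

        def add(a, b):
            a, b = int(a), int(b)
            excl.add((a, b) if a < b else (b, a))

        for a, b in zip(self.bond_i, self.bond_j):
            add(a, b)
        for a, c in zip(self.angle_i, self.angle_k):
            add(a, c)
        for a, d in zip(self.dih_i, self.dih_l):
            add(a, d)
        for a, b in zip(self.contact_i, self.contact_j):
            add(a, b)
        return excl

    def ev_candidate_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All index pairs subject to excluded volume with at least one
        mobile atom, and their pair radii sigma_ij."""
        excl = self.excluded_pairs()
        n = self.n_atoms
        mob = np.flatnonzero(self.mobile)
        ii, jj = [], []
        seen: set[tuple[int, int]] = set()
        for a in mob:
            for b in range(n):
                if a == b:
                    continue
                p = (int(a), int(b)) if a < b else (int(b), int(a))
                if p in seen or p in excl:
                    continue
                seen.add(p)
                ii.append(p[0])
                jj.append(p[1])
        ii = np.array(ii, dtype=np.int64)
        jj = np.array(jj, dtype=np.int64)
        sig = 0.5 * (self.sigma[ii] + self.sigma[jj])
        return ii, jj, sig

    # --- serialization ----------------------------------------------------

    def to_json(self) -> str:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "StructurePotential":
        d = json.loads(text)
        kw = {}
        for f in dataclasses.fields(cls):
            v = d[f.name]
            if f.name in ("k_bond", "k_angle", "k_dihedral", "eps_ev"):
                kw[f.name] = float(v)
            elif f.name == "contact_form":
                kw[f.name] = str(v)
            elif f.name == "mobile":
                kw[f.name] = np.asarray(v, dtype=bool)
            elif f.name in ("atom_ids", "bond_i", "bond_j", "angle_i",
                            "angle_j", "angle_k", "dih_i", "dih_j", "dih_k",
                            "dih_l", "contact_i", "contact_j",
                            "restraint_idx"):
                kw[f.name] = np.asarray(v, dtype=np.int64)
            else:
                kw[f.name] = np.asarray(v, dtype=np.float64)
        kw["restraint_x0"] = kw["restraint_x0"].reshape(-1, 3)
        return cls(**kw)


def _angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_potential(s: Structure, cm: ContactMap,
                    params: ForceFieldParams | None = None,
                    rigid_chains: tuple[str, ...] = (),
                    ) -> StructurePotential:
    """Build the Go potential for a reference structure and its contact map.

    ``rigid_chains`` lists chain ids whose intra-chain contacts get the
    semi-rigid eps multiplier (``rigid_chain_contact_scale``).
    """
    params = params or ForceFieldParams()
    s.validate()
    cm.validate()

    id_to_idx = {int(a): k for k, a in enumerate(s.atom_id)}
    for a in np.concatenate([cm.i, cm.j]):
        if int(a) not in id_to_idx:
            raise ValidationError(f"contact references unknown atom id {int(a)}")

    bonds = _bonded_index_pairs(s)
    bond_i = np.array([a for a, _ in bonds], dtype=np.int64)
    bond_j = np.array([b for _, b in bonds], dtype=np.int64)
    bond_r0 = np.array([np.linalg.norm(s.coords[a] - s.coords[b])
                        for a, b in bonds], dtype=np.float64)

    ai, aj, ak, a0 = [], [], [], []
    di, dj, dk, dl, d0 = [], [], [], [], []
    for (a, b), (b2, c) in zip(bonds, bonds[1:]):
        if b != b2:
            continue
        ai.append(a)
        aj.append(b)
        ak.append(c)
        a0.append(_angle(s.coords[a], s.coords[b], s.coords[c]))
    for (a, b), (b2, c), (c2, d) in zip(bonds, bonds[1:], bonds[2:]):
        if b != b2 or c != c2:
            continue
        di.append(a)
        dj.append(b)
        dk.append(c)
        dl.append(d)
        d0.append(_dihedral(s.coords[a], s.coords[b], s.coords[c],
                            s.coords[d]))

    ci = np.array([id_to_idx[int(a)] for a in cm.i], dtype=np.int64)
    cj = np.array([id_to_idx[int(a)] for a in cm.j], dtype=np.int64)
    eps = np.full(cm.n_contacts, params.eps_contact, dtype=np.float64)
    for chain in rigid_chains:
        mask = s.chain_mask(chain)
        intra = mask[ci] & mask[cj]
        eps[intra] *= params.rigid_chain_contact_scale

    return StructurePotential(
        atom_ids=np.array(s.atom_id, copy=True),
        mobile=np.array(s.mobile, copy=True),
        bond_i=bond_i, bond_j=bond_j, bond_r0=bond_r0, k_bond=params.k_bond,
        angle_i=np.array(ai, dtype=np.int64),
        angle_j=np.array(aj, dtype=np.int64),
        angle_k=np.array(ak, dtype=np.int64),
        angle_theta0=np.array(a0, dtype=np.float64), k_angle=params.k_angle,
        dih_i=np.array(di, dtype=np.int64), dih_j=np.array(dj, dtype=np.int64),
        dih_k=np.array(dk, dtype=np.int64), dih_l=np.array(dl, dtype=np.int64),
        dih_phi0=np.array(d0, dtype=np.float64), k_dihedral=params.k_dihedral,
        contact_i=ci, contact_j=cj,
        contact_r0=np.array(cm.r0, copy=True), contact_eps=eps,
        contact_form=params.contact_form,
        sigma=np.full(s.n_atoms, params.sigma_ev, dtype=np.float64),
        eps_ev=params.eps_ev,
    )


def truncate_tail(s: Structure, chain_id: str,
                  n_terminal_residues: int) -> Structure:
    """Remove the first ``n_terminal_residues`` residues of one chain.

    Residue order follows the chain's atom order.  Surviving atoms keep
    their ids, names and coordinates untouched; removing every residue of
    the chain removes the chain.
    """
    s.validate()
    mask = s.chain_mask(chain_id)
    if not np.any(mask):
        raise ValidationError(f"unknown chain {chain_id!r}")
    res_in_chain: list[int] = []
    for r in s.residue_index[mask]:
        if not res_in_chain or res_in_chain[-1] != int(r):
            res_in_chain.append(int(r))
    if n_terminal_residues < 0 or n_terminal_residues > len(res_in_chain):
        raise ValidationError(
            f"cannot remove {n_terminal_residues} residues from a "
            f"{len(res_in_chain)}-residue chain")
    doomed = set(res_in_chain[:n_terminal_residues])
    keep = ~(mask & np.isin(s.residue_index, list(doomed) or [-1]))
    return s.subset(keep).validate()
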