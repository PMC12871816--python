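"""Contact maps, Go-potential construction, tail truncation."""

import numpy as np
import pytest

import tailgate as tg
from tailgate.forcefield import StructurePotential

from conftest import random_structure
from test_structure_io import make_structure


def brute_force_contacts(s: tg.Structure, cutoff: float, min_sep: int):
    """Independent O(N^2) oracle for the native-contact definition."""
    out = set()
    for a in range(s.n_atoms):
        for b in range(a + 1, s.n_atoms):
            bonded = (b == a + 1 and s.chain_id[a] == s.chain_id[b])
            if bonded:
                continue
            if s.chain_id[a] == s.chain_id[b] and \
                    abs(int(s.residue_index[a]) - int(s.residue_index[b])) \
                    < min_sep:
                continue
            if np.linalg.norm(s.coords[a] - s.coords[b]) <= cutoff:
                out.add((int(s.atom_id[a]), int(s.atom_id[b])))
    return out


class TestContactMap:
    def test_interchain_pair_within_cutoff(self):
        s = make_structure([[0.0, 0.0, 0.0], [0.35, 0.0, 0.0]],
                           chains=["A", "B"])
        cm = tg.compute_contact_map(s, cutoff=0.55, min_seq_separation=4)
        assert cm.n_contacts == 1
        assert (int(cm.i[0]), int(cm.j[0])) == (1, 2)
        assert cm.r0[0] == pytest.approx(0.35, abs=1e-12)

    def test_short_sequence_separation_excluded(self):
        s = make_structure([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                            [0.3, 0.0, 0.0]], chains=["A", "A", "A"])
        cm = tg.compute_contact_map(s, cutoff=0.55, min_seq_separation=4)
        assert cm.n_contacts == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n_atoms=50, n_chains=3, box=1.5)
        cm = tg.compute_contact_map(s, cutoff=0.55, min_seq_separation=4)
        assert cm.pairs() == brute_force_contacts(s, 0.55, 4)

    def test_entries_canonical_and_sorted(self):
        rng = np.random.default_rng(123)
        s = random_structure(rng, n_atoms=40, n_chains=2, box=1.2)
        cm = tg.compute_contact_map(s, 0.55, 4)
        assert np.all(cm.i < cm.j)
        order = np.lexsort((cm.j, cm.i))
        assert np.array_equal(order, np.arange(cm.n_contacts))

    def test_invalid_cutoff(self):
        s = make_structure([[0.0, 0.0, 0.0]])
        with pytest.raises(tg.ValidationError):
            tg.compute_contact_map(s, cutoff=-1.0)


class TestBuildPotential:
    def test_reference_energy_and_gradient(self, full_bundle, forcefield,
                                           full_system):
        pot = full_system.potential
        ev = tg.energy_forces(full_system, full_bundle.post_structure.coords)
        assert ev.energy == pytest.approx(
            -float(np.sum(pot.contact_eps)), abs=1e-9)
        assert np.max(np.abs(ev.forces[pot.mobile])) < 1e-8

    @pytest.mark.parametrize("form", ["12-6", "12-10"])
    def test_contact_well_shape(self, form):
        s = make_structure([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]],
                           chains=["A", "B"])
        cm = tg.compute_contact_map(s, 0.55, 4)
        pot = tg.build_potential(s, cm, tg.ForceFieldParams(contact_form=form))
        sys = tg.CompiledSystem(pot)

        def energy(r):
            c = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
            return tg.energy_forces(sys, c).energy

        assert energy(0.5) == pytest.approx(-1.0, abs=1e-12)
        e2 = energy(1.0)   # pulled to 2 r0
        assert -1.0 < e2 < 0.0
        assert abs(energy(50.0)) < 1e-6

    def test_unknown_contact_atom_rejected(self):
        s = make_structure([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]],
                           chains=["A", "B"])
        cm = tg.ContactMap(np.array([1]), np.array([99]), np.array([0.5]))
        with pytest.raises(tg.ValidationError, match="unknown atom"):
            tg.build_potential(s, cm, tg.ForceFieldParams())

    def test_rigid_chain_contact_scale(self):
        coords = [[0.0, 0.0, 0.0], [0.38, 0.0, 0.0], [0.0, 0.45, 0.0],
                  [0.38, 0.45, 0.0], [0.0, 0.9, 0.0]]
        s = make_structure(coords, chains=["A"] * 5)
        s.residue_index = np.array([1, 2, 6, 7, 12])  # far in sequence
        cm = tg.compute_contact_map(s, 0.55, 4)
        assert cm.n_contacts > 0
        pot = tg.build_potential(s, cm, tg.ForceFieldParams(),
                                 rigid_chains=("A",))
        np.testing.assert_allclose(pot.contact_eps, 3.0)

    def test_rigid_body_energy_invariance(self, full_bundle, forcefield):
        """Rigidly translating + rotating all coordinates leaves the
        energy of the structure-based terms unchanged (positional
        restraints, which pin to space, are deliberately absent here)."""
        post = full_bundle.post_structure
        cm = tg.compute_contact_map(post, forcefield.cutoff,
                                    forcefield.min_seq_separation)
        full_system = tg.CompiledSystem(
            tg.build_potential(post, cm, forcefield))
        coords = post.coords
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        e0 = tg.energy_forces(full_system, coords).energy
        e1 = tg.energy_forces(full_system, moved).energy
        assert abs(e1 - e0) < 1e-9

    def test_topology_json_roundtrip(self, full_system):
        pot = full_system.potential
        pot2 = StructurePotential.from_json(pot.to_json())
        assert np.array_equal(pot2.contact_i, pot.contact_i)
        np.testing.assert_array_equal(pot2.sigma, pot.sigma)
        np.testing.assert_array_equal(pot2.dih_phi0, pot.dih_phi0)
        assert pot2.contact_form == pot.contact_form


class TestTruncateTail:
    def test_zero_residues_is_identity(self, full_bundle):
        s = full_bundle.post_structure
        assert tg.truncate_tail(s, "T", 0) == s

    def test_full_tail_removal_matches_tailless_generator(
            self, full_bundle, truncated_bundle, geometry):
        cut = tg.truncate_tail(full_bundle.post_structure, "T",
                               geometry.tail_residues)
        assert cut == truncated_bundle.post_structure

    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_atom_count_oracle(self, full_bundle, n):
        s = full_bundle.post_structure
        mask = s.chain_mask("T")
        tail_res = s.residue_index[mask]
        removed = sum(1 for r in tail_res
                      if r in set(sorted(set(tail_res))[:n]))
        cut = tg.truncate_tail(s, "T", n)
        assert cut.n_atoms == s.n_atoms - removed
        survivors = np.isin(s.atom_id, cut.atom_id)
        assert np.array_equal(s.atom_id[survivors], cut.atom_id)

    def test_unknown_chain_rejected(self, full_bundle):
        with pytest.raises(tg.ValidationError, match="unknown chain"):
            tg.truncate_tail(full_bundle.post_structure, "Z", 1)

    def test_truncated_potential_is_term_subset(self, geometry, forcefield):
        """Building the potential from the truncated structure gives exactly
        the full-structure terms minus those touching removed atoms."""
        full = tg.make_translocation_system(geometry, True, 0).post_structure
        cut = tg.truncate_tail(full, "T", geometry.tail_residues)
        cm_full = tg.compute_contact_map(full, forcefield.cutoff,
                                         forcefield.min_seq_separation)
        cm_cut = tg.compute_contact_map(cut, forcefield.cutoff,
                                        forcefield.min_seq_separation)
        removed = set(full.atom_id[full.chain_mask("T")].tolist())
        expected = {p for p in cm_full.pairs()
                    if p[0] not in removed and p[1] not in removed}
        assert cm_cut.pairs() == expected

        pot_full = tg.build_potential(full, cm_full, forcefield)
        pot_cut = tg.build_potential(cut, cm_cut, forcefield)

        def term_ids(pot, s, *arrays):
            return {tuple(int(s.atom_id[pot_idx[k]]) for pot_idx in arrays)
                    for k in range(arrays[0].shape[0])}

        for arrays_full, arrays_cut in (
                ((pot_full.bond_i, pot_full.bond_j),
                 (pot_cut.bond_i, pot_cut.bond_j)),
                ((pot_full.angle_i, pot_full.angle_j, pot_full.angle_k),
                 (pot_cut.angle_i, pot_cut.angle_j, pot_cut.angle_k)),
                ((pot_full.dih_i, pot_full.dih_j, pot_full.dih_k,
                  pot_full.dih_l),
                 (pot_cut.dih_i, pot_cut.dih_j, pot_cut.dih_k,
                  pot_cut.dih_l))):
            ids_full = term_ids(pot_full, full, *arrays_full)
            ids_cut = term_ids(pot_cut, cut, *arrays_cut)
            kept = {t for t in ids_full if not (set(t) & removed)}
            assert ids_cut == kept
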