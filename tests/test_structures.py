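"""Structure parsing, contact-map construction and interfacial flexibility."""

import numpy as np
import pytest

import bindscape as bs
from bindscape.errors import ParseError, StructureError


class TestReadStructure:
    def test_hand_parsed_toy_pdb(self, toy_pdb_text):
        s = bs.read_structure(toy_pdb_text, mode="dimer")
        assert len(s.chains) == 2
        assert [c.chain_id for c in s.chains] == ["A", "B"]
        # coordinates equal the ATOM fields, converted angstrom -> nm
        np.testing.assert_allclose(
            s.chains[0].coords,
            [[0, 0, 0], [0.38, 0, 0], [0.38, 0.38, 0]], atol=1e-12)
        np.testing.assert_allclose(s.chains[1].coords[:, 2], 0.6)

    def test_no_ca_atoms_is_parse_error(self):
        with pytest.raises(ParseError):
            bs.read_structure("REMARK nothing here\nEND\n")

    def test_dimer_mode_rejects_three_chains(self, toy_pdb_text):
        third = toy_pdb_text.replace("END", "").replace("TER\n", "", 1)
        third += ("ATOM      7  CA  GLY C   1      10.000  10.000  10.000"
                  "  1.00  0.00           C\nEND\n")
        with pytest.raises(StructureError):
            bs.read_structure(third, mode="dimer")

    def test_unequal_chain_lengths_rejected(self, toy_pdb_text):
        # drop one residue from chain B
        lines = [ln for ln in toy_pdb_text.splitlines()
                 if not (ln.startswith("ATOM") and " B " in ln and "   3 " in ln)]
        with pytest.raises(StructureError):
            bs.read_structure("\n".join(lines), mode="dimer")

    def test_monomer_mode(self, toy_pdb_text):
        chain_a = toy_pdb_text.split("TER")[0] + "TER\nEND\n"
        s = bs.read_structure(chain_a, mode="monomer")
        assert len(s.chains) == 1

    def test_pdb_export_round_trip(self, toy_structure):
        from bindscape.io import to_pdb
        s2 = bs.read_structure(to_pdb(toy_structure), mode="dimer")
        np.testing.assert_allclose(s2.all_coords(),
                                   toy_structure.all_coords(), atol=1e-3)


class TestBuildContactMap:
    def test_out_of_range_pair_gives_empty_map(self):
        a = bs.Chain("A", [1], [[0.0, 0.0, 0.0]])
        b = bs.Chain("B", [1], [[1.2, 0.0, 0.0]])
        cmap = bs.build_contact_map(bs.DimerStructure(chains=(a, b)),
                                    cutoff=0.8)
        assert len(cmap) == 0

    def test_unit_square_matches_brute_force(self):
        # 4 beads of one chain on a square of side 0.5, cutoff just above
        # the side, min_seq_sep 2: brute force over all 6 pairs
        side = 0.5
        coords = np.array([[0, 0, 0], [side, 0, 0],
                           [side, side, 0], [0, side, 0]], dtype=float)
        chain = bs.Chain("A", np.arange(4), coords)
        s = bs.DimerStructure(chains=(chain,))
        cutoff, sep = 1.1 * side, 2
        cmap = bs.build_contact_map(s, cutoff=cutoff, min_seq_sep=sep)
        expected = set()
        for i in range(4):
            for j in range(i + 1, 4):
                if (j - i >= sep
                        and np.linalg.norm(coords[i] - coords[j]) <= cutoff):
                    expected.add((i, j))
        got = {(i, j) for i, j in zip(cmap.res_i, cmap.res_j)}
        assert got == expected == {(0, 3)}

    def test_interchain_pair_classified_inter(self):
        a = bs.Chain("A", np.arange(8), np.arange(24).reshape(8, 3) * 10.0)
        coords_b = np.arange(24).reshape(8, 3) * 10.0 + 500.0
        coords_b[7] = a.coords[3] + [0.5, 0, 0]  # res 3 of A near res 7 of B
        b = bs.Chain("B", np.arange(8), coords_b)
        cmap = bs.build_contact_map(bs.DimerStructure(chains=(a, b)),
                                    cutoff=0.8)
        inter = cmap.subset("inter")
        assert len(inter) == 1
        assert (inter.res_i[0], inter.res_j[0]) == (3, 7)
        assert inter.cls[0] == "inter"

    def test_classification_is_a_partition(self, toy_structure):
        cmap = bs.build_contact_map(toy_structure)
        assert set(np.unique(cmap.cls)) <= {"intra", "inter"}
        assert cmap.n_intra + cmap.n_inter == len(cmap)

    def test_homodimer_chain_symmetry(self, toy_structure):
        # intra contact sets of the two identical chains match as index sets
        cmap = bs.build_contact_map(toy_structure)
        s0 = {(i, j) for i, j in zip(cmap.intra_of_chain(0).res_i,
                                     cmap.intra_of_chain(0).res_j)}
        s1 = {(i, j) for i, j in zip(cmap.intra_of_chain(1).res_i,
                                     cmap.intra_of_chain(1).res_j)}
        assert s0 == s1 and len(s0) > 0

    def test_min_seq_sep_enforced(self, toy_structure):
        cmap = bs.build_contact_map(toy_structure, min_seq_sep=4)
        intra = cmap.subset("intra")
        assert np.all(np.abs(intra.res_i - intra.res_j) >= 4)


class TestInterfacialFlexibility:
    def _map(self, pairs, n_per=10, n_chains=2):
        ca, ri, cb, rj, cls = zip(*pairs)
        return bs.ContactMap(np.array(ca), np.array(ri), np.array(cb),
                             np.array(rj), np.full(len(pairs), 0.5),
                             np.array(cls, dtype="<U5"),
                             n_per_chain=n_per, n_chains=n_chains)

    def test_no_inter_contacts_gives_zero(self):
        cmap = self._map([(0, 0, 0, 5, "intra"), (1, 2, 1, 7, "intra")])
        assert bs.interfacial_flexibility(cmap).rho == 0.0

    def test_saturated_map_gives_one(self):
        pairs = [(c, r, c, r + 5, "intra") for c in range(2) for r in range(5)]
        pairs += [(0, r, 1, r, "inter") for r in range(10)]
        cmap = self._map(pairs)
        assert bs.interfacial_flexibility(cmap).rho == 1.0

    def test_two_of_ten_both_kinds(self):
        # 10-residue universe (2 chains of 5); exactly global residues
        # 2 (chain 0, res 2) and 7 (chain 1, res 2) have both contact kinds
        pairs = [(0, 0, 0, 2, "intra"), (1, 2, 1, 4, "intra"),
                 (0, 2, 1, 2, "inter")]
        cmap = self._map(pairs, n_per=5, n_chains=2)
        m = bs.interfacial_flexibility(cmap)
        assert m.n_both == 2
        assert m.rho == pytest.approx(2 / 10)

    def test_counts_partition_residues(self, toy_cmap):
        m = bs.interfacial_flexibility(toy_cmap)
        assert m.n_both + m.n_inter_only + m.n_intra_only <= m.n_residues
        assert m.rho == m.n_both / m.n_residues

    def test_empty_universe_is_error(self):
        cmap = self._map([(0, 0, 1, 0, "inter")])
        object.__setattr__(cmap, "n_per_chain", 0)
        with pytest.raises(StructureError):
            bs.interfacial_flexibility(cmap)


def test_duplicate_pairs_rejected():
    with pytest.raises(StructureError):
        bs.ContactMap(np.array([0, 1]), np.array([0, 0]), np.array([1, 0]),
                      np.array([0, 0]), np.array([0.5, 0.5]),
                      np.array(["inter", "inter"], dtype="<U5"),
                      n_per_chain=5, n_chains=2)
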