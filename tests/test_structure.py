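import numpy as np
import pytest

from isoscope.structure import (
    PDBParseError,
    inter_chain_contacts,
    load_structure,
    metal_coordination,
    variant_interface_table,
)


def make_pdb(atoms, models=1):
    """Minimal PDB text from (chain, res_id, res_name, atom_name, element, xyz)."""
    lines = []
    for m in range(1, models + 1):
        if models > 1:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for chain, res_id, res_name, atom_name, element, (x, y, z) in atoms:
            record = "HETATM" if element not in ("C", "N", "O", "S", "H") else "ATOM  "
            shift = 10.0 * (m - 1)
            lines.append(
                f"{record}{serial:5d} {atom_name:<4s}{res_name:>4s} {chain}{res_id:4d}    "
                f"{x + shift:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{element:>2s}"
            )
            serial += 1
        if models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


TOY_ATOMS = [
    ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
    ("A", 2, "GLY", "CA", "C", (10.0, 0.0, 0.0)),
    ("A", 3, "GLY", "CA", "C", (20.0, 0.0, 0.0)),
    ("B", 1, "ALA", "CA", "C", (0.0, 3.5, 0.0)),
    ("B", 2, "ALA", "CA", "C", (10.0, 40.0, 0.0)),
    ("B", 3, "ALA", "CA", "C", (20.0, 40.0, 0.0)),
]


class TestLoadStructure:
    def test_two_chains_three_residues(self):
        s = load_structure(make_pdb(TOY_ATOMS), structure_id="toy")
        assert s.n_chains == 2
        assert len(s.residues()) == 6

    def test_zn_element_retained(self):
        atoms = TOY_ATOMS + [("Z", 9, "ZN", "ZN", "ZN", (50.0, 50.0, 50.0))]
        s = load_structure(make_pdb(atoms))
        assert "ZN" in {e.upper() for e in s.atoms.element}

    def test_multi_model_selects_first(self):
        text = make_pdb(TOY_ATOMS, models=2)
        s = load_structure(text)
        assert s.atoms.coord[0, 0] == pytest.approx(0.0)
        all_models = load_structure(text, all_models=True)
        assert len(all_models) == 2
        assert all_models[1].atoms.coord[0, 0] == pytest.approx(10.0)

    def test_no_atoms_rejected(self):
        with pytest.raises(PDBParseError):
            load_structure("HEADER only\nEND\n")


class TestInterChainContacts:
    def test_pair_within_cutoff(self):
        s = load_structure(make_pdb(TOY_ATOMS), structure_id="toy")
        table = inter_chain_contacts(s, cutoff=4.0)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.chain_i, row.residue_i, row.chain_j, row.residue_j) == ("A", 1, "B", 1)
        assert row.min_distance == pytest.approx(3.5)

    def test_pair_beyond_cutoff(self):
        s = load_structure(make_pdb(TOY_ATOMS))
        assert inter_chain_contacts(s, cutoff=3.0).empty

    def test_single_chain_empty(self):
        s = load_structure(make_pdb(TOY_ATOMS[:3]))
        assert inter_chain_contacts(s).empty

    def test_hydrogens_ignored(self):
        atoms = TOY_ATOMS + [("B", 9, "GLY", "H", "H", (0.0, 1.0, 0.0))]
        s = load_structure(make_pdb(atoms))
        table = inter_chain_contacts(s, cutoff=4.0)
        assert 9 not in set(table.residue_j)

    def test_500_random_atoms_vs_brute_force(self, rng):
        """Exact set equality with an independent all-pairs O(n^2) oracle."""
        n = 500
        coords = rng.uniform(0, 60, size=(n, 3))
        chains = ["ABC"[i % 3] for i in range(n)]
        atoms = [
            (chains[i], i // 3 + 1, "GLY", "CA", "C", tuple(coords[i]))
            for i in range(n)
        ]
        s = load_structure(make_pdb(atoms))
        cutoff = 4.0
        table = inter_chain_contacts(s, cutoff=cutoff)
        got = {
            (r.chain_i, r.residue_i, r.chain_j, r.residue_j)
            for r in table.itertuples()
        }
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if chains[i] == chains[j]:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                    a = (chains[i], i // 3 + 1)
                    b = (chains[j], j // 3 + 1)
                    if (b[0], b[1]) < (a[0], a[1]):
                        a, b = b, a
                    expected.add((a[0], a[1], b[0], b[1]))
        assert got == expected

    def test_symmetry_and_cutoff_monotonicity(self, rng):
        coords = rng.uniform(0, 30, size=(60, 3))
        atoms = [
            ("AB"[i % 2], i // 2 + 1, "GLY", "CA", "C", tuple(coords[i]))
            for i in range(60)
        ]
        s = load_structure(make_pdb(atoms))
        small = inter_chain_contacts(s, cutoff=3.0)
        big = inter_chain_contacts(s, cutoff=5.0)
        key = lambda t: {(r.chain_i, r.residue_i, r.chain_j, r.residue_j) for r in t.itertuples()}
        assert key(small) <= key(big)
        for r in big.itertuples():
            assert (r.chain_i, r.residue_i) <= (r.chain_j, r.residue_j)


class TestMetalCoordination:
    def _zn_site(self, n_dist):
        atoms = [
            ("A", i, "HIS", "ND1", "N", (2.1 * dx, 2.1 * dy, 2.1 * dz))
            for i, (dx, dy, dz) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)], start=1)
        ]
        atoms = [
            (c, r, rn, an, el, (x * n_dist / 2.1, y * n_dist / 2.1, z * n_dist / 2.1))
            for c, r, rn, an, el, (x, y, z) in atoms
        ]
        atoms.append(("A", 9, "ZN", "ZN", "ZN", (0.0, 0.0, 0.0)))
        return load_structure(make_pdb(atoms))

    def test_three_histidines_at_2_1(self):
        table = metal_coordination(self._zn_site(2.1))
        assert sorted(table.residue_i) == [1, 2, 3]
        assert (table.kind == "metal-coordination").all()
        assert np.allclose(table.min_distance, 2.1, atol=1e-3)

    def test_nearest_at_3_2_empty(self):
        assert metal_coordination(self._zn_site(3.2)).empty

    def test_no_metal_empty(self):
        s = load_structure(make_pdb(TOY_ATOMS))
        assert metal_coordination(s).empty


class TestVariantInterfaceTable:
    def _contacts(self, sid, pairs):
        import pandas as pd

        from isoscope.structure import CONTACT_COLUMNS

        rows = [
            {
                "chain_i": a[0], "residue_i": a[1], "resname_i": "XXX",
                "chain_j": b[0], "residue_j": b[1], "resname_j": "XXX",
                "min_distance": 3.5, "kind": "interface", "structure_id": sid,
            }
            for a, b in pairs
        ]
        return pd.DataFrame(rows, columns=CONTACT_COLUMNS)

    def test_dimer_interface_variants_marked(self):
        # chain-local B24/B25 map to precursor 48/49
        contacts = self._contacts("s1", [(("B", 24), ("D", 24)), (("B", 25), ("D", 25))])
        numbering = {("B", 24): 48, ("B", 25): 49, ("D", 24): 48, ("D", 25): 49}
        table = variant_interface_table(
            [contacts], numbering, {48: "clinvar", 49: "gnomad"}
        )
        marked = table[table.warning == ""]
        assert list(marked.precursor_position) == [48, 49]
        assert (marked["s1"] == "x").all()

    def test_non_interface_variant_absent(self):
        contacts = self._contacts("s1", [(("B", 24), ("D", 24))])
        numbering = {("B", 24): 48, ("D", 24): 48}
        table = variant_interface_table([contacts], numbering, {48: "a", 99: "b"})
        assert 99 not in set(table.precursor_position)

    def test_per_structure_marks(self):
        c1 = self._contacts("s1", [(("B", 24), ("D", 24))])
        c2 = self._contacts("s2", [(("B", 25), ("D", 25))])
        numbering = {("B", 24): 48, ("D", 24): 48, ("B", 25): 49, ("D", 25): 49}
        table = variant_interface_table([c1, c2], numbering, {48: "v", 49: "v"})
        r48 = table[table.precursor_position == 48].iloc[0]
        assert r48["s1"] == "x" and r48["s2"] == ""
        r49 = table[table.precursor_position == 49].iloc[0]
        assert r49["s1"] == "" and r49["s2"] == "x"

    def test_unmapped_residue_warns_not_fails(self):
        contacts = self._contacts("s1", [(("B", 24), ("Z", 1))])
        numbering = {("B", 24): 48}
        table = variant_interface_table([contacts], numbering, {48: "v"})
        assert (table.warning == "unmapped_residue").any()
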