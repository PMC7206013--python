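"""Coordinate-model parsing and geometric QC on synthetic PDB fixtures.

All fixtures are synthetic coordinate files written by the tests; they
encode the geometric situations the checker must handle (alt-locs, waters,
chain gaps, a dyad around a scissile carbonyl), not any deposited model.
"""

from __future__ import annotations

import numpy as np
import pytest

from micromerge.geometry import (
    AtomSelector,
    atom_distance,
    chain_gaps,
    count_polymer_chains,
    dyad_distances,
    read_pdb,
)


def pdb_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, alt="", element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:<4s}{alt or ' '}{resname:<3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def residue_lines(serial, resname, chain, resnum, origin):
    x, y, z = origin
    lines = [
        pdb_line(serial, "N", resname, chain, resnum, x, y, z),
        pdb_line(serial + 1, "CA", resname, chain, resnum, x + 1.4, y, z, element="C"),
        pdb_line(serial + 2, "C", resname, chain, resnum, x + 2.4, y + 1.0, z),
        pdb_line(serial + 3, "O", resname, chain, resnum, x + 3.5, y + 1.0, z),
    ]
    return lines, serial + 4


@pytest.fixture
def simple_model(tmp_path):
    path = tmp_path / "synthetic_three_atoms.pdb"
    path.write_text(
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0)
        + pdb_line(2, "CA", "GLY", "A", 1, 3.0, 4.0, 0.0, element="C")
        + pdb_line(3, "C", "GLY", "A", 1, 1.0, 2.0, 2.0)
        + "END\n"
    )
    model, diags = read_pdb(path)
    assert diags == []
    return model


class TestReadPdb:
    def test_three_atom_fixture_exact_coordinates(self, simple_model):
        res = simple_model.chain("A").residues[1]
        assert res.atoms["N"].position().tolist() == [0.0, 0.0, 0.0]
        assert res.atoms["CA"].position().tolist() == [3.0, 4.0, 0.0]
        assert res.atoms["C"].position().tolist() == [1.0, 2.0, 2.0]

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "synthetic_altloc.pdb"
        path.write_text(
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.6, alt="A", element="C")
            + pdb_line(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.4, alt="B", element="C")
            + "END\n"
        )
        model, _ = read_pdb(path)
        atom = model.chain("A").residues[1].atoms["CA"]
        assert atom.alt_loc == "A"
        assert atom.position().tolist() == [0.0, 0.0, 0.0]

    def test_altloc_tie_prefers_a(self, tmp_path):
        path = tmp_path / "synthetic_altloc_tie.pdb"
        path.write_text(
            pdb_line(1, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.5, alt="B", element="C")
            + pdb_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.5, alt="A", element="C")
            + "END\n"
        )
        model, _ = read_pdb(path)
        assert model.chain("A").residues[1].atoms["CA"].alt_loc == "A"

    def test_malformed_record_diagnosed(self, tmp_path):
        path = tmp_path / "synthetic_bad.pdb"
        good = pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C")
        bad = good[:30] + "  xx.xxx" + good[38:]
        path.write_text(good + bad + "END\n")
        model, diags = read_pdb(path)
        assert len(diags) == 1 and "line 2" in diags[0]

    def test_empty_model_fails(self, tmp_path):
        path = tmp_path / "synthetic_empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(path)


class TestChainCounting:
    def test_waters_not_counted_as_polymer(self, tmp_path):
        lines = []
        serial = 1
        for i in range(1, 26):
            ls, serial = residue_lines(serial, "ALA", "A", i, (float(i), 0.0, 0.0))
            lines += ls
        for i in range(1, 31):
            lines.append(pdb_line(serial, "O", "HOH", "W", i, 50.0 + i, 0.0, 0.0))
            serial += 1
        path = tmp_path / "synthetic_protein_waters.pdb"
        path.write_text("".join(lines) + "END\n")
        model, _ = read_pdb(path)
        assert count_polymer_chains(model, min_residues=20) == 1

    def test_two_protein_chains(self, tmp_path):
        lines = []
        serial = 1
        for chain in ("A", "B"):
            for i in range(1, 26):
                ls, serial = residue_lines(serial, "GLY", chain, i, (float(i), 10.0, 0.0))
                lines += ls
        path = tmp_path / "synthetic_dimer.pdb"
        path.write_text("".join(lines) + "END\n")
        model, _ = read_pdb(path)
        assert count_polymer_chains(model) == 2


class TestDistances:
    def test_identical_atom_zero(self, simple_model):
        sel = AtomSelector("A", 1, "CA")
        assert atom_distance(simple_model, sel, sel) == 0.0

    def test_three_four_five(self, simple_model):
        d = atom_distance(simple_model, AtomSelector("A", 1, "N"), AtomSelector("A", 1, "CA"))
        assert d == pytest.approx(5.0)

    def test_triangle_inequality(self, simple_model):
        a, b, c = (AtomSelector("A", 1, n) for n in ("N", "CA", "C"))
        dab = atom_distance(simple_model, a, b)
        dbc = atom_distance(simple_model, b, c)
        dac = atom_distance(simple_model, a, c)
        assert dac <= dab + dbc + 1e-12

    def test_unresolved_selection_names_selector(self, simple_model):
        with pytest.raises(KeyError, match="A/9/XX"):
            atom_distance(
                simple_model, AtomSelector("A", 1, "N"), AtomSelector("A", 9, "XX")
            )


class TestChainGaps:
    def make_chain(self, tmp_path, numbers):
        lines = []
        serial = 1
        for i in numbers:
            ls, serial = residue_lines(serial, "ALA", "A", i, (float(i), 0.0, 0.0))
            lines += ls
        path = tmp_path / "synthetic_gaps.pdb"
        path.write_text("".join(lines) + "END\n")
        model, _ = read_pdb(path)
        return model

    def test_single_gap(self, tmp_path):
        model = self.make_chain(tmp_path, [1, 2, 3, 7, 8, 9, 10])
        assert chain_gaps(model, "A") == [(4, 6)]

    def test_contiguous_chain_has_no_gaps(self, tmp_path):
        model = self.make_chain(tmp_path, list(range(1, 11)))
        assert chain_gaps(model, "A") == []

    def test_gaps_sorted_disjoint_within_span(self, tmp_path):
        numbers = [1, 2, 5, 6, 10, 15]
        model = self.make_chain(tmp_path, numbers)
        gaps = chain_gaps(model, "A")
        assert gaps == [(3, 4), (7, 9), (11, 14)]
        flat = [x for g in gaps for x in g]
        assert flat == sorted(flat)
        for lo, hi in gaps:
            assert numbers[0] < lo <= hi < numbers[-1]


class TestDyadGeometry:
    def test_dyad_candidates_on_synthetic_active_site(self, tmp_path):
        """A synthetic zymogen-like site: His NE2 and Cys SG equidistant
        (3.2 Å) from the scissile lysine's carbonyl carbon."""
        lines = []
        serial = 1
        # His 86 with NE2 at distance 3.2 from target carbonyl at origin
        ls, serial = residue_lines(serial, "HIS", "A", 86, (10.0, 0.0, 0.0))
        lines += ls
        lines.append(pdb_line(serial, "NE2", "HIS", "A", 86, 3.2, 0.0, 0.0, element="N"))
        serial += 1
        # Cys 139 with SG at 3.2 on the other side
        ls, serial = residue_lines(serial, "CYS", "A", 139, (-10.0, 0.0, 0.0))
        lines += ls
        lines.append(pdb_line(serial, "SG", "CYS", "A", 139, -3.2, 0.0, 0.0, element="S"))
        serial += 1
        # Lys 225 whose carbonyl carbon sits at the origin
        lines.append(pdb_line(serial, "N", "LYS", "A", 225, 0.0, 2.0, 0.0))
        lines.append(pdb_line(serial + 1, "CA", "LYS", "A", 225, 0.0, 1.0, 0.0, element="C"))
        lines.append(pdb_line(serial + 2, "C", "LYS", "A", 225, 0.0, 0.0, 0.0))
        path = tmp_path / "synthetic_active_site.pdb"
        path.write_text("".join(lines) + "END\n")
        model, _ = read_pdb(path)
        dists = dyad_distances(model, "A")
        assert dists["His86.NE2"] == pytest.approx(3.2)
        assert dists["Cys139.SG"] == pytest.approx(3.2)

    def test_cys_to_ala_mutant_uses_cb(self, tmp_path):
        lines = []
        serial = 1
        ls, serial = residue_lines(serial, "ALA", "A", 139, (5.0, 0.0, 0.0))
        lines += ls
        lines.append(pdb_line(serial, "CB", "ALA", "A", 139, 3.5, 0.0, 0.0, element="C"))
        serial += 1
        lines.append(pdb_line(serial, "C", "LYS", "A", 225, 0.0, 0.0, 0.0))
        path = tmp_path / "synthetic_mutant_site.pdb"
        path.write_text("".join(lines) + "END\n")
        model, _ = read_pdb(path)
        dists = dyad_distances(model, "A")
        assert dists["Ala139.CB"] == pytest.approx(3.5)
        assert "His86.NE2" not in dists
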