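"""Unit cells, operator algebra, ASU mapping and systematic absences.

gemmi provides the independent oracle: its operator tables, absence rules
and d-spacing formula were written without reference to this package.
"""

from __future__ import annotations

import gemmi
import numpy as np
import pytest

from micromerge.symmetry import BUILTIN_SPACE_GROUPS, SpaceGroup, UnitCell, parse_triplet

GEMMI_NAMES = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "C2": "C 1 2 1",
    "P212121": "P 21 21 21",
    "P43212": "P 43 21 2",
}


def hkl_grid(limit: int) -> np.ndarray:
    r = np.arange(-limit, limit + 1)
    h, k, l = np.meshgrid(r, r, r, indexing="ij")
    grid = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    return grid[~np.all(grid == 0, axis=1)]


class TestUnitCell:
    def test_orthogonal_d_spacings_closed_form(self):
        assert UnitCell(10, 10, 10).d_spacing((1, 0, 0)) == pytest.approx(10.0)
        assert UnitCell(10, 20, 30).d_spacing((0, 2, 0)) == pytest.approx(10.0)
        assert UnitCell(10, 20, 30).d_spacing((1, 2, 3)) == pytest.approx(
            (1 / 100 + 4 / 400 + 9 / 900) ** -0.5
        )

    @pytest.mark.parametrize(
        "cell",
        [
            (10, 10, 10, 90, 90, 120),
            (23.3, 31.1, 17.9, 83.0, 100.5, 95.0),
            (50, 60, 70, 90, 90, 90),
        ],
    )
    def test_d_spacing_matches_gemmi(self, cell):
        mine = UnitCell(*cell)
        ref = gemmi.UnitCell(*cell)
        for hkl in [(1, 1, 0), (2, -1, 3), (0, 0, 5), (-3, 2, -1)]:
            assert mine.d_spacing(hkl) == pytest.approx(ref.calculate_d(hkl), rel=1e-12)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 10, 10)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 0, 90, 90)
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 1, 1, 178)  # degenerate volume

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10).d_spacing((0, 0, 0))


class TestOperators:
    @pytest.mark.parametrize("symbol", BUILTIN_SPACE_GROUPS)
    def test_builtin_operator_sets_match_gemmi(self, symbol):
        sg = SpaceGroup(symbol)
        ref = gemmi.SpaceGroup(GEMMI_NAMES[symbol])
        ref_ops = set()
        for op in ref.operations():
            rot = tuple(tuple(r // 24 for r in row) for row in op.rot)
            tran = tuple((t % 24) / 24 for t in op.tran)
            ref_ops.add((rot, tran))
        mine = {
            (
                tuple(tuple(int(x) for x in row) for row in op.rot),
                tuple(float(t) for t in op.trans),
            )
            for op in sg.ops
        }
        assert mine == ref_ops

    def test_triplet_parser_roundtrip(self):
        op = parse_triplet("-y+1/2, x+1/2, z+3/4")
        assert str(parse_triplet(str(op))) == str(op)

    def test_non_closed_operator_list_rejected(self):
        with pytest.raises(ValueError, match="closed"):
            SpaceGroup("broken", ops=["x,y,z", "-x,y+1/2,-z", "-x,-y,-z"])


class TestAsuMapping:
    def test_friedel_mates_share_canonical_in_p1(self):
        sg = SpaceGroup("P1", friedel_merged=True)
        c1, s1 = sg.map_to_asu((1, 2, 3))
        c2, s2 = sg.map_to_asu((-1, -2, -3))
        assert c1 == c2 == (1, 2, 3)
        assert (s1, s2) == (1, -1)

    def test_twofold_equivalents_in_p212121(self, p212121):
        c1, _ = p212121.map_to_asu((3, 4, 5))
        c2, _ = p212121.map_to_asu((-3, -4, 5))
        assert c1 == c2

    def test_idempotent(self, p212121):
        rng = np.random.default_rng(0)
        hkl = rng.integers(-6, 7, size=(200, 3))
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        canon, _ = p212121.map_to_asu_array(hkl)
        canon2, sign2 = p212121.map_to_asu_array(canon)
        assert np.array_equal(canon, canon2)
        assert np.all(sign2 == 1)

    @pytest.mark.parametrize("symbol", ["P21", "C2", "P43212"])
    def test_partition_sizes_match_brute_force_orbits(self, symbol):
        """Orbit partition agrees with explicit operator application."""
        sg = SpaceGroup(symbol, friedel_merged=True)
        ref = gemmi.SpaceGroup(GEMMI_NAMES[symbol]).operations()
        grid = hkl_grid(3)
        canon, _ = sg.map_to_asu_array(grid)
        mine_partition = {}
        for hkl, c in zip(map(tuple, grid), map(tuple, canon)):
            mine_partition.setdefault(c, set()).add(hkl)
        # brute force orbits via gemmi operators
        orbit_of = {}
        for hkl in map(tuple, grid):
            orbit = set()
            for op in ref:
                eq = tuple(op.apply_to_hkl(list(hkl)))
                orbit.add(eq)
                orbit.add(tuple(-x for x in eq))
            orbit_of[hkl] = frozenset(orbit)
        brute_partition = {}
        for hkl, orbit in orbit_of.items():
            brute_partition.setdefault(orbit, set()).add(hkl)
        assert sorted(len(v) for v in mine_partition.values()) == sorted(
            len(v) for v in brute_partition.values()
        )
        assert len(mine_partition) == len(brute_partition)

    def test_resolution_invariant_over_orbit(self, p212121):
        cell = UnitCell(21.0, 33.0, 47.0)
        for hkl in [(1, 2, 3), (4, 0, 1), (2, 5, -3)]:
            d0 = cell.d_spacing(hkl)
            for eq in p212121.equivalents(hkl, include_friedel=True):
                assert cell.d_spacing(eq) == pytest.approx(d0, rel=1e-12)


class TestAbsences:
    def test_p21_screw_axis_rule(self):
        sg = SpaceGroup("P21")
        assert sg.is_absent((0, 1, 0))
        assert not sg.is_absent((0, 2, 0))
        assert not sg.is_absent((1, 1, 0))

    def test_p1_has_no_absences(self):
        sg = SpaceGroup("P1")
        assert not sg.absent_array(hkl_grid(3)).any()

    def test_p212121_axial_rule(self, p212121):
        # odd axial reflections absent on all three screw axes
        for axis in range(3):
            odd = [0, 0, 0]
            odd[axis] = 3
            even = [0, 0, 0]
            even[axis] = 4
            assert p212121.is_absent(odd)
            assert not p212121.is_absent(even)

    @pytest.mark.parametrize("symbol", BUILTIN_SPACE_GROUPS)
    def test_absences_match_gemmi_oracle(self, symbol):
        """Operator-based flags agree with gemmi on every |h|,|k|,|l| <= 4."""
        sg = SpaceGroup(symbol)
        ref = gemmi.SpaceGroup(GEMMI_NAMES[symbol]).operations()
        grid = hkl_grid(4)
        mine = sg.absent_array(grid)
        theirs = np.array([ref.is_systematically_absent(list(hkl)) for hkl in grid])
        assert np.array_equal(mine, theirs)
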