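"""Unit cells, space-group symmetry, and reflection bookkeeping.

Intensities from symmetry-equivalent reflections (and Friedel mates, when
anomalous differences are not of interest) must be merged together.  This
module supplies the minimal symmetry machinery the pipeline needs: metric
tensors and d-spacings, operator algebra, mapping of Miller indices to a
canonical asymmetric-unit representative, and systematic-absence flags.

The canonical representative of an orbit is its lexicographically largest
member, over all rotational equivalents (plus Friedel mates when merged).
This avoids per-space-group asymmetric-unit boundary tables and is trivially
deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroup",
    "parse_triplet",
    "BUILTIN_SPACE_GROUPS",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.volume() <= 0:
            raise ValueError("cell parameters give non-positive volume")

    def parameters(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.c, self.alpha, self.beta, self.gamma], dtype=float
        )

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return float(self.a * self.b * self.c * np.sqrt(arg))

    def d_spacing(self, hkl: np.ndarray | Sequence[int]) -> np.ndarray | float:
        """Resolution d (Å) of one reflection or an (N, 3) array of them.

        Uses 1/d² = hᵀ G* h; for orthogonal cells this reduces to the
        familiar 1/d² = h²/a² + k²/b² + l²/c².
        """
        h = np.asarray(hkl, dtype=float)
        scalar = h.ndim == 1
        h = np.atleast_2d(h)
        if np.any(np.all(h == 0, axis=1)):
            raise ValueError("d-spacing undefined for the (0,0,0) index")
        gstar = self.reciprocal_metric_tensor()
        inv_d2 = np.einsum("ni,ij,nj->n", h, gstar, h)
        d = 1.0 / np.sqrt(inv_d2)
        return float(d[0]) if scalar else d


_TERM_RE = re.compile(r"([+-]?)\s*(?:(\d+)/(\d+)|(\d+(?:\.\d+)?)|([xyz]))")


def _parse_component(expr: str) -> tuple[np.ndarray, Fraction]:
    row = np.zeros(3, dtype=int)
    trans = Fraction(0)
    pos = 0
    expr = expr.strip()
    while pos < len(expr):
        m = _TERM_RE.match(expr, pos)
        if m is None:
            raise ValueError(f"cannot parse symmetry term at {expr[pos:]!r}")
        sign = -1 if m.group(1) == "-" else 1
        if m.group(5):
            row["xyz".index(m.group(5))] += sign
        elif m.group(2):
            trans += sign * Fraction(int(m.group(2)), int(m.group(3)))
        else:
            trans += sign * Fraction(m.group(4)).limit_denominator(24)
        pos = m.end()
    return row, trans % 1


def parse_triplet(triplet: str) -> "SymOp":
    """Parse an operator triplet such as ``-x, y+1/2, -z`` into a SymOp."""
    parts = triplet.split(",")
    if len(parts) != 3:
        raise ValueError(f"triplet must have three components: {triplet!r}")
    rows, trans = zip(*(_parse_component(p) for p in parts))
    return SymOp(np.array(rows, dtype=int), tuple(trans))


@dataclass(frozen=True)
class SymOp:
    """One space-group operation: integer rotation matrix + fractional shift."""

    rot: np.ndarray
    trans: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", np.asarray(self.rot, dtype=int))
        object.__setattr__(self, "trans", tuple(Fraction(t) % 1 for t in self.trans))
        if self.rot.shape != (3, 3):
            raise ValueError("rotation part must be 3x3")
        if abs(int(round(np.linalg.det(self.rot)))) != 1:
            raise ValueError("rotation part must have determinant ±1")

    def key(self) -> tuple:
        return (tuple(self.rot.ravel().tolist()), self.trans)

    def compose(self, other: "SymOp") -> "SymOp":
        rot = self.rot @ other.rot
        trans = tuple(
            (sum(Fraction(int(self.rot[i, j])) * other.trans[j] for j in range(3)) + self.trans[i]) % 1
            for i in range(3)
        )
        return SymOp(rot, trans)  # type: ignore[arg-type]

    def __str__(self) -> str:
        comps = []
        for i in range(3):
            s = ""
            for j, ax in enumerate("xyz"):
                v = int(self.rot[i, j])
                if v:
                    s += ("+" if v > 0 and s else "-" if v < 0 else "") + ax
            t = self.trans[i]
            if t:
                s += f"+{t}"
            comps.append(s or "0")
        return ",".join(comps)


_BUILTIN_TRIPLETS: dict[str, list[str]] = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "C2": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P212121": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
    "P43212": [
        "x,y,z",
        "-x,-y,z+1/2",
        "-y+1/2,x+1/2,z+3/4",
        "y+1/2,-x+1/2,z+1/4",
        "-x+1/2,y+1/2,-z+3/4",
        "x+1/2,-y+1/2,-z+1/4",
        "y,x,-z",
        "-y,-x,-z+1/2",
    ],
}

# Which of (a, b, c, alpha, beta, gamma) the lattice leaves free, per system.
_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "P1": ("a", "b", "c", "alpha", "beta", "gamma"),
    "P21": ("a", "b", "c", "beta"),
    "C2": ("a", "b", "c", "beta"),
    "P212121": ("a", "b", "c"),
    "P43212": ("a", "c"),
}


def _normalize_symbol(symbol: str) -> str:
    s = symbol.replace(" ", "")
    for sub, plain in zip("₀₁₂₃₄₅₆₇₈₉", "0123456789"):
        s = s.replace(sub, plain)
    return s.upper().replace("P2(1)", "P21")


class SpaceGroup:
    """A space group given by an explicit operator list.

    Built-in symbols cover the low-symmetry groups protein crystals commonly
    adopt (P1, P2₁, C2, P2₁2₁2₁, P4₃2₁2); any other group may be supplied as
    an operator-triplet list.  ``friedel_merged`` controls whether Friedel
    mates share a canonical index (on by default; switched off for anomalous
    work).
    """

    def __init__(
        self,
        symbol: str,
        ops: Iterable[SymOp] | Iterable[str] | None = None,
        friedel_merged: bool = True,
    ) -> None:
        self.symbol = symbol
        self.friedel_merged = friedel_merged
        if ops is None:
            key = _normalize_symbol(symbol)
            if key not in _BUILTIN_TRIPLETS:
                raise ValueError(
                    f"unknown space group {symbol!r}; supply explicit operators "
                    f"(built-ins: {sorted(_BUILTIN_TRIPLETS)})"
                )
            ops = _BUILTIN_TRIPLETS[key]
        parsed = [op if isinstance(op, SymOp) else parse_triplet(op) for op in ops]
        self.ops: list[SymOp] = parsed
        self._validate_group()
        # (n_ops, 3, 3) stack of rotations and (n_ops, 3) float translations
        self._rots = np.stack([op.rot for op in self.ops])
        self._trans = np.array([[float(t) for t in op.trans] for op in self.ops])

    # -- group-theoretic sanity ------------------------------------------------
    def _validate_group(self) -> None:
        keys = {op.key() for op in self.ops}
        if len(keys) != len(self.ops):
            raise ValueError("duplicate operators in space group")
        identity = SymOp(np.eye(3, dtype=int), (Fraction(0),) * 3)
        if identity.key() not in keys:
            raise ValueError("identity operator missing")
        for a in self.ops:
            for b in self.ops:
                if a.compose(b).key() not in keys:
                    raise ValueError(
                        f"operators not closed under composition: {a} ∘ {b}"
                    )

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    def free_cell_parameters(self) -> tuple[str, ...]:
        key = _normalize_symbol(self.symbol)
        return _FREE_PARAMS.get(key, ("a", "b", "c", "alpha", "beta", "gamma"))

    # -- reflection algebra ----------------------------------------------------
    def equivalents(self, hkl: Sequence[int], include_friedel: bool | None = None) -> set[tuple[int, int, int]]:
        """All rotational equivalents of ``hkl`` (± Friedel mates)."""
        if include_friedel is None:
            include_friedel = self.friedel_merged
        h = np.asarray(hkl, dtype=int)
        eq = {tuple(int(x) for x in h @ op.rot) for op in self.ops}
        if include_friedel:
            eq |= {(-a, -b, -c) for (a, b, c) in eq}
        return eq

    def map_to_asu(self, hkl: Sequence[int]) -> tuple[tuple[int, int, int], int]:
        """Canonical index and Friedel sign of one reflection."""
        canon, sign = self.map_to_asu_array(np.asarray(hkl, dtype=int)[None, :])
        return tuple(int(x) for x in canon[0]), int(sign[0])

    def map_to_asu_array(self, hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized ASU mapping.

        Returns ``(canonical, sign)`` where canonical is the lexicographically
        largest member of each orbit (over rotational equivalents, plus
        Friedel mates when ``friedel_merged``), and sign is +1 when the input
        belongs to the same Friedel class as its canonical representative,
        −1 otherwise (always +1 for centric reflections and when not merging
        Friedel mates).
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("(0,0,0) has no asymmetric-unit representative")
        # (n_ops, N, 3): h' = h R per operator
        direct = np.einsum("nj,oji->oni", hkl, self._rots)
        if self.friedel_merged:
            candidates = np.concatenate([direct, -direct], axis=0)
        else:
            candidates = direct
        cmax = int(np.abs(candidates).max())
        base = 2 * cmax + 1
        enc = (
            (candidates[..., 0] + cmax) * base * base
            + (candidates[..., 1] + cmax) * base
            + (candidates[..., 2] + cmax)
        )
        best = np.argmax(enc, axis=0)
        canon = candidates[best, np.arange(hkl.shape[0])]
        if self.friedel_merged:
            # centric orbits contain the canonical index in both classes;
            # report +1 there so the sign is deterministic
            direct_enc = enc[: self.n_ops]
            canon_enc = np.take_along_axis(enc, best[None, :], axis=0)[0]
            sign = np.where((direct_enc == canon_enc).any(axis=0), 1, -1)
        else:
            sign = np.ones(hkl.shape[0], dtype=int)
        return canon, sign.astype(int)

    def is_absent(self, hkl: Sequence[int]) -> bool:
        return bool(self.absent_array(np.asarray(hkl, dtype=int)[None, :])[0])

    def absent_array(self, hkl: np.ndarray) -> np.ndarray:
        """Systematic-absence flags: some operator fixes h (hR = h) while
        h·t is non-integral, so the structure factor vanishes identically."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        absent = np.zeros(hkl.shape[0], dtype=bool)
        for rot, trans in zip(self._rots, self._trans):
            if not trans.any():
                continue
            fixed = np.all(hkl @ rot == hkl, axis=1)
            phase = hkl @ trans
            noninteg = ~np.isclose(phase - np.round(phase), 0.0, atol=1e-9)
            absent |= fixed & noninteg
        return absent

    def __repr__(self) -> str:
        return f"SpaceGroup({self.symbol!r}, n_ops={self.n_ops}, friedel_merged={self.friedel_merged})"


BUILTIN_SPACE_GROUPS = tuple(_BUILTIN_TRIPLETS)
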