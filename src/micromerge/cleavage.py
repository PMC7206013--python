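"""In-silico protease digestion and fragment mass inventories.

The metacaspase studied here cleaves C-terminal to lysine or arginine; its
known self-cleavage sites sit in the inter-domain linker (Lys225 first, then
Arg180/Arg190/Lys210 in the linker's N-terminal half and Lys237/Lys267 in
its C-terminal half).  Its substrate Propep1 (92 residues) is cut at Arg69
to release the Pep1 elicitor, and at Arg6/Arg7 under high calcium.
Chymotryptic sub-digestion (after Phe/Tyr/Trp) is used when mapping sites by
mass spectrometry.  This module turns a sequence plus a cleavage rule into
an exact fragment tiling with average and monoisotopic masses.

Residue numbering is 1-based inclusive throughout, matching how sites are
named (Lys225 means the bond after residue 225 is cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "CleavageRule",
    "Fragment",
    "FragmentSet",
    "digest",
    "fragment_mass",
    "propep1_products",
    "read_fasta",
    "METACASPASE_RULE",
    "CHYMOTRYPSIN_RULE",
    "synthetic_atmc4_sequence",
    "synthetic_propep1_sequence",
]

# residue_masses v1: standard amino-acid residue masses (Da)
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.01528
WATER_MONOISOTOPIC = 18.0105646863

_ALPHABET = set(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter protein sequence with an optional numbering offset.

    Residue i (1-based, after the offset) is ``sequence[i - 1 - offset]``.
    """

    id: str
    sequence: str
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"non-standard residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, number: int) -> str:
        idx = number - 1 - self.offset
        if not 0 <= idx < len(self.sequence):
            raise IndexError(f"residue {number} outside {self.id!r}")
        return self.sequence[idx]


@dataclass(frozen=True)
class CleavageRule:
    """Either an explicit site list or a cut-after residue class.

    ``sites``: residue numbers whose C-terminal peptide bond is cut.
    ``residues``: cut after every occurrence of these residue types.
    Exactly one of the two must be given.
    """

    name: str
    sites: tuple[int, ...] = ()
    residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if bool(self.sites) == bool(self.residues):
            raise ValueError("give either explicit sites or a residue class, not both/neither")
        object.__setattr__(self, "sites", tuple(sorted(set(self.sites))))
        object.__setattr__(self, "residues", frozenset(r.upper() for r in self.residues))
        if self.residues - _ALPHABET:
            raise ValueError(f"unknown residues in class rule: {self.residues - _ALPHABET}")

    def cut_positions(self, seq: ProteinSequence) -> list[int]:
        """Residue numbers after which the chain is cut (internal cuts only)."""
        n = len(seq)
        last = seq.offset + n
        if self.sites:
            for s in self.sites:
                if not seq.offset + 1 <= s <= last:
                    raise ValueError(f"cleavage site {s} outside {seq.id!r}")
            return [s for s in self.sites if s < last]
        return [
            seq.offset + i + 1
            for i, r in enumerate(seq.sequence[:-1])  # terminal residue: no trailing cut
            if r in self.residues
        ]


METACASPASE_RULE = CleavageRule(name="metacaspase-K/R", residues=frozenset("KR"))
CHYMOTRYPSIN_RULE = CleavageRule(name="chymotrypsin-F/Y/W", residues=frozenset("FYW"))


@dataclass(frozen=True)
class Fragment:
    start: int            # 1-based inclusive, in parent numbering
    end: int
    sequence: str
    average_mass: float
    monoisotopic_mass: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FragmentSet:
    parent_id: str
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        frs = self.fragments
        for a, b in zip(frs, frs[1:]):
            if b.start != a.end + 1:
                raise ValueError(f"fragments do not tile the parent: gap after {a.end}")

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]

    def spans(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.fragments]


def fragment_mass(sequence: str) -> tuple[float, float]:
    """(average, monoisotopic) mass in Da: residue masses plus one water."""
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    avg = sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVERAGE
    mono = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in seq) + WATER_MONOISOTOPIC
    return avg, mono


def _make_fragment(seq: ProteinSequence, start: int, end: int) -> Fragment:
    sub = seq.sequence[start - 1 - seq.offset : end - seq.offset]
    avg, mono = fragment_mass(sub)
    return Fragment(start=start, end=end, sequence=sub, average_mass=avg, monoisotopic_mass=mono)


def digest(seq: ProteinSequence, rule: CleavageRule) -> FragmentSet:
    """Cut C-terminal to each matching position; fragments tile the parent."""
    cuts = rule.cut_positions(seq)
    first = seq.offset + 1
    last = seq.offset + len(seq)
    bounds = [first - 1] + cuts + [last]
    frags = tuple(
        _make_fragment(seq, lo + 1, hi) for lo, hi in zip(bounds, bounds[1:]) if hi > lo
    )
    return FragmentSet(parent_id=seq.id, fragments=frags)


def missed_cleavage_fragments(
    seq: ProteinSequence, rule: CleavageRule, max_missed: int = 1
) -> list[Fragment]:
    """All fragments with up to ``max_missed`` internal missed cleavages.

    These are the peptide-search candidates; unlike :func:`digest` they do
    not tile the parent.
    """
    cuts = rule.cut_positions(seq)
    bounds = [seq.offset] + cuts + [seq.offset + len(seq)]
    frags = []
    for i in range(len(bounds) - 1):
        for miss in range(max_missed + 1):
            j = i + 1 + miss
            if j >= len(bounds):
                break
            frags.append(_make_fragment(seq, bounds[i] + 1, bounds[j]))
    return frags


def propep1_products(
    seq: ProteinSequence,
    calcium_level: str = "low",
    high_sites: Sequence[int] = (6, 7),
    primary_site: int = 69,
) -> FragmentSet:
    """Calcium-dependent cleavage products of Propep1.

    Low calcium initiates cleavage at Arg69 only, releasing the Pep1
    elicitor (70–92); high calcium additionally processes the N-terminal
    stub at Arg6/Arg7.  Sites only fire when the residue actually is Lys or
    Arg, so an R6A/R7A mutant keeps just the Arg69 cut even at high calcium.
    """
    if calcium_level not in ("low", "high"):
        raise ValueError("calcium_level must be 'low' or 'high'")
    candidates = [primary_site]
    if calcium_level == "high":
        candidates += list(high_sites)
    active = sorted(s for s in set(candidates) if seq.residue(s) in ("K", "R"))
    if not active:
        # no site matches (fully mutated): the parent stays intact
        return FragmentSet(
            parent_id=seq.id,
            fragments=(_make_fragment(seq, seq.offset + 1, seq.offset + len(seq)),),
        )
    rule = CleavageRule(name=f"propep1-{calcium_level}-ca", sites=tuple(active))
    return digest(seq, rule)


def read_fasta(path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(id=r.id, sequence=str(r.seq)) for r in records]


# ---------------------------------------------------------------------------
# synthetic stand-in sequences (the real constructs are not printed in any
# bundled source; only the residue classes at the named positions matter)

_NEUTRAL = "ASTGLVDEQNPI"  # residues inert to both K/R and F/Y/W rules


def _synthetic_backbone(length: int) -> list[str]:
    return [_NEUTRAL[i % len(_NEUTRAL)] for i in range(length)]


def synthetic_atmc4_sequence() -> ProteinSequence:
    """Synthetic 418-residue stand-in for the metacaspase.

    Deterministic inert backbone with the catalytically relevant residues at
    their published positions: His86, Cys139, and the self-cleavage sites
    Arg180, Arg190, Lys210, Lys225, Lys237, Lys267.  Not the real sequence.
    """
    res = _synthetic_backbone(418)
    for pos, aa in {86: "H", 139: "C", 180: "R", 190: "R", 210: "K",
                    225: "K", 237: "K", 267: "K"}.items():
        res[pos - 1] = aa
    return ProteinSequence(id="AtMC4_synthetic", sequence="".join(res))


def synthetic_propep1_sequence(r6a_r7a: bool = False) -> ProteinSequence:
    """Synthetic 92-residue stand-in for Propep1 (Arg6, Arg7, Arg69).

    With ``r6a_r7a`` the two N-terminal arginines are alanine, reproducing
    the double mutant that confines cleavage to Arg69.  Not the real
    sequence.
    """
    res = _synthetic_backbone(92)
    res[68] = "R"
    if not r6a_r7a:
        res[5] = "R"
        res[6] = "R"
    else:
        res[5] = "A"
        res[6] = "A"
    return ProteinSequence(id="Propep1_synthetic" + ("_R6A_R7A" if r6a_r7a else ""), sequence="".join(res))
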