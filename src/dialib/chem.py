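"""Residue masses, proteolytic digestion, and peptide/fragment m/z.

Monoisotopic chemistry underlying every library-building stage: a residue
mass table with fixed modifications (carbamidomethyl-C by default), a
configurable cleavage rule (trypsin by default: cut C-terminal to K/R
unless followed by P), and the standard singly/multiply protonated y/b
fragment and precursor m/z formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from pyteomics import mass as _ptmass

PROTON_MASS = 1.007276466
WATER_MASS = 18.0105646
CARBAMIDOMETHYL = 57.021464

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC = {aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}


class ChemError(ValueError):
    """Invalid sequence, residue, or fragment request."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue -> monoisotopic mass (Da) plus fixed modification deltas.

    The default table applies carbamidomethylation (+57.021464 Da) to
    cysteine, matching standard alkylation of Cys in shotgun proteomics.
    """

    masses: dict[str, float] = field(default_factory=lambda: dict(MONOISOTOPIC))
    fixed_modifications: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    proton: float = PROTON_MASS
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_RESIDUES if aa not in self.masses]
        if missing:
            raise ChemError(f"residue table missing standard residues: {missing}")
        if any(m <= 0 for m in self.masses.values()):
            raise ChemError("all residue masses must be positive")

    def residue_mass(self, residue: str) -> float:
        """Modified monoisotopic mass of one residue."""
        try:
            base = self.masses[residue]
        except KeyError:
            raise ChemError(f"residue {residue!r} absent from mass table") from None
        return base + self.fixed_modifications.get(residue, 0.0)

    def with_fixed_modifications(self, mods: dict[str, float]) -> "ResidueMassTable":
        return replace(self, fixed_modifications=dict(mods))


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class PeptideSeq:
    """A peptide, optionally anchored to a parent protein.

    ``start``/``end`` are 1-based inclusive coordinates on the parent.
    """

    sequence: str
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ChemError("empty peptide sequence")
        bad = set(self.sequence) - set(STANDARD_RESIDUES)
        if bad:
            raise ChemError(f"non-standard residues in peptide: {sorted(bad)}")
        if self.missed_cleavages < 0:
            raise ChemError("missed_cleavages must be >= 0")
        if self.start is not None and self.end is not None:
            if self.end - self.start + 1 != len(self.sequence):
                raise ChemError("start/end inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cut after ``cut_after`` unless followed by a
    suppressor residue; join up to ``max_missed`` adjacent fragments; apply
    length bounds last."""

    cut_after: frozenset[str] = frozenset("KR")
    suppressors: frozenset[str] = frozenset("P")
    max_missed: int = 0
    min_len: int = 5
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.cut_after & self.suppressors:
            raise ChemError("cut_after and suppressor sets must be disjoint")
        if not 0 <= self.max_missed <= 5:
            raise ChemError("max_missed must be in [0, 5]")
        if self.min_len > self.max_len:
            raise ChemError("min_len must be <= max_len")

    def cuts_after(self, sequence: str, i: int) -> bool:
        """True if the bond after 0-based position ``i`` is cleaved."""
        if sequence[i] not in self.cut_after:
            return False
        return i + 1 >= len(sequence) or sequence[i + 1] not in self.suppressors


def trypsin(max_missed: int = 0, min_len: int = 5, max_len: int = 50) -> CleavageRule:
    """Conventional trypsin: cut C-terminal to K/R, suppressed before P."""
    return CleavageRule(max_missed=max_missed, min_len=min_len, max_len=max_len)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'y' or 'b'
    ordinal: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("y", "b"):
            raise ChemError(f"unknown ion series {self.series!r}")
        if self.ordinal < 1:
            raise ChemError("fragment ordinal must be >= 1")
        if self.charge < 1:
            raise ChemError("fragment charge must be >= 1")
        if self.mz <= 0:
            raise ChemError("fragment m/z must be positive")


def digest(
    sequence: str,
    rule: CleavageRule | None = None,
    *,
    protein_id: str | None = None,
    skip_invalid: bool = False,
) -> list[PeptideSeq]:
    """In-silico digest of a protein sequence.

    Fragments are maximal runs between allowed cut sites, extended by up to
    ``rule.max_missed`` joins of adjacent fragments; each peptide carries
    1-based positions and its missed-cleavage count. Length filters are
    applied last, so concatenating the 0-missed-cleavage peptides (before
    filtering, ``min_len=1``) reconstructs the input.

    Parameters
    ----------
    sequence
        Protein residue string (uppercase).
    rule
        Cleavage rule; default trypsin with no missed cleavages.
    skip_invalid
        If True, non-standard residues are dropped from the sequence
        instead of raising.
    """
    if rule is None:
        rule = trypsin()
    if not sequence:
        raise ChemError("cannot digest an empty sequence")
    bad = set(sequence) - set(STANDARD_RESIDUES)
    if bad:
        if not skip_invalid:
            raise ChemError(f"non-standard residues in sequence: {sorted(bad)}")
        sequence = "".join(c for c in sequence if c in STANDARD_RESIDUES)
        if not sequence:
            raise ChemError("sequence empty after removing non-standard residues")

    # 0-based indices one past each cleaved bond, plus the sequence ends
    cut_points = [0]
    for i in range(len(sequence) - 1):
        if rule.cuts_after(sequence, i):
            cut_points.append(i + 1)
    cut_points.append(len(sequence))

    base: list[tuple[int, int]] = [
        (cut_points[k], cut_points[k + 1]) for k in range(len(cut_points) - 1)
    ]

    peptides: list[PeptideSeq] = []
    for k, (lo, _) in enumerate(base):
        for missed in range(rule.max_missed + 1):
            if k + missed >= len(base):
                break
            hi = base[k + missed][1]
            if not rule.min_len <= hi - lo <= rule.max_len:
                continue
            peptides.append(
                PeptideSeq(
                    sequence=sequence[lo:hi],
                    protein_id=protein_id,
                    start=lo + 1,
                    end=hi,
                    missed_cleavages=missed,
                )
            )
    return peptides


def peptide_neutral_mass(
    peptide: PeptideSeq | str, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Monoisotopic neutral mass: sum of modified residue masses + water."""
    seq = peptide.sequence if isinstance(peptide, PeptideSeq) else peptide
    if not seq:
        raise ChemError("empty peptide")
    return sum(table.residue_mass(aa) for aa in seq) + table.water


def fragment_mz(
    peptide: PeptideSeq | str,
    series: str,
    ordinal: int,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """m/z of the b_k or y_k fragment at the given charge.

    b_k = (sum of first k residues + z*proton) / z
    y_k = (sum of last k residues + water + z*proton) / z
    """
    seq = peptide.sequence if isinstance(peptide, PeptideSeq) else peptide
    if not 1 <= ordinal <= len(seq) - 1:
        raise ChemError(
            f"ordinal {ordinal} out of range for peptide of length {len(seq)}"
        )
    if charge < 1:
        raise ChemError("fragment charge must be >= 1")
    if series == "b":
        residues = seq[:ordinal]
        neutral = sum(table.residue_mass(aa) for aa in residues)
    elif series == "y":
        residues = seq[-ordinal:]
        neutral = sum(table.residue_mass(aa) for aa in residues) + table.water
    else:
        raise ChemError(f"unknown ion series {series!r}")
    return (neutral + charge * table.proton) / charge


def precursor_mz(
    peptide: PeptideSeq | str,
    charge: int,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Precursor m/z: (neutral mass + z*proton) / z."""
    if charge < 1:
        raise ChemError("precursor charge must be >= 1")
    return (peptide_neutral_mass(peptide, table) + charge * table.proton) / charge


def theoretical_fragments(
    peptide: PeptideSeq | str,
    series: tuple[str, ...] = ("y", "b"),
    charges: tuple[int, ...] = (1, 2),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[FragmentIon]:
    """All y/b fragment ions of a peptide for the requested charges."""
    seq = peptide.sequence if isinstance(peptide, PeptideSeq) else peptide
    ions = []
    for s in series:
        for k in range(1, len(seq)):
            for z in charges:
                ions.append(FragmentIon(s, k, z, fragment_mz(seq, s, k, z, table)))
    return ions


def equate_il(sequence: str) -> str:
    """Collapse I/L ambiguity (both replaced by 'L') for uniqueness checks."""
    return sequence.replace("I", "L")
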