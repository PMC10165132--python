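"""Peptide mass arithmetic and theoretical fragment-ion enumeration.

Twelve backbone ion types are considered: a, b and y ions, each singly
charged with and without a neutral loss of water or ammonia, plus doubly
charged a, b and y ions.  Internal fragments (two backbone cleavages, so
the fragment carries neither terminus) come in a- and b-type flavours.

Monoisotopic masses are used throughout; the residue and molecule masses
come from :mod:`pyteomics.mass`.  Fragment m/z follows the usual
conventions: ``mz = (neutral + z * proton) / z`` for backbone ions, while
internal fragments are reported as neutral-plus-H-atom masses taken
directly as singly charged m/z (b-type internal mass = residue sum + H
atom; a-type = b-type − CO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

# --- constants -------------------------------------------------------------

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

PROTON: float = _pmass.nist_mass["H+"][0][0]          # 1.00727646677
H_ATOM: float = _pmass.nist_mass["H"][0][0]           # 1.00782503207
WATER: float = _pmass.calculate_mass(formula="H2O")   # 18.01056468
AMMONIA: float = _pmass.calculate_mass(formula="NH3")  # 17.02654910
CARBON_MONOXIDE: float = _pmass.calculate_mass(formula="CO")  # 27.99491462

#: Fixed modification: carbamidomethylation of cysteine, applied to every C.
MOD_CARBAMIDOMETHYL: float = 57.02146
#: Variable modification: oxidation of methionine, given per position.
MOD_OXIDATION: float = 15.99491

#: Residues whose presence licenses a water neutral loss (besides y ions,
#: which always contain the C-terminus and are always eligible).
WATER_LOSS_RESIDUES = frozenset("DEST")
#: Residues whose presence licenses an ammonia neutral loss.
AMMONIA_LOSS_RESIDUES = frozenset("RKQN")

LOSS_MASSES = {"none": 0.0, "H2O": WATER, "NH3": AMMONIA}

#: Canonical labels for the 12 backbone ion types, in display order.
BACKBONE_ION_TYPES = (
    "a", "b", "y",
    "a-H2O", "b-H2O", "y-H2O",
    "a-NH3", "b-NH3", "y-NH3",
    "a(2+)", "b(2+)", "y(2+)",
)
INTERNAL_ION_TYPES = ("Int-b", "Int-a")


class UnknownResidueError(ValueError):
    """A sequence contains a character that is not a standard residue code."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with modifications and a precursor charge.

    ``mods`` holds explicit variable modifications as ``(position, delta)``
    with 1-based positions.  Carbamidomethylation of cysteine is fixed and
    applied implicitly to every C; it never appears in ``mods``.
    """

    sequence: str
    mods: tuple[tuple[int, float], ...] = ()
    precursor_charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in RESIDUE_MASSES:
                raise UnknownResidueError(
                    f"unknown residue code {ch!r} in sequence {self.sequence!r}"
                )
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        seen: set[int] = set()
        for pos, _delta in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside [1, {len(self.sequence)}]")
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            seen.add(pos)
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be a positive integer")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_mass(self, position: int) -> float:
        """Monoisotopic mass of the residue at a 1-based position, with mods."""
        aa = self.sequence[position - 1]
        m = RESIDUE_MASSES[aa]
        if aa == "C":
            m += MOD_CARBAMIDOMETHYL
        for pos, delta in self.mods:
            if pos == position:
                m += delta
        return m

    def residue_masses(self) -> list[float]:
        return [self.residue_mass(i) for i in range(1, len(self) + 1)]


@dataclass(frozen=True)
class TheoreticalIon:
    """One expected backbone fragment peak."""

    series: str           # 'a', 'b' or 'y'
    index: int            # 1-based cleavage ordinal, counted from the series' terminus
    charge: int           # 1 or 2
    loss: str             # 'none', 'H2O' or 'NH3'
    mz: float

    @property
    def ion_type(self) -> str:
        """Canonical label among the 12 backbone ion types."""
        if self.charge == 2:
            return f"{self.series}(2+)"
        if self.loss != "none":
            return f"{self.series}-{self.loss}"
        return self.series


@dataclass(frozen=True)
class InternalFragment:
    """A doubly cleaved fragment carrying neither terminus.

    ``mass`` doubles as the singly charged m/z: these ions are treated as
    carrying their charge without an added proton, so m/z = mass.
    """

    start: int            # 1-based, inclusive; >= 2
    end: int              # 1-based, inclusive; <= L-1
    ion_type: str         # 'a' or 'b'
    mass: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def type_label(self) -> str:
        return "Int-a" if self.ion_type == "a" else "Int-b"


# --- operations ------------------------------------------------------------

def peptide_neutral_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + modification deltas + water."""
    return sum(peptide.residue_masses()) + WATER


def _eligible_losses(fragment_residues: str, is_y: bool) -> list[str]:
    losses = ["none"]
    if is_y or not WATER_LOSS_RESIDUES.isdisjoint(fragment_residues):
        losses.append("H2O")
    if not AMMONIA_LOSS_RESIDUES.isdisjoint(fragment_residues):
        losses.append("NH3")
    return losses


def enumerate_backbone_ions(
    peptide: Peptide,
    series_set: Sequence[str] = ("a", "b", "y"),
    charges: Sequence[int] = (1, 2),
    losses: Sequence[str] = ("none", "H2O", "NH3"),
) -> list[TheoreticalIon]:
    """Enumerate backbone fragment ions for every cleavage site.

    For cleavage index i in 1..L−1 the b fragment is the N-terminal prefix
    of i residues and the y fragment the C-terminal suffix of i residues
    (plus water); a ions are b ions minus CO.  Water loss is emitted only
    for y ions or fragments containing D/E/S/T; ammonia loss only for
    fragments containing R/K/Q/N.  Neutral-loss variants are restricted to
    charge 1, matching the twelve-type accounting.
    """
    L = len(peptide)
    if L < 2:
        raise ValueError("peptide must have at least 2 residues (one cleavage site)")
    bad = set(series_set) - {"a", "b", "y"}
    if bad:
        raise ValueError(f"unknown ion series: {sorted(bad)}")

    res = peptide.residue_masses()
    seq = peptide.sequence
    prefix = [0.0]
    for m in res:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    ions: list[TheoreticalIon] = []
    for i in range(1, L):
        b_neutral = prefix[i]
        frags = {
            "a": (b_neutral - CARBON_MONOXIDE, seq[:i], False),
            "b": (b_neutral, seq[:i], False),
            "y": (total - prefix[L - i] + WATER, seq[L - i:], True),
        }
        for series in series_set:
            neutral, residues, is_y = frags[series]
            allowed = _eligible_losses(residues, is_y)
            for charge in charges:
                for loss in losses:
                    if loss not in allowed:
                        continue
                    if loss != "none" and charge != 1:
                        continue
                    mz = (neutral - LOSS_MASSES[loss] + charge * PROTON) / charge
                    ions.append(TheoreticalIon(series, i, charge, loss, mz))
    return ions


def enumerate_internal_fragments(
    peptide: Peptide,
    min_len: int = 1,
    ion_types: Sequence[str] = ("b", "a"),
) -> list[InternalFragment]:
    """Enumerate internal fragments over positions 2..L−1.

    All contiguous spans of length >= ``min_len`` within positions 2..L−1
    are produced.  b-type mass = residue sum + H atom; a-type = b-type − CO.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    L = len(peptide)
    if L < min_len + 2:
        raise ValueError(
            f"peptide of length {L} has no internal span of length >= {min_len}"
        )
    res = peptide.residue_masses()
    frags: list[InternalFragment] = []
    for start in range(2, L):               # 1-based start in [2, L-1]
        running = 0.0
        for end in range(start, L):         # 1-based end in [start, L-1]
            running += res[end - 1]
            if end - start + 1 < min_len:
                continue
            b_mass = running + H_ATOM
            for ion_type in ion_types:
                mass_ = b_mass if ion_type == "b" else b_mass - CARBON_MONOXIDE
                frags.append(InternalFragment(start, end, ion_type, mass_))
    return frags
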