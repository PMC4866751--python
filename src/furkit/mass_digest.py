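"""In-silico trypsin digestion and monoisotopic mass / fragment-ion arithmetic.

Peptides from a zero-missed-cleavage digest are labelled T1..Tn from the
N-terminus; a trailing ``*`` marks a peptide carrying at least one
carbamidomethylated cysteine, following the usual peptide-map annotation of
iodoacetamide-alkylated samples.  Fragment ions are the singly-charged-by-
default b/y series used to read a modification site off the ladder.

Masses are monoisotopic throughout: residue masses come from the standard
table (via pyteomics), water is 18.010565 Da and the proton 1.007276 Da, so
every number here is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass

from .seq_annotation import ProteinRecord

WATER = 18.010565
PROTON = 1.007276

#: Monoisotopic residue (not free amino-acid) masses, Da.
RESIDUE_MASS: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


@dataclass(frozen=True)
class Modification:
    """A covalent mass shift restricted to a set of residue letters."""

    name: str
    delta_mono: float
    targets: frozenset[str]

    def allows(self, residue: str) -> bool:
        return residue in self.targets


CARBAMIDOMETHYL = Modification("Carbamidomethyl", 57.021464, frozenset("C"))
#: His and Met are both oxidation candidates by default: Met is the competing
#: site the ladder-walk has to discriminate against.
OXIDATION = Modification("Oxidation", 15.994915, frozenset("HM"))


class ModificationError(ValueError):
    """Raised when a modification targets an incompatible residue."""


@dataclass(frozen=True)
class TrypticPeptide:
    """A digested peptide with its ordinal label and parent coordinates.

    ``start``/``end`` are 1-based inclusive in the parent; ``fixed_mods`` is
    a tuple of (peptide-local 1-based index, Modification).
    """

    parent_id: str
    label: str
    start: int
    end: int
    sequence: str
    fixed_mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        assert self.end - self.start + 1 == len(self.sequence)
        for pos, mod in self.fixed_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ModificationError(f"mod position {pos} outside peptide")
            if not mod.allows(self.sequence[pos - 1]):
                raise ModificationError(
                    f"{mod.name} cannot target {self.sequence[pos - 1]!r} at {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float
    contains_positions: frozenset[int]

    @property
    def name(self) -> str:
        z = "+" * self.charge
        return f"{self.series}{self.index}({z})"


def digest_trypsin(record: ProteinRecord, missed_cleavages: int = 0) -> list[TrypticPeptide]:
    """Cleave C-terminal to K or R except before P; label T1..Tn.

    The zero-missed-cleavage peptides are contiguous, non-overlapping and
    concatenate back to the parent.  With ``missed_cleavages`` > 0, joined
    spans are appended with compound labels "Tm-Tn".
    """
    seq = record.sequence
    # cut after index i (0-based) when seq[i] in KR and next residue not P
    cuts = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(seq)]
    base: list[TrypticPeptide] = []
    for n, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        base.append(
            TrypticPeptide(
                parent_id=record.id,
                label=f"T{n}",
                start=lo + 1,
                end=hi,
                sequence=seq[lo:hi],
            )
        )
    peptides = list(base)
    for k in range(1, missed_cleavages + 1):
        for i in range(len(base) - k):
            first, last = base[i], base[i + k]
            peptides.append(
                TrypticPeptide(
                    parent_id=record.id,
                    label=f"{first.label}-{last.label}",
                    start=first.start,
                    end=last.end,
                    sequence=seq[first.start - 1 : last.end],
                )
            )
    return peptides


def _mod_mass_at(
    peptide: TrypticPeptide, variable_mods: Iterable[tuple[int, Modification]]
) -> dict[int, float]:
    """Total modification mass per peptide-local position (validated)."""
    deltas: dict[int, float] = {}
    for pos, mod in peptide.fixed_mods:
        deltas[pos] = deltas.get(pos, 0.0) + mod.delta_mono
    for pos, mod in variable_mods:
        if not 1 <= pos <= len(peptide):
            raise ModificationError(f"mod position {pos} outside peptide")
        if not mod.allows(peptide.sequence[pos - 1]):
            raise ModificationError(
                f"{mod.name} cannot target {peptide.sequence[pos - 1]!r} at {pos}"
            )
        deltas[pos] = deltas.get(pos, 0.0) + mod.delta_mono
    return deltas


def peptide_mass(
    peptide: TrypticPeptide,
    variable_mods: Sequence[tuple[int, Modification]] = (),
) -> float:
    """Neutral monoisotopic mass: residues + water + fixed + variable mods."""
    deltas = _mod_mass_at(peptide, variable_mods)
    return (
        sum(RESIDUE_MASS[aa] for aa in peptide.sequence)
        + WATER
        + sum(deltas.values())
    )


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """(M + z * proton) / z for a z-fold protonated precursor."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def fragment_ladder(
    peptide: TrypticPeptide,
    variable_mods: Sequence[tuple[int, Modification]] = (),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Full b/y ladder (indices 1..n-1) at charges 1..max_charge.

    b_i covers peptide positions 1..i; y_i covers n-i+1..n.  Singly charged:
    b_i = sum(residues+mods in 1..i) + proton;  y_i = sum + water + proton.
    Higher charges follow (m + z*proton)/z on the same neutral fragment sum.
    """
    n = len(peptide)
    deltas = _mod_mass_at(peptide, variable_mods)
    masses = [
        RESIDUE_MASS[aa] + deltas.get(i + 1, 0.0)
        for i, aa in enumerate(peptide.sequence)
    ]
    ions: list[FragmentIon] = []
    prefix = 0.0
    for i in range(1, n):
        prefix += masses[i - 1]
        for z in range(1, max_charge + 1):
            ions.append(
                FragmentIon(
                    series="b",
                    index=i,
                    charge=z,
                    mz=(prefix + z * PROTON) / z,
                    contains_positions=frozenset(range(1, i + 1)),
                )
            )
    suffix = 0.0
    for i in range(1, n):
        suffix += masses[n - i]
        for z in range(1, max_charge + 1):
            ions.append(
                FragmentIon(
                    series="y",
                    index=i,
                    charge=z,
                    mz=(suffix + WATER + z * PROTON) / z,
                    contains_positions=frozenset(range(n - i + 1, n + 1)),
                )
            )
    return ions


def apply_fixed_carbamidomethyl(peptide: TrypticPeptide) -> TrypticPeptide:
    """Alkylate every Cys (+57.021464); star the label iff any Cys present."""
    cys_positions = [i + 1 for i, aa in enumerate(peptide.sequence) if aa == "C"]
    if not cys_positions:
        return peptide
    mods = tuple(
        (pos, CARBAMIDOMETHYL)
        for pos in cys_positions
        if not any(p == pos and m.name == CARBAMIDOMETHYL.name for p, m in peptide.fixed_mods)
    )
    label = peptide.label if peptide.label.endswith("*") else peptide.label + "*"
    return replace(peptide, label=label, fixed_mods=peptide.fixed_mods + mods)


def peptide_table(
    record: ProteinRecord,
    missed_cleavages: int = 0,
    carbamidomethyl: bool = True,
) -> "pd.DataFrame":
    """Digest summary table: label, coordinates, M, [M+H]+ .. [M+3H]3+."""
    import pandas as pd

    rows = []
    for pep in digest_trypsin(record, missed_cleavages):
        if carbamidomethyl:
            pep = apply_fixed_carbamidomethyl(pep)
        m = peptide_mass(pep)
        rows.append(
            {
                "parent": pep.parent_id,
                "label": pep.label,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "M": m,
                "MH1": precursor_mz(m, 1),
                "MH2": precursor_mz(m, 2),
                "MH3": precursor_mz(m, 3),
            }
        )
    return pd.DataFrame(rows)
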