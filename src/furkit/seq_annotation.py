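"""Fur-family sequence annotation.

Classifies Fur-family metalloregulators (Fur / Zur / PerR subtypes) from the
residues found at the positions of the reference protein's two metal sites:

* a *structural* Zn2+ site of four cysteines arranged in two C-x-x-C motifs
  (reference positions 96, 99, 136, 139), which stabilizes the dimerization
  domain, and
* a *regulatory* metal site in the inter-domain hinge (reference positions
  37, 85, 91, 93, 104; His/Asp-rich in PerR and Fur, His/Cys in Zur), whose
  occupancy gates DNA binding.

Targets are placed in the reference frame by pairwise global alignment; the
subtype call is a rule cascade over the aligned residues.  All coordinates in
this module are 1-based inclusive, matching the field's residue numbering
(His37, Asp104, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Sentinel for a reference position that falls opposite a gap in the target.
GAP = None

# Trp / Tyr molar absorptivities at 280 nm (M^-1 cm^-1), reduced-Cys
# convention: no cystine term.
_EPS_TRP = 5500
_EPS_TYR = 1490


class Subtype(str, Enum):
    PERR_LIKE = "PERR_LIKE"
    FUR_LIKE = "FUR_LIKE"
    ZUR_LIKE = "ZUR_LIKE"
    UNCLASSIFIED = "UNCLASSIFIED"


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; the unit of annotation and digestion.

    ``sequence`` must be uppercase over the 20 standard one-letter codes.
    ``allow_x`` additionally admits 'X' (unknown residue); an X never
    satisfies a signature rule downstream.
    """

    id: str
    sequence: str
    description: str = ""
    allow_x: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be nonempty")
        if not self.sequence:
            raise SequenceError(f"{self.id}: sequence must be nonempty")
        alphabet = STANDARD_AA | ({"X"} if self.allow_x else set())
        bad = set(self.sequence) - alphabet
        if bad:
            raise SequenceError(
                f"{self.id}: illegal residue characters {sorted(bad)} "
                "(20 standard one-letter codes expected)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        return self.sequence[pos - 1]


def read_fasta(path: str | Path, allow_x: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` s.

    Order is preserved; empty files and duplicate ids are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq).upper(),
                description=entry.description,
                allow_x=allow_x,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


@dataclass(frozen=True)
class ReferenceScheme:
    """The reference coordinate frame for metal-site residue extraction.

    ``structural_positions`` must carry Cys in the reference (the four-Cys
    structural Zn site); ``regulatory_positions`` are the hinge-site ligands.
    """

    reference: ProteinRecord
    structural_positions: tuple[int, ...] = (96, 99, 136, 139)
    regulatory_positions: tuple[int, ...] = (37, 85, 91, 93, 104)

    def __post_init__(self) -> None:
        for name, positions in (
            ("structural_positions", self.structural_positions),
            ("regulatory_positions", self.regulatory_positions),
        ):
            if list(positions) != sorted(set(positions)):
                raise ValueError(f"{name} must be strictly increasing")
            if any(p < 1 or p > len(self.reference) for p in positions):
                raise ValueError(f"{name} outside reference length")
        for p in self.structural_positions:
            if self.reference.residue(p) != "C":
                raise ValueError(
                    f"reference residue at structural position {p} is "
                    f"{self.reference.residue(p)!r}, expected Cys"
                )

    @property
    def all_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.structural_positions + self.regulatory_positions))


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    matches: int
    aligned_length: int
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)
        assert self.matches <= self.aligned_length


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Affine penalties: a gap of length k costs open + (k-1)*extend.
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment, BLOSUM62, affine gaps.

    Deterministic: among co-optimal alignments the engine's first traceback
    is taken, which is stable for fixed inputs and parameters.
    """
    if not a.sequence or not b.sequence:
        raise SequenceError("cannot align empty sequences")
    aligner = _make_aligner(open_gap, extend_gap)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        aligned_length=len(aligned_a),
        score=float(alignment.score),
    )


def percent_identity(alignment: AlignmentResult) -> float:
    """100 x matches / alignment columns (terminal gaps included)."""
    if alignment.aligned_length == 0:
        raise ValueError("zero-length alignment")
    return 100.0 * alignment.matches / alignment.aligned_length


def map_positions(
    alignment: AlignmentResult, scheme: ReferenceScheme
) -> dict[int, tuple[int | None, str]]:
    """Map each scheme reference position to (target position | GAP, residue).

    ``alignment`` must have the scheme's reference as sequence *a*.  Both
    sides are 1-based; a reference position opposite a gap maps to
    ``(GAP, '-')``.
    """
    degapped_a = alignment.aligned_a.replace("-", "")
    if degapped_a != scheme.reference.sequence:
        raise ValueError("alignment sequence a is not the scheme reference")
    wanted = set(scheme.all_positions)
    out: dict[int, tuple[int | None, str]] = {}
    ref_pos = 0
    tgt_pos = 0
    for col_a, col_b in zip(alignment.aligned_a, alignment.aligned_b):
        if col_a != "-":
            ref_pos += 1
        if col_b != "-":
            tgt_pos += 1
        if col_a != "-" and ref_pos in wanted:
            if col_b == "-":
                out[ref_pos] = (GAP, "-")
            else:
                out[ref_pos] = (tgt_pos, col_b)
    assert set(out) == wanted, "reference position beyond alignment"
    return out


def find_cxxc(record: ProteinRecord) -> list[int]:
    """All 1-based starts p with sequence[p]=='C' and sequence[p+3]=='C'.

    Overlapping motifs are all reported.
    """
    seq = record.sequence
    return [i + 1 for i in range(len(seq) - 3) if seq[i] == "C" and seq[i + 3] == "C"]


@dataclass(frozen=True)
class SiteProfile:
    """Residues found at the reference metal-site positions in a target."""

    residue_at: Mapping[int, tuple[int | None, str]]
    cxxc_motifs: tuple[int, ...]
    structural_cys_count: int


def extract_site_profile(record: ProteinRecord, scheme: ReferenceScheme) -> SiteProfile:
    alignment = global_align(scheme.reference, record)
    residue_at = map_positions(alignment, scheme)
    cys_count = sum(
        1 for p in scheme.structural_positions if residue_at[p][1] == "C"
    )
    return SiteProfile(
        residue_at=residue_at,
        cxxc_motifs=tuple(find_cxxc(record)),
        structural_cys_count=cys_count,
    )


@dataclass(frozen=True)
class SubtypeCall:
    subtype: Subtype
    evidence: tuple[str, ...]
    has_structural_site: bool


def classify_subtype(
    profile: SiteProfile,
    scheme: ReferenceScheme | None = None,
) -> SubtypeCall:
    """Rule cascade over the regulatory-site residues.

    1. Cys aligned to reference 85 (the Zur S-donor position) together with
       a non-His at reference 37 (Zur lacks that N-donor)  ->  ZUR_LIKE.
    2. Else, His at 37/91/93: Asp at 104 -> PERR_LIKE, Glu at 104 -> FUR_LIKE.
       (A Glu at 85 with Asp retained at 104 still classifies PERR_LIKE.)
    3. Otherwise UNCLASSIFIED.  An 'X' at a signature position fails the rule
       it participates in; UNCLASSIFIED is the fallback, never an exception.
    """
    res = {p: profile.residue_at[p][1] for p in (37, 85, 91, 93, 104)}
    evidence = [f"ref {p} -> {res[p]}" for p in (37, 85, 91, 93, 104)]
    evidence.append(
        f"structural Cys {profile.structural_cys_count}/4 at reference Cys positions"
    )

    subtype = Subtype.UNCLASSIFIED
    if res[85] == "C" and res[37] != "H":
        subtype = Subtype.ZUR_LIKE
        evidence.append("S-donor Cys at ref 85 and no His at ref 37: Zur signature")
    elif res[37] == "H" and res[91] == "H" and res[93] == "H":
        if res[104] == "D":
            subtype = Subtype.PERR_LIKE
            evidence.append("His triad 37/91/93 with Asp at ref 104: PerR signature")
        elif res[104] == "E":
            subtype = Subtype.FUR_LIKE
            evidence.append("His triad 37/91/93 with Glu at ref 104: Fur signature")
        else:
            evidence.append("His triad present but no Asp/Glu O-donor at ref 104")
    else:
        evidence.append("incomplete His triad at ref 37/91/93")

    return SubtypeCall(
        subtype=subtype,
        evidence=tuple(evidence),
        has_structural_site=profile.structural_cys_count == 4,
    )


def extinction_coefficient_280(record: ProteinRecord) -> int:
    """Molar absorptivity at 280 nm: 5500 per Trp + 1490 per Tyr (M^-1 cm^-1).

    Reduced-cysteine convention: cystine contributes nothing.  Additive under
    sequence concatenation.
    """
    return _EPS_TRP * record.sequence.count("W") + _EPS_TYR * record.sequence.count("Y")


def identity_matrix(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over all pairs (100 on the diagonal)."""
    if len(records) < 2:
        raise ValueError("identity_matrix needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate record ids")
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(records):
        for j in range(i + 1, len(records)):
            pid = percent_identity(global_align(a, records[j]))
            mat.iat[i, j] = pid
            mat.iat[j, i] = pid
    return mat


def annotate_record(record: ProteinRecord, scheme: ReferenceScheme) -> dict:
    """Full per-protein annotation report (JSON-serializable)."""
    profile = extract_site_profile(record, scheme)
    call = classify_subtype(profile)
    return {
        "id": record.id,
        "subtype": call.subtype.value,
        "evidence": list(call.evidence),
        "has_structural_site": call.has_structural_site,
        "site_residues": {
            str(p): {"target_position": profile.residue_at[p][0], "residue": profile.residue_at[p][1]}
            for p in scheme.all_positions
        },
        "cxxc": list(profile.cxxc_motifs),
        "epsilon280": extinction_coefficient_280(record),
    }
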