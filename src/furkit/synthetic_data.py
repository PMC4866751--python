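"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure its downstream stage
assumes — Fur-family sequences with implanted metal-site signatures, b/y
ladders with jitter and noise peaks, exponential-approach PAR traces, and
single-site binding titrations — so the whole pipeline is testable without
any download.  All randomness flows through ``numpy.random.default_rng``
with a mandatory integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dna_binding import TitrationPoint, simulate_titration
from .mass_digest import TrypticPeptide, fragment_ladder, peptide_mass, precursor_mz
from .seq_annotation import ProteinRecord, ReferenceScheme, Subtype
from .site_localization import PeakList
from .zinc_kinetics import KineticTrace, simulate_trace

#: Background alphabet: the 20 standard residues minus C/H/D/E, so no
#: accidental Cys motifs or His/Asp/Glu signatures arise off-site.
BACKGROUND_AA = "AFGIKLMNPQRSTVWY"

_STRUCTURAL = (96, 99, 136, 139)
_TEMPLATE_LENGTH = 150
_TEMPLATE_SEED = 97  # fixes the shared neutral backbone, not a per-call seed

#: Residues implanted at the regulatory positions (ref 37/85/91/93/104) per
#: subtype.  ZUR_LIKE carries the S-donor Cys at 85 and lacks the N-donor
#: His at 37.
_SUBTYPE_SIGNATURES: dict[Subtype, dict[int, str]] = {
    Subtype.PERR_LIKE: {37: "H", 85: "D", 91: "H", 93: "H", 104: "D"},
    Subtype.FUR_LIKE: {37: "H", 85: "D", 91: "H", 93: "H", 104: "E"},
    Subtype.ZUR_LIKE: {37: "A", 85: "C", 91: "H", 93: "H", 104: "D"},
}


def _template_backbone() -> str:
    """The fixed neutral backbone shared by the reference and all generated
    sequences; site positions are overwritten by the caller."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    return "".join(rng.choice(list(BACKGROUND_AA), size=_TEMPLATE_LENGTH))


_TEMPLATE = _template_backbone()


def _implant(seq: list[str], signature: dict[int, str]) -> None:
    for pos in _STRUCTURAL:
        seq[pos - 1] = "C"
    for pos, aa in signature.items():
        seq[pos - 1] = aa


def make_fur_family_sequence(
    subtype: Subtype | str,
    length: int = _TEMPLATE_LENGTH,
    seed: int = 0,
    mutation_rate: float = 0.3,
) -> ProteinRecord:
    """A Fur-family sequence with the subtype's site signature implanted.

    The fixed template backbone carries the sites at the canonical reference
    positions; per-seed, a ``mutation_rate`` fraction of the non-site
    positions is resampled from the background alphabet (never creating
    C/H/D/E), so different seeds give different sequences with identical
    classification and an exact, gap-free mapping onto the reference frame.
    """
    subtype = Subtype(subtype)
    if subtype is Subtype.UNCLASSIFIED:
        raise ValueError("cannot implant an UNCLASSIFIED signature")
    if length < _TEMPLATE_LENGTH:
        raise ValueError(
            f"length {length} too short to host all sites (need >= {_TEMPLATE_LENGTH})"
        )
    rng = np.random.default_rng(seed)
    signature = _SUBTYPE_SIGNATURES[subtype]
    site_positions = set(_STRUCTURAL) | set(signature)
    seq = list(_TEMPLATE)
    if length > _TEMPLATE_LENGTH:
        seq += list(rng.choice(list(BACKGROUND_AA), size=length - _TEMPLATE_LENGTH))
    for i in range(len(seq)):
        if (i + 1) not in site_positions and rng.random() < mutation_rate:
            seq[i] = str(rng.choice(list(BACKGROUND_AA)))
    _implant(seq, signature)
    return ProteinRecord(
        id=f"synthetic_{subtype.value.lower()}_{seed}",
        sequence="".join(seq),
        description=f"synthetic_{subtype.value.lower()}_{seed} synthetic Fur-family sequence, seed={seed}",
    )


def make_reference_record() -> ProteinRecord:
    """The synthetic PerR-template reference sequence.

    A stand-in reference frame (not a database sequence): the fixed backbone
    with the PerR signature (His37/Asp85/His91/His93/Asp104) and the four
    structural Cys (96/99/136/139, two C-x-x-C motifs) implanted, so all
    reference-position semantics hold by construction.
    """
    seq = list(_TEMPLATE)
    _implant(seq, _SUBTYPE_SIGNATURES[Subtype.PERR_LIKE])
    return ProteinRecord(
        id="PerR_template",
        sequence="".join(seq),
        description="PerR_template synthetic PerR-like reference frame",
    )


def default_reference_scheme() -> ReferenceScheme:
    return ReferenceScheme(reference=make_reference_record())


def make_peptide_spectrum(
    peptide: TrypticPeptide,
    true_site: int,
    delta: float,
    coverage: float = 1.0,
    jitter: float = 0.0,
    n_noise: int = 0,
    seed: int = 0,
    max_charge: int = 1,
) -> PeakList:
    """An observed-spectrum emulation of the shifted b/y ladder.

    A ``coverage`` fraction of the ladder ions (shift placed at
    ``true_site``) is kept, each with Gaussian m/z jitter of sd ``jitter``
    Da, plus ``n_noise`` uniform random peaks across the m/z range.
    """
    if not 1 <= true_site <= len(peptide):
        raise ValueError("true_site outside peptide")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from .site_localization import theoretical_ladders_with_site

    ions = theoretical_ladders_with_site(peptide, delta, true_site, max_charge)
    n_keep = int(round(coverage * len(ions)))
    keep = rng.choice(len(ions), size=n_keep, replace=False) if n_keep else []
    peaks = [
        (ions[i].mz + (rng.normal(0.0, jitter) if jitter > 0 else 0.0),
         float(rng.uniform(0.3, 1.0)))
        for i in keep
    ]
    if ions:
        lo, hi = min(i.mz for i in ions) - 50.0, max(i.mz for i in ions) + 50.0
    else:  # pragma: no cover - length-1 peptide has no ladder
        lo, hi = 100.0, 2000.0
    for _ in range(n_noise):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(0.05, 0.3))))
    mass = peptide_mass(peptide) + delta
    charge = 2
    return PeakList(
        peaks=tuple(sorted(peaks)),
        precursor_mz=precursor_mz(mass, charge),
        precursor_charge=charge,
        title=f"{peptide.parent_id}|{peptide.label}+{delta:.0f} site={true_site} seed={seed}",
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the kinetics / binding generators.

    Defaults are the assay protocol: 5 uM protein treated with 0/1/10/100 mM
    H2O2 under 100 uM PAR, A494 sampled every 1 s for 30 min with 0.002 AU
    noise; EMSA as an 8-point 2-fold titration, 10 to 1280 nM, with 10%
    multiplicative noise on the bound fraction.
    """

    seed: int = 0
    k2: float = 0.03  # M^-1 s^-1
    zn_content: float = 0.8  # mol/mol monomer
    protein_conc: float = 5e-6  # M
    h2o2_concs: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1)  # M
    noise_sd: float = 0.002  # AU
    dt: float = 1.0  # s
    duration: float = 1800.0  # s
    kd: float = 70e-9  # M
    emsa_concs: tuple[float, ...] = tuple(10e-9 * 2**i for i in range(8))
    emsa_noise: float = 0.10
    emsa_noise_mode: str = "multiplicative"


def make_kinetics_dataset(config: GeneratorConfig) -> list[KineticTrace]:
    """One PAR trace per H2O2 concentration, including the 0 mM control."""
    return [
        simulate_trace(
            k2=config.k2,
            h2o2=c,
            zn_content=config.zn_content,
            protein_conc=config.protein_conc,
            noise_sd=config.noise_sd,
            dt=config.dt,
            duration=config.duration,
            seed=config.seed + i,
        )
        for i, c in enumerate(config.h2o2_concs)
    ]


def make_emsa_dataset(config: GeneratorConfig) -> list[TitrationPoint]:
    return simulate_titration(
        kd=config.kd,
        concs=config.emsa_concs,
        noise_sd=config.emsa_noise,
        seed=config.seed,
        noise_mode=config.emsa_noise_mode,
    )


def make_random_peptide(
    rng: np.random.Generator,
    length: int,
    n_candidates: int = 2,
    candidate_residues: str = "HM",
) -> tuple[TrypticPeptide, list[int]]:
    """A random peptide carrying ``n_candidates`` oxidation-candidate
    residues (His/Met) at distinct random positions; returns the peptide and
    the sorted candidate positions."""
    if length < n_candidates + 1:
        raise ValueError("peptide too short for candidate count")
    background = [aa for aa in BACKGROUND_AA if aa not in candidate_residues]
    seq = [str(rng.choice(background)) for _ in range(length)]
    positions = sorted(
        int(p) + 1 for p in rng.choice(length, size=n_candidates, replace=False)
    )
    for pos in positions:
        seq[pos - 1] = str(rng.choice(list(candidate_residues)))
    sequence = "".join(seq)
    peptide = TrypticPeptide(
        parent_id="synthetic",
        label="T1",
        start=1,
        end=length,
        sequence=sequence,
    )
    return peptide, positions
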