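"""Ladder-walk localization of a mass shift on a tryptic peptide.

Given an observed MS/MS peak list for a peptide carrying a known mass shift
(e.g. +15.9949 Da for 2-oxo-histidine), each candidate site implies a split
of the b/y ladder into shifted ions (those containing the site) and
unshifted ions.  A candidate is scored by the ions observed in the state it
predicts, minus the ions observed in the *wrong* state (contradictions);
intensities are not used for scoring, only recorded.  A unique, sufficiently
supported maximum localizes the site; ties are surfaced as AMBIGUOUS and
thin evidence as INCONSISTENT rather than guessed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .mass_digest import FragmentIon, TrypticPeptide, fragment_ladder


class LocalizationStatus(str, Enum):
    LOCALIZED = "LOCALIZED"
    AMBIGUOUS = "AMBIGUOUS"
    INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class PeakList:
    """An observed MS/MS spectrum: (m/z, intensity) pairs sorted by m/z."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float = 0.0
    precursor_charge: int = 0
    title: str = ""

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("intensities must be nonnegative")

    @property
    def mzs(self) -> list[float]:
        return [p[0] for p in self.peaks]


@dataclass(frozen=True)
class MatchTolerance:
    mode: str = "Da"  # 'Da' or 'ppm'
    value: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("Da", "ppm"):
            raise ValueError("tolerance mode must be 'Da' or 'ppm'")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def window(self, mz: float) -> float:
        return self.value if self.mode == "Da" else mz * self.value * 1e-6


@dataclass(frozen=True)
class LadderMatch:
    site: int
    matched_unshifted: int
    matched_shifted: int
    contradictions: int
    matched_ions: tuple[tuple[FragmentIon, float], ...] = ()

    @property
    def matched(self) -> int:
        return self.matched_unshifted + self.matched_shifted

    @property
    def score(self) -> int:
        return self.matched - self.contradictions


@dataclass(frozen=True)
class LocalizationResult:
    peptide: TrypticPeptide
    delta: float
    ranking: tuple[LadderMatch, ...]
    status: LocalizationStatus
    best_site: int | None


def theoretical_ladders_with_site(
    peptide: TrypticPeptide,
    delta: float,
    site: int,
    max_charge: int = 1,
) -> list[FragmentIon]:
    """b/y ladder with ``delta`` placed at peptide-local position ``site``.

    Ions whose ``contains_positions`` include the site carry the shift;
    all others are the plain ladder ions.
    """
    if not 1 <= site <= len(peptide):
        raise ValueError(f"site {site} outside peptide of length {len(peptide)}")
    ions = []
    for ion in fragment_ladder(peptide, max_charge=max_charge):
        if site in ion.contains_positions:
            ions.append(
                FragmentIon(
                    series=ion.series,
                    index=ion.index,
                    charge=ion.charge,
                    mz=ion.mz + delta / ion.charge,
                    contains_positions=ion.contains_positions,
                )
            )
        else:
            ions.append(ion)
    return ions


def match_peaks(
    theoretical: Sequence[FragmentIon],
    observed: PeakList,
    tol: MatchTolerance,
) -> list[tuple[FragmentIon, float]]:
    """Nearest-peak matching within tolerance.

    Each theoretical ion takes the nearest observed peak inside the window;
    equidistant peaks break toward the lower m/z.  One observed peak may
    serve several theoretical ions (they are reported independently).
    """
    mzs = observed.mzs
    out: list[tuple[FragmentIon, float]] = []
    if not mzs:
        return out
    for ion in theoretical:
        i = bisect.bisect_left(mzs, ion.mz)
        best: float | None = None
        for j in (i - 1, i):
            if 0 <= j < len(mzs):
                cand = mzs[j]
                if abs(cand - ion.mz) <= tol.window(ion.mz):
                    if (
                        best is None
                        or abs(cand - ion.mz) < abs(best - ion.mz)
                        or (abs(cand - ion.mz) == abs(best - ion.mz) and cand < best)
                    ):
                        best = cand
        if best is not None:
            out.append((ion, best))
    return out


@dataclass(frozen=True)
class MinSupport:
    """Minimum evidence for a LOCALIZED call: the non-call guard.

    A weak spectrum (few matched ions, or no shifted/unshifted ions at all)
    yields INCONSISTENT instead of a site.
    """

    min_matched: int = 4
    min_shifted: int = 1
    min_unshifted: int = 1

    def satisfied(self, m: LadderMatch) -> bool:
        return (
            m.matched >= self.min_matched
            and m.matched_shifted >= self.min_shifted
            and m.matched_unshifted >= self.min_unshifted
        )


def score_candidate(
    peptide: TrypticPeptide,
    delta: float,
    site: int,
    observed: PeakList,
    tol: MatchTolerance,
    max_charge: int = 1,
) -> LadderMatch:
    """Score one placement: consistent matches minus wrong-state matches."""
    plain = fragment_ladder(peptide, max_charge=max_charge)
    matched_ions: list[tuple[FragmentIon, float]] = []
    n_shift = n_unshift = n_contra = 0
    for ion in plain:
        contains = site in ion.contains_positions
        right_mz = ion.mz + (delta / ion.charge if contains else 0.0)
        wrong_mz = ion.mz + (0.0 if contains else delta / ion.charge)
        right_ion = FragmentIon(ion.series, ion.index, ion.charge, right_mz, ion.contains_positions)
        hit = match_peaks([right_ion], observed, tol)
        if hit:
            matched_ions.append(hit[0])
            if contains:
                n_shift += 1
            else:
                n_unshift += 1
        else:
            wrong_ion = FragmentIon(ion.series, ion.index, ion.charge, wrong_mz, ion.contains_positions)
            if match_peaks([wrong_ion], observed, tol):
                n_contra += 1
    return LadderMatch(
        site=site,
        matched_unshifted=n_unshift,
        matched_shifted=n_shift,
        contradictions=n_contra,
        matched_ions=tuple(matched_ions),
    )


def localize_modification(
    peptide: TrypticPeptide,
    delta: float,
    candidates: Sequence[int],
    observed: PeakList,
    tol: MatchTolerance = MatchTolerance(),
    max_charge: int = 1,
    min_support: MinSupport = MinSupport(),
) -> LocalizationResult:
    """Rank candidate sites by ladder-walk score and call the modified residue."""
    if not candidates:
        raise ValueError("at least one candidate site required")
    for c in candidates:
        if not 1 <= c <= len(peptide):
            raise ValueError(f"candidate {c} outside peptide")
    ranking = sorted(
        (
            score_candidate(peptide, delta, c, observed, tol, max_charge)
            for c in candidates
        ),
        key=lambda m: (-m.score, m.site),
    )
    best = ranking[0]
    if not min_support.satisfied(best):
        status, best_site = LocalizationStatus.INCONSISTENT, None
    elif len(ranking) > 1 and ranking[1].score == best.score:
        status, best_site = LocalizationStatus.AMBIGUOUS, None
    else:
        status, best_site = LocalizationStatus.LOCALIZED, best.site
    return LocalizationResult(
        peptide=peptide,
        delta=delta,
        ranking=tuple(ranking),
        status=status,
        best_site=best_site,
    )


def discriminating_ions(
    peptide: TrypticPeptide,
    delta: float,
    site_a: int,
    site_b: int,
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Ions whose m/z differs between the two placements.

    These are exactly the ions containing one of the two sites but not the
    other; for distinct sites the list is never empty.
    """
    if site_a == site_b:
        raise ValueError("sites must differ")
    n = len(peptide)
    for s in (site_a, site_b):
        if not 1 <= s <= n:
            raise ValueError(f"site {s} outside peptide")
    out = []
    for ion in fragment_ladder(peptide, max_charge=max_charge):
        if (site_a in ion.contains_positions) != (site_b in ion.contains_positions):
            out.append(ion)
    return out


def matched_ion_table(result: LocalizationResult) -> "pd.DataFrame":
    """Matched-ion table for the best-ranked site (series, index, predicted,
    shifted?, observed), mirroring the supplementary-figure layout."""
    import pandas as pd

    best = result.ranking[0]
    rows = [
        {
            "series": ion.series,
            "index": ion.index,
            "charge": ion.charge,
            "predicted_mz": ion.mz,
            "shifted": best.site in ion.contains_positions,
            "observed_mz": obs,
        }
        for ion, obs in best.matched_ions
    ]
    return pd.DataFrame(rows)
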