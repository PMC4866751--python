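# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Sequence annotation

**Reference frame.** All site semantics are expressed in the coordinates of
a PerR-type reference sequence: the structural Zn²⁺ site is the four-Cys
cluster at positions 96, 99, 136 and 139 (two C-x-x-C motifs), and the
regulatory metal site is positions 37, 85, 91, 93 and 104 (His/Asp in PerR).
The packaged reference is a *synthetic* PerR-template sequence built by the
generator — a fixed neutral backbone with His37/Asp85/His91/His93/Asp104 and
the four Cys implanted — not a database sequence. Any real reference can be
supplied as a FASTA path (`annotate --reference`); using the synthetic
template guarantees the positional invariants by construction and keeps the
package free of third-party sequence data.

**Alignment.** Pairwise global alignment uses Biopython's `PairwiseAligner`
with BLOSUM62 and affine gap penalties (open 10, extend 0.5; a gap of
length k costs 10 + 0.5(k−1); terminal gaps charged like internal ones).
Among co-optimal alignments the engine's first traceback is taken, which is
deterministic for fixed inputs. The test suite checks optimal scores against
an independently written three-state (Gotoh) dynamic program on hundreds of
random short pairs. Percent identity is 100 × matches / alignment columns,
terminal gaps included — stated explicitly so the tests are exact. Published
identity values computed from multiple-sequence alignments can drift a point
or two from pairwise values; this module is pairwise only.

**Subtype rules.** The classifier is a fixed cascade over the residues
aligned to the reference positions: (1) Cys at the position aligned to
reference 85 (the Zur S-donor position — the cross-numbering from Zur's own
coordinates is resolved by the alignment, never assumed) together with a
non-His at 37 calls Zur-like; (2) otherwise a complete His triad at
37/91/93 calls PerR-like with Asp at 104 or Fur-like with Glu at 104 —
note a Glu replacing Asp85 with Asp retained at 104 still classifies
PerR-like, because the O-donor at 104 is the discriminating position;
(3) anything else, including an unknown residue `X` at a signature
position, is UNCLASSIFIED — the fallback is never an exception and never a
guess. `has_structural_site` requires all four structural positions to be
Cys.

**ε₂₈₀.** 5,500 M⁻¹cm⁻¹ per Trp plus 1,490 per Tyr, reduced-Cys convention
(no cystine term). The rule is additive under concatenation, which the
property tests exercise.

## Digestion and mass arithmetic

Trypsin cleaves C-terminal to Lys/Arg except before Pro. Zero-missed-
cleavage peptides are labelled T1…Tn from the N-terminus; missed-cleavage
products get compound labels "Tm-Tn"; a `*` is appended when a peptide
carries at least one carbamidomethylated Cys, following peptide-map
annotation practice for iodoacetamide-treated samples. The N-terminal
peptide always includes residue 1; no initiator-Met clipping is applied.

Masses are monoisotopic: residue masses from the standard table (via
pyteomics), water 18.010565 Da, proton 1.007276 Da — fixed constants so the
arithmetic is bit-reproducible. b_i is the sum of residues 1..i (+ mods)
plus a proton; y_i is the suffix sum plus water and a proton; charges z > 1
follow (m + z·proton)/z. Complementarity b_i + y_{n−i} = M + 2·proton holds
to 1e-9 Da and is tested on random peptides, as is agreement with
pyteomics' own mass calculator and cleavage function (independent routes).

Printed peptide-map values in MALDI spectra are interpreted as singly
protonated monoisotopic [M+H]⁺ and compared within ±0.3 Da; ESI precursor
values in tandem spectra are instrument-observed and are not used as exact
targets. Oxidation (+15.994915 Da) targets His and Met by default: Met is
the competing site every His-localization has to discriminate against.

## Ladder-walk site localization

For a peptide carrying a known mass shift δ, placing δ at site s shifts
exactly the ions whose residue span contains s. Each candidate is scored as
(ions matched in the state the placement predicts) − (ions matched in the
wrong state); matching takes the nearest observed peak within tolerance
(default 0.5 Da, appropriate for linear ion-trap fragment spectra; ppm mode
available), ties broken toward lower m/z. Intensities are never scored —
the published assignments argue from presence/absence of shifted ions —
only recorded for reporting.

Calls: a unique maximal score that meets minimum support (≥ 4 matched ions
including ≥ 1 shifted and ≥ 1 unshifted) is LOCALIZED; tied maxima are
surfaced as AMBIGUOUS, never broken silently; anything below minimum
support is INCONSISTENT. The non-call states are deliberate: weak spectra
must produce "could not be mapped", not a guess. Ion containment is always
computed from peptide coordinates; published figure annotations that
number ions inconsistently with the stated peptide boundaries are not
replicated.

Fragment charge states default to 1+ (the annotated b/y series in the
relevant figures are singly charged); 2+ is available.

## Zn-release kinetics

Model: single-exponential pseudo-first-order approach,
A(t) = baseline + plateau·(1 − e^(−k_obs·t)), justified because H₂O₂
(1–100 mM) exceeds protein (5 μM) by ≥ 200-fold, so [H₂O₂] is effectively
constant and k_obs = k₂[H₂O₂]. PAR binding is treated as instantaneous
relative to release (PAR at 100 μM is in ≥ 20-fold excess over releasable
Zn). The plateau converts to stoichiometry via Beer–Lambert with
ε₄₉₄ = 85,000 M⁻¹cm⁻¹ and 1 cm path.

Fit initialization: baseline from the first point, plateau from the signal
range, k_obs from ln 2 / t½ (time to half-range). An exactly flat trace is
reported as degenerate (k_obs = 0) rather than fitted.

**Identifiability guard.** When the observation window never approaches the
plateau (fitted k_obs·t_max < 1, i.e. less than ~63% of the asymptote
reached), plateau and k_obs are constrained only through their product and
the linearized covariance from the least-squares fit is meaningless — in
practice it can report absurdly small uncertainties on a runaway plateau.
Such fits keep their point estimates but report unknown (infinite)
standard errors. The through-origin regression of k_obs on [H₂O₂] then
weights by 1/SE² over points with usable uncertainties, falling back to an
unweighted slope (dominated, correctly, by the best-determined highest
concentration) when fewer than two remain. The origin is forced because the
0 mM control shows no detectable release; a free-intercept mode exists as a
diagnostic only in the sense that the regression inputs are exposed.

Each protein series is fitted independently; no pooling across proteins.
Baseline is an explicit fit parameter, so modest offsets in real traces are
absorbed rather than biasing the plateau.

## DNA binding

Single-site isotherm θ(P) = P/(P + K_d), Hill coefficient fixed at 1, no
ligand depletion (trace-labelled probe far below K_d) — both assumptions
are recorded in the fit report. The fit requires ≥ 4 points and rejects
all-bound or all-free titrations as non-identifiable instead of returning a
boundary estimate. K_d is apparent, on the protein-concentration basis as
supplied (monomer vs dimer bookkeeping is the caller's).

## Synthetic generators

All generators take a mandatory integer seed through
`numpy.random.default_rng`; identical seeds give identical output on any
platform.

*Sequences.* A fixed neutral template backbone (150 residues) carries the
implanted site residues at the canonical reference positions; per seed, 30%
of non-site positions are resampled. The background alphabet excludes
C/H/D/E so no accidental Cys motifs or His/Asp/Glu signatures arise, and
the mutation load keeps the alignment to the reference gap-free, making the
position mapping exact by construction. The real *B. licheniformis*
sequences are not embedded; `furkit.fetch` documents the genome accession
(AE017333) and retrieves them when a network is available.

*Spectra.* A coverage fraction of the shifted-ladder ions, Gaussian m/z
jitter, plus uniform noise peaks across the m/z range. No intensity model,
no isotope envelopes, no neutral losses — passing localization tests shows
robustness to missing ions and random peaks, not to realistic intensity
structure or co-eluting peptides.

*Kinetics / binding.* Defaults are the assay protocol: 0/1/10/100 mM H₂O₂,
5 μM protein, 1 s sampling for 1800 s, Gaussian noise 0.002 AU; EMSA as an
8-point 2-fold titration from 10 to 1280 nM with 10% multiplicative noise.
Gaussian iid noise does not emulate baseline drift, mixing dead time, or
gel-quantification nonlinearity.

## Problem sizes

The bundled checks use 20 replicate kinetics series per rate constant, 50
replicate titrations, 500 seeded localization trials for oracle equivalence
and 500 for noise robustness, 1,000 random peptides for the mass-arithmetic
invariants, and 200 random pairs for the alignment-score oracle; these
sizes give stable estimates (the stochastic recoveries reproduce their
generating values to well within the stated 5–15% tolerances) while keeping
the default suite fast.

## Known limitations

* Subtype classification reads nine alignment positions; it is a signature
  check, not a profile or HMM search, and degrades with remote homologs
  whose alignment to the reference frame is unreliable.
* Percent identities are pairwise; values printed alongside multiple
  alignments can differ by a point or two.
* Localization treats candidate placements one at a time; peptides carrying
  two simultaneous oxidations are out of scope.
* The kinetics model is single-exponential with a single class of Zn sites;
  multi-phasic release would be mis-fit and should be caught by inspecting
  residuals, which the fit report does not automate.
* The worked-example checks on the real database sequences require network
  access to fetch them; offline runs exercise every code path on synthetic
  stand-ins (so named in ids and docstrings) instead.
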