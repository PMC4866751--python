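# furkit

Analysis toolkit for Fur-family metalloregulators — the bacterial
transcription factors (Fur, Zur, PerR and relatives) that sense iron, zinc
or peroxide through metal sites in a winged-helix dimer. The package covers
the biochemical workflow used to characterize such proteins:

* **Sequence annotation** — pairwise global alignment onto a PerR reference
  frame, extraction of the residues at the structural Zn²⁺ site (four Cys in
  two C-x-x-C motifs, reference positions 96/99/136/139) and the regulatory
  metal site (positions 37/85/91/93/104), rule-based subtype classification
  (PerR-like / Fur-like / Zur-like), percent-identity matrices, and
  Trp/Tyr-based ε₂₈₀ coefficients.
* **In-silico tryptic digestion** — K/R cleavage (not before Pro), ordinal
  peptide labels T1…Tn, monoisotopic masses, precursor m/z, fixed Cys
  carbamidomethylation (+57.0215 Da) and variable His/Met oxidation
  (+15.9949 Da).
* **Oxidation-site localization** — b/y fragment-ion ladder walking: for a
  peptide with a +16 Da shift, each candidate residue splits the ladder into
  shifted and unshifted ions; candidates are scored by consistent minus
  contradicting matches against an observed MGF peak list, with explicit
  AMBIGUOUS / INCONSISTENT non-calls.
* **Zn-release kinetics** — PAR (4-(2-pyridylazo)resorcinol) reports released
  Zn²⁺ at 494 nm (ε = 85,000 M⁻¹cm⁻¹). Traces follow the pseudo-first-order
  model A(t) = baseline + plateau·(1 − e^(−k_obs·t)) with k_obs = k₂[H₂O₂];
  a through-origin regression of k_obs on [H₂O₂] yields the second-order rate
  constant k₂, and plateau / (ε·l·[protein]) yields the Zn stoichiometry.
* **DNA binding** — apparent K_d from EMSA titrations under the single-site
  isotherm θ(P) = P / (P + K_d).
* **Synthetic data** — seeded generators for every input (signature-implanted
  sequences, jittered fragment ladders, noisy kinetics traces, binding
  titrations), so the whole pipeline runs and is tested with no downloads.

## Worked example

```python
from furkit import *
from furkit.synthetic_data import (
    GeneratorConfig, make_kinetics_dataset, make_emsa_dataset,
    make_fur_family_sequence, default_reference_scheme,
)
from furkit.zinc_kinetics import fit_release_series
from furkit.dna_binding import fit_kd

cfg = GeneratorConfig(seed=11, k2=0.03, zn_content=0.8)   # study conditions
fit = fit_release_series(make_kinetics_dataset(cfg))
print(f"k2 = {fit.k2:.4f} M^-1 s^-1   Zn content = {fit.zn_content:.3f} mol/mol")

bfit = fit_kd(make_emsa_dataset(cfg))
print(f"apparent Kd = {bfit.kd_apparent*1e9:.1f} nM")

rec = make_fur_family_sequence("ZUR_LIKE", seed=11)
call = classify_subtype(extract_site_profile(rec, default_reference_scheme()))
print(call.subtype.value, call.has_structural_site)
```

prints

```
k2 = 0.0300 M^-1 s^-1   Zn content = 0.800 mol/mol
apparent Kd = 69.5 nM
ZUR_LIKE True
```

i.e. the kinetics stage recovers the generating rate constant
(0.03 M⁻¹s⁻¹) and stoichiometry (0.8 Zn per monomer) from the noisy
0/1/10/100 mM H₂O₂ trace series, the binding stage recovers the 70 nM
affinity from an 8-point titration with 10% noise, and a sequence generated
with the Zur signature (S-donor Cys aligned to reference position 85, no
His at position 37) is classified back as Zur-like with its four-Cys
structural site intact.

The same stages are available from the shell:

```sh
furkit simulate --seed 7 --out bundle        # synthetic FASTA/MGF/CSV bundle
furkit run --input bundle --out results      # annotate→digest→localize→fit
furkit digest --fasta proteins.fasta --cam --out peptides.tsv
furkit localize --peptide AGLSTVFNQWMAHGLSTVFNK --candidates H,M \
       --mgf spectrum.mgf --tol 0.5
```

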