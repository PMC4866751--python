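"""End-to-end pipeline: simulate a fixture bundle, then run every stage.

``simulate_bundle`` writes a self-describing directory (FASTA, MGF,
kinetics CSVs, EMSA CSV, manifest.json with the seed and parameters);
``run_pipeline`` executes annotate -> digest -> localize -> kinetics ->
binding over such a bundle and writes one JSON summary.  With identical
inputs and seed the summary is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as fio
from .config import PipelineConfig
from .dna_binding import fit_kd
from .mass_digest import OXIDATION, TrypticPeptide, digest_trypsin, peptide_table
from .seq_annotation import ReferenceScheme, annotate_record, identity_matrix, read_fasta, write_fasta
from .site_localization import MatchTolerance, localize_modification
from .synthetic_data import (
    GeneratorConfig,
    Subtype,
    default_reference_scheme,
    make_emsa_dataset,
    make_fur_family_sequence,
    make_kinetics_dataset,
    make_peptide_spectrum,
)
from .zinc_kinetics import estimate_zn_content, fit_release_series

log = logging.getLogger("furkit")


def simulate_bundle(out_dir: str | Path, seed: int = 0, config: GeneratorConfig | None = None) -> Path:
    """Write a complete synthetic fixture bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or GeneratorConfig(seed=seed)

    records = [
        make_fur_family_sequence(subtype, seed=seed + i)
        for i, subtype in enumerate((Subtype.PERR_LIKE, Subtype.FUR_LIKE, Subtype.ZUR_LIKE))
    ]
    write_fasta(records, out / "proteins.fasta")

    # one oxidized-peptide spectrum per His-containing tryptic peptide of the
    # first (PerR-like) protein, true site = the His position
    spectra = []
    spectrum_meta = []
    for pep in digest_trypsin(records[0]):
        his = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "H"]
        if not his or len(pep) < 6:
            continue
        true_site = his[0]
        spec = make_peptide_spectrum(
            pep, true_site, OXIDATION.delta_mono,
            coverage=0.9, jitter=0.02, n_noise=3, seed=seed + pep.start,
        )
        spectra.append(spec)
        candidates = sorted(
            i + 1 for i, aa in enumerate(pep.sequence) if aa in OXIDATION.targets
        )
        spectrum_meta.append(
            {
                "title": spec.title,
                "parent_id": pep.parent_id,
                "label": pep.label,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "candidates": candidates,
                "true_site": true_site,
            }
        )
    fio.write_mgf(spectra, out / "spectra.mgf")

    kin_dir = out / "kinetics"
    kin_dir.mkdir(exist_ok=True)
    for i, trace in enumerate(make_kinetics_dataset(config)):
        fio.write_trace_csv(trace, kin_dir / f"trace_{i}.csv")

    fio.write_titration_csv(make_emsa_dataset(config), out / "emsa.csv")

    manifest = {
        "seed": seed,
        "generator": {
            "k2": config.k2,
            "zn_content": config.zn_content,
            "protein_conc": config.protein_conc,
            "h2o2_concs": list(config.h2o2_concs),
            "noise_sd": config.noise_sd,
            "kd": config.kd,
            "emsa_concs": list(config.emsa_concs),
            "emsa_noise": config.emsa_noise,
        },
        "spectra": spectrum_meta,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """annotate -> digest -> localize -> kinetics -> binding on a bundle."""
    bundle = Path(config.input_dir)
    out = Path(config.output_dir)
    if not bundle.is_dir():
        raise FileNotFoundError(f"input bundle {bundle} is not a directory")
    out.mkdir(parents=True, exist_ok=True)

    if config.reference_fasta:
        scheme = ReferenceScheme(reference=read_fasta(config.reference_fasta)[0])
    else:
        scheme = default_reference_scheme()

    summary: dict = {"seed": config.seed}

    stage = "annotate"
    try:
        records = read_fasta(bundle / "proteins.fasta")
        summary["annotation"] = [annotate_record(r, scheme) for r in records]
        if len(records) >= 2:
            mat = identity_matrix(records)
            mat.to_csv(out / "identity_matrix.tsv", sep="\t")
            summary["identity_matrix"] = {
                "ids": list(mat.index),
                "values": [[round(v, 2) for v in row] for row in mat.to_numpy().tolist()],
            }

        stage = "digest"
        tables = [peptide_table(r) for r in records]
        for r, table in zip(records, tables):
            table.to_csv(out / f"peptides_{r.id}.tsv", sep="\t", index=False)
        summary["peptides"] = {
            r.id: int(len(table)) for r, table in zip(records, tables)
        }

        stage = "localize"
        manifest = json.loads((bundle / "manifest.json").read_text())
        spectra = {s.title: s for s in fio.read_mgf(bundle / "spectra.mgf")}
        calls = []
        for meta in manifest.get("spectra", []):
            pep = TrypticPeptide(
                parent_id=meta["parent_id"],
                label=meta["label"],
                start=meta["start"],
                end=meta["end"],
                sequence=meta["sequence"],
            )
            result = localize_modification(
                pep,
                config.oxidation_delta,
                meta["candidates"],
                spectra[meta["title"]],
                MatchTolerance("Da", config.tolerance_da),
            )
            calls.append(
                {
                    "title": meta["title"],
                    "status": result.status.value,
                    "best_site": result.best_site,
                    "scores": {str(m.site): m.score for m in result.ranking},
                }
            )
        summary["localization"] = calls

        stage = "kinetics"
        traces = [
            fio.read_trace_csv(p)
            for p in sorted(bundle.glob("kinetics/trace_*.csv"))
        ]
        if traces:
            fit = fit_release_series(traces)
            summary["kinetics"] = {
                "k2_M1s1": fit.k2,
                "k2_se": fit.k2_se,
                "zn_content_per_monomer": fit.zn_content,
                "k_obs_per_trace": {
                    f"{c:g}": f.k_obs for c, f in fit.trace_fits if not f.degenerate
                },
            }

        stage = "binding"
        emsa = bundle / "emsa.csv"
        if emsa.exists():
            bfit = fit_kd(fio.read_titration_csv(emsa))
            summary["binding"] = {
                "kd_apparent_M": bfit.kd_apparent,
                "kd_se": bfit.kd_se,
                "model": bfit.model,
                "assumptions": list(bfit.assumptions),
            }
    except Exception as err:
        # partial outputs stay in place; the failure names its stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
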