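"""Format round-tripping: MGF peak lists, kinetics CSV, titration CSV.

FASTA lives in :mod:`furkit.seq_annotation` (read_fasta / write_fasta).
The MGF dialect is one spectrum per BEGIN IONS block with TITLE, PEPMASS
and CHARGE ("2+" style) headers.  Kinetics traces are two-column CSVs
(time_s, a494) with a YAML sidecar for the concentrations; titrations are
two-column CSVs (protein_conc_M, fraction_bound).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .dna_binding import TitrationPoint
from .site_localization import PeakList
from .zinc_kinetics import KineticTrace


def read_mgf(path: str | Path) -> list[PeakList]:
    """All spectra from an MGF file, TITLE/PEPMASS/CHARGE honored."""
    spectra: list[PeakList] = []
    with _mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge", [0])
            spectra.append(
                PeakList(
                    peaks=tuple(
                        (float(m), float(i))
                        for m, i in zip(spec["m/z array"], spec["intensity array"])
                    ),
                    precursor_mz=float(pepmass[0]) if pepmass[0] else 0.0,
                    precursor_charge=int(charge[0]) if charge else 0,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[PeakList], path: str | Path) -> None:
    entries = []
    for spec in spectra:
        entries.append(
            {
                "m/z array": np.array([p[0] for p in spec.peaks]),
                "intensity array": np.array([p[1] for p in spec.peaks]),
                "params": {
                    "title": spec.title,
                    "pepmass": spec.precursor_mz,
                    "charge": f"{spec.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    """Trace as CSV plus a YAML sidecar (<path>.yaml) with the conditions."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "a494": trace.a494}).to_csv(path, index=False)
    sidecar = {
        "protein_conc_M": float(trace.protein_conc),
        "h2o2_conc_M": float(trace.h2o2_conc),
        "path_length_cm": float(trace.path_length),
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_trace_csv(path: str | Path) -> KineticTrace:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    return KineticTrace(
        time=df["time_s"].to_numpy(float),
        a494=df["a494"].to_numpy(float),
        protein_conc=float(sidecar["protein_conc_M"]),
        h2o2_conc=float(sidecar["h2o2_conc_M"]),
        path_length=float(sidecar.get("path_length_cm", 1.0)),
    )


def write_titration_csv(points: Sequence[TitrationPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_conc_M": [p.protein_conc for p in points],
            "fraction_bound": [p.fraction_bound for p in points],
        }
    ).to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> list[TitrationPoint]:
    df = pd.read_csv(path)
    return [
        TitrationPoint(float(c), float(f))
        for c, f in zip(df["protein_conc_M"], df["fraction_bound"])
    ]
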