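"""Helper for obtaining the real B. licheniformis Fur-family sequences.

The five proteins analysed in the worked examples are the locus tags
BL00075 (PerR), BL03703 (Zur), BL05249 (Fur), BL00690 (PerR2) and BL00950
(PerR3) from the *Bacillus licheniformis* ATCC 14580 genome (GenBank
AE017333 / RefSeq NC_006322).  They are deliberately not shipped with the
package; this helper fetches them from NCBI when a network is available.
All tests run on synthetic fixtures instead.
"""

from __future__ import annotations

import io as _io
import json
import urllib.parse
import urllib.request

from .seq_annotation import ProteinRecord, SequenceError

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
GENOME_ACCESSION = "AE017333"
LOCUS_TAGS = ("BL00075", "BL03703", "BL05249", "BL00690", "BL00950")


def fetch_locus_protein(locus_tag: str, timeout: float = 15.0) -> ProteinRecord:
    """Fetch one protein sequence by locus tag via NCBI E-utilities.

    Raises URLError/HTTPError when offline; callers should treat that as
    "worked examples unavailable", not as a pipeline failure.
    """
    query = urllib.parse.quote(f"{locus_tag}[Gene Name] AND Bacillus licheniformis[Organism]")
    search_url = f"{EUTILS}/esearch.fcgi?db=protein&retmode=json&term={query}"
    with urllib.request.urlopen(search_url, timeout=timeout) as resp:
        ids = json.load(resp)["esearchresult"]["idlist"]
    if not ids:
        raise SequenceError(f"no protein record found for locus tag {locus_tag}")
    fetch_url = f"{EUTILS}/efetch.fcgi?db=protein&rettype=fasta&retmode=text&id={ids[0]}"
    with urllib.request.urlopen(fetch_url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = text.strip().splitlines()
    sequence = "".join(lines[1:]).upper()
    return ProteinRecord(id=locus_tag, sequence=sequence, description=lines[0][1:])


def fetch_all(timeout: float = 15.0) -> list[ProteinRecord]:
    """All five Fur-family proteins (network required)."""
    return [fetch_locus_protein(tag, timeout=timeout) for tag in LOCUS_TAGS]
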