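#!/usr/bin/env python
"""Download the published catalytic-subunit accession sequences from NCBI.

Writes data/table2_sequences.fasta with the protein sequences whose
pairwise identity/similarity values are checked in
tests/test_acceptance.py. Requires network access; the library itself
never fetches anything.

Usage: python scripts/fetch_reference_sequences.py
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# accession -> (species, note)
ACCESSIONS = {
    "NP_002721.1": ("Homo sapiens", "PKA Calpha"),
    "P22694.2": ("Homo sapiens", "PKA Cbeta"),
    "NP_476977.1": ("Drosophila melanogaster", "PKA-C1"),
    "PX409858": ("Gecarcinus lateralis", "PKA-C_1"),
    "PX409857": ("Carcinus maenas", "PKA-C_GLY2"),
    "XP_070000929.1": ("Penaeus vannamei", "PKA-C_GLY1"),
}


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode({
        "db": "protein", "id": accession, "rettype": "fasta",
        "retmode": "text"})
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    out = Path(__file__).resolve().parent.parent / "data"
    out.mkdir(exist_ok=True)
    target = out / "table2_sequences.fasta"
    chunks = []
    for accession, (species, note) in ACCESSIONS.items():
        print(f"fetching {accession} ({species} {note}) ...", flush=True)
        raw = fetch(accession).strip()
        if not raw.startswith(">"):
            print(f"  unexpected response for {accession}", file=sys.stderr)
            return 1
        # normalize the header to the bare accession + metadata dialect
        lines = raw.splitlines()
        lines[0] = f">{accession} species={species}"
        chunks.append("\n".join(lines))
        time.sleep(0.4)  # NCBI rate courtesy
    target.write_text("\n".join(chunks) + "\n", encoding="utf-8")
    print(f"wrote {target}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
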