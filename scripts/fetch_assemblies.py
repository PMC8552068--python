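#!/usr/bin/env python
"""Download the public genome assemblies used by the genome-level checks
into ``data/assemblies/`` (one .fna and one .gff per accession).

Requires network access to the NCBI Datasets API. Run once from the
repository root:

    python scripts/fetch_assemblies.py
"""

from __future__ import annotations

import io
import shutil
import sys
import urllib.request
import zipfile
from pathlib import Path

ACCESSIONS = [
    "GCA_003047065.1",  # L. acidophilus
    "GCA_000010005.1",  # L. reuteri
    "GCA_000022965.1",  # B. animalis subsp. lactis
    "GCA_900637145.1",  # B. breve
]

API = (
    "https://api.ncbi.nlm.nih.gov/datasets/v2alpha/genome/accession/"
    "{acc}/download?include_annotation_type=GENOME_FASTA,GENOME_GFF"
)

OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "assemblies"


def fetch(accession: str) -> None:
    url = API.format(acc=accession)
    print(f"fetching {accession} ...", flush=True)
    with urllib.request.urlopen(url, timeout=300) as resp:
        payload = resp.read()
    with zipfile.ZipFile(io.BytesIO(payload)) as zf:
        for name in zf.namelist():
            if name.endswith(".fna"):
                suffix = "fna"
            elif name.endswith(".gff"):
                suffix = "gff"
            else:
                continue
            dest = OUT_DIR / f"{accession}.{suffix}"
            with zf.open(name) as src, open(dest, "wb") as out:
                shutil.copyfileobj(src, out)
            print(f"  wrote {dest}")


def main() -> int:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    failures = []
    for acc in ACCESSIONS:
        try:
            fetch(acc)
        except Exception as exc:  # noqa: BLE001 - report and continue
            print(f"  FAILED for {acc}: {exc}", file=sys.stderr)
            failures.append(acc)
    for acc in ACCESSIONS:
        for suffix in ("fna", "gff"):
            path = OUT_DIR / f"{acc}.{suffix}"
            status = "ok" if path.exists() else "MISSING"
            print(f"{path}: {status}")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
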