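#!/usr/bin/env python
"""Fetch the deposited reference data used by the accession-based analyses.

Downloads the four deposited atomic models (mmCIF) and four shell-protein
sequences (FASTA) into ``data/deposited`` and ``data/sequences`` under the
repository root.  Requires network access; all downstream code works on
synthetic data without it.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shellkit.datasets import DEPOSITED_MODELS, SEQUENCES, data_dir

RCSB_URL = "https://files.rcsb.org/download/{acc}.cif"
UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch(url: str, dest: Path) -> None:
    if dest.exists():
        print(f"  {dest} exists, skipping")
        return
    print(f"  {url} -> {dest}")
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=120) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    root = data_dir()
    print(f"data dir: {root}")
    failures = []
    for acc in DEPOSITED_MODELS:
        try:
            fetch(RCSB_URL.format(acc=acc), root / "deposited" / f"{acc}.cif")
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append((acc, str(exc)))
    for acc in SEQUENCES:
        try:
            fetch(UNIPROT_URL.format(acc=acc), root / "sequences" / f"{acc}.fasta")
        except Exception as exc:  # noqa: BLE001
            failures.append((acc, str(exc)))
    if failures:
        print("FAILED:")
        for acc, err in failures:
            print(f"  {acc}: {err}")
        return 1
    print("all reference data fetched")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
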