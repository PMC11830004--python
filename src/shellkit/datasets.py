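"""Locations of optional deposited reference data.

The deposited atomic models (PDB 7P1T, 9GOT, 9HQ7, 9HQC) and shell-protein
sequences (UniProt O07181, Q9WZP2, K5BEG2, B2HH42) are not redistributed
with the package; ``scripts/fetch_data.py`` downloads them into
``data/deposited`` and ``data/sequences`` under the repository root (or
``$SHELLKIT_DATA_DIR``).  Analyses that need them raise
:class:`MissingDataError` with fetch instructions when the files are
absent.
"""

from __future__ import annotations

import os
from pathlib import Path

__all__ = [
    "MissingDataError",
    "data_dir",
    "deposited_model_path",
    "sequence_path",
    "load_deposited_model",
    "load_sequence",
    "DEPOSITED_MODELS",
    "SEQUENCES",
]

#: PDB accessions of the complete shell and the three intermediates.
DEPOSITED_MODELS = {
    "7P1T": "complete 60-subunit shell",
    "9GOT": "48-subunit intermediate",
    "9HQ7": "52-subunit intermediate",
    "9HQC": "54-subunit intermediate",
}

#: UniProt accessions of the shell-protein sequences.
SEQUENCES = {
    "O07181": "M. tuberculosis Enc",
    "B2HH42": "M. marinum Enc",
    "K5BEG2": "M. hassiacum Enc",
    "Q9WZP2": "T. maritima Enc",
}


class MissingDataError(FileNotFoundError):
    """Deposited reference data has not been fetched into the data dir."""


def data_dir() -> Path:
    env = os.environ.get("SHELLKIT_DATA_DIR")
    if env:
        return Path(env)
    return Path(__file__).resolve().parents[2] / "data"


def deposited_model_path(accession: str) -> Path:
    return data_dir() / "deposited" / f"{accession.upper()}.cif"


def sequence_path(accession: str) -> Path:
    return data_dir() / "sequences" / f"{accession.upper()}.fasta"


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingDataError(
            f"{what} not found at {path}; run `python scripts/fetch_data.py` "
            "(network required) or set SHELLKIT_DATA_DIR"
        )
    return path


def load_deposited_model(accession: str):
    from shellkit.structure_io import load_shell_model

    path = _require(deposited_model_path(accession), f"deposited model {accession}")
    return load_shell_model(path, format="mmcif")


def load_sequence(accession: str) -> str:
    path = _require(sequence_path(accession), f"sequence {accession}")
    lines = path.read_text().splitlines()
    return "".join(l.strip() for l in lines if l and not l.startswith(">"))
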