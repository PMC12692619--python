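"""Protein sequence records, FASTA I/O and mature-sequence handling.

Coordinates are 1-based and inclusive throughout the package, matching the
convention of epitope tables ("38~45" means residues 38..45 including both).
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard one-letter residue codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes collapsed to X at parse time (no propensity-scale value exists).
AMBIGUOUS_AA = "UBZJO"

_VALID = set(STANDARD_AA) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``residues`` is an uppercase string over the 20 standard one-letter codes
    plus ``X`` for positions with no defined identity.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in _VALID]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"record {self.id!r}: invalid residue {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(
                f"interval {start}..{end} outside sequence of length {len(self)}"
            )
        return self.residues[start - 1 : end]


def _clean(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("*", "")
    mapped = []
    for i, c in enumerate(seq):
        if c in AMBIGUOUS_AA:
            log.warning("record %s: ambiguous residue %s at %d mapped to X",
                        record_id, c, i + 1)
            mapped.append("X")
        else:
            mapped.append(c)
    return "".join(mapped)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Residues are uppercased; the ambiguity letters U/B/Z/J/O are mapped to X
    with a logged warning.  Any other non-amino-acid character raises a
    ``ValueError`` naming the record and position.  An empty file is an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _clean(str(rec.seq), rec.id)
        records.append(ProteinRecord(id=rec.id, residues=residues,
                                     description=rec.description))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def mature_sequence(record: ProteinRecord, signal_end: int) -> ProteinRecord:
    """Strip an N-terminal signal peptide ending at ``signal_end`` (1-based).

    ``signal_end = 0`` returns the record unchanged; ``signal_end`` must be
    strictly less than the sequence length so a non-empty mature chain remains.
    """
    n = len(record)
    if not 0 <= signal_end < n:
        raise ValueError(
            f"signal_end={signal_end} out of range for length-{n} sequence"
        )
    if signal_end == 0:
        return record
    return ProteinRecord(
        id=record.id,
        residues=record.residues[signal_end:],
        description=record.description,
    )


def fetch_uniprot_fasta(accessions: Iterable[str], timeout: float = 30.0,
                        ) -> list[ProteinRecord]:
    """Fetch sequences from UniProtKB by accession (requires network access).

    Intended for pulling reference allergen sequences; results should be cached
    to a local FASTA for offline reuse.
    """
    records = []
    for acc in accessions:
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
        lines = text.strip().splitlines()
        if not lines or not lines[0].startswith(">"):
            raise ValueError(f"{acc}: unexpected UniProt response")
        seq = _clean("".join(lines[1:]), acc)
        records.append(ProteinRecord(id=acc, residues=seq,
                                     description=lines[0][1:]))
    return records
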