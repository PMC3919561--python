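"""Protein records and FASTA I/O.

Sequences are uppercase strings over the 20 canonical amino acids.  Record
ids are the first whitespace-delimited token of the FASTA header; the taxon
a record belongs to is carried alongside the sequence because every search
in the pipeline is organized per proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)

__all__ = ["AMINO_ACIDS", "ProteinRecord", "read_fasta", "write_fasta", "read_proteome_dir"]


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    taxon_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.protein_id!r}: unknown residues {sorted(bad)} "
                f"(expected the 20-letter amino-acid alphabet)")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path, taxon_id: str, wildcard: str | None = None) -> list:
    """Read one proteome FASTA.

    ``wildcard``: if given, residues outside the 20-letter alphabet are
    replaced by this character instead of being rejected (it must itself be
    a canonical residue used as a neutral stand-in).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if wildcard is not None:
            seq = "".join(c if c in _AA_SET else wildcard for c in seq)
        records.append(ProteinRecord(rec.id, taxon_id, seq))
    return records


def write_fasta(path, records: Iterable[ProteinRecord]) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_proteome_dir(directory, taxa: Iterable[str] | None = None,
                      wildcard: str | None = None) -> dict:
    """Read ``<taxon>.fa`` / ``<taxon>.fasta`` files from a directory."""
    directory = Path(directory)
    proteomes: dict = {}
    paths = sorted(list(directory.glob("*.fa")) + list(directory.glob("*.fasta")))
    for p in paths:
        taxon = p.stem
        if taxa is not None and taxon not in set(taxa):
            continue
        proteomes[taxon] = read_fasta(p, taxon, wildcard=wildcard)
    return proteomes
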