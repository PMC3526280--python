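"""Genome container and FASTA I/O.

Genomes are strictly A/C/G/T: ambiguity codes belong in motifs, not in the
reference sequence, so they are rejected at parse time with the offending
contig and offset. Coordinates are 0-based internally; file formats written
elsewhere in the package use 1-based coordinates (GFF3 convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GENOME_ALPHABET = frozenset("ACGT")


class FastaError(ValueError):
    """Malformed FASTA input (bad record, duplicate id or disallowed character)."""


@dataclass
class GenomeSequence:
    """An ordered collection of named contigs over the {A,C,G,T} alphabet.

    Parameters
    ----------
    contigs
        Ordered ``(id, sequence)`` pairs. Ids must be unique and non-empty,
        sequences non-empty and free of ambiguity codes.
    circular
        Per-contig circularity flags keyed by contig id. Contigs default to
        linear; circular contigs let motif scans wrap across the origin.
    """

    contigs: list[tuple[str, str]]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if not cid:
                raise FastaError("contig id must be non-empty")
            if cid in seen:
                raise FastaError(f"duplicate contig id {cid!r}")
            seen.add(cid)
            if not seq:
                raise FastaError(f"contig {cid!r} has empty sequence")
            bad = next((i for i, c in enumerate(seq) if c not in _GENOME_ALPHABET), None)
            if bad is not None:
                raise FastaError(
                    f"contig {cid!r} contains disallowed character "
                    f"{seq[bad]!r} at offset {bad} (genomes must be A/C/G/T)"
                )
        for cid in self.circular:
            if cid not in seen:
                raise FastaError(f"circularity flag for unknown contig {cid!r}")

    # -- mapping-style helpers -------------------------------------------

    def ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def seq(self, contig_id: str) -> str:
        for cid, s in self.contigs:
            if cid == contig_id:
                return s
        raise KeyError(contig_id)

    def length(self, contig_id: str) -> int:
        return len(self.seq(contig_id))

    def is_circular(self, contig_id: str) -> bool:
        return self.circular.get(contig_id, False)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return self.contigs == other.contigs and all(
            self.is_circular(c) == other.is_circular(c) for c in self.ids()
        )


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a genome from FASTA, validating the A/C/G/T alphabet.

    Sequences are uppercased before validation; any remaining non-ACGT
    character (including N) raises :class:`FastaError` naming the contig
    and 0-based offset.
    """
    contigs: list[tuple[str, str]] = []
    with open(path) as handle:
        head = handle.read(1)
        if head == "":
            raise FastaError(f"{path}: empty file")
        if head != ">":
            raise FastaError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            contigs.append((rec.id, str(rec.seq).upper()))
    if not contigs:
        raise FastaError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs=contigs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    """Write a genome to FASTA (wrap at ``width`` columns). Round-trips with
    :func:`read_fasta` on both ids and sequences."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs
    ]
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
    os.replace(tmp, path)
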