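"""IUPAC motif algebra and genome scanning.

A methyltransferase recognition motif is a degenerate IUPAC string with a
marked methylated offset and a modification type (m6A, m4C or m5C).
Bipartite (Type I style) motifs are ordinary IUPAC strings containing an
internal run of >=4 N's separating two specific half-sites; no special dyad
type is used.

Strand convention: a site's strand is the strand carrying the methylated
base, and the pattern is always read 5'->3' on that strand. A minus-strand
match is therefore a forward-strand match of the reverse-complement
pattern, with the methylated offset mapped back to duplex coordinates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from kinmeth.genome import GenomeSequence

IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "M": "K", "K": "M", "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class MotifError(ValueError):
    """Invalid IUPAC pattern or motif definition."""


def _check_pattern(pattern: str) -> None:
    for i, c in enumerate(pattern):
        if c not in IUPAC_TO_BASES:
            raise MotifError(f"invalid IUPAC code {c!r} at position {i} in {pattern!r}")


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC string (an involution)."""
    _check_pattern(pattern)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def expand_iupac(pattern: str, max_size: int = 4096) -> set[str]:
    """Expand a degenerate pattern into the set of concrete A/C/G/T strings.

    The expansion is exactly the Cartesian product of per-position base
    sets; ``max_size`` guards against combinatorial blow-up.
    """
    _check_pattern(pattern)
    size = 1
    for c in pattern:
        size *= len(IUPAC_TO_BASES[c])
        if size > max_size:
            raise MotifError(
                f"expansion of {pattern!r} exceeds max_size={max_size}"
            )
    sets = [sorted(IUPAC_TO_BASES[c]) for c in pattern]
    return {"".join(p) for p in itertools.product(*sets)}


def _n_run(pattern: str) -> tuple[int, int] | None:
    """Longest internal maximal run of N's, as (start, length); None if < 4."""
    best: tuple[int, int] | None = None
    for m in re.finditer(r"N+", pattern):
        start, length = m.start(), m.end() - m.start()
        if start == 0 or m.end() == len(pattern):
            continue  # flanking N's are not a spacer
        if best is None or length > best[1]:
            best = (start, length)
    if best is not None and best[1] >= 4:
        return best
    return None


@dataclass(frozen=True)
class IupacMotif:
    """A recognition motif: degenerate pattern + methylated offset + mod type.

    ``methylated_offset`` is the 0-based index of the methylated base in the
    pattern; its code must be compatible with A for m6A and with C for
    m4C/m5C.
    """

    pattern: str
    methylated_offset: int
    mod_type: str = "m6A"
    name: str | None = None

    def __post_init__(self) -> None:
        _check_pattern(self.pattern)
        if len(self.pattern) < 2:
            raise MotifError(f"pattern {self.pattern!r} shorter than 2")
        if not 0 <= self.methylated_offset < len(self.pattern):
            raise MotifError(
                f"methylated_offset {self.methylated_offset} outside {self.pattern!r}"
            )
        if self.mod_type not in ("m6A", "m4C", "m5C"):
            raise MotifError(f"unknown mod_type {self.mod_type!r}")
        target = "A" if self.mod_type == "m6A" else "C"
        code = self.pattern[self.methylated_offset]
        if target not in IUPAC_TO_BASES[code]:
            raise MotifError(
                f"code {code!r} at methylated_offset is incompatible with "
                f"{target} required by {self.mod_type}"
            )
        run = _n_run(self.pattern)
        if run is not None:
            start, length = run
            if start < 2 or len(self.pattern) - (start + length) < 2:
                raise MotifError(
                    f"bipartite motif {self.pattern!r} needs half-sites of length >= 2"
                )

    @property
    def is_bipartite(self) -> bool:
        return _n_run(self.pattern) is not None

    def half_sites(self) -> tuple[str, int, str] | None:
        """(left half, spacer length, right half) for bipartite motifs, else None."""
        run = _n_run(self.pattern)
        if run is None:
            return None
        start, length = run
        return self.pattern[:start], length, self.pattern[start + length:]

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return f"{self.pattern}@{self.methylated_offset}/{self.mod_type}"


@dataclass(frozen=True, order=True)
class MotifSite:
    """One methylatable genome position: 0-based duplex coordinate of the
    methylated base plus the strand carrying it."""

    contig: str
    position: int
    strand: str
    motif: IupacMotif = field(compare=False)


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern:
        bases = sorted(IUPAC_TO_BASES[c])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def _forward_match_starts(seq: str, pattern: str, circular: bool) -> list[int]:
    L = len(pattern)
    scan_seq = seq + seq[: L - 1] if circular and len(seq) >= 1 else seq
    starts = [m.start() for m in _pattern_regex(pattern).finditer(scan_seq)]
    if circular:
        starts = [s for s in starts if s < len(seq)]
    return starts


def scan_motif(genome: GenomeSequence, motif: IupacMotif) -> list[MotifSite]:
    """All sites of a motif on both strands of a genome.

    Overlapping occurrences are all reported; circular contigs wrap across
    the origin. Output is sorted by (contig order, position, strand) with
    '+' before '-', and free of duplicates.
    """
    L = len(motif.pattern)
    off = motif.methylated_offset
    rc = revcomp_iupac(motif.pattern)
    sites: set[tuple[int, str, int, str]] = set()
    for idx, (cid, seq) in enumerate(genome.contigs):
        circ = genome.is_circular(cid)
        n = len(seq)
        if n < L and not circ:
            continue
        for s in _forward_match_starts(seq, motif.pattern, circ):
            sites.add((idx, cid, (s + off) % n if circ else s + off, "+"))
        for s in _forward_match_starts(seq, rc, circ):
            pos = s + (L - 1 - off)
            sites.add((idx, cid, pos % n if circ else pos, "-"))
    return [
        MotifSite(contig=cid, position=pos, strand=strand, motif=motif)
        for idx, cid, pos, strand in sorted(sites)
    ]


def duplex_site_count(genome: GenomeSequence, motif: IupacMotif) -> int:
    """Number of distinct duplex occurrences (pattern footprints) of a motif.

    A footprint is identified by its forward-strand start coordinate; a
    palindromic site matched on both strands counts once. This is the
    alternative denominator convention to per-strand methylatable positions.
    """
    L = len(motif.pattern)
    rc = revcomp_iupac(motif.pattern)
    total = 0
    for cid, seq in genome.contigs:
        circ = genome.is_circular(cid)
        fwd = set(_forward_match_starts(seq, motif.pattern, circ))
        rev = set(_forward_match_starts(seq, rc, circ))
        total += len(fwd | rev)
    return total


def matches_at(
    genome: GenomeSequence,
    contig: str,
    position: int,
    strand: str,
    pattern: str,
    offset: int,
) -> bool:
    """True iff placing ``pattern`` (read 5'->3' on ``strand``) with its
    ``offset`` on the duplex coordinate ``position`` matches the genome.

    Placements running off the end of a linear contig are False; circular
    contigs wrap.
    """
    _check_pattern(pattern)
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = genome.seq(contig)
    n = len(seq)
    circ = genome.is_circular(contig)
    if not 0 <= position < n:
        return False
    for q, code in enumerate(pattern):
        if strand == "+":
            coord = position - offset + q
        else:
            coord = position + offset - q
        if circ:
            coord %= n
        elif not 0 <= coord < n:
            return False
        base = seq[coord]
        if strand == "-":
            base = IUPAC_COMPLEMENT[base]
        if base not in IUPAC_TO_BASES[code]:
            return False
    return True


def write_bed(sites: list[MotifSite], path: str, mod_type_column: bool = False) -> None:
    """Write motif sites as BED6 (0-based half-open, name = pattern).

    With ``mod_type_column`` an extra seventh column carries the
    modification type, the convention used for truth sets.
    """
    import os

    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        for s in sites:
            row = [
                s.contig, str(s.position), str(s.position + 1),
                s.motif.pattern, "0", s.strand,
            ]
            if mod_type_column:
                row.append(s.motif.mod_type)
            fh.write("\t".join(row) + "\n")
    os.replace(tmp, path)
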