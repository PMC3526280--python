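"""Methylome summaries: threshold selection, extent of methylation,
strand pairing of complementary motifs and RM-system typing.

The detection threshold follows the unassigned-fraction rule: the score
cutoff is the lowest one for which at most a target fraction (1% by
default; 5% for m4C-dominated genomes) of the retained kinetic hits match
none of the discovered recognition motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kinmeth.detection import KineticScoreRecord
from kinmeth.discovery import assign_calls_to_motifs
from kinmeth.genome import GenomeSequence
from kinmeth.motifs import IupacMotif, revcomp_iupac, scan_motif, duplex_site_count


def select_threshold(
    records: list[KineticScoreRecord],
    motifs: list[IupacMotif],
    genome: GenomeSequence,
    target_unassigned: float = 0.01,
) -> float:
    """Minimal score threshold whose retained set has an unassigned
    fraction <= target (the largest such retained set).

    Records must be sorted by descending score. Records with equal scores
    are retained or excluded together. Returns +inf if no cut attains the
    target (even the single top record is unassigned).
    """
    if not records:
        raise ValueError("select_threshold needs at least one record")
    if any(records[i].score < records[i + 1].score for i in range(len(records) - 1)):
        raise ValueError("records must be sorted by descending score")
    assigned, _ = assign_calls_to_motifs(records, motifs, genome)
    flags = np.array([rec in assigned for rec in records])
    scores = np.array([rec.score for rec in records])
    cum_un = np.cumsum(~flags)
    ks = np.arange(1, len(records) + 1)
    frac = cum_un / ks
    # legal cut points: after the last record of each distinct score
    boundary = np.ones(len(records), dtype=bool)
    boundary[:-1] = scores[:-1] > scores[1:]
    ok = boundary & (frac <= target_unassigned)
    if not ok.any():
        return math.inf
    k = int(np.flatnonzero(ok)[-1]) + 1
    return float(scores[k - 1])


def retained_records(
    records: list[KineticScoreRecord], threshold: float
) -> list[KineticScoreRecord]:
    return [r for r in records if r.score >= threshold]


def methylation_extent(
    genome: GenomeSequence,
    motif: IupacMotif,
    records_above_threshold: list[KineticScoreRecord],
) -> tuple[int, int, float]:
    """(n_detected, n_sites, fraction) for one motif.

    ``n_sites`` counts per-strand methylatable positions (both strands of a
    palindromic site count as two); ``n_detected`` counts sites with a
    retained call at exactly that (position, strand).
    """
    sites = scan_motif(genome, motif)
    called = {(r.contig, r.position, r.strand) for r in records_above_threshold}
    n_detected = sum((s.contig, s.position, s.strand) in called for s in sites)
    n_sites = len(sites)
    fraction = n_detected / n_sites if n_sites else 0.0
    return n_detected, n_sites, fraction


@dataclass
class MotifGroup:
    """One MTase specificity: either a single motif or a complementary
    strand pair describing the two strands of one duplex site."""

    motifs: list[IupacMotif]
    double_strand: bool

    @property
    def is_bipartite(self) -> bool:
        return self.motifs[0].is_bipartite


def pair_strand_motifs(motifs: list[IupacMotif]) -> list[MotifGroup]:
    """Partition motifs into strand groups.

    Two motifs group iff one's pattern is the reverse complement of the
    other's (same modification type): they describe the two strands of one
    duplex specificity. A self-reverse-complementary motif methylates both
    strands on its own (its mirrored offset is its own offset) and
    self-pairs. Everything else is a single-strand motif. The partition
    does not depend on input order beyond which member is listed first.
    """
    groups: list[MotifGroup] = []
    used: set[int] = set()
    for i, m in enumerate(motifs):
        if i in used:
            continue
        rc = revcomp_iupac(m.pattern)
        if rc == m.pattern:
            groups.append(MotifGroup(motifs=[m], double_strand=True))
            used.add(i)
            continue
        partner = None
        for j in range(i + 1, len(motifs)):
            if j in used:
                continue
            other = motifs[j]
            if other.pattern == rc and other.mod_type == m.mod_type:
                partner = j
                break
        if partner is not None:
            groups.append(MotifGroup(motifs=[m, motifs[partner]], double_strand=True))
            used.update({i, partner})
        else:
            groups.append(MotifGroup(motifs=[m], double_strand=False))
            used.add(i)
    return groups


@dataclass(frozen=True)
class RMTypeCall:
    label: str  # TypeI | TypeII | TypeIII_or_IIG | unclassified
    rationale: str


def classify_rm_type(group: MotifGroup) -> RMTypeCall:
    """Heuristic RM-system type from motif structure and strandedness.

    Bipartite recognition sequences methylated on both strands are the
    hallmark of Type I systems; contiguous double-strand motifs behave as
    Type II; contiguous single-strand motifs match Type III (and most
    Type IIG) enzymes; a bipartite single-strand motif fits no standard
    class and is flagged.
    """
    bip = group.is_bipartite
    ds = group.double_strand
    if bip and ds:
        return RMTypeCall("TypeI", "bipartite recognition sequence, both strands methylated")
    if not bip and ds:
        return RMTypeCall("TypeII", "contiguous recognition sequence, both strands methylated")
    if not bip and not ds:
        return RMTypeCall("TypeIII_or_IIG",
                          "contiguous recognition sequence, single strand methylated")
    return RMTypeCall("unclassified",
                      "bipartite recognition sequence but single strand methylated")


@dataclass
class MotifSummary:
    """Per-motif genome-wide summary row."""

    motif: IupacMotif
    partner: IupacMotif | None
    n_sites: int
    n_duplex_sites: int
    n_detected: int
    fraction: float
    mean_score: float
    rm_type: str


def build_summary(
    genome: GenomeSequence,
    groups: list[MotifGroup],
    records: list[KineticScoreRecord],
    threshold: float,
) -> list[MotifSummary]:
    """One summary row per motif (partners cross-referenced), using calls
    with score >= threshold; rows ordered by descending per-strand site
    count, then pattern."""
    retained = retained_records(records, threshold)
    called = {}
    for r in retained:
        called[(r.contig, r.position, r.strand)] = r
    rows: list[MotifSummary] = []
    for group in groups:
        call = classify_rm_type(group)
        members = group.motifs
        for idx, motif in enumerate(members):
            partner = None
            if len(members) == 2:
                partner = members[1 - idx]
            elif group.double_strand:
                partner = motif  # self-complementary: its own partner
            sites = scan_motif(genome, motif)
            hits = [
                called[(s.contig, s.position, s.strand)]
                for s in sites
                if (s.contig, s.position, s.strand) in called
            ]
            n_sites = len(sites)
            fraction = len(hits) / n_sites if n_sites else 0.0
            mean_score = float(np.mean([h.score for h in hits])) if hits else math.nan
            rows.append(MotifSummary(
                motif=motif,
                partner=partner,
                n_sites=n_sites,
                n_duplex_sites=duplex_site_count(genome, motif),
                n_detected=len(hits),
                fraction=fraction,
                mean_score=mean_score,
                rm_type=call.label,
            ))
    rows.sort(key=lambda r: (-r.n_sites, r.motif.pattern, r.motif.methylated_offset))
    return rows


def summary_frame(rows: list[MotifSummary]) -> pd.DataFrame:
    """Tabular form of the summary (stable column order and formatting)."""
    return pd.DataFrame([
        {
            "pattern": r.motif.pattern,
            "methylated_offset": r.motif.methylated_offset,
            "mod_type": r.motif.mod_type,
            "partner_pattern": r.partner.pattern if r.partner else "",
            "n_sites_per_strand": r.n_sites,
            "n_duplex_sites": r.n_duplex_sites,
            "n_detected": r.n_detected,
            "fraction_methylated": round(r.fraction, 6),
            "mean_score": round(r.mean_score, 2) if math.isfinite(r.mean_score) else "",
            "rm_type": r.rm_type,
        }
        for r in rows
    ])
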