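"""Per-position modified-base calling from kinetic summaries.

The statistic is a Phred-like kinetic score: a one-sided one-sample t-test
of the observed mean log-IPD at a position against an in-silico sequence
context reference, transformed as -10*log10(p). Modified bases (m6A, m4C)
lengthen interpulse durations, so only positive shifts count as signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinmeth.genome import GenomeSequence

SCORE_CAP = 1000.0
_LN10 = math.log(10.0)

_ASCII_TO_CODE = np.full(128, 255, dtype=np.uint8)
for _b, _c in zip("ACGT", range(4)):
    _ASCII_TO_CODE[ord(_b)] = _c
_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class KineticScoreRecord:
    """A scored position: Phred-like modification score plus coverage and
    the IPD ratio exp(mean_logipd - ref_mean)."""

    contig: str
    position: int  # 0-based duplex coordinate
    strand: str
    base: str
    score: float
    n_obs: int
    ipd_ratio: float

    def sort_key(self):
        return (-self.score, self.contig, self.position, self.strand)


@dataclass
class ContextModel:
    """In-silico kinetic reference: expected mean/SD of the per-position
    mean log-IPD for each centered k-mer context, with a global fallback
    for contexts unseen in training."""

    order: int
    table: dict[str, tuple[float, float]]
    fallback: tuple[float, float]

    def __post_init__(self) -> None:
        if self.order % 2 != 1:
            raise ValueError("context order must be odd (centered k-mer)")
        if not self.fallback[1] > 0:
            raise ValueError("fallback SD must be > 0")
        for kmer, (_, sd) in self.table.items():
            if len(kmer) != self.order:
                raise ValueError(f"context {kmer!r} length != order {self.order}")
            if not sd > 0:
                raise ValueError(f"context {kmer!r} has non-positive SD")

    def lookup(self, context: str) -> tuple[float, float]:
        return self.table.get(context, self.fallback)

    def mean_array(self) -> np.ndarray:
        """Dense 4^k array of reference means (fallback-filled), indexed by
        the base-4 encoding of the k-mer."""
        k = self.order
        arr = np.full(4 ** k, self.fallback[0])
        for kmer, (m, _) in self.table.items():
            idx = 0
            for c in kmer:
                idx = idx * 4 + _ASCII_TO_CODE[ord(c)]
            arr[idx] = m
        return arr


def _context_indices(codes: np.ndarray, strand: str, k: int) -> np.ndarray:
    """Base-4 index of the centered k-mer (read 5'->3' on the strand) at each
    position; -1 where the context is incomplete (contig edges)."""
    n = len(codes)
    h = k // 2
    idx = np.full(n, -1, dtype=np.int64)
    if n < k:
        return idx
    core = np.zeros(n - 2 * h, dtype=np.int64)
    if strand == "+":
        for j in range(k):
            core = core * 4 + codes[j:n - 2 * h + j]
    else:
        for j in range(k - 1, -1, -1):
            core = core * 4 + (3 - codes[j:n - 2 * h + j].astype(np.int64))
    idx[h:n - h] = core
    return idx


def build_context_model(
    genome: GenomeSequence,
    tracks: pd.DataFrame,
    k: int = 3,
    min_obs: int = 2,
) -> ContextModel:
    """Train the context reference from unmethylated kinetics.

    For each k-mer, the reference mean/SD is the mean and SD across
    positions of the per-position mean log-IPD. Contexts absent from
    training defer to the global fallback.
    """
    if k % 2 != 1:
        raise ValueError("context order must be odd")
    nk = 4 ** k
    sums = np.zeros(nk)
    sqs = np.zeros(nk)
    counts = np.zeros(nk, dtype=np.int64)
    seqs = {cid: _ASCII_TO_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            for cid, s in genome.contigs}
    for (cid, strand), grp in tracks.groupby(["contig", "strand"], sort=True):
        codes = seqs[str(cid)]
        ctx = _context_indices(codes, str(strand), k)
        pos = grp["position"].to_numpy()
        mean = grp["mean_logipd"].to_numpy()
        nobs = grp["n_obs"].to_numpy()
        ok = (nobs >= min_obs) & np.isfinite(mean) & (ctx[pos] >= 0)
        ci = ctx[pos[ok]]
        np.add.at(sums, ci, mean[ok])
        np.add.at(sqs, ci, mean[ok] ** 2)
        np.add.at(counts, ci, 1)
    total = counts.sum()
    if total < 2:
        raise ValueError("not enough training positions for a context model")
    g_mean = sums.sum() / total
    g_var = (sqs.sum() - total * g_mean ** 2) / (total - 1)
    fallback = (float(g_mean), float(math.sqrt(max(g_var, 1e-12))))
    table: dict[str, tuple[float, float]] = {}
    for idx in np.nonzero(counts >= 2)[0]:
        c = counts[idx]
        m = sums[idx] / c
        v = (sqs[idx] - c * m ** 2) / (c - 1)
        kmer = ""
        rem = int(idx)
        for _ in range(k):
            kmer = _CODE_BASE[rem % 4] + kmer
            rem //= 4
        table[kmer] = (float(m), float(math.sqrt(max(v, 1e-12))))
    return ContextModel(order=k, table=table, fallback=fallback)


def kinetic_score(
    n_obs: int,
    mean_logipd: float,
    sd_logipd: float,
    ref_mean: float,
    ref_sd: float | None = None,
    cap: float = SCORE_CAP,
) -> float:
    """Phred-like modification score for one position.

    One-sided one-sample t statistic t = (mean - ref_mean) / (sd / sqrt(n)),
    p = upper tail of Student t with n-1 df, score = -10*log10(p) capped at
    ``cap``. ``ref_sd`` is accepted for interface completeness but the
    reference mean is treated as known. Raises for n_obs < 2 (no SD).
    """
    if n_obs < 2:
        raise ValueError("kinetic score requires n_obs >= 2")
    shift = mean_logipd - ref_mean
    if sd_logipd <= 0:
        return cap if shift > 0 else 0.0
    t = shift / (sd_logipd / math.sqrt(n_obs))
    logp = stats.t.logsf(t, n_obs - 1)
    return float(min(cap, max(0.0, -10.0 * logp / _LN10)))


def detect_modified_positions(
    genome: GenomeSequence,
    tracks: pd.DataFrame,
    model: ContextModel,
    min_coverage: int = 10,
    score_floor: float = 20.0,
    bases: tuple[str, ...] = ("A", "C"),
    cap: float = SCORE_CAP,
) -> list[KineticScoreRecord]:
    """Genome-wide kinetic-score detection.

    Scores every position with n_obs >= max(2, min_coverage) whose strand
    base is in ``bases`` (default A and C: the m6A/m4C chemistry; m5C is not
    called genome-wide), and returns records with score >= score_floor
    sorted by descending score, ties broken by (contig, position, strand).
    """
    if tracks.empty:
        return []
    k = model.order
    means = model.mean_array()
    seqs = {cid: _ASCII_TO_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            for cid, s in genome.contigs}
    base_ok = set(bases)
    records: list[KineticScoreRecord] = []
    min_n = max(2, min_coverage)
    for (cid, strand), grp in tracks.groupby(["contig", "strand"], sort=True):
        cid, strand = str(cid), str(strand)
        codes = seqs[cid]
        ctx = _context_indices(codes, strand, k)
        pos = grp["position"].to_numpy()
        mean = grp["mean_logipd"].to_numpy()
        sd = grp["sd_logipd"].to_numpy()
        nobs = grp["n_obs"].to_numpy()
        basearr = grp["base"].to_numpy()
        ok = (
            (nobs >= min_n)
            & np.isfinite(mean)
            & np.isfinite(sd)
            & (sd > 0)
            & np.isin(basearr, list(base_ok))
        )
        if not ok.any():
            continue
        p_ok = pos[ok]
        ci = ctx[p_ok]
        ref = np.where(ci >= 0, means[np.clip(ci, 0, None)], model.fallback[0])
        tstat = (mean[ok] - ref) / (sd[ok] / np.sqrt(nobs[ok]))
        logp = stats.t.logsf(tstat, nobs[ok] - 1)
        score = np.minimum(cap, np.maximum(0.0, -10.0 * logp / _LN10))
        ratio = np.exp(mean[ok] - ref)
        keep = score >= score_floor
        for p, b, s, nn, r in zip(
            p_ok[keep], basearr[ok][keep], score[keep], nobs[ok][keep], ratio[keep]
        ):
            records.append(KineticScoreRecord(
                contig=cid, position=int(p), strand=strand, base=str(b),
                score=float(s), n_obs=int(nn), ipd_ratio=float(r),
            ))
    records.sort(key=KineticScoreRecord.sort_key)
    return records


def top_hits(records: list[KineticScoreRecord], n: int = 1000) -> list[KineticScoreRecord]:
    """First min(n, len) records of an already-sorted detection list."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return records[:n]


def find_coverage_gaps(
    tracks: pd.DataFrame,
    genome: GenomeSequence,
    min_len: int = 1000,
) -> list[tuple[str, int, int]]:
    """Maximal runs of positions with zero coverage on both strands.

    Positions absent from the kinetics table count as uncovered. Returns
    0-based half-open (contig, start, end) intervals of length >= min_len,
    sorted by contig order then start.
    """
    gaps: list[tuple[str, int, int]] = []
    for cid, seq in genome.contigs:
        n = len(seq)
        cov = np.zeros(n, dtype=np.int64)
        sub = tracks[tracks["contig"] == cid]
        if not sub.empty:
            np.add.at(cov, sub["position"].to_numpy(), sub["n_obs"].to_numpy())
        zero = cov == 0
        if not zero.any():
            continue
        # run-length boundaries of the zero mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= min_len:
                gaps.append((cid, int(start), int(end)))
    return gaps
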