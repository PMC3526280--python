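"""Consensus motif discovery from kinetic-hit sequence windows.

This module replaces an external motif finder with an implemented
algorithm tailored to methylation signals: every window is centered on a
called modified base, so candidate motifs can be anchored at fixed offsets
relative to the center and scored by positioned enrichment against a
background model, with no alignment step.

Algorithm
---------
1. *Seed enumeration.* From the window set, enumerate positioned seeds
   covering the center: contiguous k-mers (k = 4..8) and spaced dyads (two
   half-sites of 2-5 nt separated by 4-9 nonspecific positions — the
   structure of Type I recognition sequences). A seed's support is the
   number of windows carrying it at exactly that offset; its p-value is the
   binomial tail of the support against the positioned background match
   probability, Bonferroni-corrected over all enumerated seeds.
2. *Greedy refinement.* Starting from the most significant seed:
   degenerate single positions to IUPAC supersets while the relative
   support gain stays large (recovers R/Y/W/H... positions that split the
   concrete seeds), and extend the pattern outward one column at a time
   when a small base set is strongly over-represented at the flanking
   column among supporting windows.
3. *Mask and repeat.* Supporting windows are removed and the search
   repeats until no seed passes the significance gate.
4. *Refit.* Each candidate is re-fit against the unmasked window set and
   columns whose coverage lift disappears there are pruned: hard masking
   creates anti-correlated shadows (windows matching two overlapping
   motifs are consumed by the first), and this pass removes them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from kinmeth.detection import KineticScoreRecord
from kinmeth.genome import GenomeSequence
from kinmeth.motifs import (
    BASES_TO_IUPAC,
    IUPAC_TO_BASES,
    IupacMotif,
    MotifError,
    matches_at,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CHAR_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Window:
    """A +/-w sequence context around a called base, read 5'->3' on the
    called strand (minus-strand windows are reverse-complemented); contig
    edges are padded with N."""

    seq: str
    center: int
    record: KineticScoreRecord | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.center < len(self.seq):
            raise ValueError("center outside window")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"window contains invalid characters {bad}")


@dataclass
class DiscoveryParams:
    """Tunables of the seed -> generalize -> mask loop."""

    w: int = 20
    kmin: int = 4
    kmax: int = 8
    half_min: int = 2
    half_max: int = 5
    spacer_min: int = 4
    spacer_max: int = 9
    min_support: int = 5
    enrich_floor: float = 10.0
    seed_alpha: float = 0.01       # on the Bonferroni-adjusted seed p-value
    gain_rel: float = 0.25         # relative support gain to accept a widening
    ext_alpha: float = 2e-4        # per-column extension/specification alpha
    lift_min: float = 0.38         # relative coverage lift above background
    depletion_tol: float = 0.25    # widening may not add a depleted base
    max_motifs: int = 20
    max_len: int = 30
    m5c_score_ceiling: float = 40.0


@dataclass
class MotifCandidate:
    motif: IupacMotif
    support: int
    enrichment: float
    log10_p: float
    mean_score: float = math.nan


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def extract_windows(
    records: list[KineticScoreRecord],
    genome: GenomeSequence,
    w: int = 20,
) -> list[Window]:
    """Sequence windows of +/- w bases around each called position, oriented
    5'->3' on the called strand."""
    seqs = dict(genome.contigs)
    out: list[Window] = []
    for rec in records:
        s = seqs[rec.contig]
        n = len(s)
        lo, hi = rec.position - w, rec.position + w + 1
        chunk = s[max(lo, 0):min(hi, n)]
        pad_l = max(0, -lo)
        pad_r = max(0, hi - n)
        win = "N" * pad_l + chunk + "N" * pad_r
        if rec.strand == "-":
            win = "".join(_COMP[c] for c in reversed(win))
        out.append(Window(seq=win, center=w, record=rec))
    return out


# ---------------------------------------------------------------------------
# background and binomial machinery
# ---------------------------------------------------------------------------


def genome_base_probs(genome: GenomeSequence) -> dict[str, float]:
    """Order-0 (mononucleotide) background from both strands of a genome."""
    counts = {b: 0 for b in _BASES}
    for _, seq in genome.contigs:
        for b in _BASES:
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty genome background")
    # both strands: average with the complement
    probs = {}
    for b in _BASES:
        probs[b] = (counts[b] + counts[_COMP[b]]) / (2 * total)
    return probs


def _as_probs(background) -> dict[str, float]:
    if isinstance(background, GenomeSequence):
        return genome_base_probs(background)
    return dict(background)


def _code_prob(code: str, probs: dict[str, float]) -> float:
    return sum(probs[b] for b in IUPAC_TO_BASES[code])


def _pattern_prob(pattern: list[str], probs: dict[str, float]) -> float:
    p = 1.0
    for code in pattern:
        if code != "N":
            p *= _code_prob(code, probs)
    return p


def log10_binom_sf(x: int, n: int, p: float) -> float:
    """log10 P(Bin(n, p) >= x), computed stably by term summation.

    This is the enrichment p-value used throughout discovery; it stays
    finite far below float underflow.
    """
    if x <= 0:
        return 0.0
    if x > n:
        return -math.inf
    p = min(max(p, 1e-300), 1.0 - 1e-12)
    js = np.arange(x, n + 1)
    terms = (
        gammaln(n + 1) - gammaln(js + 1) - gammaln(n - js + 1)
        + js * math.log(p) + (n - js) * math.log1p(-p)
    )
    return float(logsumexp(terms) / math.log(10.0))


# ---------------------------------------------------------------------------
# vectorized window matrix
# ---------------------------------------------------------------------------


class _WindowMatrix:
    """Windows packed as a (n, 2w+1) uint8 matrix for fast positioned
    pattern matching."""

    def __init__(self, windows: list[Window]):
        if not windows:
            self.mat = np.zeros((0, 0), dtype=np.uint8)
            self.center = 0
            self.windows = []
            return
        length = len(windows[0].seq)
        center = windows[0].center
        for win in windows:
            if len(win.seq) != length or win.center != center:
                raise ValueError("windows must share length and center")
        self.windows = windows
        self.center = center
        self.mat = np.frombuffer(
            "".join(w.seq for w in windows).encode(), dtype=np.uint8
        ).reshape(len(windows), length).copy()
        lut = np.zeros(128, dtype=np.uint8)
        for ch, code in _CHAR_CODE.items():
            lut[ord(ch)] = code
        self.mat = lut[self.mat]

    def __len__(self) -> int:
        return self.mat.shape[0]

    @property
    def width(self) -> int:
        return self.mat.shape[1]

    def match_mask(
        self, pattern: list[str], offset: int, active: np.ndarray
    ) -> np.ndarray:
        """Boolean mask over all rows: window matches pattern placed with
        its offset on the window center. Pad N in a window matches only an
        N in the pattern; pattern columns outside the window fail unless N."""
        start = self.center - offset
        mask = active.copy()
        for q, code in enumerate(pattern):
            if code == "N":
                continue
            col = start + q
            if col < 0 or col >= self.width:
                mask[:] = False
                return mask
            allowed = np.zeros(5, dtype=bool)
            for b in IUPAC_TO_BASES[code]:
                allowed[_CHAR_CODE[b]] = True
            mask &= allowed[self.mat[:, col]]
            if not mask.any():
                return mask
        return mask

    def column_counts(self, col: int, rows: np.ndarray) -> np.ndarray:
        """Base counts (A,C,G,T) at a window column over given rows; N/pad
        excluded."""
        if col < 0 or col >= self.width:
            return np.zeros(4, dtype=np.int64)
        vals = self.mat[rows, col]
        return np.bincount(vals, minlength=5)[:4].astype(np.int64)


# ---------------------------------------------------------------------------
# seed enumeration
# ---------------------------------------------------------------------------


def _enumerate_seeds(
    windows: list[Window], active: np.ndarray, params: DiscoveryParams
) -> dict[tuple, int]:
    """Count positioned seeds over the active windows.

    Keys: ("C", kmer, center_offset) for contiguous seeds and
    ("D", left, gap, right, center_offset) for spaced dyads.
    """
    counts: dict[tuple, int] = {}
    for wi, win in enumerate(windows):
        if not active[wi]:
            continue
        s, c, L = win.seq, win.center, len(win.seq)
        for k in range(params.kmin, params.kmax + 1):
            for start in range(max(0, c - k + 1), min(c, L - k) + 1):
                sub = s[start:start + k]
                if "N" in sub:
                    continue
                key = ("C", sub, c - start)
                counts[key] = counts.get(key, 0) + 1
        for a in range(params.half_min, params.half_max + 1):
            for b in range(params.half_min, params.half_max + 1):
                for g in range(params.spacer_min, params.spacer_max + 1):
                    for cl in range(a):  # center inside the left half-site
                        ls = c - cl
                        rs = ls + a + g
                        if ls < 0 or rs + b > L:
                            continue
                        left, right = s[ls:ls + a], s[rs:rs + b]
                        if "N" in left or "N" in right:
                            continue
                        key = ("D", left, g, right, cl)
                        counts[key] = counts.get(key, 0) + 1
                    for cr in range(b):  # center inside the right half-site
                        rs = c - cr
                        ls = rs - g - a
                        if ls < 0 or rs + b > L:
                            continue
                        left, right = s[ls:ls + a], s[rs:rs + b]
                        if "N" in left or "N" in right:
                            continue
                        key = ("D", left, g, right, a + g + cr)
                        counts[key] = counts.get(key, 0) + 1
    return counts


def _seed_pattern(key: tuple) -> tuple[list[str], int]:
    if key[0] == "C":
        _, kmer, off = key
        return list(kmer), off
    _, left, gap, right, off = key
    return list(left) + ["N"] * gap + list(right), off


def _best_seed(
    counts: dict[tuple, int],
    n_active: int,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int, float] | None:
    """Most significant seed passing support, enrichment and the
    Bonferroni-adjusted significance gate; ties broken lexicographically."""
    m_tests = max(len(counts), 1)
    log10_alpha = math.log10(params.seed_alpha) - math.log10(m_tests)
    best = None
    for key, x in counts.items():
        if x < params.min_support:
            continue
        pattern, off = _seed_pattern(key)
        p0 = _pattern_prob(pattern, probs)
        expected = n_active * p0
        if expected > 0 and x / expected < params.enrich_floor:
            continue
        lp = log10_binom_sf(x, n_active, p0)
        if lp >= log10_alpha:
            continue
        item = (lp, "".join(pattern), off)
        if best is None or item < best[:3]:
            best = (lp, "".join(pattern), off, pattern)
    if best is None:
        return None
    return best[3], best[2], best[0]


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def _widen_once(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    active: np.ndarray,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int] | None:
    """Best single-position IUPAC widening with relative support gain >=
    gain_rel and enrichment still >= enrich_floor; None if no position
    qualifies. The methylated (center) position is never widened.

    A base may only join a position's set if it is not depleted there:
    among windows matching the pattern with that position relaxed, its
    frequency must reach (1 - depletion_tol) of its background
    probability. This blocks absorbing the flank of an overlapping
    complementary-strand motif (where the candidate base is in fact
    under-represented) while still allowing genuinely degenerate
    positions, whose variant bases occur at or above background rates.
    """
    old = int(wm.match_mask(pattern, offset, active).sum())
    if old == 0:
        return None
    n_active = int(active.sum())
    best = None
    for q, code in enumerate(pattern):
        if q == offset or code == "N":
            continue
        cur = IUPAC_TO_BASES[code]
        if len(cur) >= 3:
            continue
        relaxed = pattern.copy()
        relaxed[q] = "N"
        relaxed_rows = np.flatnonzero(wm.match_mask(relaxed, offset, active))
        col_counts = wm.column_counts(wm.center - offset + q, relaxed_rows)
        n_col = int(col_counts.sum())
        for b in _BASES:
            if b in cur:
                continue
            if n_col > 0:
                freq_b = col_counts[_CHAR_CODE[b]] / n_col
                if freq_b < (1.0 - params.depletion_tol) * probs[b]:
                    continue
            new_code = BASES_TO_IUPAC[frozenset(cur | {b})]
            trial = pattern.copy()
            trial[q] = new_code
            sup = int(wm.match_mask(trial, offset, active).sum())
            gain = (sup - old) / old
            if gain < params.gain_rel:
                continue
            p0 = _pattern_prob(trial, probs)
            if n_active * p0 > 0 and sup / (n_active * p0) < params.enrich_floor:
                continue
            item = (-gain, "".join(trial))
            if best is None or item < best[0]:
                best = (item, trial, sup)
    if best is None:
        return None
    return best[1], best[2]


def _column_code(
    counts: np.ndarray,
    probs: dict[str, float],
    params: DiscoveryParams,
    require_significance: bool = True,
) -> str | None:
    """Best IUPAC code (set size 1-3) for a column, or None.

    Acceptance needs a relative coverage lift over the background
    probability of the set and (optionally) a binomial tail below
    ext_alpha. The most significant qualifying set wins; ties favour
    smaller sets."""
    n_col = int(counts.sum())
    if n_col == 0:
        return None
    best = None
    for size in (1, 2, 3):
        for combo in combinations(range(4), size):
            x = int(counts[list(combo)].sum())
            p_s = sum(probs[_BASES[i]] for i in combo)
            if p_s >= 1.0:
                continue
            need = p_s + params.lift_min * (1.0 - p_s)
            if x / n_col < need:
                continue
            lp = log10_binom_sf(x, n_col, p_s)
            if require_significance and lp >= math.log10(params.ext_alpha):
                continue
            code = BASES_TO_IUPAC[frozenset(_BASES[i] for i in combo)]
            item = (lp, size, code)
            if best is None or item < best:
                best = item
    return best[2] if best else None


def _specify_once(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    active: np.ndarray,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int] | None:
    """Specify one interior N column whose base composition among
    supporting windows is significantly constrained.

    Dyad seeds treat every position between the half-sites as spacer; a
    degenerate specific position adjacent to a half-site (e.g. the Y of
    TAAYN5TGC) is then swallowed by the spacer and can only be recovered
    by re-testing interior columns once supporters are collected."""
    rows = np.flatnonzero(wm.match_mask(pattern, offset, active))
    if len(rows) < params.min_support:
        return None
    best = None
    for q, code in enumerate(pattern):
        if code != "N" or q == offset:
            continue
        counts = wm.column_counts(wm.center - offset + q, rows)
        new_code = _column_code(counts, probs, params)
        if new_code is None:
            continue
        x = int(counts[[_CHAR_CODE[b] for b in IUPAC_TO_BASES[new_code]]].sum())
        lp = log10_binom_sf(x, int(counts.sum()), _code_prob(new_code, probs))
        if best is None or lp < best[0]:
            best = (lp, q, new_code)
    if best is None:
        return None
    _, q, new_code = best
    trial = pattern.copy()
    trial[q] = new_code
    return trial, offset


def _extend_once(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    active: np.ndarray,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int] | None:
    """Add one specific flanking column (left or right) if its base
    composition among supporting windows is significantly constrained."""
    if len(pattern) >= params.max_len:
        return None
    sup_mask = wm.match_mask(pattern, offset, active)
    rows = np.flatnonzero(sup_mask)
    if len(rows) < params.min_support:
        return None
    start = wm.center - offset
    options = []
    left_counts = wm.column_counts(start - 1, rows)
    code = _column_code(left_counts, probs, params)
    if code is not None:
        options.append((left_counts, code, "L"))
    right_counts = wm.column_counts(start + len(pattern), rows)
    code = _column_code(right_counts, probs, params)
    if code is not None:
        options.append((right_counts, code, "R"))
    if not options:
        return None
    # prefer the more significant side
    def _lp(opt):
        counts, code, _ = opt
        x = int(counts[[_CHAR_CODE[b] for b in IUPAC_TO_BASES[code]]].sum())
        return log10_binom_sf(x, int(counts.sum()), _code_prob(code, probs))
    options.sort(key=lambda o: (_lp(o), o[2]))
    counts, code, side = options[0]
    if side == "L":
        return [code] + pattern, offset + 1
    return pattern + [code], offset


def _refine(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    active: np.ndarray,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int]:
    """Alternate widening, interior specification and extension to a
    fixpoint (bounded)."""
    for _ in range(64):
        widened = _widen_once(pattern, offset, wm, active, probs, params)
        if widened is not None:
            pattern, _ = widened
            continue
        specified = _specify_once(pattern, offset, wm, active, probs, params)
        if specified is not None:
            pattern, offset = specified
            continue
        extended = _extend_once(pattern, offset, wm, active, probs, params)
        if extended is not None:
            pattern, offset = extended
            continue
        break
    return pattern, offset


def _trim(pattern: list[str], offset: int) -> tuple[list[str], int]:
    lo = 0
    while lo < len(pattern) and pattern[lo] == "N":
        lo += 1
    hi = len(pattern)
    while hi > lo and pattern[hi - 1] == "N":
        hi -= 1
    return pattern[lo:hi], offset - lo


def _refit_candidate(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> tuple[list[str], int] | None:
    """Re-test every specific column against the full (unmasked) window set
    and prune columns whose coverage lift vanishes there.

    A pruned column is one whose apparent specificity was an artifact of
    masking order: among all windows matching the rest of the pattern, its
    base set is no longer over-represented."""
    full = np.ones(len(wm), dtype=bool)
    order = sorted(
        (q for q, c in enumerate(pattern) if q != offset and c != "N"),
        key=lambda q: -abs(q - offset),
    )
    for q in order:
        relaxed = pattern.copy()
        relaxed[q] = "N"
        rows = np.flatnonzero(wm.match_mask(relaxed, offset, full))
        counts = wm.column_counts(wm.center - offset + q, rows)
        n_col = int(counts.sum())
        if n_col == 0:
            pattern[q] = "N"
            continue
        code = pattern[q]
        x = int(counts[[_CHAR_CODE[b] for b in IUPAC_TO_BASES[code]]].sum())
        p_s = _code_prob(code, probs)
        need = p_s + params.lift_min * (1.0 - p_s)
        if x / n_col < need:
            pattern[q] = "N"
    pattern, offset = _trim(pattern, offset)
    if len(pattern) < 2 or offset < 0 or offset >= len(pattern):
        return None
    return pattern, offset


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _candidate_from(
    pattern: list[str],
    offset: int,
    wm: _WindowMatrix,
    probs: dict[str, float],
    params: DiscoveryParams,
) -> MotifCandidate | None:
    full = np.ones(len(wm), dtype=bool)
    mask = wm.match_mask(pattern, offset, full)
    support = int(mask.sum())
    if support < params.min_support:
        return None
    center_code = pattern[offset]
    if center_code not in ("A", "C"):
        return None
    p0 = _pattern_prob(pattern, probs)
    n = len(wm)
    enrichment = support / (n * p0) if n * p0 > 0 else math.inf
    lp = log10_binom_sf(support, n, p0)
    scores = [
        wm.windows[i].record.score
        for i in np.flatnonzero(mask)
        if wm.windows[i].record is not None
    ]
    mean_score = float(np.mean(scores)) if scores else math.nan
    if center_code == "A":
        mod = "m6A"
    else:
        mod = "m4C" if (math.isnan(mean_score)
                        or mean_score >= params.m5c_score_ceiling) else "m5C"
    try:
        motif = IupacMotif("".join(pattern), offset, mod)
    except MotifError:
        return None
    return MotifCandidate(
        motif=motif, support=support, enrichment=enrichment,
        log10_p=lp, mean_score=mean_score,
    )


def discover_motifs(
    windows: list[Window],
    genome_background,
    params: DiscoveryParams | None = None,
) -> list[MotifCandidate]:
    """Derive IUPAC consensus motifs from center-anchored windows.

    ``genome_background`` is a :class:`GenomeSequence` or a dict of
    mononucleotide probabilities. Returns candidates in discovery order
    (most significant first); each window can support several candidates
    after the final refit, but masking ensures each candidate explains
    windows the previous ones did not.
    """
    params = params or DiscoveryParams()
    probs = _as_probs(genome_background)
    if len(windows) < params.min_support:
        logger.warning(
            "discovery needs >= %d windows, got %d", params.min_support, len(windows)
        )
        return []
    wm = _WindowMatrix(windows)
    active = np.ones(len(wm), dtype=bool)
    raw: list[tuple[list[str], int]] = []
    m_tests = 1
    for _ in range(params.max_motifs):
        n_active = int(active.sum())
        if n_active < params.min_support:
            break
        counts = _enumerate_seeds(windows, active, params)
        m_tests = max(m_tests, len(counts))
        seed = _best_seed(counts, n_active, probs, params)
        if seed is None:
            break
        pattern, offset, _ = seed
        pattern, offset = _refine(pattern, offset, wm, active, probs, params)
        explained = wm.match_mask(pattern, offset, active)
        if not explained.any():
            break
        raw.append((pattern, offset))
        active &= ~explained

    # refit against the unmasked set, prune shadow columns, deduplicate,
    # and re-apply the Bonferroni significance gate to the final pattern.
    # The final gate is two orders stricter than the seed gate: refinement
    # selects over many possible patterns per seed, and a refitted pattern
    # can be much looser than the seed that launched it.
    log10_gate = math.log10(params.seed_alpha) - 2.0 - math.log10(m_tests)
    out: list[MotifCandidate] = []
    seen: set[tuple[str, int]] = set()
    for pattern, offset in raw:
        refit = _refit_candidate(pattern.copy(), offset, wm, probs, params)
        if refit is None:
            continue
        pattern, offset = refit
        key = ("".join(pattern), offset)
        if key in seen:
            continue
        cand = _candidate_from(pattern, offset, wm, probs, params)
        if cand is None or cand.log10_p >= log10_gate:
            continue
        seen.add(key)
        out.append(cand)
    return out


def refine_motif(
    motif: IupacMotif,
    windows: list[Window],
    genome_background,
    params: DiscoveryParams | None = None,
) -> MotifCandidate | None:
    """Re-refine an already-discovered motif against a (larger) window set.

    Starting from the motif's own pattern, runs the widen/specify/extend
    loop and the shadow-pruning refit with every window active. Useful
    after iterative discovery: motifs found in a round where their windows
    were diluted (or split across concrete variants of a degenerate
    position) converge to their full pattern once all supporting windows
    are available.
    """
    params = params or DiscoveryParams()
    probs = _as_probs(genome_background)
    if len(windows) < params.min_support:
        return None
    wm = _WindowMatrix(windows)
    active = np.ones(len(wm), dtype=bool)
    pattern = list(motif.pattern)
    offset = motif.methylated_offset
    pattern, offset = _refine(pattern, offset, wm, active, probs, params)
    refit = _refit_candidate(pattern, offset, wm, probs, params)
    if refit is None:
        return None
    pattern, offset = refit
    return _candidate_from(pattern, offset, wm, probs, params)


def assign_calls_to_motifs(
    records: list[KineticScoreRecord],
    motifs: list[IupacMotif],
    genome: GenomeSequence,
) -> tuple[dict[KineticScoreRecord, IupacMotif], list[KineticScoreRecord]]:
    """Assign each record to the first motif (in list order) whose pattern
    matches the genome with its methylated offset on the record's
    position/strand; the rest are unassigned."""
    assigned: dict[KineticScoreRecord, IupacMotif] = {}
    unassigned: list[KineticScoreRecord] = []
    for rec in records:
        hit = None
        for motif in motifs:
            if matches_at(genome, rec.contig, rec.position, rec.strand,
                          motif.pattern, motif.methylated_offset):
                hit = motif
                break
        if hit is None:
            unassigned.append(rec)
        else:
            assigned[rec] = hit
    return assigned, unassigned


def write_windows_fasta(windows: list[Window], path: str) -> None:
    """Windows as FASTA; the description records the center index and,
    when available, the source call (contig:position:strand score)."""
    import os

    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        for i, win in enumerate(windows):
            desc = f"center={win.center}"
            if win.record is not None:
                r = win.record
                desc += f" source={r.contig}:{r.position + 1}:{r.strand} score={r.score:.2f}"
            fh.write(f">window_{i} {desc}\n{win.seq}\n")
    os.replace(tmp, path)


def read_windows_fasta(path: str) -> list[Window]:
    """Inverse of :func:`write_windows_fasta` (source records are not
    reconstructed)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        center = None
        for field in rec.description.split():
            if field.startswith("center="):
                center = int(field.split("=", 1)[1])
        if center is None:
            raise ValueError(f"{path}: window {rec.id} lacks a center= field")
        out.append(Window(seq=str(rec.seq).upper(), center=center))
    return out


def residual_motif_check(
    windows: list[Window],
    genome_background,
    params: DiscoveryParams | None = None,
) -> list[MotifCandidate]:
    """Run discovery on the unassigned windows; a clean methylome analysis
    returns nothing here."""
    if not windows:
        return []
    return discover_motifs(windows, genome_background, params)
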