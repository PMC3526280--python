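"""Synthetic SMRT kinetics: random genomes, planted methylomes, IPD summaries.

The generator emulates the conditions of whole-genome bacterial methylome
runs at desk scale: a random genome with an organism-like GC content, a set
of planted methyltransferase specificities (including bipartite Type I
motifs and strand-paired asymmetric motifs), and per-position/per-strand
summaries (count, mean, SD) of log interpulse durations.

Signal model
------------
Log-IPDs at an unmethylated position are Normal(mu(context), sigma) where
mu depends on the centered 3-mer sequence context. Methylation shifts the
mean by a modification-type-dependent delta with the field's qualitative
ordering m6A > m4C > m5C; m5C additionally leaks half its (already weak)
shift to the two adjacent positions on the same strand, making it diffuse.
Per-strand coverage is Poisson. Only the per-position summary statistics
(n, mean, SD) are retained, drawn from their exact sampling distributions
(Normal for the mean, scaled chi-square for the SD), which keeps the
downstream t-test exactly calibrated on the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinmeth.genome import GenomeSequence
from kinmeth.motifs import IupacMotif, scan_motif

# Fixed internal seed for the per-3-mer baseline table: context effects are a
# property of the (synthetic) chemistry, identical across runs and seeds, so
# a reference model trained on one null run transfers to any other.
_CONTEXT_TABLE_SEED = 731_405_809
_CONTEXT_ORDER = 3
_CONTEXT_SD = 0.15

DEFAULT_DELTAS = {"m6A": math.log(4.0), "m4C": math.log(2.0), "m5C": math.log(1.2)}
DEFAULT_SIGMA = 0.6

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def _context_table() -> np.ndarray:
    """Per-3-mer baseline mean log-IPD offsets (deterministic)."""
    rng = np.random.default_rng(_CONTEXT_TABLE_SEED)
    return rng.normal(0.0, _CONTEXT_SD, size=4 ** _CONTEXT_ORDER)


_MU_TABLE = _context_table()


@dataclass
class SimulationConfig:
    """Conditions for one synthetic methylome run.

    ``planted`` pairs each motif with its methylated fraction f: every
    genomic site of the motif is independently methylated with probability
    f. ``deltas`` are the mean log-IPD shifts per modification type and must
    respect delta(m6A) > delta(m4C) > delta(m5C) >= 0.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.5
    planted: list[tuple[IupacMotif, float]] = field(default_factory=list)
    coverage_mean: float = 60.0
    sigma: float = DEFAULT_SIGMA
    deltas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTAS))
    context_order: int = _CONTEXT_ORDER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")
        d = self.deltas
        if not (d["m6A"] > d["m4C"] > d["m5C"] >= 0.0):
            raise ValueError("deltas must satisfy m6A > m4C > m5C >= 0")
        for motif, f in self.planted:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"methylated fraction {f} for {motif} not in [0, 1]")


@dataclass(frozen=True, order=True)
class TruthEntry:
    contig: str
    position: int
    strand: str
    mod_type: str
    motif: IupacMotif = field(compare=False)


@dataclass
class TruthSet:
    """The planted methylated positions: a subset of the scanned motif sites,
    chosen by independent Bernoulli(f) draws per site."""

    entries: list[TruthEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self) -> set[tuple[str, int, str]]:
        return {(e.contig, e.position, e.strand) for e in self.entries}

    def by_motif(self, motif: IupacMotif) -> list[TruthEntry]:
        return [e for e in self.entries if e.motif == motif]


def simulate_genome(length: int, gc_fraction: float, seed: int) -> GenomeSequence:
    """I.i.d. random genome with P(G) = P(C) = gc_fraction / 2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = "".join(_CODE_BASE[c] for c in codes)
    return GenomeSequence(contigs=[("sim", seq)])


def base_probabilities(gc_fraction: float) -> dict[str, float]:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return {"A": at, "C": gc, "G": gc, "T": at}


def plant_methylation(
    genome: GenomeSequence,
    planted: list[tuple[IupacMotif, float]],
    seed: int,
) -> TruthSet:
    """Select methylated sites: each scanned site of each motif is included
    independently with probability f, in deterministic (motif order, site
    order) sequence for a given seed."""
    rng = np.random.default_rng(seed)
    entries: list[TruthEntry] = []
    taken: set[tuple[str, int, str]] = set()
    for motif, f in planted:
        sites = scan_motif(genome, motif)
        draws = rng.random(len(sites))
        for site, u in zip(sites, draws):
            if u >= f:
                continue
            key = (site.contig, site.position, site.strand)
            if key in taken:
                continue
            taken.add(key)
            entries.append(
                TruthEntry(site.contig, site.position, site.strand,
                           motif.mod_type, motif)
            )
    entries.sort()
    return TruthSet(entries=entries)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy().view(np.uint8)


def _context_mu(seq_codes: np.ndarray, strand: str) -> np.ndarray:
    """Baseline mean log-IPD per position for one strand of a contig.

    The context is the centered 3-mer read 5'->3' on that strand; positions
    without a full context (contig edges) fall back to the global baseline 0.
    """
    n = len(seq_codes)
    mu = np.zeros(n)
    if n < 3:
        return mu
    left, center, right = seq_codes[:-2], seq_codes[1:-1], seq_codes[2:]
    if strand == "+":
        idx = 16 * left + 4 * center + right
    else:
        idx = 16 * (3 - right) + 4 * (3 - center) + (3 - left)
    mu[1:-1] = _MU_TABLE[idx]
    return mu


_ASCII_TO_CODE = np.full(128, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _c

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_ipds(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-position/per-strand kinetic summaries for a genome and truth set.

    Returns a DataFrame with one row per (contig, position, strand):
    columns contig, position (0-based), strand, base (the strand's base,
    5'->3'), n_obs, mean_logipd, sd_logipd. Positions with n_obs == 0 carry
    NaN statistics; n_obs == 1 carries a mean but NaN SD.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth_by = {}
    for e in truth.entries:
        truth_by.setdefault((e.contig, e.strand), []).append((e.position, e.mod_type))

    frames = []
    for cid, seq in genome.contigs:
        codes = _ASCII_TO_CODE[_encode(seq)]
        n = len(seq)
        for strand in ("+", "-"):
            mu = _context_mu(codes, strand)
            delta = np.zeros(n)
            for pos, mod in truth_by.get((cid, strand), []):
                d = config.deltas[mod]
                delta[pos] += d
                if mod == "m5C":  # diffuse signal: leak to neighbours
                    if pos > 0:
                        delta[pos - 1] += d / 2.0
                    if pos < n - 1:
                        delta[pos + 1] += d / 2.0
            n_obs = rng.poisson(config.coverage_mean, size=n)
            mean = np.full(n, np.nan)
            sd = np.full(n, np.nan)
            has = n_obs >= 1
            mean[has] = (
                mu[has] + delta[has]
                + rng.standard_normal(has.sum()) * config.sigma / np.sqrt(n_obs[has])
            )
            two = n_obs >= 2
            df_ = (n_obs[two] - 1).astype(float)
            sd[two] = config.sigma * np.sqrt(rng.chisquare(df_) / df_)
            bases = np.array(list(seq if strand == "+"
                                  else "".join(_COMPLEMENT_BASE[b] for b in seq)))
            frames.append(pd.DataFrame({
                "contig": cid,
                "position": np.arange(n, dtype=np.int64),
                "strand": strand,
                "base": bases,
                "n_obs": n_obs.astype(np.int64),
                "mean_logipd": mean,
                "sd_logipd": sd,
            }))
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["contig", "position", "strand"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


def write_kinetics(tracks: pd.DataFrame, path: str) -> None:
    """Kinetics table as TSV (1-based positions, NA for missing stats)."""
    import os

    out = tracks.copy()
    out["position"] = out["position"] + 1
    tmp = f"{path}.tmp{os.getpid()}"
    out.to_csv(tmp, sep="\t", index=False, na_rep="NA", float_format="%.6f")
    os.replace(tmp, path)


def read_kinetics(path: str) -> pd.DataFrame:
    """Read a kinetics TSV (inverse of :func:`write_kinetics`).

    Malformed rows are reported with their 1-based file row number.
    """
    required = ["contig", "position", "strand", "base", "n_obs",
                "mean_logipd", "sd_logipd"]
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"],
                         dtype={"contig": str, "strand": str, "base": str})
    except Exception as exc:  # surface parser row info
        raise ValueError(f"{path}: malformed kinetics table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = int(df.index[bad_strand][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: row {row}: invalid strand {df['strand'][bad_strand].iloc[0]!r}")
    if (df["n_obs"] < 0).any():
        row = int(df.index[df["n_obs"] < 0][0]) + 2
        raise ValueError(f"{path}: row {row}: negative n_obs")
    df["position"] = df["position"].astype(np.int64) - 1
    if (df["position"] < 0).any():
        row = int(df.index[df["position"] < 0][0]) + 2
        raise ValueError(f"{path}: row {row}: position must be >= 1")
    return df


# ---------------------------------------------------------------------------
# Organism-style fixtures
# ---------------------------------------------------------------------------

#: Planted motif complements emulating the six study organisms. Asymmetric
#: double-strand specificities are planted as an explicit strand pair
#: (pattern + reverse complement with mirrored offset); palindromic motifs
#: cover both strands with a single entry.
FIXTURE_DEFS: dict[str, dict] = {
    "gmet": {
        "gc": 0.59,
        "motifs": [
            ("GGATC", 2, "m6A", 1.0),     # M.GmeI, top strand
            ("GATCC", 1, "m6A", 1.0),     # M.GmeI, bottom strand
            ("TCCAGG", 3, "m6A", 1.0),    # M.GmeII, Type III, single strand
        ],
    },
    "csal": {
        "gc": 0.64,
        "motifs": [
            ("RGATCY", 2, "m6A", 0.85),          # M.CsaI, incomplete in vivo
            ("CCACNNNNNNCTC", 2, "m6A", 1.0),    # M.CsaII Type I, top
            ("GAGNNNNNNGTGG", 1, "m6A", 1.0),    # M.CsaII Type I, bottom
        ],
    },
    # 500 kb: the two Type I specificities have 8 specific positions each
    # (~10 duplex sites per 100 kb of random sequence); at 200 kb the site
    # population is too small for degenerate spacer-adjacent positions
    # (H, D) to be statistically identifiable.
    "vbr": {
        "gc": 0.45,
        "length": 500_000,
        "motifs": [
            ("GATC", 1, "m6A", 1.0),                  # M.VbrDam
            ("AGHANNNNNNNTGAC", 3, "m6A", 1.0),       # M.VbrI Type I, top
            ("GTCANNNNNNNTDCT", 3, "m6A", 1.0),       # M.VbrI Type I, bottom
            ("CTAGNNNNNNRTAA", 2, "m6A", 1.0),        # M.VbrII Type I, top
            ("TTAYNNNNNNCTAG", 2, "m6A", 1.0),        # M.VbrII Type I, bottom
        ],
    },
    "cje81": {
        "gc": 0.31,
        "motifs": [
            ("RAATTY", 2, "m6A", 1.0),           # M.CjeFI
            ("GGRCA", 4, "m6A", 1.0),            # RM.CjeFV, single strand
            ("GCAAGG", 3, "m6A", 1.0),           # RM.CjeFIII, single strand
            ("CAAYNNNNNNACT", 2, "m6A", 1.0),    # CjeFII Type I, top
            ("AGTNNNNNNRTTG", 0, "m6A", 1.0),    # CjeFII Type I, bottom
            ("TAAYNNNNNTGC", 2, "m6A", 1.0),     # CjeFIV Type I, top
            ("GCANNNNNRTTA", 2, "m6A", 1.0),     # CjeFIV Type I, bottom
        ],
    },
    "cje11168": {
        "gc": 0.31,
        "motifs": [
            ("RAATTY", 2, "m6A", 1.0),           # M.CjeNI
            ("GAGNNNNNGT", 1, "m6A", 1.0),       # RM.CjeNII, both strands
            ("ACNNNNNCTC", 0, "m6A", 1.0),       # RM.CjeNII, bottom
            ("GKAAYG", 3, "m6A", 1.0),           # RM.CjeNIII, single strand
            ("TAAYNNNNNTGC", 2, "m6A", 1.0),     # CjeNIV Type I, top
            ("GCANNNNNRTTA", 2, "m6A", 1.0),     # CjeNIV Type I, bottom
        ],
    },
    "bce": {
        "gc": 0.35,
        "motifs": [
            ("TAAGNNNNNNNTGG", 2, "m6A", 1.0),   # BceSVI Type I, top
            ("CCANNNNNNNCTTA", 2, "m6A", 1.0),   # BceSVI Type I, bottom
            ("ACGGC", 1, "m4C", 1.0),            # M1.BceSIII
            ("GCCGT", 1, "m4C", 1.0),            # M2.BceSIII
            ("GCWGC", 1, "m5C", 1.0),            # weak m5C nuisance
            ("GGWCC", 4, "m5C", 1.0),            # weak m5C nuisance
        ],
    },
}

FIXTURE_NAMES = tuple(FIXTURE_DEFS)


@dataclass
class Fixture:
    """A complete synthetic methylome: genome, planted truth, kinetics and
    the planted motif list (the expected discovery outcome)."""

    name: str
    genome: GenomeSequence
    truth: TruthSet
    tracks: pd.DataFrame
    motifs: list[IupacMotif]
    config: SimulationConfig


def _fixture_seeds(name: str, seed: int) -> tuple[int, int, int, int]:
    idx = list(FIXTURE_DEFS).index(name)
    ss = np.random.SeedSequence(entropy=[int(seed), idx, 977])
    return tuple(int(s.generate_state(1)[0]) for s in ss.spawn(4))


def make_fixture(
    name: str,
    seed: int = 0,
    genome_length: int | None = None,
    coverage_mean: float = 60.0,
) -> Fixture:
    """Build the named organism-style fixture, fully determined by ``seed``.

    ``name`` is one of gmet, csal, vbr, cje81, cje11168, bce. The default
    genome length is 200 kb (500 kb for vbr, whose bipartite specificities
    need a larger site population to be identifiable).
    """
    if name not in FIXTURE_DEFS:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    spec = FIXTURE_DEFS[name]
    if genome_length is None:
        genome_length = spec.get("length", 200_000)
    motifs = [IupacMotif(p, o, m, name=f"{name}:{p}") for p, o, m, _ in spec["motifs"]]
    planted = [(motif, f) for motif, (_, _, _, f) in zip(motifs, spec["motifs"])]
    s_genome, s_truth, s_ipd, _ = _fixture_seeds(name, seed)
    config = SimulationConfig(
        genome_length=genome_length,
        gc_fraction=spec["gc"],
        planted=planted,
        coverage_mean=coverage_mean,
        seed=s_ipd,
    )
    genome = simulate_genome(genome_length, spec["gc"], s_genome)
    truth = plant_methylation(genome, planted, s_truth)
    tracks = simulate_ipds(genome, truth, config, seed=s_ipd)
    return Fixture(name=name, genome=genome, truth=truth, tracks=tracks,
                   motifs=motifs, config=config)


def simulate_reference_tracks(
    genome: GenomeSequence, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Unmethylated kinetics for the same genome — the training material for
    the in-silico context reference."""
    return simulate_ipds(genome, TruthSet(entries=[]), config, seed=seed)
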