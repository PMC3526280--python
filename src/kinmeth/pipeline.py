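"""End-to-end workflow: simulate/load -> detect -> discover -> summarize.

Artifacts written per run (all plain text, atomically via temp + rename):

* ``modified_positions.gff3`` — one feature per retained modified position
  (type = mod_type of the assigned motif, or ``modified_DNA_base``),
  1-based, with coverage, IPD ratio, sequence context and motif attributes
* ``motifs.csv`` — discovered motif candidates with support/enrichment
* ``summary.csv`` — per-motif extent-of-methylation and RM-type table
* ``residual.csv`` — motifs found among above-threshold unassigned hits
  (expected empty for a clean methylome)
* ``coverage_gaps.bed`` — zero-coverage intervals (possible deletions)
* ``manifest.yaml`` — resolved configuration + seed; rerunning from the
  manifest reproduces every artifact byte-for-byte

Motif discovery runs iteratively: after the first round, hits unassigned
to any motif are re-windowed and discovery repeats on them (up to
``max_rounds``), mirroring — and slightly generalizing — the residual
re-analysis step of the underlying method. In genomes where one abundant
specificity floods the top hits, low-abundance (often Type I) motifs only
reach workable support in these residual rounds.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from kinmeth.detection import (
    KineticScoreRecord,
    build_context_model,
    detect_modified_positions,
    find_coverage_gaps,
    top_hits,
)
from kinmeth.discovery import (
    DiscoveryParams,
    MotifCandidate,
    assign_calls_to_motifs,
    discover_motifs,
    extract_windows,
    genome_base_probs,
    refine_motif,
    residual_motif_check,
)
from kinmeth.genome import GenomeSequence, read_fasta
from kinmeth.motifs import IupacMotif
from kinmeth.simulate import (
    FIXTURE_NAMES,
    make_fixture,
    read_kinetics,
    simulate_reference_tracks,
)
from kinmeth.summary import (
    MotifSummary,
    build_summary,
    pair_strand_motifs,
    retained_records,
    select_threshold,
    summary_frame,
)

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    # inputs: either a named fixture or external files
    fixture: str | None = None
    genome_path: str | None = None
    kinetics_path: str | None = None
    ref_kinetics_path: str | None = None
    # fixture simulation scale (genome_length None = the fixture's default)
    genome_length: int | None = None
    coverage_mean: float = 60.0
    # detection
    context_order: int = 3
    min_coverage: int = 10
    score_floor: float = 20.0
    # discovery
    window_halfwidth: int = 20
    n_top: int = 1000
    min_support: int = 5
    enrich_floor: float = 10.0
    max_rounds: int = 3
    # summary
    target_unassigned: float = 0.01
    # misc
    min_gap_len: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.fixture is None and (self.genome_path is None or self.kinetics_path is None):
            raise ValueError("need either a fixture name or genome + kinetics paths")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if not 0.0 <= self.target_unassigned < 1.0:
            raise ValueError("target_unassigned must be in [0, 1)")
        if self.n_top < 1 or self.window_halfwidth < 1 or self.context_order % 2 != 1:
            raise ValueError("invalid discovery/detection parameters")

    def discovery_params(self) -> DiscoveryParams:
        return DiscoveryParams(
            w=self.window_halfwidth,
            min_support=self.min_support,
            enrich_floor=self.enrich_floor,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: GenomeSequence
    records: list[KineticScoreRecord]
    motifs: list[IupacMotif]
    candidates: list[MotifCandidate]
    threshold: float
    retained: list[KineticScoreRecord]
    assigned: dict[KineticScoreRecord, IupacMotif]
    unassigned: list[KineticScoreRecord]
    summaries: list[MotifSummary]
    residual: list[MotifCandidate]
    gaps: list[tuple[str, int, int]]
    truth: object = None
    artifacts: dict[str, str] = field(default_factory=dict)

    @property
    def clean_residual(self) -> bool:
        return not self.residual

    @property
    def threshold_attained(self) -> bool:
        return math.isfinite(self.threshold)


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _gff3_text(
    records: list[KineticScoreRecord],
    assigned: dict[KineticScoreRecord, IupacMotif],
    genome: GenomeSequence,
    w: int,
) -> str:
    from kinmeth.discovery import extract_windows as _ew

    order = {cid: i for i, cid in enumerate(genome.ids())}
    recs = sorted(records, key=lambda r: (order[r.contig], r.position, r.strand))
    wins = _ew(recs, genome, w=w)
    lines = ["##gff-version 3"]
    for rec, win in zip(recs, wins):
        motif = assigned.get(rec)
        ftype = motif.mod_type if motif else "modified_DNA_base"
        attrs = (
            f"coverage={rec.n_obs};IPDRatio={rec.ipd_ratio:.4f};"
            f"context={win.seq};motif={motif.pattern if motif else 'unassigned'}"
        )
        lines.append("\t".join([
            rec.contig, "kinmeth", ftype,
            str(rec.position + 1), str(rec.position + 1),
            f"{rec.score:.2f}", rec.strand, ".", attrs,
        ]))
    return "\n".join(lines) + "\n"


def _candidates_csv(cands: list[MotifCandidate]) -> str:
    lines = ["pattern,methylated_offset,mod_type,support,enrichment,log10_p,mean_score"]
    for c in cands:
        lp = f"{c.log10_p:.4f}" if math.isfinite(c.log10_p) else "-inf"
        ms = f"{c.mean_score:.2f}" if math.isfinite(c.mean_score) else ""
        lines.append(
            f"{c.motif.pattern},{c.motif.methylated_offset},{c.motif.mod_type},"
            f"{c.support},{c.enrichment:.4g},{lp},{ms}"
        )
    return "\n".join(lines) + "\n"


def _manifest_text(config: PipelineConfig) -> str:
    payload = {
        "tool": "kinmeth",
        "version": _VERSION,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
    }
    return yaml.safe_dump(payload, sort_keys=True)


def config_from_manifest(path: str) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return PipelineConfig(**payload["config"])


def _load_inputs(config: PipelineConfig):
    """Returns (genome, tracks, context_model_training_tracks, truth|None)."""
    if config.fixture is not None:
        fx = make_fixture(
            config.fixture,
            seed=config.seed,
            genome_length=config.genome_length,
            coverage_mean=config.coverage_mean,
        )
        ref_seed = int(np.random.SeedSequence([config.seed, 4242]).generate_state(1)[0])
        ref = simulate_reference_tracks(fx.genome, fx.config, seed=ref_seed)
        return fx.genome, fx.tracks, ref, fx.truth
    genome = read_fasta(config.genome_path)
    tracks = read_kinetics(config.kinetics_path)
    if config.ref_kinetics_path:
        ref = read_kinetics(config.ref_kinetics_path)
    else:
        logger.warning(
            "no reference kinetics supplied; training the context model on the "
            "input tracks (methylated positions slightly inflate the reference)"
        )
        ref = tracks
    return genome, tracks, ref, None


def _iterative_discovery(
    genome: GenomeSequence,
    records: list[KineticScoreRecord],
    config: PipelineConfig,
) -> tuple[list[MotifCandidate], list[IupacMotif]]:
    """Discovery on top hits, then repeated on top unassigned hits."""
    params = config.discovery_params()
    probs = genome_base_probs(genome)
    candidates: list[MotifCandidate] = []
    motifs: list[IupacMotif] = []
    pool = records
    for round_no in range(config.max_rounds):
        if motifs:
            _, pool = assign_calls_to_motifs(records, motifs, genome)
        hits = top_hits(pool, config.n_top)
        if len(hits) < params.min_support:
            break
        windows = extract_windows(hits, genome, w=config.window_halfwidth)
        found = discover_motifs(windows, probs, params)
        new = [c for c in found
               if (c.motif.pattern, c.motif.methylated_offset)
               not in {(m.pattern, m.methylated_offset) for m in motifs}]
        if not new:
            break
        logger.info("discovery round %d: %d new motif(s)", round_no + 1,
                    len(new))
        candidates.extend(new)
        motifs.extend(c.motif for c in new)

    # polish: re-refine every motif against the windows of all detected
    # records, where low-abundance motifs are no longer diluted by the
    # top-N cut and concrete variants of a degenerate position reunite
    if motifs:
        all_windows = extract_windows(records, genome, w=config.window_halfwidth)
        polished: list[MotifCandidate] = []
        seen: set[tuple[str, int]] = set()
        for cand in candidates:
            refined = refine_motif(cand.motif, all_windows, probs, params)
            if refined is None:
                refined = cand
            key = (refined.motif.pattern, refined.motif.methylated_offset)
            if key in seen:
                continue
            seen.add(key)
            polished.append(refined)
        candidates = polished
        motifs = [c.motif for c in candidates]
    return candidates, motifs


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Execute the full workflow; write artifacts if ``outdir`` is given."""
    config.validate()
    genome, tracks, ref_tracks, truth = _load_inputs(config)

    model = build_context_model(genome, ref_tracks, k=config.context_order)
    records = detect_modified_positions(
        genome, tracks, model,
        min_coverage=config.min_coverage,
        score_floor=config.score_floor,
    )
    gaps = find_coverage_gaps(tracks, genome, min_len=config.min_gap_len)

    candidates, motifs = _iterative_discovery(genome, records, config)

    if records:
        threshold = select_threshold(
            records, motifs, genome, target_unassigned=config.target_unassigned
        )
    else:
        threshold = math.inf
    if not math.isfinite(threshold) and records:
        logger.warning(
            "unassigned-fraction target %.3f unattainable; all %d records "
            "left below threshold", config.target_unassigned, len(records)
        )
    retained = retained_records(records, threshold)
    assigned, unassigned = assign_calls_to_motifs(retained, motifs, genome)

    groups = pair_strand_motifs(motifs)
    summaries = build_summary(genome, groups, records, threshold)

    probs = genome_base_probs(genome)
    residual_windows = extract_windows(
        top_hits(unassigned, config.n_top), genome, w=config.window_halfwidth
    )
    residual = residual_motif_check(residual_windows, probs,
                                    config.discovery_params())

    result = PipelineResult(
        config=config, genome=genome, records=records, motifs=motifs,
        candidates=candidates, threshold=threshold, retained=retained,
        assigned=assigned, unassigned=unassigned, summaries=summaries,
        residual=residual, gaps=gaps, truth=truth,
    )
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    config = result.config
    paths = {}

    paths["gff3"] = os.path.join(outdir, "modified_positions.gff3")
    _atomic_write(paths["gff3"], _gff3_text(
        result.retained, result.assigned, result.genome, config.window_halfwidth
    ))

    paths["motifs"] = os.path.join(outdir, "motifs.csv")
    _atomic_write(paths["motifs"], _candidates_csv(result.candidates))

    paths["summary"] = os.path.join(outdir, "summary.csv")
    thr = f"{result.threshold:.2f}" if math.isfinite(result.threshold) else "inf"
    frame = summary_frame(result.summaries)
    paths_text = f"# kinetic score threshold: {thr}\n" + frame.to_csv(index=False)
    _atomic_write(paths["summary"], paths_text)

    paths["residual"] = os.path.join(outdir, "residual.csv")
    _atomic_write(paths["residual"], _candidates_csv(result.residual))

    paths["gaps"] = os.path.join(outdir, "coverage_gaps.bed")
    gap_lines = [
        f"{cid}\t{start}\t{end}\tcoverage_gap\t0\t." for cid, start, end in result.gaps
    ]
    _atomic_write(paths["gaps"], "\n".join(gap_lines) + ("\n" if gap_lines else ""))

    paths["manifest"] = os.path.join(outdir, "manifest.yaml")
    _atomic_write(paths["manifest"], _manifest_text(config))

    result.artifacts = paths
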