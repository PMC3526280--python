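"""Threshold selection, extent of methylation, pairing and RM typing."""

import itertools
import math

import numpy as np
import pytest

from kinmeth.detection import (
    KineticScoreRecord,
    build_context_model,
    detect_modified_positions,
)
from kinmeth.genome import GenomeSequence
from kinmeth.motifs import IupacMotif, scan_motif
from kinmeth.summary import (
    MotifGroup,
    build_summary,
    classify_rm_type,
    methylation_extent,
    pair_strand_motifs,
    retained_records,
    select_threshold,
    summary_frame,
)
from kinmeth.simulate import (
    SimulationConfig,
    TruthSet,
    plant_methylation,
    simulate_genome,
    simulate_ipds,
)

GATC = IupacMotif("GATC", 1, "m6A")


def _rec(pos, score, contig="c", strand="+"):
    return KineticScoreRecord(contig, pos, strand, "A", float(score), 60, 3.0)


def _flagged_instance(scores, flags):
    """Genome + motif + records realizing given scores and assigned flags.

    The genome is a run of AGATCA blocks; records with flag True sit on the
    GATC adenine, records with flag False on an off-motif position.
    """
    block = "AGATCAGG"  # GATC at offset 1..4, methylated A at 2
    seq = block * len(scores)
    g = GenomeSequence(contigs=[("c", seq)])
    records = []
    for i, (score, flag) in enumerate(zip(scores, flags)):
        pos = 8 * i + (2 if flag else 6)
        records.append(_rec(pos, score))
    records.sort(key=lambda r: (-r.score, r.position))
    return g, [GATC], records


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def test_threshold_all_assigned_keeps_everything():
    g, motifs, records = _flagged_instance([90, 70, 50], [True, True, True])
    assert select_threshold(records, motifs, g) == 50.0


def test_threshold_spec_example():
    scores = [100, 90, 80, 70, 60, 50]
    flags = [True, True, True, True, False, True]
    g, motifs, records = _flagged_instance(scores, flags)
    assert select_threshold(records, motifs, g, target_unassigned=0.2) == 50.0


def test_threshold_target_zero_excludes_unassigned():
    scores = [100, 90, 80, 70, 60, 50]
    flags = [True, True, True, True, False, True]
    g, motifs, records = _flagged_instance(scores, flags)
    assert select_threshold(records, motifs, g, target_unassigned=0.0) == 70.0


def test_threshold_unattainable_returns_sentinel():
    g, motifs, records = _flagged_instance([80], [False])
    assert select_threshold(records, motifs, g, target_unassigned=0.0) == math.inf


def test_threshold_empty_records_is_an_error():
    g, motifs, _ = _flagged_instance([10], [True])
    with pytest.raises(ValueError):
        select_threshold([], motifs, g)


def _sweep_oracle(scores, flags, target):
    """Exhaustive check of every distinct score cut (largest retained set)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    scores = [scores[i] for i in order]
    flags = [flags[i] for i in order]
    best = None
    for cut in sorted(set(scores)):
        kept = [f for s, f in zip(scores, flags) if s >= cut]
        if not kept:
            continue
        frac = sum(not f for f in kept) / len(kept)
        if frac <= target and (best is None or len(kept) > best[1]):
            best = (cut, len(kept))
    return math.inf if best is None else float(best[0])


def test_threshold_matches_exhaustive_sweep():
    rng = np.random.default_rng(83)
    for _ in range(40):
        n = int(rng.integers(1, 60))
        scores = rng.integers(1, 15, size=n) * 10.0  # many ties
        flags = rng.random(n) < 0.7
        target = float(rng.choice([0.0, 0.05, 0.1, 0.3]))
        g, motifs, records = _flagged_instance(list(scores), list(flags))
        got = select_threshold(records, motifs, g, target_unassigned=target)
        want = _sweep_oracle(list(scores), list(flags), target)
        assert got == want


def test_threshold_monotone_in_target():
    rng = np.random.default_rng(89)
    scores = rng.integers(1, 20, size=50) * 10.0
    flags = rng.random(50) < 0.6
    g, motifs, records = _flagged_instance(list(scores), list(flags))
    targets = [0.0, 0.01, 0.05, 0.1, 0.2, 0.5]
    thrs = [select_threshold(records, motifs, g, target_unassigned=t)
            for t in targets]
    assert all(a >= b for a, b in zip(thrs, thrs[1:]))


# ---------------------------------------------------------------------------
# extent of methylation
# ---------------------------------------------------------------------------


def test_extent_no_records():
    g = GenomeSequence(contigs=[("c", "AAGATCAA")])
    n_det, n_sites, frac = methylation_extent(g, GATC, [])
    assert (n_det, n_sites, frac) == (0, 2, 0.0)


@pytest.mark.parametrize("f", [0.25, 0.5, 0.75, 1.0])
def test_extent_recovers_planted_fraction(f):
    """End-to-end extent estimate within the binomial 99% CI of f."""
    g = simulate_genome(40_000, 0.5, seed=int(f * 100))
    truth = plant_methylation(g, [(GATC, f)], seed=7)
    cfg = SimulationConfig(genome_length=40_000, coverage_mean=60.0, seed=7)
    tracks = simulate_ipds(g, truth, cfg)
    null = simulate_ipds(g, TruthSet(entries=[]), cfg, seed=8)
    model = build_context_model(g, null, k=3)
    records = detect_modified_positions(g, tracks, model,
                                        min_coverage=10, score_floor=60.0)
    n_det, n_sites, frac = methylation_extent(g, GATC, records)
    half = 2.576 * math.sqrt(f * (1 - f) / n_sites)
    assert abs(frac - f) <= half + 0.01


# ---------------------------------------------------------------------------
# strand pairing
# ---------------------------------------------------------------------------


def test_pairing_complementary_pair():
    m1 = IupacMotif("GGATC", 2, "m6A")
    m2 = IupacMotif("GATCC", 1, "m6A")
    groups = pair_strand_motifs([m1, m2])
    assert len(groups) == 1
    assert groups[0].double_strand and set(groups[0].motifs) == {m1, m2}


def test_pairing_self_complementary():
    m = IupacMotif("RGATCY", 2, "m6A")
    [group] = pair_strand_motifs([m])
    assert group.double_strand and group.motifs == [m]


def test_pairing_single_strand_motif():
    m = IupacMotif("TCCAGG", 3, "m6A")
    [group] = pair_strand_motifs([m])
    assert not group.double_strand


def test_pairing_is_a_partition_invariant_under_order():
    motifs = [
        IupacMotif("GGATC", 2, "m6A"),
        IupacMotif("GATCC", 1, "m6A"),
        IupacMotif("TCCAGG", 3, "m6A"),
        IupacMotif("RGATCY", 2, "m6A"),
        IupacMotif("ACGGC", 1, "m4C"),
        IupacMotif("GCCGT", 1, "m4C"),
    ]
    canonical = None
    for perm in itertools.islice(itertools.permutations(motifs), 0, 720, 77):
        groups = pair_strand_motifs(list(perm))
        seen = [m for grp in groups for m in grp.motifs]
        assert sorted(seen, key=str) == sorted(motifs, key=str)
        assert len(seen) == len(motifs)  # each motif in exactly one group
        shape = sorted(
            (tuple(sorted(str(m) for m in grp.motifs)), grp.double_strand)
            for grp in groups
        )
        if canonical is None:
            canonical = shape
        assert shape == canonical


def test_mixed_mod_types_do_not_pair():
    m1 = IupacMotif("ACGGC", 1, "m4C")
    m2 = IupacMotif("GCCGT", 1, "m5C")  # revcomp pattern but different chemistry
    groups = pair_strand_motifs([m1, m2])
    assert len(groups) == 2


# ---------------------------------------------------------------------------
# RM typing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("motifs,double,label", [
    ([IupacMotif("CCACNNNNNNCTC", 2, "m6A")], True, "TypeI"),
    ([IupacMotif("GGRCA", 4, "m6A")], False, "TypeIII_or_IIG"),
    ([IupacMotif("RGATCY", 2, "m6A")], True, "TypeII"),
    ([IupacMotif("CCACNNNNNNCTC", 2, "m6A")], False, "unclassified"),
])
def test_classify_rm_type(motifs, double, label):
    assert classify_rm_type(MotifGroup(motifs=motifs, double_strand=double)).label == label


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


def test_gmet_summary_three_rows_two_groups(pipeline_for):
    res = pipeline_for("gmet")
    groups = pair_strand_motifs(res.motifs)
    assert len(groups) == 2
    assert len(res.summaries) == 3
    assert all(0.0 <= s.fraction <= 1.0 for s in res.summaries)
    patterns = {s.motif.pattern for s in res.summaries}
    assert patterns == {"GGATC", "GATCC", "TCCAGG"}


def test_summary_deterministic_bytes(pipeline_for):
    res = pipeline_for("gmet")
    groups = pair_strand_motifs(res.motifs)
    rows1 = build_summary(res.genome, groups, res.records, res.threshold)
    rows2 = build_summary(res.genome, groups, res.records, res.threshold)
    assert summary_frame(rows1).to_csv(index=False) == summary_frame(rows2).to_csv(index=False)


def test_summary_rows_ordered_by_site_count(pipeline_for):
    res = pipeline_for("gmet")
    counts = [s.n_sites for s in res.summaries]
    assert counts == sorted(counts, reverse=True)


def test_retained_records_filter():
    records = [_rec(0, 90), _rec(1, 50), _rec(2, 10)]
    assert retained_records(records, 50.0) == records[:2]
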