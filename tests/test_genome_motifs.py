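"""Genome container, IUPAC algebra and motif scanning."""

import pytest
from hypothesis import given, settings, strategies as st

from kinmeth.genome import FastaError, GenomeSequence, read_fasta, write_fasta
from kinmeth.motifs import (
    IUPAC_TO_BASES,
    IupacMotif,
    MotifError,
    duplex_site_count,
    expand_iupac,
    matches_at,
    revcomp_iupac,
    scan_motif,
    write_bed,
)

IUPAC_CODES = "ACGTRYMKSWBDHVN"


# ---------------------------------------------------------------------------
# FASTA round trips and validation
# ---------------------------------------------------------------------------


def test_read_single_record(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">c1\nACGT\n")
    g = read_fasta(p)
    assert g.ids() == ["c1"]
    assert g.seq("c1") == "ACGT"
    assert g.length("c1") == 4


def test_fasta_round_trip(tmp_path):
    g = GenomeSequence(contigs=[("chrA", "ACGTACGTGGCC"), ("p1", "TTTTAA")])
    p = tmp_path / "rt.fasta"
    write_fasta(g, p)
    assert read_fasta(p) == g


def test_ambiguity_codes_rejected_with_location(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">c1\nACGTN\n")
    with pytest.raises(FastaError, match=r"c1.*offset 4"):
        read_fasta(p)


@pytest.mark.parametrize("text,match", [
    ("", "empty"),
    ("ACGT\n", "header"),
])
def test_malformed_fasta(tmp_path, text, match):
    p = tmp_path / "x.fasta"
    p.write_text(text)
    with pytest.raises(FastaError, match=match):
        read_fasta(p)


def test_genome_invariants():
    with pytest.raises(FastaError, match="duplicate"):
        GenomeSequence(contigs=[("a", "ACGT"), ("a", "GGGG")])
    with pytest.raises(FastaError, match="empty sequence"):
        GenomeSequence(contigs=[("a", "")])


# ---------------------------------------------------------------------------
# IUPAC algebra
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("pattern,expected", [
    ("RGATCY", "RGATCY"),        # self-reverse-complementary
    ("GGATC", "GATCC"),
    ("CCACNNNNNNCTC", "GAGNNNNNNGTGG"),
])
def test_revcomp_examples(pattern, expected):
    assert revcomp_iupac(pattern) == expected


def test_revcomp_invalid_code():
    with pytest.raises(MotifError):
        revcomp_iupac("ACGX")


@given(st.text(alphabet=IUPAC_CODES, min_size=1, max_size=30))
@settings(max_examples=200, deadline=None)
def test_revcomp_involution(pattern):
    assert revcomp_iupac(revcomp_iupac(pattern)) == pattern


def test_revcomp_is_basewise_complement():
    # reverse complement = complement of each code, reversed
    pattern = "CCACNNNNNNCTC"
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    manual = "".join(comp[c] for c in pattern)[::-1]
    assert revcomp_iupac(pattern) == manual


@pytest.mark.parametrize("pattern,expected", [
    ("GCWGC", {"GCAGC", "GCTGC"}),
    ("RY", {"AC", "AT", "GC", "GT"}),
    ("N", {"A", "C", "G", "T"}),
])
def test_expand_examples(pattern, expected):
    assert expand_iupac(pattern) == expected


def test_expand_size_guard():
    with pytest.raises(MotifError, match="max_size"):
        expand_iupac("N" * 10, max_size=1000)


# ---------------------------------------------------------------------------
# motif type invariants
# ---------------------------------------------------------------------------


def test_motif_offset_compatibility():
    IupacMotif("GATC", 1, "m6A")
    IupacMotif("GCWGC", 1, "m5C")
    with pytest.raises(MotifError):
        IupacMotif("GATC", 0, "m6A")   # G cannot carry m6A
    with pytest.raises(MotifError):
        IupacMotif("GATC", 1, "m4C")   # A cannot carry m4C


def test_bipartite_detection_and_half_sites():
    m = IupacMotif("CCACNNNNNNCTC", 2, "m6A")
    assert m.is_bipartite
    assert m.half_sites() == ("CCAC", 6, "CTC")
    assert not IupacMotif("TCCAGG", 3, "m6A").is_bipartite
    # a short internal N run is not a spacer
    assert not IupacMotif("GAGNNGT", 1, "m6A").is_bipartite
    with pytest.raises(MotifError, match="half-site"):
        IupacMotif("ANNNNTTT", 0, "m6A")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _genome(seq, circular=False):
    return GenomeSequence(contigs=[("c", seq)], circular={"c": circular})


def test_scan_palindrome_hits_both_strands():
    sites = scan_motif(_genome("AAGATCAA"), IupacMotif("GATC", 1, "m6A"))
    assert [(s.position, s.strand) for s in sites] == [(3, "+"), (4, "-")]


def test_scan_no_occurrence():
    assert scan_motif(_genome("AAAAAAAAAA"), IupacMotif("TCCAGG", 3, "m6A")) == []


def test_scan_bipartite_single_instance():
    # one CCACNNNNNNCTC instance inside a 30-mer
    seq = "TT" + "CCAC" + "GGGGGG" + "CTC" + "TTTTTTTTTTTTTTT"
    plus = scan_motif(_genome(seq), IupacMotif("CCACNNNNNNCTC", 2, "m6A"))
    assert [(s.position, s.strand) for s in plus] == [(4, "+")]
    minus = scan_motif(_genome(seq), IupacMotif("GAGNNNNNNGTGG", 1, "m6A"))
    assert [(s.position, s.strand) for s in minus] == [(13, "-")]


def test_scan_circular_wraps_origin():
    # GATC split across the origin: ...GA | TC...
    seq = "TCGGGGGA"
    motif = IupacMotif("GATC", 1, "m6A")
    assert scan_motif(_genome(seq), motif) == []
    wrapped = scan_motif(_genome(seq, circular=True), motif)
    assert {(s.position, s.strand) for s in wrapped} == {(7, "+"), (0, "-")}


def _brute_force_sites(seq, motif):
    """Oracle: expand the pattern and compare every placement on both strands."""
    L = len(motif.pattern)
    out = set()
    fwd = expand_iupac(motif.pattern, max_size=65536)
    rev = expand_iupac(revcomp_iupac(motif.pattern), max_size=65536)
    for start in range(len(seq) - L + 1):
        chunk = seq[start:start + L]
        if chunk in fwd:
            out.add((start + motif.methylated_offset, "+"))
        if chunk in rev:
            out.add((start + L - 1 - motif.methylated_offset, "-"))
    return out


MOTIF_POOL = [
    IupacMotif("GATC", 1, "m6A"),
    IupacMotif("RGATCY", 2, "m6A"),
    IupacMotif("GCWGC", 1, "m5C"),
    IupacMotif("TCCAGG", 3, "m6A"),
    IupacMotif("CCACNNNNNNCTC", 2, "m6A"),
    IupacMotif("GKAAYG", 3, "m6A"),
    IupacMotif("ACGGC", 1, "m4C"),
]


@given(
    seq=st.text(alphabet="ACGT", min_size=10, max_size=2000),
    motif_idx=st.integers(min_value=0, max_value=len(MOTIF_POOL) - 1),
)
@settings(max_examples=60, deadline=None)
def test_scan_equals_brute_force(seq, motif_idx):
    motif = MOTIF_POOL[motif_idx]
    got = {(s.position, s.strand) for s in scan_motif(_genome(seq), motif)}
    assert got == _brute_force_sites(seq, motif)


@given(
    seq=st.text(alphabet="ACGT", min_size=20, max_size=1000),
    motif_idx=st.integers(min_value=0, max_value=len(MOTIF_POOL) - 1),
)
@settings(max_examples=40, deadline=None)
def test_scan_strand_symmetry(seq, motif_idx):
    """Sites of a motif mirror the sites of its reverse complement with the
    mirrored offset, with strands swapped."""
    m = MOTIF_POOL[motif_idx]
    L = len(m.pattern)
    rc_pat = revcomp_iupac(m.pattern)
    mirrored = L - 1 - m.methylated_offset
    mod = m.mod_type
    if mod == "m6A" and "A" not in IUPAC_TO_BASES[rc_pat[mirrored]]:
        mod = "m4C" if "C" in IUPAC_TO_BASES[rc_pat[mirrored]] else None
    elif mod != "m6A" and "C" not in IUPAC_TO_BASES[rc_pat[mirrored]]:
        mod = "m6A" if "A" in IUPAC_TO_BASES[rc_pat[mirrored]] else None
    if mod is None:
        return
    rc = IupacMotif(rc_pat, mirrored, mod)
    flip = {"+": "-", "-": "+"}
    got = {(s.position, flip[s.strand]) for s in scan_motif(_genome(seq), rc)}
    want = {(s.position, s.strand) for s in scan_motif(_genome(seq), m)}
    assert got == want


def test_palindrome_strand_counts_equal():
    import numpy as np

    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    for motif in (IupacMotif("RGATCY", 2, "m6A"), IupacMotif("GATC", 1, "m6A")):
        sites = scan_motif(_genome(seq), motif)
        plus = sum(s.strand == "+" for s in sites)
        minus = sum(s.strand == "-" for s in sites)
        assert plus == minus


def test_duplex_site_count_palindrome():
    # palindromic duplex occurrences counted once, per-strand positions twice
    g = _genome("AAGATCAA")
    motif = IupacMotif("GATC", 1, "m6A")
    assert duplex_site_count(g, motif) == 1
    assert len(scan_motif(g, motif)) == 2


# ---------------------------------------------------------------------------
# matches_at
# ---------------------------------------------------------------------------


def test_matches_at_examples():
    g = _genome("AAGATCAA")
    assert matches_at(g, "c", 3, "+", "GATC", 1)
    assert not matches_at(g, "c", 3, "-", "GATC", 1)
    assert matches_at(g, "c", 4, "-", "GATC", 1)
    # placement running off the contig end
    assert not matches_at(g, "c", 1, "+", "GATC", 1)
    assert not matches_at(g, "c", 7, "+", "GATC", 1)


def test_write_bed(tmp_path):
    g = _genome("AAGATCAA")
    sites = scan_motif(g, IupacMotif("GATC", 1, "m6A"))
    p = tmp_path / "sites.bed"
    write_bed(sites, str(p))
    rows = [line.split("\t") for line in p.read_text().splitlines()]
    assert rows == [
        ["c", "3", "4", "GATC", "0", "+"],
        ["c", "4", "5", "GATC", "0", "-"],
    ]
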