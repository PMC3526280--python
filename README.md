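# kinmeth

Bacterial methylome determination from single-molecule sequencing
kinetics.

DNA methyltransferases (MTases) — mostly components of
restriction–modification (RM) systems — decorate bacterial genomes with
N6-methyladenine (m6A) and N4-methylcytosine (m4C). During single-molecule
real-time sequencing a modified template base lengthens the polymerase's
interpulse durations (IPDs), so the methylome can be read directly from
sequencing kinetics: every modified position, on each strand, genome-wide.
`kinmeth` implements that analysis for microbiologists and genome
annotators: it calls modified bases from per-position IPD summaries,
derives the MTase recognition motifs (degenerate sites like RGATCY,
bipartite Type I sites like CCAC(N)6CTC), quantifies how completely each
specificity is methylated, and classifies the responsible RM system type.
A synthetic-kinetics generator with planted methylomes modeled on six
well-studied bacteria makes the whole pipeline testable without real
sequencing data.

## The statistic and the algorithm

Each position/strand carries a summary (n, m, s) of its aligned log-IPDs.
Modification is detected with a one-sided one-sample t-test against an
in-silico sequence-context reference mean mu_ctx (a per-3-mer table trained
on unmethylated kinetics):

    t = (m − mu_ctx) / (s / √n),   score = −10·log10 P(T_{n−1} > t)

The Phred-like *kinetic score* is thresholded so that at most 1% of
retained hits match no discovered motif (5% in m4C-dominated genomes).
Motifs are found from ±20 bp windows around the top 1000 hits: windows are
center-anchored on the called base, so candidate motifs are scored by
*positioned* binomial enrichment of contiguous k-mers and spaced dyads
(half-sites 2–5 nt, spacers 4–9 nt — the Type I architecture), then
greedily generalized to IUPAC degeneracy, extended, masked and re-fit.
Complementary strand motifs (e.g. GGATC/GATCC) are paired into duplex
specificities, and RM type follows the structure: bipartite + both strands
= Type I, contiguous + both strands = Type II, contiguous + one strand =
Type III/IIG.

## Worked example

Analyze the *G. metallireducens*-style synthetic methylome (200 kb genome,
three planted m6A specificities, ~60× per-strand coverage):

```python
from kinmeth import PipelineConfig, run_pipeline
from kinmeth.summary import pair_strand_motifs, classify_rm_type

result = run_pipeline(PipelineConfig(fixture="gmet", seed=1))
print(f"detected positions: {len(result.records)}")
print(f"score threshold:    {result.threshold:.1f}")
print(f"retained calls:     {len(result.retained)}")
for group in pair_strand_motifs(result.motifs):
    label = classify_rm_type(group).label
    print(f"{label:>15}: {' / '.join(str(m) for m in group.motifs)}")
for s in result.summaries:
    print(f"  {s.motif.pattern:>7}  {s.n_detected}/{s.n_sites} sites methylated "
          f"({100*s.fraction:.1f}%), mean score {s.mean_score:.0f}")
```

prints

```
detected positions: 2876
score threshold:    42.9
retained calls:     876
         TypeII: GGATC@2/m6A / GATCC@1/m6A
 TypeIII_or_IIG: TCCAGG@3/m6A
    GATCC  441/441 sites methylated (100.0%), mean score 254
    GGATC  441/441 sites methylated (100.0%), mean score 253
   TCCAGG  124/124 sites methylated (100.0%), mean score 258
```

Reading this: 2876 positions scored above the detection floor (the excess
over the 876 retained are low-scoring noise removed by the 1%-unassigned
threshold of 42.9). Discovery recovered exactly the planted complement —
a fused-MTase Type II pair methylating GG**A**TC and its complement
G**A**TCC, and the single-strand Type III site TCC**A**GG (`@k` marks the
methylated offset) — and every genomic site of all three specificities is
detected as methylated, the hallmark of fully active MTases.

The same workflow runs from the shell:

```sh
kinmeth run-all --fixture gmet --seed 1 --out results/gmet
```

writing a modified-position GFF3, motif and summary CSVs, a residual
report, a coverage-gap BED and a manifest from which the run can be
replayed byte-for-byte (`kinmeth run-all --manifest ... --out ...`).
External data enter through `--genome` (FASTA) and `--kinetics` (TSV of
per-position/per-strand log-IPD summaries; see `kinmeth simulate` output
for the format).

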