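# Methods

`kinmeth` determines bacterial methylomes from single-molecule sequencing
kinetics: it calls modified bases (N6-methyladenine, N4-methylcytosine) from
per-position interpulse-duration (IPD) summaries, derives the
methyltransferase (MTase) recognition motifs — including degenerate and
bipartite Type I sites — from the called positions, and summarizes the
extent of methylation and restriction–modification (RM) system type per
specificity. A synthetic-kinetics generator makes every stage testable at
desk scale.

## The kinetic score

At each genomic position and strand the input is a summary of the log-IPD
observations aligned there: count `n`, mean `m`, and standard deviation
`s`. Modification of the template base lengthens IPDs, so the statistic is
a one-sided one-sample t-test of `m` against an in-silico sequence-context
reference mean `mu_ctx`:

    t = (m - mu_ctx) / (s / sqrt(n)),    p = P(T_{n-1} > t)
    score = -10 * log10(p)   (capped at 1000)

Working in log space makes the heavy-tailed IPD distribution approximately
normal and the test well calibrated. The reference is a table of per
centered-k-mer (k = 3 by default) means trained on unmethylated kinetics of
the same genome; contexts unseen in training fall back to the global mean.
Reference uncertainty is ignored (it is negligible whenever thousands of
positions share a context; with fewer the score degrades gracefully toward
anti-conservatism, which the threshold rule later absorbs). Positions are
scored only where the strand base is A or C — the m6A/m4C chemistry —
because 5-methylcytosine produces a signal too weak and diffuse for
genome-wide calling; the default gates are coverage >= 10 per strand and
score >= 20 (p = 0.01) before threshold refinement.

## Motif discovery

Every detection window is centered on a called base, so motifs are searched
*positioned*: a candidate's methylated offset is pinned to the window
center and no alignment is needed. Discovery iterates four steps:

1. **Seeds.** All contiguous 4–8-mers covering the center and all spaced
   dyads (half-sites of 2–5 nt separated by 4–9 nonspecific positions —
   bracketing the 3–5 nt half-sites and 5–8 nt spacers of known Type I
   sites) are enumerated at their observed offsets. A seed's support is
   its positioned window count; its p-value is the binomial upper tail of
   the support against the background match probability (order-0 genome
   composition), Bonferroni-corrected over all enumerated seeds
   (significance gate 0.01, support >= 5, enrichment >= 10).
2. **Refinement.** From the most significant seed, three moves repeat to a
   fixpoint: *widening* a position to an IUPAC superset when the added
   base's windows raise support by >= 25% and the base is not depleted at
   that column (the depletion guard stops a motif from absorbing the flank
   of an overlapping complementary-strand motif); *specifying* an interior
   spacer column whose base composition is significantly constrained
   (recovers degenerate positions swallowed by a dyad spacer, e.g. the Y
   of TAAYN5TGC); and *extending* by one flanking column when a base set
   of size <= 3 covers the supporters with a relative lift >= 0.38 over
   its background probability at per-column alpha 2e-4. The lift floor
   sits between the lift of a pure supporting population (~0.5 or more)
   and the second-order lift (~0.23) produced by a 50/50 mixture of two
   overlapping strand motifs, which is what makes the GGATC/GATCC-style
   pairs separable.
3. **Masking.** Supporting windows are removed and the search repeats.
4. **Refit.** Each candidate is re-fit against the unmasked windows;
   columns whose coverage lift vanishes there are pruned. Hard masking
   creates anti-correlated shadows (after the GGATC windows are consumed,
   the remaining GATCC windows appear G-depleted upstream), and this pass
   removes them. The final pattern must re-pass the significance gate two
   orders stricter than the seed gate, because refinement selects over
   many patterns per seed and can loosen one into a chance cluster.

The pipeline runs discovery on the top 1000 hits, then repeatedly on the
top unassigned hits (3 rounds maximum): in genomes where one abundant
specificity floods the top hits (Dam-dominated V. breoganii), rarer Type I
motifs only reach workable support among the residuals. A final *polish*
re-refines every motif against the windows of all detected positions, where
support is undiluted and concrete variants of a degenerate position (the H
of AGHAN7TGAC arrives as three separate seeds) reunite.

A discovered motif's modification type is read from its center base: A
means m6A; C means m4C unless the mean kinetic score of its supporting hits
is below 40, in which case it is reported as m5C — the weak/diffuse end of
the signal-strength ordering.

## Threshold, extent, pairing and typing

The reported methylome uses a single score threshold chosen by the
unassigned-fraction rule: the lowest cutoff (largest retained set, ties in
score kept together) at which at most 1% of retained hits match none of
the discovered motifs (5% for m4C-dominated genomes, whose weaker signals
blur into the noise tail). If no cutoff attains the target the pipeline
continues with an infinite sentinel and a prominent warning. Extent of
methylation for a motif is the fraction of its per-strand genomic positions
(both strands of a palindromic site count as two; duplex-footprint counts
are also emitted) carrying a retained call.

Motifs whose patterns are reverse complements of each other (same
modification type) are paired as the two strands of one duplex
specificity; a self-reverse-complementary motif covers both strands alone.
RM-type calls follow the structural heuristic: bipartite + double-strand =
Type I; contiguous + double-strand = Type II; contiguous + single-strand =
Type III or IIG; bipartite + single-strand is flagged unclassified. The
heuristic mislabels the rare Type IIG enzymes that methylate both strands
(e.g. a GAGN5GT-type specificity is called Type I); distinguishing those
requires gene-level evidence outside this package's scope.

## The synthetic generator

The generator emulates whole-genome bacterial methylome runs: an i.i.d.
random genome at an organism-like GC content, a planted motif complement,
and per-position/per-strand log-IPD summaries. Unmethylated positions are
Normal(mu_ctx, sigma) in log space with per-3-mer baselines (sigma = 0.6);
methylation shifts the mean by delta(m6A) = ln 4, delta(m4C) = ln 2,
delta(m5C) = ln 1.2, and m5C leaks half its shift to the two adjacent
positions on the same strand (the diffuse signal). Per-strand coverage is
Poisson with mean 60. Only (n, mean, SD) are retained, drawn from their
exact sampling distributions, which keeps the null t-test exactly
calibrated by construction. Each motif site is methylated independently
with probability f (1.0 for fully active MTases; 0.85 for the deliberately
incomplete RGATCY methylation).

Six fixtures mirror the motif complements of the study organisms
(G. metallireducens, C. salexigens, V. breoganii, C. jejuni 81-176,
C. jejuni NCTC 11168, B. cereus), with asymmetric double-strand
specificities planted as explicit strand pairs. Genomes are 200 kb —
large enough that every contiguous specificity has hundreds of sites —
except V. breoganii's 500 kb: its two Type I specificities fix 8 positions
each (~10 duplex sites per 100 kb), and at 200 kb the ~20 supporting
windows per oriented pattern cannot statistically distinguish a true
3-base degenerate column from a skewed spacer column.

What the generator does *not* model limits what green tests show about
real data: there is no alignment error, no polymerase pausing or damage,
no per-read IPD structure (summaries are drawn directly from sampling
distributions), no phosphorothioate or other backbone modification
signals, no sequence-composition structure beyond mononucleotide
frequencies, and real IPD context effects are far stronger and longer-range
than the k = 3 baseline used here. Passing fixtures demonstrates the
statistical machinery end to end, not robustness to platform artifacts.

## Numerical and design choices

* Binomial tails are computed by direct log-space term summation
  (`log10_binom_sf`), exact and finite far below float underflow, so
  extremely significant seeds remain comparable.
* Ties everywhere break deterministically: detection orders by
  (score desc, contig, position, strand with + before -); equally
  significant seeds break lexicographically by pattern; records with equal
  scores cross a threshold together.
* Degenerate inputs: empty track tables detect to nothing; an empty record
  list is an error for threshold selection; motifs scanning an empty or
  too-short contig return no sites; coverage-0 simulations produce NaN
  summaries that are skipped with n < 2.
* Coordinates are 0-based half-open internally and 1-based in all written
  artifacts (GFF3 convention); BED output stays 0-based half-open as the
  format requires.
* All randomness flows through numpy `SeedSequence` derivation from a
  single run seed; rerunning a pipeline from its manifest reproduces every
  artifact byte for byte.
* Scale choices for the test suite: null-calibration checks use 30 kb
  genomes and the no-signal discovery null uses 30 trials of 200 windows —
  sizes at which the binomial tolerances in the assertions are already
  tight while the whole suite stays fast.

## Known limitations

* Exact motif recovery is a property of site counts: specificities with
  under ~25 supporting windows can lose 3-base degenerate columns (D/H/B/V)
  or, more rarely, gain a spurious column from the fixed composition of a
  small site population.
* The m5C nuisance signal in the B. cereus fixture produces genuine weak
  shadow candidates centered on bases adjacent to the methylated cytosine
  (leakage); they are reported with correspondingly weak mean scores rather
  than suppressed.
* The unassigned-fraction rule assumes the discovered motif set is
  essentially complete; a missed true specificity inflates the threshold
  and deflates every extent estimate.
* RM typing is structural only (see above); promiscuous near-nonspecific
  MTase rules are out of the discovery envelope by design.
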