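# Methods

## The problem

Bacterial dRNA-seq (differential RNA-seq) distinguishes two kinds of RNA 5'
end at nucleotide resolution.  Nascent transcripts begin with a
5'-triphosphate, which cannot be adapter-ligated until tobacco acid
pyrophosphatase (TAP) converts it to a monophosphate; processed and
degrading RNAs already carry a 5'-monophosphate.  Sequencing the 5' ends of
the same RNA sample with and without TAP treatment therefore yields, at
each genome position, a pair of counts whose ratio separates transcription
start sites (TSSs; strongly plus-TAP enriched) from processing/degradation
sites (ratio near 1).  A third, amplification-free "global" RNA-seq
(gRNA-seq) library gives full-length strand-specific coverage, whose sharp
5' step-ups ("leading edges of transcription") independently mark
transcription-unit starts.

`drnamap` implements the complete analysis: track building from
alignments, M-A classification of 5' ends, edge detection, three-class TSS
assignment, leaderless-mRNA and processing-site annotation, small-RNA
calling, and microarray concordance, together with a synthetic-data
generator so every stage is testable without the original sequencing
libraries.

## M-A classification

For every strand-position with a minimum summed count (`min_total`,
default 5, to suppress noise-only positions),

    M = log2(plus_adj) - log2(minus_adj)
    A = (log2(plus_adj) + log2(minus_adj)) / 2

where `*_adj` are the library counts plus a pseudocount (default +1,
keeping M and A finite and conservative at low counts; a pseudocount of 0
is accepted when every retained count is positive).  Counts can optionally
be rescaled to counts-per-million of each library's total before the
pseudocount.  **Normalization is off by default**: the shipped boundary
polynomials were drawn on raw-read-count axes, so rescaling would shift
every point along A and invalidate them; turn it on (ideally together with
`fit_boundary`) when the two libraries' depths differ substantially.

A position is a TSS candidate iff `M > M_threshold(A)` (strictly), with

    S. coelicolor:  M_threshold(A) = 0.054 A^2 - 0.96 A + 4.68
    E. coli:        M_threshold(A) = -0.003 A^3 + 0.13 A^2 - 1.57 A + 7.08

shipped as the organism presets.  These boundaries were originally placed
by eye around the processing-site cone; `fit_boundary` offers an
algorithmic stand-in (per-A-bin M quantile, default 99.5%, least-squares
fitted by a polynomial of chosen degree) for data where no preset applies.

Candidate positions are merged by single-linkage chaining with an 8-nt gap:
a position joins the growing cluster when it lies within 8 nt of the
nearest previous member (promoters commonly initiate from a cluster of
adjacent positions).  We read "within 8 nt of each other" as chained
nearest-member linkage rather than a bound on cluster diameter; the
alternative would split long initiation regions arbitrarily.  The cluster
representative is the member with the highest plus-TAP count (smallest
position on ties) — the modal initiation nucleotide — rendered in tables as
`f1.<pos>` / `r1.<pos>`.

## Leading edges

The original leading-edge calls were manual; `detect_edges` is this
package's operationalization and is wholly a design choice.  At each
position `p` with a complete window on both sides, the mean depth over
`window` bp (default 50) on the transcript's 5' side and 3' side give

    fold_change = (downstream_mean + eps) / (upstream_mean + eps),  eps = 1

and `p` is an edge candidate when `fold_change >= 4` and
`downstream_mean >= 5`.  Candidate runs closer than `window` are thinned to
their max-fold member so a noisy shoulder yields one call.  For
reverse-strand transcripts the geometry is mirrored (upstream lies at
higher coordinates).  Defaults were chosen so both mRNA-scale and
rRNA-scale units produce edges; all are exposed.  Positions whose upstream
window would cross the sequence boundary are not evaluated, so a transcript
starting at base 1 of the record is not callable as an edge.

## TSS classes and processing sites

A cluster with a passing same-strand edge within `tolerance` bp (default
10; unstated in the source analysis) of any member is Class I; an enriched
cluster without one is Class II; a passing edge with no enriched cluster
within tolerance becomes a Class III entry anchored at the edge position
(no 5'-end cluster exists to anchor it).  Processing sites are the
complementary catalogue: positions with `minus_count >= 10` at or below the
boundary, excluding anything within 8 nt (the clustering gap, for symmetry)
of a class I/II member.  Cleavages that leave 5'-hydroxyl ends are
invisible to the monophosphate-specific protocol and are neither modelled
nor simulated.

## Feature-level annotation

*Leaders.*  Each class I/III TSS is assigned to the nearest same-strand
gene start at or downstream of it within 500 bp.  `leader_length` counts
the transcribed nt before the start codon (TSS at the A of ATG gives 0);
`leaderless` uses the strict threshold `leader_length < 10`.

*Offsets.*  In the `three_prime` convention a site k nt inside a feature
from its mature 3' end has offset −k and k nt past it +k (the classic
"−43" cleavage in the 3' end of 16S rRNA is literally −43); the
boundary base itself is 0.

*tRNA CCA.*  For a tRNA whose genomic 3' end encodes CCA, a 5' end at the
second C means the downstream product begins C-A: cleavage within the
motif, between the Cs.  For CCA-less tRNAs, 5' ends within 5 nt downstream
of the 3' end are reported as trailer cleavages.

*sRNAs.*  Candidates are maximal same-strand coverage runs with depth ≥ 20,
length 50–500 nt, flanking mean depth (25 bp each side) below 1/5 of the
island mean, and not fully inside a same-strand annotated gene.  Each is
screened for an inverted repeat (stem ≥ 8 bp, loop ≤ 8 nt, ≤ 1 mismatch) in
its 3'-terminal 60 nt — the signature of an intrinsic terminator — and
flagged `antisense` / `utr_adjacent` as appropriate.  A terminator hairpin
immediately (≤ 100 bp) downstream of a same-strand gene marks the candidate
as a putative decay intermediate (the stable 3' fragment of an mRNA) rather
than an independent sRNA.  Names follow the nearest-gene convention
`scr<N>(d/u +/-)`: numeric suffix of the nearest gene id (full id when
there is none), downstream/upstream in the gene's orientation, same or
opposite strand.  The length, depth and flank-fold cutoffs quantify the
qualitative criterion "short and abundant relative to background" and are
all configurable.

`find_palindrome` is an exhaustive arm-pair scan (windows capped at 200 nt)
ranking by longest stem, then shortest loop, then fewest mismatches;
non-ACGT characters never pair.

## Microarray concordance

Each 60-mer probe's sequencing signal is `log2(mean per-base depth over the
probe interval + 1)`, taken from the coverage vector of the probe's target
strand; concordance with the array's log2 RNA/gDNA signal is summarized by
Pearson's r and a least-squares line (scipy).  Zero variance or fewer than
three finite pairs make r undefined rather than raising.

## Synthetic data

The generator emulates the statistical structure the classifier assumes,
not any particular organism's sequence.  Defaults describe a 2-Mb GC-rich
(0.72; an E. coli-like preset uses 0.51) chromosome carrying 250
non-overlapping transcription units (600–2000 bp, lognormal expression,
sigma 0.4), one processing site per kb of unit body, 20 intergenic sRNA
units, and 15% leaderless genes.  Per-site 5'-end counts are negative
binomial (size = 10 — RNA-seq counts are overdispersed relative to
Poisson) around mean 30 in the minus library; plus-library means are
multiplied by a lognormal enrichment fold (log2 mean 4 = 16-fold, sd 0.5)
at TSSs and ~1 (log2 sd 0.1) at processing sites.  Minus-library TSS
counts are deliberately nonzero: a fraction of nascent ends is
de-pyrophosphorylated in vivo (RppH and similar enzymes), so TSSs appear
in both libraries at mean ratio 1:fold.  Coverage is a per-unit step
(mean 50 × expression) on background 2, NB-noised per position.  A
scattering of mean-1 background 5' ends models library noise.  Everything
derives from the config seed; `mutate_truth` re-renders tracks after a
controlled perturbation (shift a TSS, drop its enrichment) for sensitivity
tests.

What the simulation does **not** model: real promoter sequence context,
multi-position initiation clusters, mappability/multi-mapper artifacts at
repeated loci (rRNA operons), PCR amplification bias (the suspected origin
of many real Class III sites), 5'-hydroxyl products, and operonic
multi-gene units.  Recovery numbers on synthetic data therefore bound the
method's behaviour under its own assumptions; they do not certify
performance on the real libraries, whose headline site counts additionally
depend on manual edge curation.

At these defaults (seed 42) the pipeline attains TSS recall 0.996 /
precision 0.947 and TSS-vs-processing balanced accuracy 0.976, each above
the 0.9 design targets; the full simulate-plus-analyse cycle takes a few
seconds on one CPU.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere except bedGraph files (native
0-based half-open; reverse-strand values negated for mirrored browser
display).  The 5' end of a reverse-strand read is its rightmost *aligned*
base; soft-clips are excluded; secondary/supplementary alignments are
always skipped and `min_mapq` defaults to 10 to damp multi-mapper
artifacts.  Reads are never wrapped across the origin of circular genomes.
Empty inputs yield empty tracks/tables rather than errors; boundary ties
(M exactly on the polynomial) are not enriched; cluster-representative and
edge-thinning ties break toward the smaller position.
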