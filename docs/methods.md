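# Methods

This note documents the models implemented in `antisdscan`, the
parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make every result
deterministic.

## 1. The duplex hybridization model

SD detection rests on the minimum free energy (MFE) of *intermolecular*
hybridization between a short mRNA window and the 16S 3' tail.  The
model is the one used by miRNA-target style hybridization tools: the two
strands may form stacked Watson-Crick and G:U pairs, bulge loops and
internal loops; intramolecular pairs, multi-branch loops and pseudoknots
are excluded.  Energies are Turner/Mathews 1999-style nearest-neighbor
parameters at 37 °C, shipped as a plain-text table
(`data/rna_nn_params.txt`) whose grammar is documented in the file
header.

Scoring conventions, in full:

- **Stacks.** `stack[outer][inner]` with the inner pair read reversed
  (the layout standard for nearest-neighbor tables).
- **Bulges.** Length-indexed penalty; a single-nucleotide bulge retains
  the stacking term of its flanking pairs.
- **Internal loops.** Length-indexed penalty plus an asymmetry term
  `min(3.0, 0.5·|a−b|)` kcal/mol for side lengths a, b.  Loop sizes above
  30 are extrapolated logarithmically (`+1.07856·ln(size/30)`).
  Per-strand loop lengths are capped at 15 nt by default (configurable;
  irrelevant for 10-nt windows but defined for generality).
- **Helix ends.** Each end of the duplex collects the 5' and 3'
  dangling-end terms of whatever flanking nucleotides exist on either
  strand.  A helix end with no flanking nucleotide on *either* strand
  (both strands end flush with the terminal pair) pays a blunt-end term
  of +0.45 kcal/mol.
- **No duplex-initiation term and no terminal-AU penalty** in the duplex
  model.

The last two conventions are the model's calibration: the four SD
tetramers that can pair with the CCUCCUU core — AAGG, AGGA, GGAG, GAGG —
hybridized against the canonical tail `UGGAUCACCUCCUUA` must score −7.1,
−8.0, −9.3 and −9.1 kcal/mol, and the perfect AAGGAGG:CCUCCUU helix
−13.2 kcal/mol.  With Turner-1999 stacks these five values are met
*exactly* under the stated conventions, and under no additive convention
we could find when the tetramers are hybridized against the bare
heptamer instead: the reference energies include dangling-end
contributions from the tail bases flanking the core (the A 3' of
CCUCCUU contributes −0.7 kcal/mol to the AAGG value, for example).  The
tetramer calibration therefore targets the core *in its tail context*,
and `derive_sd_threshold` hybridizes against the full canonical tail.
The SD threshold is the mean of the four values rounded to one decimal:
(−7.1 − 8.0 − 9.3 − 9.1)/4 = −8.375 → **−8.4 kcal/mol**.

Energies are integers in centi-kcal/mol internally, so comparisons and
tie-breaking are exact; ties are resolved deterministically (lower
energy, then more pairs, then leftmost query span, then lexicographic
pair order).  "No possible pairing" is a distinct no-match sentinel
(`None`), never ΔG = 0.

An exhaustive enumerator (`enumerate_duplex_structures`) generates every
monotonic pseudoknot-free pair set and scores it with the same
structure-scoring function; it serves as the independent oracle for the
dynamic program in the test suite (they must agree exactly on all
instances with ≤ 100 pair combinations).  The scanner uses a batched
integer DP (numpy) over all windows of all genes of an organism;
agreement between the batch and single-duplex paths is itself a test.

## 2. Intramolecular folding and the unstructured tail

The 16S tail is delimited by folding the 3'-terminal ≤ 40 nt with a
Zuker-style MFE recursion restricted to hairpins, stacks, bulges and
internal loops (no multiloops, which so short a region does not need).
The folding model reuses the duplex tables plus the hairpin-loop length
penalties; minimum hairpin loop 3 nt; a +0.5 kcal/mol terminal penalty is
applied per AU/GU helix end (hairpin-closing, loop-closing and
external-facing pairs); no dangling ends.  The *unstructured tail* is
every base strictly 3' of the last paired base of the MFE structure;
its length is whatever folding yields, never forced.  An exhaustive
structure enumerator again provides the oracle on inputs ≤ 20 nt.

A caveat worth recording: on genuine 16S 3'-terminal 40-mers, MFE models
of this family (including full-featured folders run with default
parameters) often predict weak spurious pairings between bases upstream
of the terminal helix and the CACCUCC region, which would clip the tail
to a few bases.  Curated annotations of the tail (~15 nt in Bacteria,
~13 nt in Archaea) implicitly discount such marginal structure.  The
packaged tests therefore exercise tail delimitation on a designed
construct (`SYNTHETIC_LAST40`): an unpairable leader, a stable GC-stem
hairpin in the position of the terminal helix, and the canonical 15-nt
tail, which the folder recovers exactly.  Real 16S input is handled by
the same code path, but borderline upstream structure may shorten the
reported tail relative to curated values.

## 3. Core location and coordinates

All positional statistics use the coordinate system anchored at the
central U of the CCUCC core (position 0).  If CCUCC occurs in the tail,
the 3'-most occurrence is the core (it is the one positioned like the
canonical anti-SD; multiplicity is logged).  If not, the tail is aligned
globally to the canonical tail with EMBOSS-Needle-like scoring (match
+5, mismatch −4, gap open −10, gap extend −0.5) and the tail base
aligned to the reference's central U becomes the anchor; if that base is
a gap the organism's core position is unresolvable — it is excluded from
positional profiling but still classifiable.  Paralogous 16S copies are
consolidated by majority tail (ties: lexicographically smallest,
logged); the discordance count and whether the majority conserves CCUCC
are reported.  One exact-match criterion decides "core present"; the
manual, lineage-informed curation that a survey would apply to
borderline tails is out of scope, so borderline organisms may classify
differently than a curated analysis would.

## 4. Scanning and summaries

The scanned region is the 18 nt at gene-relative positions −19..−2 (the
start codon's first base is +1; there is no position 0).  An 18-nt
window with a 10-nt slider gives exactly 9 windows; ties between windows
go to the 5'-most (most distal from the start codon).  The SD rule is
ΔG ≤ −8.4 kcal/mol — inclusive, so behavior at the exact threshold is
deterministic; a strict variant is a configuration flag.  Annotated
start codons are taken verbatim; genes with fewer than 18 upstream bases
are flagged truncated and excluded from the organism denominator
(logged), as are duplicate gene ids.

## 5. Profiles, groups, classes

Only SD-positive genes contribute paired positions to the histogram; the
denominator is all scanned genes, so every frequency is bounded by
pct_SD/100.  The profile span is the maximal *contiguous* block of
positions with frequency strictly above 0.4× the histogram mode that
contains the peak (ties for the peak go to the leftmost position;
non-contiguous positions above the cutoff are logged and excluded — all
catalog spans are contiguous).  Organisms with pct_SD ≤ 5.5 (strict
"above" required) are SD-Scarce and get no profile.

The group catalog (`data/antisd_groups.tsv`) lists the 15 lineage-level
anti-SD variants by span in central-U coordinates, anti-SD sequence and
SD (reverse complement); internal consistency (length = span width,
SD = revcomp(antiSD)) is asserted on load.  Group assignment is by exact
span match; otherwise the nearest entry by |Δfirst| + |Δlast| is
reported with an unassigned verdict.

Class-level profiles pool per-gene paired positions across member
organisms, each anchored at its own central U, with frequencies over the
pooled gene count and the consensus read from the class's most common
tail.  The per-organism report emits mean SD window position and mean
profile position, from which a Pearson correlation is available — the
two averages measure different things (where the window sits in the UTR
versus which tail bases pair) and need not correlate.

Classification is the total function of (core present?, pct_SD > 5.5?)
onto categories i–iv.  The threshold-stability sweep re-categorizes a
cohort across a grid (default 4–7%) and reports agreement with the 5.5%
baseline; raising the threshold can only move organisms from Abundant to
Scarce, which the tests assert as a monotonicity property.

## 6. The synthetic-data generator

`generate_organism` emulates exactly the statistical structure the
analysis assumes: each gene independently receives (with probability
`sd_fraction`, default 0.6 — the canonical-organism regime where roughly
three of five genes carry an SD) the exact reverse complement of
`tail[planted_span]` (default span −2..+4, the CCUCCUU core) at a
uniform random admissible offset within its 18-nt window; all other
window bases, and background genes entirely, are drawn i.i.d. from a
uniform base composition.  Every gene is then *verified with the real
scanner*: planted genes must score at or below the threshold, background
genes above it; failures are resampled (rejection sampling, attempts
logged, hard cap with an error advising a different composition).  Truth
labels are therefore consistent with the scanner by construction,
whatever the parameter tables contain — the generator calibrates to the
engine, not the reverse.

Genes are tiled on one contig with 40-nt random spacers and one free
base at position −1, alternating between strands so the strand-aware
extraction path is always exercised.  Emitted 16S records wrap the tail
in the hairpin construct of §2 so the tail-annotation stage runs for
real.  Identical spec + seed gives byte-identical files; n_genes = 2000
is the default study size (recovery tests run 20 seeds in ~2-3 minutes
on one CPU).

What the generator does *not* emulate: codon structure and amino-acid
content, GC-content gradients, operons and leaderless transcripts,
phylogenetic covariance between organisms, and partially-complementary
SDs (planted SDs are exact complements; near-threshold genes arise only
from the random background).  Passing recovery tests therefore shows the
pipeline is correct and well-calibrated on its own assumptions, not that
real genomes contain SDs at any particular rate.

## 7. Known limitations

- The duplex model ignores UTR secondary-structure accessibility and
  temperature dependence (37 °C tables only).
- Tail delimitation on real 16S sequences can be clipped by marginal
  upstream structure (§2).
- The per-position profile stores position totals; the per-base
  breakdown used in some renderings is available from the stored best
  matches but the span rule is committed to position totals only.
- Start codons are taken from the annotation without re-verification;
  alternative starts are not considered.
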