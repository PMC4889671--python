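# Methods

## Translated homology search

Queries are proteins; subjects are genomes translated in all six
frames (reverse frames from the reverse complement, codons containing
N as X, trailing partial codons dropped).  Each query/frame pair is
scored by affine-gap Smith–Waterman local alignment over BLOSUM62,
computed by Biopython's pairwise aligner.  The gap convention is the
BLAST one: a gap of length L costs `gap_open + L·gap_extend`, so the
default 11/1 scheme charges 12 for a single-residue gap.  The X row
and column of the matrix are zeroed so masked residues are neutral;
stop codons in translated frames score as `*` (−4 against everything),
which strongly discourages alignments crossing stops without forbidding
them.  The search is exhaustive rather than seeded — exact by
construction, and fast enough at panel scale (tens of kilobases per
genome, ~100 Mcell/s).

Raw scores convert to bits with the Karlin–Altschul parameters for
gapped BLOSUM62 search, bits = (λ·S − ln K)/ln 2, λ = 0.267 nats,
K = 0.041.  A best raw score below the noise floor (default 35,
≈ 18 bits) is reported as "no hit" and enters downstream arithmetic as
B = 0.  The floor is a parameter, not an estimated E-value: for a
search space of m·n residue pairs the expected number of noise hits
above S bits is roughly K·m·n·2⁻ˢ, so users searching larger genomes
should raise it (for the ~100 aa × 90 kb panels used in the tests the
noise ceiling sits near 24 bits, and missing-gene detection uses a
30-bit floor, i.e. expected noise count ≈ 10⁻³).

Hits from external search tools can be supplied instead as standard
12-column tabular output; only the best hit per (query, genome) is
kept, and minus-strand coordinates are normalized to forward-strand
intervals.

## Novelty Metric

NM(q, G) = (B(q, G) − B(q, ref)) / max over panel of B(q, ·).

Properties relied on downstream: the reference column is exactly zero
wherever defined; defined values lie in [−1, 1]; NM = 1 exactly when
the reference lacks the gene and G attains the panel maximum; the
metric is invariant to rescaling all of a query's bit scores.  A query
with zero best score across the whole panel has an undefined (NA) row.
Strain clustering is average-linkage hierarchical clustering on
Euclidean distances between strain columns with NA treated as 0;
columns are sorted lexicographically before linkage, which makes the
leaf order deterministic and invariant to input column order.

## Annotation reconciliation

A gene model is a valid ORF iff its oriented sequence starts with ATG,
ends with a stop, contains no internal stop, and has length divisible
by 3.  Correction enumerates candidate starts at codon steps within
±300 bp that carry an ATG, extends each to the first in-frame stop
(bounded by the window), rejects candidates shorter than 30 nt (so a
disruption cannot be "rescued" by an ATG-stop stub), and keeps the
candidate with the smallest total boundary displacement, ties broken
toward extension.  This restores the common annotator errors (whole-
codon start/stop shifts, 3' truncations) exactly whenever the true
boundaries are in range.

Merging pairs models across tracks by reciprocal >50% same-strand
overlap (greedy, best overlap first).  Each pair keeps the member that
validates after correction, preferring track A on ties — the
precedence between two *valid* but different boundary calls is a
declared design choice, not derivable from first principles.  Unpaired
valid models from either track are kept; uncorrectable models with
coding disruptions are retained as pseudogenes.  Pseudogene and
dubious are *input designations* and are carried through unmodified:
no boundary correction is attempted on a model its annotator already
calls a pseudogene, which keeps disrupted loci from being silently
rewritten into short in-frame fragments.

## Evidence validation

FPKM = count·10⁹/(gene length · library total), with the library total
taken per condition.  The three validation rules and their boundary
semantics: transcript coverage ≥ 0.60 of the gene's genomic span
(inclusive) by a transcript mapping to exactly one locus; FPKM
strictly > 1 in at least one condition; at least one peptide with
q strictly < 0.01 that is an exact substring of exactly one predicted
protein.  Coverage is measured against gene length, not transcript
length — the rule is locus-centric.  Peptide q-values are consumed as
given; FDR estimation is upstream of this package.

The Fisher exact test is two-sided by the standard "sum all tables
with probability ≤ the observed table's" rule (with the usual 1+10⁻⁷
relative tolerance for ties), computed entirely in log space from
log-gamma hypergeometric terms combined by log-sum-exp.  It is finite
for any table — the published dubious-ORF table yields
log₁₀ p = −195.2, far below double-precision underflow territory for a
naive implementation.  Empty margins return p = 1 by convention.

## Gene geography

A feature is subtelomeric iff its distance to the nearer chromosome
end is ≤ the span (default 50 kbp; the boundary case counts as
subtelomeric — "within" is read inclusively).  A reference gene is
missing from a target genome iff its best bit score there falls below
`missing_bit_floor`; distinguishing "missing" from "diverged beyond
detection" is inherently a threshold decision and the floor is exposed.
Nonsyntenic homologs are mutual best protein hits (above the raw
floor, query coverage ≥ 0.5) whose flanking genes do not match: with
up to `synteny_flank` = 2 neighbors per side mapped through id
equality or the RBH map, a pair is called syntenic iff at least one
flanking ortholog is shared, nonsyntenic iff none is.  Clusters are
maximal same-contig runs of flagged genes with inter-gene gaps
≤ `cluster_max_gap` (default 20 kbp, exposed) and ≥ 2 members.

Reference-guided scaffolding anchors each contig by exact unique
21-mer matches against the reference (sampled every 11 bp, forward and
reverse complement), assigns it to the chromosome holding the majority
of anchors, orders by median anchor position, and orients by majority
anchor strand.  Contigs with fewer than 3 anchors are reported
unplaced, never dropped.  Exact k-mer seeds are the package's own
anchor choice: at the divergence scale of these panels (shredded or
near-identical sequence) they are unambiguous and deterministic.

N50 is the largest L such that sequences of length ≥ L contain at
least half the total length.

## Synthetic panels

The generator emulates the *structure* of a strain-panel study, not
its sequence statistics: background DNA is i.i.d. uniform over
{A,C,G,T}, genes are random codon strings between ATG and a stop, and
novel genes are generated independently of core genes so their best
cross-hits sit at the noise floor.  One reference strain carries only
the shared features (core genes, pseudogenes with planted disruptions,
dubious ORFs); each derived strain additionally carries a subset of
the novel genes, inserted at common anchor positions — singly or as
clusters with 200 bp spacing — with a configurable subtelomeric bias
(default 0.8, matching the strong end-of-chromosome skew seen in real
panels).  Shared features are laid out strictly in chromosome
interiors and subtelomeric insertions are stacked within
per-chromosome-end budgets, so planted coordinates are exact by
construction and "subtelomeric" placements remain inside the span
after all insertions.

Desk-scale defaults: 6 strains × 3 chromosomes × 30 kbp, 40 core
genes, 10 novel genes (two 3-gene clusters), 4 pseudogenes, 6 dubious
ORFs, genes of 60–150 codons, a 6 kbp synthetic subtelomere span, 20%
annotator noise, 70% expression.  Identical seed and config give
byte-identical output.

Annotator tracks perturb each true model independently per track with
probability `annotator_error_rate`, choosing uniformly among whole-
codon start shifts, stop shifts, 3' truncations, and drops; every
perturbation is logged so correction recall is measurable.  Evidence
tables give truly-expressed genes a uniquely-mapped transcript
(coverage 0.70–1.0), Poisson read counts that yield FPKM ≫ 1, and one
unique 10-mer peptide with q < 0.01; non-expressed genes get none of
the three.  One deliberately ambiguous peptide — a 10-codon block
copied between two core genes at generation time — exercises the
peptide-uniqueness filter.

What the panels do *not* emulate: real base composition, codon bias,
gene families and paralogy (beyond the one shared block), introns,
sequencing error, mappability artifacts, or quantitative expression
structure.  Passing tests therefore demonstrate that the algorithms
are correct and well-calibrated on their stated contracts, not that
thresholds like the 60% coverage rule are optimal for real RNA-Seq
data.

## Problem sizes and numerical choices

The test and acceptance workloads use the desk-scale defaults above
(panels of 4–6 strains, 60–90 kbp genomes, 100-query novelty panels,
200-gene evidence panels) — large enough that every code path and
boundary case is exercised, small enough to run comfortably on one
CPU.  Oracle comparisons (exhaustive six-frame DP, exact-rational
Fisher enumeration, N50 threshold scans) assert exact or 10⁻⁶-level
agreement.  Ties in clustering are fixed by lexicographic column
order; ties in ORF correction by preferring extension; the Fisher
two-sided rule uses the conventional relative tolerance.  Degenerate
inputs are defined explicitly: empty sequences translate to empty
peptides, empty subjects score 0, fewer than two strains cluster as
the identity, empty Fisher margins give p = 1, and contigs without
anchors are listed unplaced.

## Known limitations

The exhaustive search scales as query × genome and is not meant for
megabase genomes — use an external search tool and the tabular-hit
reader there.  The merge precedence between two valid but conflicting
boundary calls is a convention.  The missing-gene floor, cluster gap,
and subtelomere span are biological judgment calls exposed as
parameters rather than inferred from data.  E-values are deliberately
not computed; the raw-score floor plays that role at panel scale.
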