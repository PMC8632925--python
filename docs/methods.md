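# Methods

## The analysis model

The package treats a CMS study as a fixed comparative design: one or more
CMS lines, their nuclear donors, one cytoplasmic donor, and a panel of
male-fertile relatives, each contributing a set of organelle contigs. All
downstream statements are about *presence patterns* of predicted genes
across that design and about *site-level composition* of read evidence over
individual genes. Coordinates are 1-based inclusive everywhere; conversion
to 0-based half-open happens only inside format readers/writers (GFF3, SAM).
For minus-strand features, `start` is the plus-strand coordinate of the
first transcribed base, so `start > end`.

## ORF calling

`find_orfs` reports maximal ATG-initiated ORFs on both strands: for each
(stop codon, frame, strand) the single ORF beginning at the most upstream
ATG after the previous in-frame stop. `nt_length` runs from the start codon
through the last sense codon, excluding the stop, so the 75-nt threshold
equals 25 aa exactly; with the stop included, 75 nt would be only 24 aa.
Alternative starts (GTG/TTG) are not considered. Circular contigs are
scanned on the doubled sequence (plus a 3-base pad so a stop codon beginning
at the last position of the second copy is visible); an ORF may span the
origin but is capped at the contig length, and a circular frame with no stop
yields no ORF. ORFs running off a *linear* contig end are reported only on
request, flagged `truncated`, and are excluded from screening. The
transmembrane stand-in is a plain Kyte–Doolittle sliding-window scan
(window 19, threshold 1.6, maximal union of qualifying windows) — a
deliberately simple surrogate for an HMM predictor, used only in the
optional transcript-filter path and never in the four-criterion screen.

## Homology: two notions of presence

*Clustering.* `greedy_cluster` is CD-HIT-style greedy incremental
clustering over ORF nucleotide sequences: longest first (ties broken by id,
which makes the partition permutation-invariant), each sequence joining the
first representative it matches at ≥ the identity threshold. Identity is
counted over the best glocal alignment divided by the shorter sequence's
length (the CD-HIT convention), computed with edlib's extended CIGAR. The
default threshold is 0.9 (the CD-HIT default). Type classification on
synthetic data clusters at 0.8, chosen once because the typing threshold
must sit below 1 − (donor divergence); with the generator's default
divergence of 0.10, orthologous pairs sit exactly at identity 0.90 and a 0.9
threshold would split about half of them by binomial noise.

*Similarity search.* `local_similarity_search` is a seeded (11-mer),
ungapped X-drop extension local aligner scoring +1/−2, with expectation
values from the ungapped Karlin–Altschul formula `E = K·m·n·exp(−λS)` using
the published parameters for that scheme (λ = 1.28, K = 0.46; recorded in
every hit) and database size = subject length. Gapped alignment is
unnecessary here because divergence in the generator is substitution-only,
and the presence decisions the pipeline makes (E ≤ 1e-50 needs a score
around 100, i.e. ~100 bp of near-exact match) are insensitive to small-gap
refinements. "Present in a genome" for screening = at least one hit at
E ≤ 1e-50; copy number = count of non-overlapping hits admitted
best-score-first (so a partial but significant hit, such as a chimera's
known-gene prefix matching a second locus, counts as a copy — this is
deliberate and mirrors how copy-number tables in this kind of study are
built from similarity searches).

Type labels derive from each cluster's line roles: (nuclear?, cytoplasmic?)
= (F,F)→Type 1, (T,F)→Type 2, (F,T)→Type 3, (T,T)→Type 4, applied to every
CMS member; per-line percentages sum to 100.

## The four-criterion screen

Criteria — (1) ≥ 70 aa; (2) no hit at E ≤ 1e-50 in any fertile genome;
(3) a hit in every CMS genome; (4) expressed — are conjunctive, so the
final set is order-independent; the report still presents the conventional
funnel (length → fertile-absence → CMS-commonality → expression), and every
stage-1 survivor is evaluated against criteria 2–4 so multi-criterion
failures are all recorded. The fertile panel contains the nuclear donor(s)
and fertile relatives but *not* the cytoplasmic donor: the wild cytoplasmic
donor is itself fertile, yet genes inherited from it are legitimate CMS
candidates, and the screen's published form compares only against the
nuclear-side panel. "Expressed" is operationalized as ≥ 10 reads
overlapping the ORF covering ≥ 50% of its length (no numeric cutoff exists
in the source analyses; both knobs are exposed in `ScreenConfig`). An ORF
with no expression data at all is flagged `untested`, never silently
dropped.

## Structural detectors

*Blocks.* `decompose_homology_blocks` selects local-alignment HSPs
≥ 100 bp greedily by score, non-overlapping on the query, ordered by query
start, with 15-bp boundary flanks extracted for border-conservation
inspection. Ungapped extension can overrun a true junction by a few bases
when the next base happens to match; block coordinates are therefore exact
only when junctions are mismatch-guarded (as the generator's constructions
are) and otherwise correct to within a few bp, like any local aligner's HSP
edges.

*Frameshifts.* `detect_frameshift` aligns the intact reference CDS into the
query region by edit distance (edlib), merges indel runs separated by ≤ 3 bp
(an alignment may split one multi-base indel into adjacent runs), and calls
a frameshift only for a single isolated 1-bp indel; a net in-frame indel
(length divisible by 3) returns none, anything else is reported `complex`.
Positions are 1-based reference-gene coordinates of the inserted/deleted
base.

*Chimeras.* `detect_chimera` searches the ORF (prefixed with up to 100 bp
of upstream genomic context, since a chimera's known-gene segment may start
upstream of the ATG) against each known gene; a call requires a terminal
match ≥ 60 bp starting at the query 5' end and covering < 80% of the ORF.
A full-length match is reported as `homolog`, no match as none. The 60-bp /
80% thresholds are package policy (only a single printed example exists to
anchor them) and are parameters of the call.

## RNA editing

Editing rate at a site is alt/(ref+alt) on the coding strand — C and T
counts for a plus-strand gene, G and A plus-strand counts for a
minus-strand gene — so sequencing errors to the other two bases do not
dilute the denominator. Site detection requires a coding-strand C, pooled
cDNA rate ≥ 0.05 at pooled ref+alt coverage ≥ 100, and a gDNA control rate
≤ 0.01 (a "site" edited in gDNA is a genomic variant and is rejected);
missing controls flag the site `uncontrolled`. These three thresholds are
package defaults, exposed in `EditingThresholds`. Codon effects follow
`codon_index = ceil(cds_pos/3)`; a C→U change at codon offset 3 is
synonymous for all 16 NN contexts of the standard code, which the test
suite asserts exhaustively. Group comparison is a two-sided two-sample
t-test per site, Welch's unequal-variance variant by default (the robust
choice at n = 3; Student's form is available via `equal_var=True`), with
standard errors reported per group. No multiple-testing correction is
applied across sites by default, matching per-site reporting conventions;
the comparison object carries the α used. The start-codon anchor of a gene
can be inferred from ≥ 2 (contig, CDS) coordinate pairs: on the minus
strand `contig_pos + cds_pos` is constant (anchor + 1), on the plus strand
`contig_pos − cds_pos` is constant (anchor − 1); inconsistent pairs raise.

## The synthetic generator: what it emulates, and what it does not

The generator reproduces the *design* of a cell-fusion CMS study at desk
scale: 30-kb donors with 30 genes (roughly uniform 300–1,500 bp, GC 0.45),
75% of them orthologous pairs diverged at 0.10 substitutions/site
(ORF-preserving: start/stop untouched, no created stops) and the rest
donor-unique — donor-unique genes are what make Type 2/3 classes possible.
The CMS mitogenome is a shuffled concatenation of gene-bearing segments
(700–2,600 bp, flanks included) cut from both donors, each independently
duplicated with probability 0.15, plus novel junction ORFs; with the
default class shares (0.11/0.155/0.11/0.625, taken from the observed
mitochondrial gene-class fractions) the result is 1.4–1.7× either donor.
The truth ledger tiles every CMS contig byte-for-byte. The CMS chloroplast
is a 0.01-divergence ORF-preserving copy of the nuclear donor's plastome,
which is what drives its ~0% Type-3 share.

Injected events are built to be *exactly* recoverable, a property real data
lacks: injected cassettes are flanked by a 12-bp six-frame terminator
(`TTAATTAATTAA`, stops in all six frames, its own reverse complement) so no
reading frame crosses an injection boundary; a chimera's first eight novel
bases are forced to mismatch the source-gene continuation so the breakpoint
is unambiguous; a frameshift's inserted base differs from both neighbours
so the indel position cannot be left- or right-shifted; and injected
sequences are resampled until they contain no incidental ORF ≥ 210 nt in
any other frame or strand. Consequently "precision = recall = 1.0" and
"±0 bp" recovery statements certify the detectors' logic under
identifiable conditions — they do not bound performance on real genomes,
where boundaries are not guarded and homology is gapped and noisy.
Likewise, substitution-only divergence means the aligners are never
exercised against real indel structure except the single injected
frameshift.

The full study preset (`orgfusion.study.synthetic_study`) wires three CMS
lines that share three injected candidate loci — a fully novel 137-aa ORF in
two copies, a 265-aa chimera whose first 59 codons come from a
cytoplasmic-donor-unique *atp8*-like gene with editable C's engineered into
codons 10/13/16/20 (TTC/TTC/TCA/CTT, giving F10F/F13F/S16L/L20F on C→U),
and a plastid *cytochrome f*-like 310-codon gene copied into the mitogenome
with a T inserted after codon 116. That gene is engineered (codons
115–118 = CTG/AAC/AAC/ATG) so the insertion creates an immediate TAA stop
— yielding a 116-aa sub-ORF — and restores the original frame downstream
from codon 118's ATG — yielding a 193-aa sub-ORF ending at the gene's own
stop. Anther expression reads tile the novel ORF (both copies), the 193-aa
sub-ORF and the chimera, but not the 116-aa sub-ORF, so the screen's ground
truth is exactly four ORFs.

Amplicon simulation emits per-site plus-strand base counts (default) or
individual reads behind `emit_reads` (alignment itself being out of scope,
the count table is the primary interface; reads can be written as plain-text
SAM and re-piled through pysam). Editing is applied per molecule at the
replicate group's true rate; the default two-group profile is
fertile ≈ 0.60/0.65/0.52/0.65 vs sterile ≈ 0.40/0.51/0.52/0.44 at CDS
positions 58/47/39/30, i.e. three sites differ between groups and the
silent site 39 does not; coverage defaults to 1,000 per site (a desk-scale
stand-in for the tens of thousands of reads per point a MiSeq amplicon run
yields), sequencing error to 0.5% per base uniformly to the other three
bases. The gDNA control is simulated with rate 0.

## Numerical and policy choices

- Greedy clustering assigns to the *first* matching representative (CD-HIT's
  fast mode), not the best; with the test suite's identity margins the two
  coincide.
- Karlin–Altschul λ, K are fixed published ungapped constants for +1/−2;
  they are metadata on every hit rather than fitted quantities.
- `simulate_fusion_mitogenome` derives its total gene draw from
  `n_novel_junction_orfs / p(Type 1)` so the novel-ORF count and the class
  shares stay mutually consistent; an explicit `n_genes` overrides this.
- Donor gene lengths are drawn uniformly and then the largest draws are
  shrunk (never below the range minimum) if the sampled set would not fit
  the genome length; a structurally impossible request errors out.
- Degenerate t-test inputs (both groups constant and equal) return t = 0,
  p = 1 rather than NaN.
- Zero-coverage editing denominators return an undefined (None) rate and
  are flagged, never treated as rate 0.

## Problem sizes

Defaults throughout are desk scale — 30-kb donors, ~27-gene fusions, 18-kb
plastomes, coverage 1,000, three replicates per group — chosen so the whole
suite, the analysis drivers and the acceptance script each complete in
minutes while every modeled quantity (class proportions, editing rates,
copy numbers, breakpoint coordinates) is scale-free. The `paper-scale` CLI
preset (120-kb donors, 120 genes) exercises the same code at larger n.

## Known limitations

- No gapped alignment statistics; E-values are ungapped Karlin–Altschul.
- No inversions in the fusion simulator (segments are placed in forward
  orientation; inverted homology is still exercised by the block detector's
  tests).
- The hydropathy scan is not a trained transmembrane model.
- Editing analysis covers C→U (G→A on the antisense strand) only.
- Expression is judged from read intervals, not spliced/strand-aware
  transcript models.
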