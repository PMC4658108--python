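# Methods

`mirseek` re-implements, as a tested library, the downstream computations of
a blood small-RNA sequencing study: read cleaning, hierarchical annotation,
conserved/novel miRNA discovery, exact two-library differential expression,
and cross-species 3'UTR target prediction. This note documents the models,
the defaults and why they hold, what the synthetic generator does and does
not emulate, and the design choices made where the procedure was genuinely
open.

## Read cleaning

Four whole-read filters run in a fixed order; a read is charged to the
first filter it fails, so the statistics ledger partitions the input
exactly (`input = clean + Σ removed`):

1. **Quality** (on the untrimmed read): reject when bases with Phred
   `< quality_floor` (default 5) make up `≥ low_quality_fraction` (default
   0.5) of the read. The boundary is inclusive (`≥`), exposed in config.
2. **Adapters**: reject 5'-contaminated reads (the 5' adapter matches at
   the read start within 1 substitution) and reads in which no 3' adapter
   can be located; otherwise trim at the leftmost 3'-adapter occurrence.
   An occurrence is a full internal match anywhere, or a prefix of the
   adapter of ≥ 6 nt flush with the read end, each within 1 substitution.
   The tolerance and minimum overlap are package choices (standard
   trimmer heuristics); no aligner or threshold is prescribed by the
   protocol.
3. **Poly-nucleotide**: reject inserts in which one nucleotide reaches
   `polyN_fraction` (default 0.8). "Contains poly-A/T/C/G" is undefined in
   the protocol; a single-nucleotide content threshold is the standard
   vendor heuristic and gives a testable boundary.
4. **Length**: reject inserts shorter than 18 nt ("less than" → 18 nt is
   kept).

Quality is evaluated before trimming because the protocol lists it first.
Clean reads collapse to unique tags with per-sample counts; the total/unique
bookkeeping, insert-length histogram and cross-sample sharing summary are
emitted alongside.

## Annotation

Small RNAs matching non-miRNA references are removed before discovery. A
tag matches a category when it (or its reverse complement; reference
strandedness is unknown) occurs as a substring of any entry of that
category, within an optional substitution budget (default 0). Matching is
containment, not global alignment: the small RNA is a fragment of the
longer ncRNA, and containment is deterministic and oracle-checkable. When
several categories match, the fixed priority
`rRNA > tRNA > scRNA > snRNA > snoRNA > repeat > exon > intron` resolves
the tie, so every tag receives exactly one label; unmatched tags go forward
as miRNA candidates. Category summaries report proportions over both
unique tags and total reads, since published summaries are ambiguous about
the denominator.

## Discovery

Candidate tags map to the genome on both strands with at most
`map_max_mismatch` substitutions (default 1, the convention of read-mapper
based miRNA pipelines; 0 is selectable). Tags aligning inside a catalog
precursor with their 5' end within ±2 nt of the catalog mature 5' end count
toward that miRNA; tags of one precursor aggregate into a single miRNA.
Both precursor-level and mature-level countings are reported.

Remaining plus-strand alignments are clustered into read stacks (gap
≤ 20 nt, spanning a hairpin loop). For each stack the dominant 5' position
is the count-weighted mode; two windows are excised — 70 nt of context
upstream or downstream of the putative mature — since the mature arm can
flank the loop on either side. 70 nt matches the precursor scale of
standard excision heuristics.

**Folding** is weighted base-pair maximization (Nussinov-style dynamic
program): GC = 3, AU = 2, GU = 1, hairpin loops span ≥ 3 unpaired bases.
Tie-breaks are deterministic (pair the outermost base when possible;
5'-most partner). This replaces thermodynamic folding deliberately: the
optimum is exactly checkable against exhaustive structure enumeration at
desk scale. The DP is JIT-compiled when numba is available, with an
equivalent pure-Python fallback.

**Signature score** (range −4 to 10, reported when > 5):

- +4 × share of mature-arm reads whose 5' end lies within ±1 nt of the
  dominant position. Star-compatible and loop reads are excluded from this
  share's denominator — they are legitimate Dicer products and would
  otherwise dilute the 5'-homogeneity evidence they support.
- +3 if ≥ 60% of mature bases are paired in the fold.
- +2 if star-compatible reads exist. The implied star 5' end is the duplex
  partner of the 3'-most paired mature base; the ±2 nt acceptance window
  absorbs the 2-nt 3' overhang of the Dicer duplex.
- +1 if the loop (the span between the mature arm and its partner arm)
  is 3–25 nt.
- −4 × share of reads whose 5' end falls inside the loop.

A candidate whose mature arm is entirely unpaired is discarded.

**Structure randomization**: the pairing score is compared against
`shuffle_count` (default 100) dinucleotide-preserving shuffles
(Altschul–Erickson Eulerian-walk construction, preserving exact
dinucleotide counts and the terminal bases), with the add-one estimate
`p = (1 + #{score_shuffled ≥ score}) / (k + 1)`. Candidates are reported
at `p < 0.05`. Windows under 10 nt cannot be meaningfully shuffled and get
`p = 1`.

**Signal-to-noise**: reported candidates on the real genome divided by
(mean reported on ≥ 3 dinucleotide-shuffled genomes + 1). It is a
genome-level quality figure, not a per-candidate filter.

## Differential expression

Counts normalize to reads per million of clean reads
(`NE = count / total × 10⁶`). Exact zeros become 0.01 before the fold
change so `log2(NE_A/NE_B)` stays finite; pairs whose adjusted NEs are
below 1 are excluded from testing. Exclusion applies when **both** NEs are
below 1 by default (`ne_exclusion_mode`), keeping miRNAs with strong
signal in either library; "either" is selectable. Substitution and
exclusion run before testing, never after, and the result records which
rule fired.

Significance uses the exact two-library count statistic

    p(y | x) = (N₂/N₁)^y · (x+y)! / (x!·y!) / (1 + N₂/N₁)^(x+y+1)

— the negative-binomial mass with size x+1 and success probability
N₁/(N₁+N₂) — computed in log-gamma space. The lower tail C sums y′ ≤ y,
the upper tail D is 1 − Σ_{y′<y} (by complement, so no infinite sum), and
the two-sided p-value is `min(1, 2·min(C, D))`. Sidedness is a package
choice; the thresholds p < 0.01 and |log2FC| ≥ 1 are defaults exposed in
config. Because the statistic is discrete, the test is conservative: its
empirical size at nominal 0.01 stays below 0.01 under a Poisson null.

With multiple samples per group, every between-group sample pair is tested
and a miRNA is consensus-up in a group only when significant with the same
sign in **all** pairs of the contrast.

## Target prediction

Donor-species 3'UTRs are projected onto the genome by ungapped alignment:
a donor transfers when a contiguous stretch of ≥ 80% of its length aligns
with ≤ 2 substitutions and the locus lies within 1,000 nt of an annotated
gene 3' end (the proximity radius quantifies "near the gene 3' end"; no
distance is prescribed). The transferred sequence is taken from the
genome, output is sorted by locus, and unigene-derived UTRs join verbatim.

Site prediction scans every UTR offset for antiparallel complementarity to
miRNA positions 2–8 (the seed); one G:U wobble is tolerated (class
`7mer-wobble`; a perfect seed with a Watson–Crick pair at position 1 is
`8mer`, otherwise `7mer`). An ungapped alignment over the full mature
scores +5 per Watson–Crick pair, +1 per G:U, −4 per mismatch; sites with a
seed hit and score ≥ 60 are reported (a perfect 22-mer scores 110). The
scorer replaces dynamic-programming hybridization deliberately: it is
deterministic and equals a brute-force positional scan, which the tests
exercise.

Pathway tallies count a gene once per pathway regardless of how many
miRNAs or sites hit it; genes missing from the mapping are counted under
`unmapped`. Both target-counting conventions (unique genes; gene–miRNA
pairs) are emitted. Expression trends on a user-supplied per-gene FPKM
table compare group means with a 20% relative-difference threshold
(`higher_in_A` / `higher_in_B` / `tied`; absent genes are flagged).

## Synthetic data

The generator emulates the study design the pipeline assumes: a 12 kb
single-chromosome genome; 10 planted precursors (22 nt mature + 8–15 nt
loop + reverse-complement star, 0 planted stem mismatches by default); one
non-miRNA locus per category; four libraries in a 2×2 young/adult design;
mature read lengths drawn from {20, 21, 22, 23} with mode 22; ±1 nt 5'
jitter with probability 0.2; 8% star reads; 12% background reads from the
planted non-miRNA loci; and contaminant classes at 5/5/3/3/2% (low-quality,
3'-adapter-less, poly-nucleotide, short, 5'-adapter). Quality strings are
constant Q35 except the planted low-quality class at 60% Q2 — the simplest
model that exercises the quality filter. One miRNA (the most abundant) is
planted at an 8-fold young/adult change.

Planted fold changes act on the **absolute** proportion scale: group
abundances share one normalization and the per-sample background fraction
absorbs the difference in total signal. A per-sample renormalized
(compositional) model would shrink a planted 8-fold change to ~2.8-fold
after reads-per-million normalization; real libraries differ in their
non-miRNA content, so the absolute model is also the more realistic one.

Contaminant classes are unambiguous by construction (random inserts are
re-drawn if they would trip another filter), so cleaning decisions can be
compared to truth labels read by read. The generator does **not** model
sequencing errors, PCR duplicates, expression dispersion beyond
multinomial sampling, multi-locus miRNA families, or minus-strand
transcription; green tests therefore demonstrate correctness of the
implemented rules under clean Dicer-like signal, not robustness to every
artifact of real libraries.

## Problem sizes and numerics

The default test and acceptance conditions run one library at depth 10⁵
for discovery, depth-10⁵ count matrices for differential expression, and
2,000 replicate null miRNAs for the size check — large enough for the
law-of-large-numbers checks (3–4 SD tolerances) while keeping the whole
suite under a minute of compute beyond the folding JIT warm-up. All
randomness flows through `numpy.random.default_rng` seeds; every pipeline
stage is deterministic given its seed. Tail sums, the pmf and the fold DP
are exact to ≤ 1e-9 against closed-form oracles; boundary behavior
(18 nt kept, NE = 1 tested, score 5 not reported, 2 mismatches accepted)
is pinned by tests.

## Known limitations

- Folding ignores stacking energies and multiloop penalties; a weighted
  pair count can over-pair AU-rich windows relative to free-energy models.
- Annotation containment has no mismatch-aware seeding; budgets > 1 on
  large references would be slow.
- UTR transfer is ungapped; donor UTRs with indels relative to the target
  genome will under-transfer.
- The exact count statistic assumes Poisson sampling within a library;
  biological replicates with overdispersion need a dispersion-aware method,
  which is out of scope here.
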