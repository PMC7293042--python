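# Methods

## The signal

N¹-methylation of purines (m¹A, m¹G) sits on the Watson–Crick edge and
blocks canonical base pairing. During reverse transcription this produces
three observable effects at the modified template position: substitutions
(the RT inserts a more or less random nucleotide), deletions (the RT skips
the base), and abortion (no full-length cDNA; under a library protocol
that ligates both adapters at the RNA level and therefore amplifies only
complete cDNAs, aborted molecules vanish from the library entirely).
`tmodscan` detects the first two and models the third as read loss.

## Reference construction

tRNA genes are highly repetitive, so reads are mapped in two stages.

*Stage 1* uses the genome with all tRNA loci masked to `N`, plus each gene
re-attached as its own sequence with up to 50 nt of genomic flank per
side. Reads that best-align to the core genome are not tRNA reads; reads
that touch at least one flank position derive from unprocessed precursors
still carrying leader/trailer sequence. Both classes are eliminated —
precursor molecules are largely unmethylated at position 9 and would
dilute the signal. Elimination requires positive evidence: a read with no
stage-1 alignment at all stays in play. Soft-clipped bases consume no
reference and never count as flank overlap.

*Stage 2* maps the surviving reads to the mature library: introns spliced
out, `CCA` appended unconditionally, and genes with byte-identical mature
sequences collapsed to one representative (named after the
lexicographically smallest member gene, output sorted by sequence). A read
mapping to several best sites is kept only when every site yields an
identical (aligned target substring, CIGAR) pair — then exactly one copy
is retained. This is the only notion of "identical alignments" checkable
from alignment records alone. Multiple distinct best sites discard the
read.

Coordinates are 0-based half-open internally; all report files print
1-based positions on the mature sequence. "Position 9" therefore means
the ninth nucleotide of the mature sequence, which for tRNAs with
non-canonical acceptor/D-arm lengths can differ from canonical numbering —
canonical renumbering is left to the user.

## The built-in aligner

A seed-and-extend local aligner (match +1, mismatch −1, linear gap −2,
read ends soft-clipped for free) exists so the pipeline runs end-to-end
without an external mapper. Exact substring matches are found by plain
string search — provably optimal under a positive match score. Inexact
reads are routed through a 13-mer index to candidate targets and aligned
by a numpy row-vectorised Smith–Waterman whose within-row dependency
reduces, for linear gap costs, to a running maximum. All maximal-scoring
sites across all targets are reported (the multimapper rule needs them);
traceback tie-breaks prefer diagonal, then insertion, then deletion, so
output is deterministic. Tiny target sets (≤ 1,500 total bases) skip the
seeding and are aligned exhaustively. Reads over 500 nt are rejected:
this is a desk-scale aligner, not a general-purpose one.

Multi-read realignment around indels (as dedicated realignment tools do)
is not reproduced; an optional per-read left-normalisation shifts each
indel to its leftmost equivalent placement within repeats
(`left_normalize_indels`, off by default).

## Pileup

Alignments with mapping quality < 20 are skipped; base calls with Phred
< 20 are excluded from base counts while the read still counts as
spanning. Deletions are attributed to every deleted reference position,
insertions to the position immediately 5′ of the insertion event. The
per-site error rate is (non-reference base calls) / (base-call coverage);
deletions are excluded from both numerator and denominator by default
because base counts are the primary quantification, with
`include_deletions` adding them to both. Insertions never enter the rate
(they have no reference position of their own) and are reported for
diagnostics only.

## Site calling

Per sample:

1. **Background.** For each ordered substitution type ref→alt, the pooled
   ratio π = Σ alt counts / Σ base-call coverage over all positions with
   that reference base, after one trimming pass that drops positions whose
   total mismatch rate exceeds 10× the median positive mismatch rate
   (candidate modified sites must not inflate the background they are
   tested against). Deletion background per reference base uses
   coverage + deletions as denominator. Rates are floored at 10⁻⁶; event
   types with no informative positions yield p = 1 with a warning.
2. **Per-event tests.** Exact one-sided binomial tails P(X ≥ k | n, π).
   The test is exact and parameter-free, hence valid at the low coverages
   the 10-read gate admits. The event set is the three substitutions away
   from the reference plus the deletion event (four p-values); a `subs`
   mode restricts to the three substitutions.
3. **Winsorized Fisher.** The single smallest and single largest p-value
   are removed (ties lose one occurrence each; lists shorter than three
   pass through), the rest are merged by Fisher's method, −2 Σ ln p ~ χ²
   with 2m df. P-values are floored at 10⁻³⁰⁰ before the logarithm.
   With four events winsorization leaves two p-values; a site must
   therefore show at least two independently elevated event types — one
   outlier event can neither carry nor sink a site. The flip side is a
   real power cost at weak signals: the strongest event is always
   discarded.
4. **FDR.** Benjamini–Hochberg over all sites with coverage ≥ 10 in that
   sample. A site is reported as modified when q < 0.01 in at least one
   sample; the full per-sample audit trail (event p-values, combined p, q,
   pass flag) is retained.

## Differential classification

For every site called in at least one wild-type sample and every knockout
condition: *retained* if the site still passes in ≥ 1 KO sample; *lost* if
no KO sample passes **and** the WT mean error rate exceeds the KO mean by
≥ 5-fold (KO mean floored at 10⁻⁴ so error-free sites do not divide by
zero); otherwise *ambiguous*. The fold condition is an explicit,
configurable operationalisation of "the signature disappeared" —
non-significance alone is not treated as loss.

## The synthetic testbed

The generator emulates the statistical structure of a targeted tRNA
sequencing experiment, not its biochemistry:

* 50 genes of 61–87 nt (mature 64–90 nt incl. CCA) embedded in a random
  genome with ≥ 160 nt spacing; 10% exact duplicates (exercise
  collapsing), 20% with an intron of 8–20 nt placed after position 32 (as
  real tRNA introns are), 40% on the minus strand. Position 9 is drawn
  purine with 80% probability, as in real tRNAs.
* Reads are full-length mature copies — the two-adapter RNA-ligation
  protocol sequences only complete cDNAs, so there is no fragmentation —
  with counts per representative drawn negative-binomially (mean 200,
  size 50) and per-base sequencing error 0.1%, consistent with the
  Phred 30–40 quality model after the ≥ 20 quality gate; qualities carry
  a 3% low-quality fraction to exercise that gate. Background deletions
  occur at 10⁻⁴ per base.
* A modified site carries a per-read substitution probability (0.05–0.30
  across the six default sites), a spectrum spreading that mass over all
  three alternative bases, a deletion probability of half the substitution
  rate, and an RT-dropout probability of 0.2 that removes the read
  entirely. Three wild-type replicates carry all six sites; the A-knockout
  keeps only enzyme B's single site, the B-knockout only enzyme A's five
  (two replicates each). Enzyme A takes G9 targets and enzyme B an A9
  target when both exist; the B site receives the strongest signal.
* 5% of the mean coverage per gene is emitted as precursor reads
  (unspliced body plus 2–50 nt of each flank), and 50 background reads per
  sample come from non-tRNA genomic regions.

Two deliberate constructions make triage ground truth exact on noiseless
reads: the two genomic bases 3′ of every gene are drawn so the CCA tail
cannot extend an alignment into the flank, and precursor flank overhangs
are emitted error-free. Real trailers can start with C, and a mature read
whose final bases are miscalled can legitimately be eliminated as
flank-overlapping; in the simulation this affects a negligible fraction
of reads and only reduces coverage.

What the simulator does **not** emulate: tRNA secondary structure and the
broader modification landscape (m²G, t⁶A, … appear only as generic
specs if configured), RT stop/truncation signals (the full-length-only
protocol discards them; dropout is modelled as read loss, not
truncation), sequence-dependent error profiles, and amplification
artifacts. Passing tests on this testbed therefore demonstrates the
statistical machinery — calibration, power at given signal strengths,
exact bookkeeping — not performance on any real library.

### Power characteristics, measured on the testbed

At ~200× nominal coverage (~160× after dropout) a site with substitution
rate 0.05 sits near the method's detection limit: after winsorization the
two middle event p-values (counts of 2–3 against expected background
counts of ~0.05) reach the per-sample BH threshold only ~55–75% of the
time. Union over three wild-type replicates still recovers such sites in
almost every run, but a two-replicate knockout condition misses its
"retained" confirmation in a noticeable minority of runs, which then
surfaces as an *ambiguous* classification. Sites at rate ≥ 0.10 are
called essentially always. This is an inherent property of discarding the
extreme p-values at four events; the `subs` event mode is strictly weaker
still.

## Growth fit

The impedance cell-index model CI_i = CI₁·2^((t_i−t₁)/DT) is exactly
log-linear, so DT is estimated by ordinary least squares of log₂ CI on
t − t₁ rather than by nonlinear fitting (the vendor software's internal
weighting is unknown; on noiseless model data both agree to machine
precision). The exponential window is a user parameter, as the window of
exponential growth is chosen by inspection in practice. Non-growing
series (slope ≤ 0) report DT as undefined rather than a negative number;
at least three points with positive CI are required.

## Numerical and degenerate-input conventions

* p-value floor 10⁻³⁰⁰ before logs; background floor 10⁻⁶; KO-mean floor
  10⁻⁴ — all logged when hit.
* Zero base-call coverage makes the error rate *missing* (NaN), never 0.
* Collapsing excludes sequences with non-ACGT characters (warning).
* All outputs are pure functions of (config, seed); report files are
  byte-identical across re-runs on identical inputs.

## Known limitations

* No 5′ G−1 handling for His tRNAs; genomically encoded CCA yields CCACCA
  unless `cca_if_absent` is set.
* Canonical tRNA position numbering is not computed; positions are mature
  sequence indices.
* The built-in aligner's seeding can in principle miss an equally scoring
  site that shares no 13-mer with the read; exact matches are always found
  exhaustively, and on the synthetic libraries used here the seeded and
  exhaustive routes agree.
* Stage-1 elimination considers best-scoring alignments only; whether
  sub-optimal alignments should also count is a judgement call on which
  reasonable pipelines differ.
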