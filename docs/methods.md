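# Methods

This note records the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic data generator does and
does not emulate, and the known limitations.

## Read cleaning

Adapter removal is a semi-global suffix match of the 3' adapter against
the read: the leftmost position with ≥ 8 nt of overlap and a mismatch
fraction ≤ 10% wins; an adapter starting at position 0 marks an
adapter-only read.  An exact hit of the adapter's 10-nt prefix bounds
the fuzzy scan, which keeps trimming O(insert length) on typical reads
without changing the result.  After trimming, reads are discarded in a
fixed order of reasons — adapter-only, low quality (any N, or mean
phred < 20 when qualities are present), shorter than 18 nt, longer than
30 nt, polyA (≥ 80% A) — so that every raw read is accounted for exactly
once in the per-library ledger.  Reads still containing the 5' adapter
are treated as ligation carry-over and dropped.  The 18–30 nt window,
the polyA rule and the quality bound are configurable; the defaults are
the standard plant small-RNA choices.

## Hierarchical annotation

Reads are annotated with the priority structural RNA (rRNA = tRNA =
snRNA = snoRNA) > known miRNA > repeat > exon > intron; a read keeps the
highest-priority category in which it has any hit.  Structural, repeat,
exon and intron hits are exact substring matches on either strand —
reference sets are concatenated once with separator sentinels so each
lookup is a single scan.  Known-miRNA assignment is an ungapped overlap
alignment requiring ≥ 16 nt of overlap and at most 2 mismatches (a
permissive Blastn stand-in; both bounds configurable).  At scale, an
exact 8-mer word-seed index screens reads before the offset enumeration,
mirroring how a word-seeded aligner seeds hits; a read whose two
mismatches fragment every shared 8-mer would be missed by the screen,
exactly as it would escape a seeded aligner.  `match_known_mirna` itself
always applies the exact rule, and the screen can be disabled.
Multi-mapping reads count toward every matched miRNA, with no fractional
allocation — the simplest reproducible convention.  Family names
collapse to `miR<number>` with variant letters stripped; families such
as miR156/157 can be merged through an explicit map.

## Folding engine

The built-in engine minimises a simple stacking score over nested
structures: −2 per stacked pair step and +1 for every helix closed by
anything other than a hairpin loop, with Watson–Crick and G:U pairs,
helices of ≥ 3 consecutive pairs and hairpin loops of ≥ 3 nt.  A single
perfect stem of P pairs scores −2(P−1).  This is deliberately **not** a
thermodynamic nearest-neighbour model: it is exact for its own
objective (the dynamic program is checked against exhaustive structure
enumeration on short sequences), fast, and dependency-free, and the
synthetic fixtures are constructed so their scores clear the −18
"kcal/mol" precursor threshold under this engine.  A thermodynamic
engine (ViennaRNA) can be plugged in behind the same
`(structure, mfe)` contract — the −18 kcal/mol bound is calibrated to
such engines — and any callable with that signature is accepted.  The
dynamic program is JIT-compiled with numba when available and falls
back to pure Python otherwise.

## Novel miRNA discovery

Unannotated and intron-derived reads are mapped to the EST set by exact
full-length matching on both strands (an 18-mer prefix index makes this
a constant-time lookup per read); reads with more than 20 reference
loci are dropped as repeats.  Overlapping loci chain into clusters and
each cluster is seeded by its most abundant read (≥ 5 total reads by
default) — the Mireap-style convention of taking the dominant read as
the mature candidate.  Around each seed, windows with 100 nt of flank
on the far side of the read are excised in both directions; because a
long window can fold the hairpin into flank-involving alternatives
under a degenerate scoring model, each side is also excised at 60 and
40 nt and the lowest-energy qualifying structure wins ("only the lowest
free-energy structures are selected").  The miRNA\* is predicted from
the pairing map with the Dicer convention of 2-nt 3' overhangs on both
strands, stepping to the nearest paired base when an anchor position is
unpaired, and is reported as observed only when a read matches it
exactly.  The final precursor is trimmed to the mature/star span plus
20 nt of flank and refolded before evaluation.  A candidate passes when
mature length ∈ [18, 25], precursor score ≤ −18, duplex pairs ≥ 16,
bulge ≤ 4, asymmetry ≤ 4, spacing ≤ 300, and the mature sits on a
single arm; every violated rule is named in the failure reasons.
siRNA-like loci are excluded when the minus-strand read fraction lies
in [0.4, 0.6] or more than half the reads start outside the mature∪star
windows; both thresholds are explicit parameters because the original
"wide distribution" rule is qualitative.  Candidates sharing a mature
sequence, or overlapping precursor loci (a hairpin's star arm would
otherwise re-seed its own locus), keep the higher-support
representative.

## Differential expression

Counts normalise to RPM with a pseudo-value of 0.01 replacing zero
counts in normalised space only — raw zeros enter the test as zeros.
"According to the Poisson distribution" is implemented as the exact
conditional test: under equal per-read rates, x_A given x_A + x_B is
Binomial(x_A + x_B, total_A/(total_A+total_B)), and the two-sided P sums
every outcome whose probability does not exceed the observed one
(minimum-likelihood two-siding, with a 1+10⁻¹² tolerance for pmf ties).
Bonferroni multiplies by the number of miRNAs tested in that pairwise
comparison.  Significance requires |log₂FC| ≥ 1 and corrected P < 0.05
(strict).  Abundance tiers use the per-library maximum clean-read count
(> 10,000 high, > 1,000 moderate); note these absolute thresholds were
defined for ~20M-read libraries, so a scaled-down run lands mostly in
the low tier.  Trends across the three phases classify the two log₂
steps against a 1-unit threshold: (+,+) increasing, (−,−) decreasing,
(−,+) V, (+,−) reversed V, else flat.  Profile clustering is
agglomerative with Euclidean distance and complete linkage over the
pairwise log₂FC matrix; the group count k is user-set, and a constant
matrix degrades to a single group with a warning.

## Target prediction

The scoring scheme is the standard plant convention made explicit:
mismatch 1.0, G:U wobble 0.5, gap 2.0, all doubled over miRNA positions
2–13, one gap at most, sites reported at score ≤ 4.0.  An optional
strict mode adds the Schwab-style constraints (no mismatch opposite
positions 10–11, ≤ 1 mismatch in 2–12).  `score_site` enumerates every
gap placement exactly; a target insertion is weighted by the adjacent
5' miRNA position.  Genome-scale scanning first computes the ungapped
score of every window with a vectorised kernel and rescores anchors
within `max_score + 8` exactly at all window lengths in the gap budget —
a gapped site whose every ungapped anchor scores worse than that margin
would be missed, which on random sequence is vanishingly rare; the
screen can be disabled for exhaustive scanning.  Overlapping windows
deduplicate to the best score.  Cleavage positions are the EST
coordinates opposite miRNA positions 10 and 11, walking the alignment
and skipping target gaps.  In the pipeline, each novel miRNA's own
precursor locus is masked: a hairpin is trivially self-complementary
and would otherwise "target" its own transcript.

## GO enrichment

The upper-tail hypergeometric probability is computed through scipy's
survival function (log-space stable); N counts background genes with at
least one annotation, genes (not sites) are the counting unit, and only
terms with M ≥ 1 are tested, with Bonferroni over the tested terms.
The printed enrichment formula (n/N)/(m/M) is the reciprocal of the
conventional fold enrichment; since the orientation in the source
formula cannot be disambiguated, both are reported side by side.  Terms
are not propagated up the ontology graph (no ancestor closure), because
the original analysis describes none.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
three ~200,000-read libraries of 49-nt raw reads (inserts padded with
the adapter and a post-adapter sequence), 50 known mature miRNAs
(lengths mostly 21 nt), 20 novel hairpins planted in a 300-EST set,
per-miRNA Poisson read counts from a log-uniform RPM design (20–5,000
for known, 300–2,000 for the lowly-expressed novel miRNAs, many of them
phase-specific), 10% of mature reads with 1-nt 3' jitter, miRNA\* reads
at 10% of mature abundance, planted four-fold changes for 12 miRNAs at
≥ 50 RPM, and contaminants: structural-RNA/repeat/exon/intron
fragments, polyA, sub-18-nt junk, adapter-only reads, EST degradation
fragments, siRNA-like double-stranded decoy loci, and — the dominant
class, 50% — fragments of synthetic genomic loci absent from every
reference, which reproduces the real observation that most unique reads
stay unannotated and gives the 24-nt modal length with a 21-nt
shoulder.  Planted target windows are built by placing the exact
mismatches and wobbles that realise an intended alignment score, and
the GO table plants terms whose annotation concentrates in the target
genes.  Planted hairpins are verified against the discovery module's
own criteria at construction time, so fixture tests are
engine-independent.  Sampling is Poisson (not negative binomial) to
match the test's assumption; sequencing-error spectra, GC bias and
ligation bias are not modelled, and replicates are pooled into one
library per phase.  Identical configurations (including the seed)
produce byte-identical outputs.

What passing tests show, and don't: recovery and calibration results on
this generator demonstrate that the pipeline implements its stated
rules correctly and recovers structure that satisfies them; they do not
demonstrate robustness to real-data phenomena the generator omits
(overdispersion across replicates, sequencing errors, incomplete or
redundant EST assemblies, miRNA families with near-identical members).

## Problem sizes

The default study conditions are 3 × 200,000 reads, 300 ESTs of
300–800 nt, 50 known and 20 novel miRNAs; the full blind run completes
in well under two minutes on a single CPU.  Calibration uses 10,000
simulated null pairs at library size 10⁶ and 30 Bonferroni families of
300 miRNAs; power uses 1,000 four-fold replicates at 50 RPM.  Oracle
comparisons run on exhaustively enumerable sizes: folding on 12–16 nt
sequences, target alignment on ≤ 12-nt pairs, hypergeometric tails on
backgrounds of ≤ 12 genes.

## Known limitations

- The built-in folding score is not thermodynamic; absolute "kcal/mol"
  thresholds are only meaningful under a thermodynamic engine, which is
  why the engine is pluggable.
- Exact substring matching for structural/repeat/exon/intron categories
  has no mismatch tolerance, unlike the database searches it stands in
  for.
- One pooled library per phase: no replicate-aware dispersion modelling
  (negative binomial) and no FDR alternative to Bonferroni.
- The word-seed screen and the ungapped target prescreen are exactness
  trade-offs at scale; both are documented above and can be disabled.
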