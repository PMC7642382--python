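# Methods

This note documents the models, parameter choices, numerical
conventions and known limitations of `ncsplice`.

## Coordinates and junction representation

All internal coordinates are 1-based inclusive, the MAF/GTF convention;
BAM's 0-based positions are converted exactly once, where reads are
parsed.  A splice junction is the skipped intron, keyed by its first
and last intronic bases, read directly off the N operation of a spliced
read's CIGAR.  This matches GTF exon arithmetic: consecutive exons
`[s1,e1]`, `[s2,e2]` imply the canonical junction `(e1+1, s2−1)`.
Reads flagged secondary, supplementary, duplicate or QC-fail are
excluded everywhere.

## Discovery parameters

| parameter | default | meaning |
|---|---|---|
| M (`min_supporting_reads`) | 5 | minimum junction-supporting reads |
| Q (`min_mapq`) | 20 | minimum read mapping quality |
| N (`window`) | 20 bp | maximum mutation–junction distance |
| k (`control_top_fraction`) | 0.05 | case must out-rank this fraction of controls |
| `min_jaf` | 0.05 | heuristic junction-allele-fraction cut |
| `min_spliced_in_fraction` | 0.30 | mutant-allele fraction among junction reads covering a spliced-in mutation |
| `batch_size` | 200 | mutations per parallel batch |

The five-read minimum is anchored in the artifact model: at 200× depth
and mean base quality 20 the expected number of artifactual supporting
reads is 200·10^(−20/10) = 2, and P(X ≥ 5 | Poisson(2)) ≈ 5.3%.

**Distance convention.**  "Within N bp of the junction" is measured to
the nearest of the four boundary bases (first/last intronic base and
the adjacent exonic bases); the anchor is deliberately permissive since
the biological statement names no anchor.

**JAF denominator.**  Depth is counted at the exonic base immediately
adjacent to the junction boundary nearest the mutation.  Junction reads
have an aligned base there and count as covering; reads spliced over a
position do not cover it (the samtools convention).  At a boundary that
is intronic in the reference isoform, reference-origin reads splice
over the anchor, so the JAF of a genuine event approaches 1; at a
shared exonic base it approaches the altered-isoform fraction.  Either
way the 5% cut is conservative for true events.

**Spliced-in evidence.**  A mutation inside the retained (exonic)
segment of the new splice form must be visible in junction reads: among
junction-supporting reads whose aligned span covers the mutated base,
at least 30% must carry the alternate allele.  Only the covering subset
of junction reads enters the denominator; reads that do not reach the
base are uninformative.  Indels are indeterminate under per-base
inspection and are flagged rather than tested.  Mutations inside the
skipped intron are "spliced out" and exempt.

## Filter cascade

1. **Known junctions / polymorphic regions.**  A candidate is removed
   only when *both* boundaries match a canonical junction; junctions
   sharing a single boundary are retained, because extension,
   shrinkage, and new-exon junctions necessarily share one boundary
   with the canonical intron.  Blacklist intervals (BED) remove
   overlapping candidates; no default blacklist ships, since polymorphic
   loci are genome-build-specific.
2. **Coverage.**  Heuristic mode drops JAF strictly below 5% (boundary
   value passes, since the rule excludes "<5%").  Proportion mode
   computes the exact one-sided binomial upper tail
   P(X ≥ n | Binomial(depth, 0.05)) per candidate, applies
   Benjamini–Hochberg across the candidate set, and keeps q ≤ α.
   Heuristic mode is the default.
3. **Case/control.**  The fraction of control samples whose
   supporting-read count is ≥ the case count must be strictly below k;
   ties count against the case (conservative reading of "top 5%").
   The case is compared against the control distribution alone, not
   pooled with it.  At least one control is required.

Relaxing any threshold can only grow the surviving set; this
monotonicity is asserted by property tests.

## Splice-site scoring

The built-in model is a first-order position-weight matrix: per-position
base frequencies over the annotation's canonical sites (pseudocount 1
per base per position), scored as Σ log₂(f/0.25).  Log base 2 and the
uniform background match the conventional splice-score scale; the
pseudocount avoids −∞ on small annotation fixtures.  Donor sites use
9-mers (3 exonic + 6 intronic), acceptors 23-mers (20 intronic + 3
exonic), reverse-complemented on the minus strand so sequences read
5′→3′ on the transcript.  Scoring is additive, so a substitution
changes the score by exactly the log-odds difference at its position.
Training requires ≥ 50 canonical sites; below that the pipeline runs
without scores.  A subprocess adapter can delegate scoring to an
external maximum-entropy tool for parity runs; the adapter contract
(scores equal the tool's output) is tested with a stub scorer.  The
published iterative-scaling estimation of maximum-entropy parameters is
out of scope.

## Event classification

The decision tree, applied to the candidate junction against the
longest annotated transcript overlapping it (the host):

- one canonical boundary, other boundary in the intron → **exon
  extension**, *unless* a partner junction in the same intron bounds a
  plausible internal interval, in which case the pair is a **new exon**
  (the partner's inner boundary is the activated mate site, and the
  enclosed interval the new exon);
- one canonical boundary, other inside an exon → **exon shrinkage**;
- both boundaries inside one exon → **exon splitting**;
- boundaries in two different genes → **fusion**;
- no annotated transcript overlap → **new transcript** (never fails);
- two or more elementary signatures at once → **complex**.

New exons are subdivided first/middle/last by position relative to the
host's coding span (before the CDS start, internal, after the CDS end);
without CDS annotation the event is "middle".  The AMS search is
confined to the annotated intron containing the PSS, requires ≥ M
supporting reads for the partner, and restricts the enclosed exon to
15–600 bp (the simulator's exon-size range — the least arbitrary bound
available).  Ties between qualifying partners go to higher read
support, then to the shorter enclosed exon.  Frameshift is `length mod
3 ≠ 0`; premature stop scans the inserted sequence in CDS frame for a
stop codon, with the phase computed from coding bases upstream of the
insertion.  A junction pairing two canonical boundaries that do not
form an annotated intron (an exon-skipping-like signature) is reported
as complex; classifying skipping events is not a goal.

## Statistical framework

- **Required depth** is the ceiling of the Gaussian-approximation
  formula; default Z values 1.645 / 0.84 (5% type-I error, 80% power).
  Because the underlying test statistic is discrete, realized power at
  the recommended depth differs from the nominal level by a few points
  in either direction (at R = 150, J₁ = 0.10: 0.83 under the z-rule,
  0.75 under the exact binomial test).  The Monte-Carlo validation in
  the test suite therefore checks the formula under the Gaussian
  sampling model it assumes, and checks separately that the z-rule
  attains ≥ 80% under binomial sampling.
- **New-exon probability** uses the exact form 1 − (1 − 4⁻³²)^(L−E−31)
  via `expm1`/`log1p`; the linearized form (L−E−31)·4⁻³² is available
  and agrees to < 10⁻⁶ relative error for spans up to 10⁶.
- **Tukey outliers** use type-7 (linearly interpolated) quartiles;
  Tukey fences are sensitive to the quartile convention, so this is
  fixed and documented.  A zero IQR makes the score undefined and flags
  the result degenerate.  The optional score→p mapping is a
  *reconstruction* (normal model centred at the median with
  σ = IQR/1.349, one-sided by tail) and is labelled as such; BH
  correction is applied across genes.
- **Fisher's exact test** is two-sided by the standard
  equally-or-less-probable-tables rule (verified against full
  hypergeometric enumeration); the reported odds ratio is
  (n₂/n₁)/(t₂/t₁).

## Simulator and benchmark

The generator emulates the benchmark design: a 10⁶ bp i.i.d. genome at
40% GC; one plus-strand gene of 100 exons with exon lengths uniform in
15–600 bp and introns in 100–1000 bp; transcripts with 200 bp UTRs at
both ends and a 50 bp poly(A) tail (UTR and tail lengths are this
package's choice; they are not part of the stated design); exon
extensions of 5–50 bp at either exon end, with the causal mutation
placed at the novel splice boundary (first/last intronic base of the
novel intron, hence spliced out of the altered transcript); 75 bp reads
with uniform start positions and substitution rate 0.001 (no indels —
not characteristic of short-read data); mixtures with an exact
altered-read count at the requested fraction.

Reads carry gold-standard alignments derived from their origin
(exon-structure-mapped CIGARs with N gaps; poly(A) overhang
soft-clipped).  The published benchmark realigned simulated reads with
a spliced aligner; emitting origin-derived alignments instead makes the
measurement aligner-independent and desk-scale, so sensitivity isolates
the pipeline's detection logic.  FASTQ export is available for running
an external aligner.  The stated benchmark description ties base errors
to a "Q = 75 base quality", which is inconsistent with the stated
substitution rate of 0.001; the substitution rate is taken as
operative and bases are written with a fixed quality character.

For the benchmark, each injected event is its own case sample (one
mutation, one read mixture) with two reference-only controls, and reads
are simulated over a ±600 bp genomic window around the novel junction
rather than the whole transcript; per-base depth at the junction equals
the nominal coverage either way, and the windowing keeps one benchmark
run (20 events) under ~10 s.  Sensitivity counts a truth event as
recovered only when a reported junction matches both boundaries
exactly.

**What passing benchmarks do and do not show.**  Gold alignments remove
alignment error, the i.i.d. genome removes repeat-induced
multi-mapping, and simulated controls are free of shared artifacts, so
the measured sensitivity is an upper bound on real-data performance
(which depends on the spliced aligner).  Specificity against alignment
artifacts is exercised only through the artifact model and the
case/control design, not by simulating artifacts.

## Known limitations

- Substitutions only in the spliced-in check; indel-carrying candidates
  are flagged indeterminate rather than resolved.
- No de novo transcript reassembly, protein emission, or
  nonsense-mediated-decay prediction.
- The non-coding classification set defaults to the eight standard
  coding MAF classes and is configurable; MAF dialects differ and no
  attempt is made to normalize exotic classification strings.
- Control panels are taken as given (BAMs or a count table); building
  panels of normals and subtracting germline variation are out of
  scope.
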