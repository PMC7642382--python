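# ncsplice

Discovery and classification of **splice-site-creating non-coding
mutations** from RNA-Seq alignments.

Somatic mutations outside coding annotations can create or strengthen
splice sites, rerouting splicing into new exons, extended or shrunken
exons, and other rearrangements.  These events are visible in RNA-Seq
as *non-canonical splice junctions* — introns skipped by spliced reads
that match no annotated transcript — appearing close to the causal
mutation.  `ncsplice` pairs somatic mutations (MAF) with junctions
extracted from spliced alignments (BAM/SAM), filters the candidates,
scores splice-site strength, classifies the event, and ships the
statistical framework and a simulation benchmark for the whole
procedure.

## What it computes

**Junction discovery.**  For each non-coding mutation, junctions within
*N* = 20 bp (the span of a splice region) with at least *M* = 5
supporting reads of mapping quality *Q* ≥ 20 become candidates.  Each
candidate carries the junction allele fraction

> JAF = supporting reads / total reads at the site,

measured at the exonic base adjacent to the mutated splice boundary.

**Filter cascade.**  Candidates are removed when they (1) match a
canonical junction or fall in a polymorphic region (e.g. *HLA*); (2)
fail the coverage filter — either the heuristic JAF ≥ 5% cut or,
alternatively, a one-sided binomial proportion test of the JAF against
a 5% null with Benjamini–Hochberg correction; (3) fail the
case/control comparison — the case's supporting-read count must rank in
the top *k* = 5% against mutation-free control samples.  An automated
review step re-checks the five-read minimum and, for mutations retained
inside the new splice form ("spliced-in"), requires ≥ 30% of the
junction reads covering the mutation to carry the mutant allele.

**Scoring and classification.**  Donor sites are scored over 9-mers
(3 exonic + 6 intronic bases) and acceptors over 23-mers (20 intronic +
3 exonic) with a position-weight log₂-odds model trained on the
supplied annotation (an external maximum-entropy scorer can be plugged
in).  Events are classified into seven categories: new exon creation
(first / middle / last), exon extension, exon shrinkage, exon
splitting, gene fusion, new transcript, and complex.  For new exons the
mutation-created **primary splice site (PSS)** recruits an **activated
mate site (AMS)** elsewhere in the same intron; frameshift and
premature-stop impact is called against the annotated CDS.

**Statistics.**  The required read depth for a target power follows the
Gaussian-approximated one-sided binomial formula

> R ≥ ((Z₁₋α √(J₀(1−J₀)) + Z₁₋β √(J₁(1−J₁))) / (J₁ − J₀))²,

artifact expectations are `depth · 10^(−Q/10)` with a Poisson tail
motivating the five-read minimum, long-intron bias toward new-exon
creation is `(L_L − E − 31)/(L_S − E − 31)`, expression outliers use
Tukey fences `(x − Q3)/IQR` (upper) and `(x − Q1)/IQR` (lower), and
cancer-gene enrichment uses the two-sided Fisher exact test.

**Simulator.**  A synthetic 1 Mb locus (40% GC) carries a 100-exon gene
(exons 15–600 bp, introns 100–1000 bp); exon extensions of 5–50 bp are
injected and 75-bp reads (substitution rate 0.001) are mixed at chosen
altered-read fractions.  Reads carry gold-standard spliced alignments
derived from their origin, so the benchmark measures the detection
logic independent of any aligner.

## Worked example

`examples/simulate_and_discover.py` injects a 24-bp 3′ exon extension
into a simulated gene, mixes altered reads at 30% with 200× coverage,
and runs the full pipeline against two mutation-free controls:

```
injected: 24-bp 3' extension of exon 10, novel intron ('chrS', 10199, 11159)
causal mutation: chrS:10199G>A (spliced out of the new form)
stage counts: {'input': 1, 'discovery': 1, 'known_polymorphic': 1,
               'coverage': 1, 'case_control': 1, 'review': 1}
called: exon_extension at chrS:10199-11159 (73 reads, JAF 0.97)
```

The one discovered junction matches the injected novel intron exactly:
73 spliced reads support it (well above the 5-read minimum), the JAF of
0.97 reflects that at the novel boundary essentially all covering reads
come from the altered isoform, and the event is classified as an exon
extension because the junction shares its acceptor with the canonical
intron while its donor lies inside it.

Other examples: `power_and_artifacts.py` (required depth, artifact
threshold), `intron_bias_and_enrichment.py`, `expression_outliers.py`,
`sensitivity_benchmark.py`.  A thin CLI mirrors these capabilities:
`ncsplice discover|simulate|power|artifact-threshold|intron-bias|outliers|enrich`.

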