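"""Sensitivity-benchmark simulator.

Generates a synthetic genomic locus (default 1 Mb, 40% GC) carrying one
multi-exon gene (default 100 exons of 15-600 bp separated by introns of
100-1000 bp), injects exon-extension events (5' or 3' shifts of 5-50 bp)
with the mutation placed at the novel splice boundary, and simulates
75-bp reads from reference and altered transcripts mixed at a chosen
fraction with a per-base substitution rate of 0.001.  Because the reads'
origins are known, gold-standard spliced alignments (origin-derived
CIGARs) are emitted directly, so measured sensitivity reflects the
detection logic rather than any particular spliced aligner.  Transcripts
carry 200-bp UTRs on both ends and a 50-bp poly(A) tail; read segments
falling in the tail are soft-clipped in the gold alignment.  Simulated
genes are laid on the plus strand.  All outputs are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import SomaticMutation, TranscriptModel

log = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
READ_LENGTH = 75
SUBSTITUTION_RATE = 0.001
UTR_LENGTH = 200
POLYA_LENGTH = 50
MIN_ANCHOR = 10  # aligned bases required for a gold alignment record

#: The benchmark design mixes altered with reference reads at fractions
#: 0.1 to 0.5 in increments of 0.05 (nine test sets).
MIXTURE_GRID = tuple(round(0.1 + 0.05 * i, 2) for i in range(9))


@dataclass
class TruthEvent:
    """One injected splicing alteration with its expected novel junction."""

    event_type: str
    exon_index: int
    end: str  # "5p" | "3p"
    shift_bp: int
    junction: tuple  # (chrom, intron_start, intron_end)
    mutation: SomaticMutation
    altered_transcript: TranscriptModel


@dataclass
class SimulatedRead:
    """A simulated 75-bp read with its gold spliced alignment."""

    name: str
    chrom: str
    pos: int  # 1-based leftmost aligned base
    cigar: str
    seq: str
    origin: str  # "ref" | "alt"
    mapq: int = 60


@dataclass
class SimulatedLocus:
    """Synthetic genome + gene structure + injected truth events."""

    chrom: str
    genome_seq: str
    gc: float
    gene: TranscriptModel
    seed: int
    truth_events: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.genome_seq)

    def realized_gc(self) -> float:
        seq = self.genome_seq
        return (seq.count("G") + seq.count("C")) / len(seq)


def simulate_gene_locus(
    length: int = 1_000_000,
    gc: float = 0.40,
    n_exons: int = 100,
    exon_range: tuple = (15, 600),
    intron_range: tuple = (100, 1000),
    seed: int = 0,
    chrom: str = "chrS",
) -> SimulatedLocus:
    """Generate the synthetic locus and its single plus-strand gene.

    Bases are i.i.d. with P(G)+P(C) = ``gc``; exon and intron lengths are
    uniform over the given inclusive ranges.  The coding span is taken to
    run from the first to the last exon.
    """
    if min(*exon_range, *intron_range) <= 0:
        raise ValueError("exon/intron ranges must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = "".join(rng.choice(BASES, size=length, p=p))

    exon_lens = rng.integers(exon_range[0], exon_range[1] + 1, size=n_exons)
    intron_lens = rng.integers(intron_range[0], intron_range[1] + 1, size=max(0, n_exons - 1))
    margin = UTR_LENGTH + 1000
    total = int(exon_lens.sum() + intron_lens.sum())
    if total + 2 * margin > length:
        raise ValueError(
            f"gene structure ({total} bp) does not fit in a {length} bp "
            "genome; increase length"
        )
    exons = []
    pos = margin + 1  # 1-based start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el) - 1))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    gene = TranscriptModel(
        gene_id="simgene",
        transcript_id="simgene.t1",
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )
    return SimulatedLocus(chrom=chrom, genome_seq=genome, gc=gc, gene=gene, seed=seed)


def inject_exon_extension(
    locus: SimulatedLocus, exon_index: int, shift_bp: int, end: str = "3p"
) -> TruthEvent:
    """Extend one exon into its flanking intron and record the truth.

    ``end`` selects the transcript 5' or 3' side of the exon (the gene is
    plus-strand, so 5' extends the start and 3' the end).  The shift must
    stay inside the flanking intron.  The causal mutation is placed at
    the first (3') or last (5') intronic base of the novel intron, i.e.
    at the novel splice boundary, spliced out of the altered transcript.
    """
    exons = list(locus.gene.exons)
    if not 0 <= exon_index < len(exons):
        raise ValueError(f"exon_index {exon_index} out of range")
    s, e = exons[exon_index]
    if end == "3p":
        if exon_index == len(exons) - 1:
            raise ValueError("cannot extend the last exon 3' (no downstream intron)")
        next_s = exons[exon_index + 1][0]
        intron_len = next_s - e - 1
        if shift_bp >= intron_len:
            raise ValueError(
                f"shift {shift_bp} crosses the {intron_len}-bp downstream intron"
            )
        new_exon = (s, e + shift_bp)
        junction = (locus.chrom, e + shift_bp + 1, next_s - 1)
        mut_pos = e + shift_bp + 1
    elif end == "5p":
        if exon_index == 0:
            raise ValueError("cannot extend the first exon 5' (no upstream intron)")
        prev_e = exons[exon_index - 1][1]
        intron_len = s - prev_e - 1
        if shift_bp >= intron_len:
            raise ValueError(
                f"shift {shift_bp} crosses the {intron_len}-bp upstream intron"
            )
        new_exon = (s - shift_bp, e)
        junction = (locus.chrom, prev_e + 1, s - shift_bp - 1)
        mut_pos = s - shift_bp - 1
    else:
        raise ValueError("end must be '5p' or '3p'")
    exons[exon_index] = new_exon
    altered = TranscriptModel(
        gene_id=locus.gene.gene_id,
        transcript_id=f"{locus.gene.transcript_id}.ext{exon_index}{end}{shift_bp}",
        chrom=locus.chrom,
        strand="+",
        exons=exons,
        cds_start=locus.gene.cds_start,
        cds_end=locus.gene.cds_end,
    )
    ref_base = locus.genome_seq[mut_pos - 1]
    alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    mutation = SomaticMutation(
        chrom=locus.chrom,
        pos=mut_pos,
        ref_allele=ref_base,
        alt_allele=alt_base,
        sample_id=f"case_e{exon_index}_{end}",
        variant_classification="Intron",
    )
    event = TruthEvent(
        event_type="exon_extension",
        exon_index=exon_index,
        end=end,
        shift_bp=shift_bp,
        junction=junction,
        mutation=mutation,
        altered_transcript=altered,
    )
    locus.truth_events.append(event)
    return event


def _template_blocks(tm: TranscriptModel) -> list:
    """Genomic blocks of the read template: exons with UTR-extended ends."""
    blocks = [list(iv) for iv in tm.exons]
    blocks[0][0] = max(1, blocks[0][0] - UTR_LENGTH)
    blocks[-1][1] = blocks[-1][1] + UTR_LENGTH
    return [tuple(b) for b in blocks]


def _template_sequence(tm: TranscriptModel, genome_seq: str) -> str:
    parts = [genome_seq[s - 1 : e] for s, e in _template_blocks(tm)]
    return "".join(parts) + "A" * POLYA_LENGTH


def _transcript_to_genome(blocks: list, t0: int, span: int):
    """Map transcript interval [t0, t0+span) to genomic M segments.

    Returns (segments, clipped) where segments are 1-based inclusive
    genomic intervals and ``clipped`` is the number of trailing template
    bases (poly(A)) without a genomic home.
    """
    segments = []
    offset = 0
    remaining_start = t0
    remaining = span
    for s, e in blocks:
        blen = e - s + 1
        if remaining_start >= offset + blen:
            offset += blen
            continue
        local = max(remaining_start - offset, 0)
        take = min(blen - local, remaining)
        segments.append((s + local, s + local + take - 1))
        remaining -= take
        remaining_start = offset + blen
        offset += blen
        if remaining == 0:
            break
    return segments, remaining


def gold_alignment(tm_blocks: list, t0: int, read_len: int, chrom: str):
    """(pos, cigar) of the gold spliced alignment, or None if unanchored."""
    segments, clipped = _transcript_to_genome(tm_blocks, t0, read_len)
    aligned = sum(e - s + 1 for s, e in segments)
    if aligned < MIN_ANCHOR:
        return None
    ops = []
    for i, (s, e) in enumerate(segments):
        if i > 0:
            gap = s - segments[i - 1][1] - 1
            if gap > 0:
                ops.append(f"{gap}N")
        ops.append(f"{e - s + 1}M")
    if clipped > 0:
        ops.append(f"{clipped}S")
    return segments[0][0], "".join(ops)


def simulate_read_mixture(
    locus: SimulatedLocus,
    reference: TranscriptModel,
    altered: TranscriptModel,
    fraction: float,
    coverage: float,
    read_len: int = READ_LENGTH,
    sub_rate: float = SUBSTITUTION_RATE,
    seed: int = 0,
    window: Optional[tuple] = None,
) -> list:
    """Simulate a labeled case read set mixing altered and reference origins.

    Start positions are uniform over each transcript (restricted to the
    genomic ``window``, when given, to focus coverage on a region of
    interest); each base substitutes to a uniformly random different base
    with probability ``sub_rate``.  The altered-origin read count is the
    rounded ``fraction`` of the total, so the realized mixture matches
    the request up to rounding.  Returns SimulatedRead objects carrying
    gold alignments.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0,1]")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    reads: list = []
    plan = [("alt", altered, fraction), ("ref", reference, 1.0 - fraction)]
    # total reads sized so that per-base depth over the sampled span is
    # ~coverage; the alt/ref split is exact up to rounding
    starts = {}
    for origin, tm, _ in plan:
        starts[origin] = _valid_starts(tm, locus, read_len, window)
    span = max(len(starts["ref"]), len(starts["alt"])) + read_len - 1
    n_total = max(1, round(coverage * span / read_len))
    n_alt = round(n_total * fraction)
    counts = {"alt": n_alt, "ref": n_total - n_alt}
    for origin, tm, _ in plan:
        n = counts[origin]
        if n == 0:
            continue
        valid = starts[origin]
        if valid.size == 0:
            raise ValueError(f"transcript {tm.transcript_id} shorter than read_len")
        blocks = _template_blocks(tm)
        template = _template_sequence(tm, locus.genome_seq)
        chosen = rng.choice(valid, size=n, replace=True)
        for i, t0 in enumerate(sorted(int(c) for c in chosen)):
            seq = _mutate_bases(template[t0 : t0 + read_len], sub_rate, rng)
            gold = gold_alignment(blocks, t0, read_len, locus.chrom)
            if gold is None:
                continue
            pos, cigar = gold
            reads.append(
                SimulatedRead(
                    name=f"{tm.transcript_id}:{origin}:{i}",
                    chrom=locus.chrom,
                    pos=pos,
                    cigar=cigar,
                    seq=seq,
                    origin=origin,
                )
            )
    reads.sort(key=lambda r: (r.pos, r.name))
    return reads


def _valid_starts(tm, locus, read_len, window):
    blocks = _template_blocks(tm)
    tlen = sum(e - s + 1 for s, e in blocks) + POLYA_LENGTH
    if tlen < read_len:
        raise ValueError(f"transcript {tm.transcript_id} shorter than read_len")
    all_starts = np.arange(0, tlen - read_len + 1)
    if window is None:
        return all_starts
    glo, ghi = window
    # transcript coordinates of template bases inside the genomic window
    keep = []
    offset = 0
    for s, e in blocks:
        lo = max(s, glo)
        hi = min(e, ghi)
        if lo <= hi:
            keep.append((offset + (lo - s), offset + (hi - s)))
        offset += e - s + 1
    if not keep:
        return np.array([], dtype=int)
    mask = np.zeros(tlen, dtype=bool)
    for a, b in keep:
        mask[a : b + 1] = True
    ok = mask[all_starts]
    return all_starts[ok]


def _mutate_bases(seq: str, sub_rate: float, rng) -> str:
    if sub_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def evaluate_sensitivity(calls, truth: Sequence[TruthEvent]) -> float:
    """Fraction of truth events whose junction was called with exact boundaries."""
    if not truth:
        raise ValueError("truth set is empty; sensitivity undefined")
    called = set()
    for c in calls:
        if isinstance(c, tuple):
            called.add(c)
        elif hasattr(c, "junction"):  # SpliceJunction-bearing objects
            jx = c.junction
            if hasattr(jx, "key"):
                called.add(jx.key)
            else:
                called.add(tuple(jx))
        elif hasattr(c, "candidate") and c.candidate is not None:  # SpliceEvent
            called.add(c.candidate.junction.key)
    matched = sum(1 for t in truth if t.junction in called)
    return matched / len(truth)


# ---------------------------------------------------------------------------
# file emission


def write_fasta(locus: SimulatedLocus, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{locus.chrom}\n")
        seq = locus.genome_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Ensembl-dialect GTF with exon (and CDS, when defined) features."""
    with open(path, "w") as fh:
        for tm in transcripts:
            attrs = f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}";'
            for i, (s, e) in enumerate(tm.exons, start=1):
                fh.write(
                    f"{tm.chrom}\tsim\texon\t{s}\t{e}\t.\t{tm.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )
                if tm.cds_start is not None and tm.cds_end is not None:
                    cs, ce = max(s, tm.cds_start), min(e, tm.cds_end)
                    if cs <= ce:
                        fh.write(
                            f"{tm.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{tm.strand}\t0\t"
                            f'{attrs} exon_number "{i}";\n'
                        )


def write_alignments(reads: Sequence[SimulatedRead], locus: SimulatedLocus, path) -> str:
    """Write reads as a coordinate-sorted BAM (or SAM) with an index.

    Returns the path written.  SAM output (``.sam`` suffix) is plain text
    and unindexed; BAM output is indexed for region queries.
    """
    import pysam

    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": locus.chrom, "LN": locus.length}],
    }
    mode = "w" if path.endswith(".sam") else "wb"
    ordered = sorted(reads, key=lambda r: r.pos)
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = r.cigar
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            seg.set_tag("XO", r.origin)
            out.write(seg)
    if mode == "wb":
        pysam.index(path)
    return path


def write_truth_table(truth: Sequence[TruthEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_type\texon_index\tend\tshift_bp\tchrom\tintron_start\t"
            "intron_end\tmutation\tsample\n"
        )
        for t in truth:
            c, s, e = t.junction
            fh.write(
                f"{t.event_type}\t{t.exon_index}\t{t.end}\t{t.shift_bp}\t"
                f"{c}\t{s}\t{e}\t{t.mutation.key()}\t{t.mutation.sample_id}\n"
            )


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    """Optional FASTQ export for running an external spliced aligner."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
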