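import numpy as np
import pytest

from ncsplice.io_formats import (
    AnnotationIndex,
    PipelineConfig,
    SomaticMutation,
    TranscriptModel,
)
from ncsplice.junction_discovery import JunctionCandidate, SpliceJunction
from ncsplice.simulator import SimulatedRead, write_alignments


class Contig:
    """Minimal stand-in for a simulated locus when writing ad-hoc reads."""

    def __init__(self, chrom="chr1", length=100_000):
        self.chrom = chrom
        self.length = length


@pytest.fixture
def contig():
    return Contig()


def make_read(name, pos, cigar, seq=None, mapq=60, chrom="chr1"):
    if seq is None:
        import re

        qlen = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar)
        )
        seq = "A" * qlen
    return SimulatedRead(name=name, chrom=chrom, pos=pos, cigar=cigar, seq=seq, origin="ref", mapq=mapq)


@pytest.fixture
def bam_factory(tmp_path, contig):
    """Write ad-hoc reads to an indexed BAM and open it."""
    import pysam

    handles = []

    def build(reads, name="reads.bam"):
        path = write_alignments(reads, contig, tmp_path / name)
        fh = pysam.AlignmentFile(path)
        handles.append(fh)
        return fh

    yield build
    for fh in handles:
        fh.close()


@pytest.fixture
def two_gene_annotation():
    """Two plus-strand genes on chr1 for classification tests."""
    tm_a = TranscriptModel(
        "geneA", "geneA.t1", "chr1", "+",
        [(1001, 1100), (1301, 1400), (1601, 1700), (1901, 2000)],
        cds_start=1001, cds_end=2000,
    )
    tm_b = TranscriptModel(
        "geneB", "geneB.t1", "chr1", "+", [(5001, 5100), (5201, 5300)],
        cds_start=5001, cds_end=5300,
    )
    junctions = set()
    strands = {}
    for tm in (tm_a, tm_b):
        for s, e in tm.introns():
            junctions.add((tm.chrom, s, e))
            strands[(tm.chrom, s, e)] = tm.strand
    return AnnotationIndex(
        canonical_junctions=junctions,
        transcripts={t.transcript_id: t for t in (tm_a, tm_b)},
        gene_regions={
            "geneA": ("chr1", 1001, 2000),
            "geneB": ("chr1", 5001, 5300),
        },
        junction_strands=strands,
    )


@pytest.fixture
def config():
    return PipelineConfig()


def make_candidate(
    intron_start,
    intron_end,
    mutation_pos,
    n_supporting=10,
    depth=40,
    chrom="chr1",
    sample="S1",
):
    jx = SpliceJunction(
        chrom=chrom,
        intron_start=intron_start,
        intron_end=intron_end,
        n_supporting_reads=n_supporting,
        depth_at_site=depth,
        jaf=n_supporting / depth if depth else 0.0,
    )
    mut = SomaticMutation(
        chrom=chrom,
        pos=mutation_pos,
        ref_allele="A",
        alt_allele="G",
        sample_id=sample,
        variant_classification="Intron",
    )
    return JunctionCandidate(mutation=mut, junction=jx, distance_bp=0)
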