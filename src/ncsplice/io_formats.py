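"""Readers and writers for the standard input formats.

Somatic mutations arrive as MAF (tab-separated, 1-based), transcript
annotation as GTF (Ensembl attribute dialect), genomes as indexed FASTA,
alignments as BAM/SAM, blacklists as BED.  Everything is converted to a
small set of domain types at the boundary; all internal coordinates are
1-based inclusive (the MAF/GTF convention), and BAM's 0-based positions
are converted where reads are parsed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

#: Coding classifications removed before junction discovery.  The goal is to
#: keep only mutations that conventional annotation calls non-coding; the
#: exact MAF strings for the excluded families are a configurable judgment
#: call since MAF dialects differ.
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {
        "Splice_Site",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
    }
)


class FormatError(ValueError):
    """A required column or attribute is missing or unparsable."""


@dataclass(frozen=True)
class SomaticMutation:
    """One non-coding somatic mutation record (MAF coordinates, 1-based)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str
    variant_classification: str
    dna_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")

    @property
    def is_indel(self) -> bool:
        return "-" in (self.ref_allele, self.alt_allele) or len(
            self.ref_allele
        ) != len(self.alt_allele)

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass
class PipelineConfig:
    """Pipeline thresholds.

    min_supporting_reads (M), min_mapq (Q), window (N, bp) and
    control_top_fraction (k) are the four headline parameters; min_jaf is
    the heuristic junction-allele-fraction cut and min_spliced_in_fraction
    the evidence requirement for mutations retained inside the new splice
    form.  ``mode`` selects the coverage filter: ``heuristic`` (JAF cut)
    or ``proportion`` (one-sided binomial test with BH correction at
    ``alpha`` against ``null_jaf``).
    """

    min_supporting_reads: int = 5
    min_mapq: int = 20
    window: int = 20
    control_top_fraction: float = 0.05
    min_jaf: float = 0.05
    min_spliced_in_fraction: float = 0.30
    batch_size: int = 200
    seed: int = 0
    mode: str = "heuristic"
    null_jaf: float = 0.05
    alpha: float = 0.05
    excluded_classes: frozenset = DEFAULT_EXCLUDED_CLASSES
    scorer: str = "builtin"

    def __post_init__(self) -> None:
        if self.min_supporting_reads < 1:
            raise ValueError("min_supporting_reads must be positive")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be non-negative")
        if self.window < 1:
            raise ValueError("window must be positive")
        if not 0.0 < self.control_top_fraction < 1.0:
            raise ValueError("control_top_fraction must lie in (0,1)")
        if not 0.0 <= self.min_jaf <= 1.0:
            raise ValueError("min_jaf must lie in [0,1]")
        if not 0.0 <= self.min_spliced_in_fraction <= 1.0:
            raise ValueError("min_spliced_in_fraction must lie in [0,1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.mode not in ("heuristic", "proportion"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TranscriptModel:
    """Exon structure of one annotated transcript (1-based closed intervals)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list  # list[tuple[int, int]], sorted, non-overlapping
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"{self.transcript_id}: exon start {start} > end {end}"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"transcript {self.transcript_id} has overlapping or "
                    f"unsorted exons ({s1}-{e1}, {s2}-{e2})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list:
        """Intron intervals (first, last intronic base) between consecutive exons."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 >= 2:  # zero-length gap: abutting exons, no intron
                out.append((e1 + 1, s2 - 1))
        return out

    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class AnnotationIndex:
    """Canonical junctions plus interval-queryable transcripts."""

    canonical_junctions: set  # {(chrom, intron_start, intron_end)}
    transcripts: dict  # transcript_id -> TranscriptModel
    gene_regions: dict  # gene_id -> (chrom, start, end)
    junction_strands: dict = field(default_factory=dict)
    _trees: dict = field(default_factory=dict)  # chrom -> IntervalTree of tids

    def __post_init__(self) -> None:
        if not self._trees:
            for tid, tm in self.transcripts.items():
                self._trees.setdefault(tm.chrom, IntervalTree()).addi(
                    tm.start, tm.end + 1, tid
                )

    def is_canonical(self, chrom: str, intron_start: int, intron_end: int) -> bool:
        return (chrom, intron_start, intron_end) in self.canonical_junctions

    def transcripts_overlapping(
        self, chrom: str, start: int, end: int
    ) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        tids = {iv.data for iv in tree.overlap(start, end + 1)}
        return [self.transcripts[t] for t in sorted(tids)]

    def transcripts_at(self, chrom: str, pos: int) -> list:
        return self.transcripts_overlapping(chrom, pos, pos)

    def canonical_boundaries(self, chrom: str) -> set:
        """All donor/acceptor boundary positions (first/last intronic base)."""
        out = set()
        for c, s, e in self.canonical_junctions:
            if c == chrom:
                out.add(s)
                out.add(e)
        return out


def read_maf_noncoding(
    path,
    excluded_classes: Iterable[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list:
    """Read a MAF file, keeping only non-coding records.

    Records whose Variant_Classification is in ``excluded_classes`` are
    dropped; input order is preserved.  Only the six mandatory columns are
    required, extra columns are ignored (MAF dialects differ).  An optional
    ``dna_vaf`` column, when present, is carried through.
    """
    excluded = set(excluded_classes)
    mutations = []
    n_excluded = 0
    with open(path, newline="") as fh:
        lines = (ln for ln in fh if not ln.startswith("#"))
        reader = csv.DictReader(lines, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in MAF_REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"MAF missing mandatory column(s): {', '.join(missing)}")
        has_vaf = "dna_vaf" in reader.fieldnames
        for i, row in enumerate(reader, start=2):
            try:
                pos = int(row["Start_Position"])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"unparsable Start_Position at line {i}: "
                    f"{row.get('Start_Position')!r}"
                ) from exc
            if row["Variant_Classification"] in excluded:
                n_excluded += 1
                continue
            vaf = None
            if has_vaf and row["dna_vaf"] not in (None, "", "NA"):
                vaf = float(row["dna_vaf"])
            mutations.append(
                SomaticMutation(
                    chrom=row["Chromosome"],
                    pos=pos,
                    ref_allele=row["Reference_Allele"],
                    alt_allele=row["Tumor_Seq_Allele2"],
                    sample_id=row["Tumor_Sample_Barcode"],
                    variant_classification=row["Variant_Classification"],
                    dna_vaf=vaf,
                )
            )
    log.info(
        "read %d non-coding mutations (%d coding records excluded)",
        len(mutations),
        n_excluded,
    )
    return mutations


def write_maf(mutations: Sequence[SomaticMutation], path) -> None:
    """Write mutations as a minimal MAF (round-trips with read_maf_noncoding)."""
    any_vaf = any(m.dna_vaf is not None for m in mutations)
    cols = list(MAF_REQUIRED_COLUMNS) + (["dna_vaf"] if any_vaf else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for m in mutations:
            out = [
                m.chrom,
                str(m.pos),
                m.ref_allele,
                m.alt_allele,
                m.variant_classification,
                m.sample_id,
            ]
            if any_vaf:
                out.append("" if m.dna_vaf is None else repr(m.dna_vaf))
            w.writerow(out)


def build_annotation_index(gtf_path) -> AnnotationIndex:
    """Build the canonical-junction / transcript index from a GTF.

    Canonical junctions are the introns between consecutive exons of every
    annotated transcript, as a set (shared introns collapse).  CDS features,
    when present, define the coding interval of each transcript.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict = {}
    meta: dict = {}
    for f in db.features_of_type("exon"):
        try:
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"exon feature at {f.seqid}:{f.start} lacks {exc} attribute"
            ) from exc
        exons_by_tx.setdefault(tid, []).append((f.start, f.end))
        meta[tid] = (gid, f.seqid, f.strand)
    cds_by_tx: dict = {}
    try:
        cds_feats = list(db.features_of_type("CDS"))
    except Exception:
        cds_feats = []
    for f in cds_feats:
        tid = f.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        lo, hi = cds_by_tx.get(tid, (f.start, f.end))
        cds_by_tx[tid] = (min(lo, f.start), max(hi, f.end))

    transcripts = {}
    canonical = set()
    strands = {}
    gene_regions: dict = {}
    for tid, exons in exons_by_tx.items():
        gid, chrom, strand = meta[tid]
        tm = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=sorted(exons),
            cds_start=cds_by_tx.get(tid, (None, None))[0],
            cds_end=cds_by_tx.get(tid, (None, None))[1],
        )
        transcripts[tid] = tm
        for s, e in tm.introns():
            canonical.add((chrom, s, e))
            strands[(chrom, s, e)] = strand
        c, lo, hi = gene_regions.get(gid, (chrom, tm.start, tm.end))
        gene_regions[gid] = (c, min(lo, tm.start), max(hi, tm.end))

    return AnnotationIndex(
        canonical_junctions=canonical,
        transcripts=transcripts,
        gene_regions=gene_regions,
        junction_strands=strands,
    )


def read_bed_blacklist(path) -> dict:
    """Read a BED blacklist into per-chromosome interval trees.

    BED is 0-based half-open; intervals are converted to the internal
    1-based inclusive convention.
    """
    trees: dict = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with <3 columns: {ln!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            trees.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
    return trees


def read_expression_table(path):
    """Read a gene x sample expression table (TSV, first column gene ids)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)
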