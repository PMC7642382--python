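"""Extraction of non-canonical splice junctions near somatic mutations.

A splice junction is the intron skipped by a spliced read, keyed by its
first and last intronic bases (1-based inclusive), read straight off the
N operation of the CIGAR.  For each mutation, junctions within ``N`` bp
and with at least ``M`` supporting reads become candidates; each
candidate carries the local read depth, the junction allele fraction
(JAF = supporting reads / reads at the site), and — when the mutation is
retained in the new splice form — the fraction of junction reads that
actually carry the mutant allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

log = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_CONSUMES_REF = {0, 2, 7, 8}  # M, D, =, X
_OP_N = 3

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SpliceJunction:
    """An intron call with its read support at one genomic location."""

    chrom: str
    intron_start: int  # first intronic base, 1-based
    intron_end: int  # last intronic base, 1-based
    strand: str = "unknown"
    n_supporting_reads: int = 0
    depth_at_site: int = 0
    jaf: float = 0.0
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError("intron_start must be < intron_end")

    @property
    def key(self):
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass
class JunctionCandidate:
    """A (mutation, junction) pair under evaluation by the filter cascade."""

    mutation: object  # SomaticMutation
    junction: SpliceJunction
    distance_bp: int
    spliced_in: bool = False
    spliced_in_fraction: Optional[float] = None
    control_counts: list = field(default_factory=list)
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    verdict: dict = field(default_factory=dict)

    @property
    def key(self):
        return (self.mutation.key(), self.junction.key)


def _read_usable(read, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and not read.is_qcfail
        and read.mapping_quality >= min_mapq
    )


def read_junctions(read):
    """Introns implied by one alignment's N CIGAR operations (1-based)."""
    out = []
    if read.cigartuples is None:
        return out
    ref = read.reference_start  # 0-based cursor
    for op, length in read.cigartuples:
        if op == _OP_N:
            out.append((ref + 1, ref + length))
            ref += length
        elif op in _CONSUMES_REF:
            ref += length
    return out


def extract_junctions(
    alignments, chrom: str, start: int, end: int, min_mapq: int
) -> dict:
    """Tally splice junctions in a region.

    Returns a mapping ``(chrom, intron_start, intron_end) -> supporting
    read count``.  Each skipped-region (N) operation of a usable read
    (primary, non-duplicate, MAPQ >= min_mapq) tallies its intron once.
    Coordinates are 1-based inclusive.
    """
    if chrom not in alignments.references:
        raise ValueError(f"chromosome {chrom!r} absent from alignment header")
    tally: dict = {}
    for read in alignments.fetch(chrom, max(0, start - 1), end):
        if not _read_usable(read, min_mapq):
            continue
        if read.cigartuples is None:
            log.warning("read %s lacks a CIGAR; skipped", read.query_name)
            continue
        for s, e in read_junctions(read):
            key = (chrom, s, e)
            tally[key] = tally.get(key, 0) + 1
    return tally


def site_depth(alignments, chrom: str, pos: int, min_mapq: int) -> int:
    """Number of usable reads whose aligned segments cover ``pos``.

    Reads spliced over ``pos`` (the position falls in an N gap) do not
    cover it; junction-supporting reads therefore contribute depth only
    at exonic bases where they have an aligned base.
    """
    if pos < 1:
        raise ValueError("pos must be >= 1")
    if chrom not in alignments.references:
        raise ValueError(f"chromosome {chrom!r} absent from alignment header")
    p0 = pos - 1  # 0-based
    n = 0
    for read in alignments.fetch(chrom, p0, p0 + 1):
        if not _read_usable(read, min_mapq):
            continue
        for bs, be in read.get_blocks():
            if bs <= p0 < be:
                n += 1
                break
    return n


def compute_jaf(n_supporting: int, depth: int) -> float:
    """Junction allele fraction: supporting reads over total reads at the site."""
    if n_supporting < 0 or depth < 0:
        raise ValueError("counts must be non-negative")
    if n_supporting > depth:
        raise ValueError(
            f"supporting reads ({n_supporting}) exceed depth ({depth})"
        )
    if depth == 0:
        return 0.0
    return n_supporting / depth


def boundary_distance(pos: int, intron_start: int, intron_end: int) -> int:
    """Distance from ``pos`` to the nearest junction boundary base.

    The four anchors are the first/last intronic bases and the adjacent
    exonic bases on either side.
    """
    return min(
        abs(pos - intron_start),
        abs(pos - (intron_start - 1)),
        abs(pos - intron_end),
        abs(pos - (intron_end + 1)),
    )


def depth_anchor(pos: int, intron_start: int, intron_end: int) -> int:
    """Exonic base adjacent to the junction boundary nearest the mutation.

    The JAF denominator is evaluated at this base: junction-supporting
    reads have an aligned base there, so they count as covering.
    """
    d_start = min(abs(pos - intron_start), abs(pos - (intron_start - 1)))
    d_end = min(abs(pos - intron_end), abs(pos - (intron_end + 1)))
    return intron_start - 1 if d_start <= d_end else intron_end + 1


def infer_strand(genome, chrom: str, intron_start: int, intron_end: int) -> str:
    """Strand of a junction from its intronic dinucleotides (GT..AG / CT..AC)."""
    donor = fetch_sequence(genome, chrom, intron_start, intron_start + 1).upper()
    acceptor = fetch_sequence(genome, chrom, intron_end - 1, intron_end).upper()
    if donor == "GT" and acceptor == "AG":
        return "+"
    if donor == "CT" and acceptor == "AC":
        return "-"
    return "unknown"


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive substring from a pyfaidx-like genome object."""
    if start < 1:
        raise ValueError("sequence window precedes contig start")
    seq = str(genome[chrom][start - 1 : end])
    if len(seq) != end - start + 1:
        raise ValueError(
            f"window {chrom}:{start}-{end} exceeds contig bounds"
        )
    return seq


def find_candidates(
    mutation, junctions: Mapping, annotation, config
) -> list:
    """Pair a mutation with nearby, sufficiently supported junctions.

    Keeps junctions with at least ``min_supporting_reads`` reads whose
    nearest boundary lies within ``window`` bp of the mutation; the
    canonical flag is looked up in the annotation (canonical junctions
    are removed later, by the known-junction filter, so that control
    counting can still see them).
    """
    out = []
    for (chrom, s, e), count in sorted(junctions.items()):
        if chrom != mutation.chrom:
            continue
        if count < config.min_supporting_reads:
            continue
        d = boundary_distance(mutation.pos, s, e)
        if d > config.window:
            continue
        jx = SpliceJunction(
            chrom=chrom,
            intron_start=s,
            intron_end=e,
            n_supporting_reads=count,
            is_canonical=annotation.is_canonical(chrom, s, e),
        )
        out.append(JunctionCandidate(mutation=mutation, junction=jx, distance_bp=d))
    return out


def annotate_candidate(
    candidate, alignments, genome, min_mapq: int
) -> None:
    """Fill depth, JAF, strand and spliced-in evidence in place."""
    jx = candidate.junction
    anchor = depth_anchor(candidate.mutation.pos, jx.intron_start, jx.intron_end)
    jx.depth_at_site = site_depth(alignments, jx.chrom, anchor, min_mapq)
    # race-free guard: junction reads seen in a different fetch window can
    # exceed the anchor depth only through boundary effects; clamp defensively
    jx.n_supporting_reads = min(jx.n_supporting_reads, jx.depth_at_site)
    jx.jaf = compute_jaf(jx.n_supporting_reads, jx.depth_at_site)
    if genome is not None:
        jx.strand = infer_strand(genome, jx.chrom, jx.intron_start, jx.intron_end)
    frac = spliced_in_fraction(candidate, alignments, min_mapq)
    candidate.spliced_in = frac is not None
    candidate.spliced_in_fraction = frac


def spliced_in_fraction(candidate, alignments, min_mapq: int) -> Optional[float]:
    """Fraction of junction-supporting reads carrying the mutant allele.

    Defined only for spliced-in mutations — those lying in the transcribed
    segment retained by the junction (outside the skipped intron).  Among
    junction-supporting reads whose aligned span covers the mutation
    position, returns the fraction whose base equals the alternate allele.
    Returns None (absent) for spliced-out mutations and for indels, which
    are indeterminate under per-base inspection.
    """
    mut = candidate.mutation
    jx = candidate.junction
    if jx.intron_start <= mut.pos <= jx.intron_end:
        return None  # spliced out: mutation is inside the removed intron
    if mut.is_indel:
        log.warning("indel %s: spliced-in check indeterminate", mut.key())
        return None
    p0 = mut.pos - 1
    covering = 0
    with_alt = 0
    lo = min(jx.intron_start - 1, mut.pos) - 1
    hi = max(jx.intron_end + 1, mut.pos)
    for read in alignments.fetch(jx.chrom, max(0, lo - 1), hi):
        if not _read_usable(read, min_mapq):
            continue
        if (jx.intron_start, jx.intron_end) not in read_junctions(read):
            continue
        base = _base_at(read, p0)
        if base is None:
            continue
        covering += 1
        if base.upper() == mut.alt_allele.upper():
            with_alt += 1
    if covering == 0:
        # mutation retained but no junction read reaches it: no support
        return 0.0
    return with_alt / covering


def _base_at(read, p0: int) -> Optional[str]:
    """Read base aligned to 0-based reference position p0, or None."""
    if read.query_sequence is None:
        return None
    qpos = read.reference_start
    q = 0
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # aligned
            if qpos <= p0 < qpos + length:
                return read.query_sequence[q + (p0 - qpos)]
            qpos += length
            q += length
        elif op in (2, _OP_N):  # D, N consume reference only
            if qpos <= p0 < qpos + length:
                return None
            qpos += length
        elif op in (1, 4):  # I, S consume query only
            q += length
    return None
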