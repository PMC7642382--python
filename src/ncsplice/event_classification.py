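"""Classification of mutation-induced splicing consequences.

Each surviving candidate junction is placed in a seven-way taxonomy:
new exon creation (subdivided first/middle/last by location), exon
extension, exon shrinkage, exon splitting, gene fusion, new transcript,
and complex (a combination of elementary signatures).  For new exons the
mutation-created primary splice site (PSS) recruits an activated mate
site (AMS) elsewhere in the same intron; PSS and AMS bound the new exon.
Frame impact is called for events intersecting an annotated CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .junction_discovery import (
    SpliceJunction,
    boundary_distance,
    fetch_sequence,
    reverse_complement,
)

log = logging.getLogger(__name__)

CATEGORIES = (
    "new_exon_first",
    "new_exon_middle",
    "new_exon_last",
    "exon_extension",
    "exon_shrinkage",
    "exon_splitting",
    "fusion",
    "new_transcript",
    "complex",
)

#: Plausible size range for a mutation-induced new exon (bp); matches the
#: exon sizes the simulator draws from.
NEW_EXON_SIZE_RANGE = (15, 600)

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SpliceEvent:
    """Classified consequence of one splice-site-creating mutation."""

    category: str
    pss: tuple  # (position, site_type)
    ams: Optional[tuple] = None  # (position, site_type)
    new_exon: Optional[tuple] = None  # (start, end) genomic interval
    frameshift: Optional[bool] = None
    premature_stop: Optional[bool] = None
    affected_gene_ids: list = field(default_factory=list)
    host_transcript_id: Optional[str] = None
    host_intron: Optional[tuple] = None
    flags: list = field(default_factory=list)
    candidate: Optional[object] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _position_context(pos: int, transcript) -> str:
    """'exon', 'intron' or 'outside' relative to one transcript."""
    if pos < transcript.start or pos > transcript.end:
        return "outside"
    for s, e in transcript.exons:
        if s <= pos <= e:
            return "exon"
    return "intron"


def _enclosing_intron(pos: int, transcript) -> Optional[tuple]:
    for s, e in transcript.introns():
        if s <= pos <= e:
            return (s, e)
    return None


def _host_transcript(junction: SpliceJunction, annotation):
    """Longest annotated transcript overlapping the junction, if any."""
    overlapping = annotation.transcripts_overlapping(
        junction.chrom, junction.intron_start - 1, junction.intron_end + 1
    )
    if not overlapping:
        return None
    return max(overlapping, key=lambda t: (t.length(), t.transcript_id))


def _boundary_kind(pos: int, transcript, canonical_boundaries) -> str:
    """'canonical', 'intron', 'exon' or 'outside' for one junction boundary."""
    if pos in canonical_boundaries:
        return "canonical"
    return _position_context(pos, transcript)


def classify_event(
    candidate, co_junctions, annotation, config=None, genome=None
) -> SpliceEvent:
    """Place a filtered candidate in the seven-way taxonomy.

    ``co_junctions`` is the junction tally around the candidate (used to
    resolve the partner junction of a new exon).  The decision tree:
    one canonical boundary + one boundary inside the intron -> extension;
    inside the exon -> shrinkage; both boundaries inside one intron with
    a partner junction completing an internal interval -> new exon
    (first/middle/last by position relative to the coding region); both
    boundaries inside one exon -> splitting; boundaries in two genes ->
    fusion; no annotation overlap -> new transcript; two or more
    elementary signatures -> complex.
    """
    jx = candidate.junction

    genes_start = {
        t.gene_id for t in annotation.transcripts_at(jx.chrom, jx.intron_start - 1)
    }
    genes_end = {
        t.gene_id for t in annotation.transcripts_at(jx.chrom, jx.intron_end + 1)
    }
    if genes_start and genes_end and not (genes_start & genes_end):
        return SpliceEvent(
            category="fusion",
            pss=_pss(candidate),
            affected_gene_ids=sorted(genes_start | genes_end),
            candidate=candidate,
        )

    host = _host_transcript(jx, annotation)
    if host is None:
        return SpliceEvent(
            category="new_transcript",
            pss=_pss(candidate),
            candidate=candidate,
        )

    canon = {b for s, e in host.introns() for b in (s, e)}
    kind_start = _boundary_kind(jx.intron_start, host, canon)
    kind_end = _boundary_kind(jx.intron_end, host, canon)
    kinds = (kind_start, kind_end)
    signatures = []

    if "canonical" in kinds and ("intron" in kinds or "exon" in kinds or "outside" in kinds):
        novel_kind = kind_end if kind_start == "canonical" else kind_start
        if novel_kind == "intron":
            # the junction of a newly created exon also has one canonical
            # boundary; only a partner junction in the same intron
            # distinguishes new-exon creation from a plain extension
            mate = locate_activated_mate(jx, co_junctions, annotation, config, host=host)
            if mate is not None:
                ams_pos, new_exon = mate
                ev = SpliceEvent(
                    category=_new_exon_position(new_exon, host),
                    pss=_pss(candidate),
                    ams=(ams_pos, _mate_site_type(candidate)),
                    new_exon=new_exon,
                    affected_gene_ids=[host.gene_id],
                    host_transcript_id=host.transcript_id,
                    host_intron=_enclosing_intron(
                        jx.intron_start, host
                    )
                    or _enclosing_intron(jx.intron_end, host),
                    candidate=candidate,
                )
                _maybe_frame(ev, host, genome)
                return ev
            signatures.append("exon_extension")
        elif novel_kind == "exon":
            signatures.append("exon_shrinkage")
        else:
            signatures.append("exon_extension")  # extension past the terminal exon
    elif kinds == ("intron", "intron"):
        intron_a = _enclosing_intron(jx.intron_start, host)
        intron_b = _enclosing_intron(jx.intron_end, host)
        if intron_a is not None and intron_a == intron_b:
            # fully internal junction: a latent site pair inside one intron
            ev = SpliceEvent(
                category="exon_extension",
                pss=_pss(candidate),
                affected_gene_ids=[host.gene_id],
                host_transcript_id=host.transcript_id,
                host_intron=intron_a,
                flags=["no_canonical_anchor:review"],
                candidate=candidate,
            )
            return ev
        signatures.append("exon_extension")
        signatures.append("exon_extension")  # boundaries in two introns
    elif kinds == ("exon", "exon"):
        same_exon = any(
            s <= jx.intron_start and jx.intron_end <= e for s, e in host.exons
        )
        if same_exon:
            signatures.append("exon_splitting")
        else:
            signatures.extend(["exon_shrinkage", "exon_shrinkage"])
    elif kinds == ("canonical", "canonical"):
        # both boundaries canonical but the pair is not an annotated intron:
        # an exon-skipping-like rearrangement; treat as complex
        signatures.extend(["exon_extension", "exon_shrinkage"])
    elif "outside" in kinds:
        signatures.append("new_transcript")
        other = kind_end if kind_start == "outside" else kind_start
        if other in ("intron", "exon"):
            signatures.append("exon_extension")
    else:  # mixed intron/exon boundaries without a canonical anchor
        signatures.extend(["exon_extension", "exon_shrinkage"])

    if len(set(signatures)) >= 2 or len(signatures) >= 2:
        category = "complex"
    else:
        category = signatures[0]
    ev = SpliceEvent(
        category=category,
        pss=_pss(candidate),
        affected_gene_ids=[host.gene_id],
        host_transcript_id=host.transcript_id,
        host_intron=_enclosing_intron(jx.intron_start, host)
        or _enclosing_intron(jx.intron_end, host),
        candidate=candidate,
    )
    return ev


def _pss(candidate) -> tuple:
    """The novel junction boundary nearest the mutation, with its site role."""
    jx = candidate.junction
    pos = candidate.mutation.pos
    d_start = min(abs(pos - jx.intron_start), abs(pos - (jx.intron_start - 1)))
    d_end = min(abs(pos - jx.intron_end), abs(pos - (jx.intron_end + 1)))
    if d_start <= d_end:
        boundary = jx.intron_start
        site_type = "donor" if jx.strand != "-" else "acceptor"
    else:
        boundary = jx.intron_end
        site_type = "acceptor" if jx.strand != "-" else "donor"
    return (boundary, site_type)


def _mate_site_type(candidate) -> str:
    pss_type = _pss(candidate)[1]
    return "acceptor" if pss_type == "donor" else "donor"


def _new_exon_position(new_exon: tuple, host) -> str:
    """first / middle / last relative to the host transcript's coding span."""
    lo, hi = new_exon
    if host.cds_start is not None and hi < host.cds_start:
        return "new_exon_first"
    if host.cds_end is not None and lo > host.cds_end:
        return "new_exon_last"
    return "new_exon_middle"


def locate_activated_mate(
    pss_junction: SpliceJunction, co_junctions, annotation, config=None, host=None
) -> Optional[tuple]:
    """Find the partner junction bounding a new exon inside one intron.

    The primary junction has one boundary at a canonical exon edge (or,
    for fully internal new exons, at the intron side nearer the mutated
    exon) and its inner boundary inside an annotated intron.  The partner
    must be a distinct junction with its own boundary in the same intron,
    at least ``min_supporting_reads`` reads, and must enclose a plausible
    new-exon interval with the primary.  Ties between qualifying partners
    go to the higher supporting-read count, then to the junction whose
    enclosed exon is shorter (a proxy for splice-score rank when no model
    is supplied).
    Returns (ams position, (new_exon_start, new_exon_end)) or None.
    """
    min_support = config.min_supporting_reads if config is not None else 1
    if host is None:
        host = _host_transcript(pss_junction, annotation)
    if host is None:
        return None
    intron = _enclosing_intron(pss_junction.intron_start, host) or _enclosing_intron(
        pss_junction.intron_end, host
    )
    if intron is None:
        return None
    lo, hi = intron
    best = None
    for (chrom, s, e), count in co_junctions.items():
        if chrom != pss_junction.chrom or count < min_support:
            continue
        if (s, e) == (pss_junction.intron_start, pss_junction.intron_end):
            continue
        # partner on the 3' genomic side: its start boundary closes the exon
        if e == hi and lo <= s - 1 and pss_junction.intron_end + 1 <= s - 1:
            exon_iv = (pss_junction.intron_end + 1, s - 1)
            ams = s
        # partner on the 5' genomic side
        elif s == lo and e + 1 <= pss_junction.intron_start - 1:
            exon_iv = (e + 1, pss_junction.intron_start - 1)
            ams = e
        else:
            continue
        length = exon_iv[1] - exon_iv[0] + 1
        if not NEW_EXON_SIZE_RANGE[0] <= length <= NEW_EXON_SIZE_RANGE[1]:
            continue
        rank = (count, -length)
        if best is None or rank > best[0]:
            best = (rank, ams, exon_iv)
    if best is None:
        return None
    return best[1], best[2]


def _maybe_frame(event: SpliceEvent, host, genome) -> None:
    if event.new_exon is None:
        return
    if host.cds_start is None or host.cds_end is None:
        log.warning(
            "no CDS annotation for %s; frame impact undefined", host.transcript_id
        )
        return
    lo, hi = event.new_exon
    if hi < host.cds_start or lo > host.cds_end:
        return
    length = hi - lo + 1
    fs, stop = frame_impact(length, event, host, genome)
    event.frameshift = fs
    event.premature_stop = stop


def frame_impact(
    new_exon_length: int, event: SpliceEvent, cds, genome=None
) -> tuple:
    """Frameshift and premature-stop calls for an inserted exon.

    frameshift is true when the inserted coding length is not a multiple
    of three.  premature_stop is true when the inserted sequence, read in
    the frame of the interrupted CDS, contains a stop codon; it requires
    the genome and the host transcript (``cds``) and is False when either
    is unavailable.
    """
    if new_exon_length <= 0:
        raise ValueError("new_exon_length must be positive")
    frameshift = (new_exon_length % 3) != 0
    premature_stop = False
    if genome is not None and event.new_exon is not None and cds is not None:
        premature_stop = _has_inframe_stop(event.new_exon, cds, genome)
    return frameshift, premature_stop


def _has_inframe_stop(new_exon: tuple, host, genome) -> bool:
    """Scan the inserted exon for a stop codon in CDS frame."""
    lo, hi = new_exon
    seq = fetch_sequence(genome, host.chrom, lo, hi).upper()
    if host.strand == "-":
        seq = reverse_complement(seq)
    phase = _coding_phase_before(new_exon, host)
    if phase is None:
        phase = 0
    # bases needed to finish the interrupted codon
    offset = (3 - phase) % 3
    for i in range(offset, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOP_CODONS:
            return True
    return False


def _coding_phase_before(new_exon: tuple, host) -> Optional[int]:
    """Number of coding bases mod 3 upstream of the insertion point."""
    if host.cds_start is None or host.cds_end is None:
        return None
    lo, hi = new_exon
    coding = 0
    for s, e in host.exons:
        cs, ce = max(s, host.cds_start), min(e, host.cds_end)
        if cs > ce:
            continue
        if host.strand != "-":
            if ce < lo:
                coding += ce - cs + 1
            elif cs < lo <= ce:
                coding += lo - cs
        else:
            if cs > hi:
                coding += ce - cs + 1
            elif cs <= hi < ce:
                coding += ce - hi
    return coding % 3
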