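"""Splice-site strength scoring.

Donor sites are scored over a 9-mer (3 exonic + 6 intronic bases) and
acceptor sites over a 23-mer (20 intronic + 3 exonic bases), both read
5'->3' on the transcript.  The built-in model is a position-specific
log2-odds table (uniform background, pseudocount 1) trained on the
canonical junctions of the supplied annotation; scores are additive over
positions, so a single-base mutation shifts the score by exactly the
log-odds difference at that position.  An adapter for an external
maximum-entropy scorer can be plugged in for parity runs.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .junction_discovery import fetch_sequence, reverse_complement

log = logging.getLogger(__name__)

DONOR_LENGTH = 9
ACCEPTOR_LENGTH = 23
DONOR_EXONIC = 3  # bases upstream of the intron in the 9-mer
ACCEPTOR_EXONIC = 3  # bases downstream of the intron in the 23-mer
MIN_TRAINING_SITES = 50

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class SequenceError(ValueError):
    """Sequence of wrong length or with non-ACGT characters."""


def _encode(seq: str, expected_length: int) -> np.ndarray:
    seq = seq.upper()
    if len(seq) != expected_length:
        raise SequenceError(
            f"expected a {expected_length}-mer, got {len(seq)} bases"
        )
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as exc:
        raise SequenceError(f"non-ACGT base {exc} in {seq!r}") from exc


@dataclass
class SpliceSiteModel:
    """Position-specific log2-odds model for donor or acceptor sites."""

    site_type: str  # "donor" | "acceptor"
    log_odds: np.ndarray  # (expected_length, 4)
    n_training: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.log_odds.shape != (self.expected_length, 4):
            raise ValueError(
                f"log-odds table shape {self.log_odds.shape} does not match "
                f"{self.site_type} length {self.expected_length}"
            )

    @property
    def expected_length(self) -> int:
        return DONOR_LENGTH if self.site_type == "donor" else ACCEPTOR_LENGTH

    def score(self, seq: str) -> float:
        idx = _encode(seq, self.expected_length)
        return float(self.log_odds[np.arange(len(idx)), idx].sum())


@dataclass
class ScoredSitePair:
    """Reference vs mutant score at one splice site."""

    ref_seq: str
    mut_seq: str
    ref_score: float
    mut_score: float

    #: score changes below this magnitude are conventionally displayed as
    #: "little to no change"
    NO_CHANGE_BAND = 0.5

    @property
    def delta(self) -> float:
        return self.mut_score - self.ref_score


def site_window(
    boundary: int, site_type: str, strand: str
):
    """Genomic window (1-based inclusive) of the scoring k-mer.

    ``boundary`` is the first intronic base for a donor and the last
    intronic base for an acceptor, in transcript orientation.
    """
    if site_type == "donor":
        if strand == "+":
            return boundary - DONOR_EXONIC, boundary + (DONOR_LENGTH - DONOR_EXONIC) - 1
        return boundary - (DONOR_LENGTH - DONOR_EXONIC) + 1, boundary + DONOR_EXONIC
    if site_type == "acceptor":
        intronic = ACCEPTOR_LENGTH - ACCEPTOR_EXONIC
        if strand == "+":
            return boundary - intronic + 1, boundary + ACCEPTOR_EXONIC
        return boundary - ACCEPTOR_EXONIC, boundary + intronic - 1
    raise ValueError(f"unknown site_type {site_type!r}")


def extract_site_sequence(
    genome, chrom: str, boundary: int, site_type: str, strand: str
) -> str:
    """Extract the donor 9-mer or acceptor 23-mer around an intron boundary.

    Minus-strand windows are reverse-complemented so the result reads
    5'->3' on the transcript (donor: 3 exonic then 6 intronic bases;
    acceptor: 20 intronic then 3 exonic bases).
    """
    lo, hi = site_window(boundary, site_type, strand)
    seq = fetch_sequence(genome, chrom, lo, hi).upper()
    return reverse_complement(seq) if strand == "-" else seq


def mutate_site_sequence(
    seq: str, chrom: str, boundary: int, site_type: str, strand: str, mutation
) -> str:
    """Apply a substitution to an extracted site k-mer.

    Returns ``seq`` unchanged when the mutation falls outside the window
    or is an indel.
    """
    if mutation.chrom != chrom or mutation.is_indel:
        return seq
    lo, hi = site_window(boundary, site_type, strand)
    if not lo <= mutation.pos <= hi:
        return seq
    if strand == "+":
        offset = mutation.pos - lo
        alt = mutation.alt_allele.upper()
    else:
        offset = hi - mutation.pos
        alt = reverse_complement(mutation.alt_allele.upper())
    return seq[:offset] + alt + seq[offset + 1 :]


def train_site_model(annotation, genome, site_type: str) -> SpliceSiteModel:
    """Train the position-weight log-odds model on canonical junctions.

    Counts per position get a pseudocount of 1; the score of a sequence is
    the sum over positions of log2(frequency / 0.25).
    """
    length = DONOR_LENGTH if site_type == "donor" else ACCEPTOR_LENGTH
    counts = np.ones((length, 4), dtype=float)  # pseudocount
    n = 0
    for (chrom, s, e) in sorted(annotation.canonical_junctions):
        strand = annotation.junction_strands.get((chrom, s, e), "+")
        if site_type == "donor":
            boundary = s if strand == "+" else e
        else:
            boundary = e if strand == "+" else s
        try:
            seq = extract_site_sequence(genome, chrom, boundary, site_type, strand)
            idx = _encode(seq, length)
        except (ValueError, KeyError):
            continue
        counts[np.arange(length), idx] += 1
        n += 1
    if n < MIN_TRAINING_SITES:
        raise ValueError(
            f"only {n} canonical {site_type} sites available; "
            f">= {MIN_TRAINING_SITES} required for training"
        )
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return SpliceSiteModel(
        site_type=site_type,
        log_odds=np.log2(freqs / 0.25),
        n_training=n,
        source="trained on supplied annotation",
    )


def score_site_pair(model: SpliceSiteModel, ref_seq: str, mut_seq: str) -> ScoredSitePair:
    """Score a reference/mutant sequence pair with the same model."""
    return ScoredSitePair(
        ref_seq=ref_seq,
        mut_seq=mut_seq,
        ref_score=model.score(ref_seq),
        mut_score=model.score(mut_seq),
    )


@dataclass
class ExternalScorer:
    """Adapter for an external splice-site scorer.

    The command is invoked once per batch with a text file of one
    sequence per line (the tool's native 9-mer/23-mer convention) and
    must print one score per line, optionally preceded by the sequence
    and a tab.  Scores from the adapter replace the built-in model's in
    parity runs.
    """

    command: list  # argv prefix; the input file path is appended
    site_type: str = "donor"

    def score_batch(self, sequences) -> list:
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "sites.txt"
            infile.write_text("".join(s + "\n" for s in sequences))
            proc = subprocess.run(
                [*self.command, str(infile)],
                capture_output=True,
                text=True,
                check=True,
            )
        scores = []
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            scores.append(float(line.split("\t")[-1]))
        if len(scores) != len(sequences):
            raise RuntimeError(
                f"external scorer returned {len(scores)} scores "
                f"for {len(sequences)} sequences"
            )
        return scores

    def score(self, seq: str) -> float:
        return self.score_batch([seq])[0]
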