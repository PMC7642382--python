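"""The filter cascade applied to junction candidates.

Three successive stages follow discovery: removal of known junctions and
candidates in polymorphic regions (e.g. HLA); a coverage filter, either a
heuristic JAF cut or a one-sided binomial proportion test with
Benjamini-Hochberg correction; and a case/control comparison requiring
the case sample's junction support to rank in the top ``k`` fraction
against mutation-free controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .junction_discovery import extract_junctions

log = logging.getLogger(__name__)


@dataclass
class ControlPanel:
    """Per-junction supporting-read counts across control samples."""

    sample_ids: list
    counts: dict  # junction key -> list[int], one per control (zero-filled)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for key, row in self.counts.items():
            if len(row) != n:
                raise ValueError(
                    f"count list for {key} has length {len(row)}, "
                    f"expected {n} controls"
                )
            if any(c < 0 for c in row):
                raise ValueError("control counts must be non-negative")

    @property
    def n_controls(self) -> int:
        return len(self.sample_ids)

    def counts_for(self, key) -> list:
        return self.counts.get(key, [0] * self.n_controls)

    @classmethod
    def from_alignments(
        cls, control_paths: Sequence, junctions: Iterable, min_mapq: int, pad: int = 5
    ) -> "ControlPanel":
        """Tally each junction of interest in each control BAM/CRAM."""
        import pysam

        keys = list(junctions)
        counts = {k: [0] * len(control_paths) for k in keys}
        for i, path in enumerate(control_paths):
            with pysam.AlignmentFile(str(path)) as bam:
                for key in keys:
                    chrom, s, e = key
                    if chrom not in bam.references:
                        continue
                    tally = extract_junctions(bam, chrom, max(1, s - pad), e + pad, min_mapq)
                    counts[key][i] = tally.get(key, 0)
        return cls(sample_ids=[str(p) for p in control_paths], counts=counts)

    @classmethod
    def from_tsv(cls, path) -> "ControlPanel":
        """Read a precomputed junction-count table.

        Columns: chrom, intron_start, intron_end, then one column per
        control sample.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        sample_ids = list(df.columns[3:])
        counts = {}
        for _, row in df.iterrows():
            key = (str(row.iloc[0]), int(row.iloc[1]), int(row.iloc[2]))
            counts[key] = [int(row[c]) for c in sample_ids]
        return cls(sample_ids=sample_ids, counts=counts)


def filter_known_and_polymorphic(
    candidates: list, annotation, blacklist: Optional[dict] = None
) -> list:
    """Drop known junctions and candidates in polymorphic regions.

    A candidate is removed when its junction matches a canonical junction
    on both boundaries, or when the junction overlaps a blacklist
    interval.  Junctions sharing only one boundary with an annotated
    intron are retained — exon extension and shrinkage events necessarily
    share one boundary with the canonical intron.
    """
    out = []
    for cand in candidates:
        jx = cand.junction
        if annotation.is_canonical(jx.chrom, jx.intron_start, jx.intron_end):
            cand.verdict["known_junction"] = "fail"
            continue
        if blacklist:
            tree = blacklist.get(jx.chrom)
            # closed interval -> half-open query
            if tree is not None and tree.overlap(jx.intron_start, jx.intron_end + 1):
                cand.verdict["polymorphic_region"] = "fail"
                continue
        out.append(cand)
    return out


def jaf_filter(candidates: list, min_jaf: float) -> list:
    """Heuristic coverage filter: drop candidates with JAF strictly below the cut."""
    out = []
    for cand in candidates:
        if cand.junction.jaf < min_jaf:
            cand.verdict["jaf"] = "fail"
        else:
            out.append(cand)
    return out


def proportion_test_filter(
    candidates: list, null_jaf: float, alpha: float
) -> list:
    """Binomial proportion test per candidate with BH correction.

    The null is that any read at the site supports the junction with
    Bernoulli probability ``null_jaf``; the one-sided upper-tail p-value
    is P(X >= n_supporting | Binomial(depth, null_jaf)).  Candidates with
    BH-adjusted q <= alpha are retained; p and q are recorded on every
    candidate.
    """
    if not 0.0 < null_jaf < 1.0:
        raise ValueError("null_jaf must lie in (0,1)")
    if not candidates:
        return []
    pvals = []
    for cand in candidates:
        jx = cand.junction
        if jx.depth_at_site <= 0:
            raise ValueError(
                f"candidate {cand.key} has no depth; run annotate_candidate first"
            )
        # P(X >= n) = sf(n - 1)
        p = float(sps.binom.sf(jx.n_supporting_reads - 1, jx.depth_at_site, null_jaf))
        cand.p_value = p
        pvals.append(p)
    qvals = bh_fdr(pvals)
    out = []
    for cand, q in zip(candidates, qvals):
        cand.q_value = q
        if q <= alpha:
            out.append(cand)
        else:
            cand.verdict["proportion_test"] = "fail"
    return out


def bh_fdr(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    q = multipletests(p, method="fdr_bh")[1]
    return [float(x) for x in q]


def case_control_filter(candidate, controls: ControlPanel, k: float) -> bool:
    """True iff the case ranks in the top ``k`` fraction against controls.

    The fraction of control samples whose supporting-read count is >= the
    case count must be strictly below ``k``; ties count against the case.
    """
    if controls.n_controls == 0:
        raise ValueError("control panel is empty; the pipeline needs >= 1 control")
    case = candidate.junction.n_supporting_reads
    row = controls.counts_for(candidate.junction.key)
    frac = sum(1 for c in row if c >= case) / len(row)
    passed = frac < k
    candidate.control_counts = list(row)
    candidate.verdict["case_control"] = "pass" if passed else "fail"
    return passed


def apply_case_control(candidates: list, controls: ControlPanel, k: float) -> list:
    return [c for c in candidates if case_control_filter(c, controls, k)]
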