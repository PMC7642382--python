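"""Pipeline orchestration: discovery -> filters -> scoring -> classification.

The controller splits the mutation list into batches (processed serially
or by a local process pool), runs junction discovery around each
mutation, applies the filter cascade, scores the primary splice site,
classifies the event, and applies the automated review checks that stand
in for the manual inspection step (support >= M; spliced-in mutations
must reach the minimum mutant-read fraction among junction reads).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import candidate_filters as cf
from . import event_classification as ec
from . import junction_discovery as jd
from . import splice_scoring as ss
from .io_formats import (
    AnnotationIndex,
    PipelineConfig,
    SomaticMutation,
    build_annotation_index,
    read_bed_blacklist,
    read_maf_noncoding,
)

log = logging.getLogger(__name__)

#: extra bases fetched around the mutation window so that reads spanning
#: into the window are seen (max spliced read span is bounded by read
#: length plus one intron; junction keys themselves are exact)
FETCH_PAD = 500

STAGES = (
    "input",
    "discovery",
    "known_polymorphic",
    "coverage",
    "case_control",
    "review",
)


@dataclass
class PipelineResult:
    """Candidates per stage plus the final classified events."""

    stage_counts: dict
    events: list
    candidates_by_stage: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def check_monotone(self) -> None:
        counts = [self.stage_counts[s] for s in STAGES[1:] if s in self.stage_counts]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"stage counts increased: {self.stage_counts}")


def chunk_mutations(mutations: Sequence, batch_size: int) -> list:
    """Order-preserving partition into batches of ``batch_size``."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return [
        list(mutations[i : i + batch_size])
        for i in range(0, len(mutations), batch_size)
    ]


def auto_review(event, config: PipelineConfig):
    """Automated proxy for the manual review of a classified event.

    Fails when junction support is below the minimum, or when the
    mutation is spliced in but too few junction reads carry it.
    Returns ("pass", None) or ("fail", reason).
    """
    cand = event.candidate
    if cand is None:
        return ("fail", "no_candidate_evidence")
    if cand.junction.n_supporting_reads < config.min_supporting_reads:
        return ("fail", "support<M")
    if cand.spliced_in:
        frac = cand.spliced_in_fraction or 0.0
        if frac < config.min_spliced_in_fraction:
            return ("fail", f"spliced_in<{config.min_spliced_in_fraction:g}")
    return ("pass", None)


def discover_candidates(
    mutations: Sequence[SomaticMutation],
    alignments,
    annotation: AnnotationIndex,
    config: PipelineConfig,
    genome=None,
):
    """Junction discovery around each mutation.

    Returns (candidates, co_junction tallies keyed by mutation).
    """
    candidates = []
    tallies = {}
    for mut in mutations:
        lo = max(1, mut.pos - config.window - FETCH_PAD)
        hi = mut.pos + config.window + FETCH_PAD
        try:
            tally = jd.extract_junctions(
                alignments, mut.chrom, lo, hi, config.min_mapq
            )
        except ValueError:
            log.warning("chromosome %s not in alignments; mutation skipped", mut.chrom)
            continue
        tallies[mut.key()] = tally
        for cand in jd.find_candidates(mut, tally, annotation, config):
            jd.annotate_candidate(cand, alignments, genome, config.min_mapq)
            candidates.append(cand)
    return candidates, tallies


def run_pipeline(
    config: PipelineConfig,
    mutations: Sequence[SomaticMutation],
    case_alignments,
    control_paths: Sequence,
    annotation: AnnotationIndex,
    genome=None,
    blacklist: Optional[dict] = None,
    models: Optional[dict] = None,
) -> PipelineResult:
    """Run the full cascade on loaded inputs.

    ``case_alignments`` is an open (indexed) alignment file for the case
    sample; ``control_paths`` are alignment files for mutation-free
    controls (>= 1 required).  ``models`` optionally carries pre-trained
    donor/acceptor scoring models keyed by site type.
    """
    if not control_paths:
        raise ValueError("the case/control filter requires at least one control")
    t0 = time.monotonic()
    stage_counts = {"input": len(mutations)}
    by_stage = {}

    candidates, tallies = discover_candidates(
        mutations, case_alignments, annotation, config, genome
    )
    stage_counts["discovery"] = len(candidates)
    by_stage["discovery"] = list(candidates)

    candidates = cf.filter_known_and_polymorphic(candidates, annotation, blacklist)
    stage_counts["known_polymorphic"] = len(candidates)
    by_stage["known_polymorphic"] = list(candidates)

    if config.mode == "proportion":
        candidates = cf.proportion_test_filter(
            candidates, config.null_jaf, config.alpha
        )
    else:
        candidates = cf.jaf_filter(candidates, config.min_jaf)
    stage_counts["coverage"] = len(candidates)
    by_stage["coverage"] = list(candidates)

    if candidates:
        panel = cf.ControlPanel.from_alignments(
            control_paths,
            [c.junction.key for c in candidates],
            config.min_mapq,
        )
        candidates = cf.apply_case_control(
            candidates, panel, config.control_top_fraction
        )
    stage_counts["case_control"] = len(candidates)
    by_stage["case_control"] = list(candidates)

    if models is None:
        models = train_models(annotation, genome)

    events = []
    for cand in candidates:
        ev = ec.classify_event(
            cand,
            tallies.get(cand.mutation.key(), {}),
            annotation,
            config=config,
            genome=genome,
        )
        if genome is not None and models:
            _score_event(ev, cand, models, genome)
        status, reason = auto_review(ev, config)
        cand.verdict["review"] = status if status == "pass" else f"fail:{reason}"
        if status == "pass":
            events.append(ev)
    stage_counts["review"] = len(events)

    result = PipelineResult(
        stage_counts=stage_counts,
        events=events,
        candidates_by_stage=by_stage,
        provenance={
            "config": {
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in vars(config).items()
            },
            "n_controls": len(control_paths),
            "elapsed_s": round(time.monotonic() - t0, 3),
        },
    )
    result.check_monotone()
    return result


def train_models(annotation: AnnotationIndex, genome) -> dict:
    """Train donor/acceptor scoring models, or return {} when infeasible."""
    if genome is None:
        return {}
    models = {}
    for site_type in ("donor", "acceptor"):
        try:
            models[site_type] = ss.train_site_model(annotation, genome, site_type)
        except ValueError as exc:
            log.warning("skipping %s model: %s", site_type, exc)
    return models


def _score_event(event, cand, models, genome) -> None:
    """Attach reference/mutant splice scores for the primary splice site."""
    boundary, site_type = event.pss
    model = models.get(site_type)
    if model is None:
        return
    jx = cand.junction
    strand = jx.strand if jx.strand in ("+", "-") else "+"
    try:
        ref_seq = ss.extract_site_sequence(
            genome, jx.chrom, boundary, site_type, strand
        )
    except ValueError:
        return
    mut_seq = ss.mutate_site_sequence(
        ref_seq, jx.chrom, boundary, site_type, strand, cand.mutation
    )
    pair = ss.score_site_pair(model, ref_seq, mut_seq)
    cand.verdict["splice_score"] = {
        "ref": round(pair.ref_score, 4),
        "mut": round(pair.mut_score, 4),
        "delta": round(pair.delta, 4),
    }
    event.flags.append(f"score_delta={pair.delta:+.2f}")


# ---------------------------------------------------------------------------
# batched / parallel driver over files


def _process_batch(args):
    (batch, bam_path, control_paths, gtf_path, fasta_path, bed_path, config) = args
    import pyfaidx
    import pysam

    annotation = build_annotation_index(gtf_path)
    genome = pyfaidx.Fasta(fasta_path) if fasta_path else None
    blacklist = read_bed_blacklist(bed_path) if bed_path else None
    with pysam.AlignmentFile(bam_path) as bam:
        result = run_pipeline(
            config, batch, bam, control_paths, annotation, genome, blacklist
        )
    return result


def run_pipeline_files(
    config: PipelineConfig,
    maf_path,
    bam_path,
    control_paths: Sequence,
    gtf_path,
    fasta_path=None,
    bed_path=None,
    threads: int = 1,
) -> PipelineResult:
    """File-based entry point with optional local parallelism over batches.

    Serial and parallel execution produce identical results; batches are
    the unit of distribution, mirroring cluster-style chunked processing
    with a local process pool.
    """
    mutations = read_maf_noncoding(maf_path, config.excluded_classes)
    batches = chunk_mutations(mutations, config.batch_size)
    jobs = [
        (
            batch,
            str(bam_path),
            [str(p) for p in control_paths],
            str(gtf_path),
            str(fasta_path) if fasta_path else None,
            str(bed_path) if bed_path else None,
            config,
        )
        for batch in batches
    ]
    if threads > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_process_batch, jobs))
    else:
        results = [_process_batch(j) for j in jobs]
    return merge_results(results, config)


def merge_results(results: Sequence[PipelineResult], config) -> PipelineResult:
    if not results:
        return PipelineResult(stage_counts={s: 0 for s in STAGES}, events=[])
    counts = {s: sum(r.stage_counts.get(s, 0) for r in results) for s in STAGES}
    events = [e for r in results for e in r.events]
    events.sort(
        key=lambda e: (
            e.candidate.junction.key if e.candidate else ("", 0, 0),
            e.category,
        )
    )
    merged = PipelineResult(
        stage_counts=counts,
        events=events,
        provenance={"n_batches": len(results), **results[0].provenance},
    )
    merged.check_monotone()
    return merged


# ---------------------------------------------------------------------------
# result emission


RESULT_COLUMNS = [
    "sample",
    "genes",
    "mutation",
    "junction",
    "category",
    "pss",
    "ams",
    "new_exon_length",
    "frameshift",
    "premature_stop",
    "supporting_reads",
    "depth",
    "jaf",
    "spliced_in_fraction",
    "ref_score",
    "mut_score",
    "delta_score",
]


def write_events_tsv(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for ev in result.events:
            cand = ev.candidate
            jx = cand.junction
            score = cand.verdict.get("splice_score", {})
            new_exon_len = (
                ev.new_exon[1] - ev.new_exon[0] + 1 if ev.new_exon else ""
            )
            row = [
                cand.mutation.sample_id,
                ",".join(ev.affected_gene_ids),
                cand.mutation.key(),
                f"{jx.chrom}:{jx.intron_start}-{jx.intron_end}",
                ev.category,
                f"{ev.pss[0]}:{ev.pss[1]}",
                f"{ev.ams[0]}:{ev.ams[1]}" if ev.ams else "",
                new_exon_len,
                "" if ev.frameshift is None else str(ev.frameshift),
                "" if ev.premature_stop is None else str(ev.premature_stop),
                jx.n_supporting_reads,
                jx.depth_at_site,
                f"{jx.jaf:.4f}",
                ""
                if cand.spliced_in_fraction is None
                else f"{cand.spliced_in_fraction:.4f}",
                score.get("ref", ""),
                score.get("mut", ""),
                score.get("delta", ""),
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_run_report(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "stage_counts": result.stage_counts,
                "n_events": len(result.events),
                "provenance": result.provenance,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
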