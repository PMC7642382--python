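"""Sensitivity benchmark: simulated loci through the full pipeline.

Builds a synthetic locus, injects exon extensions, simulates case read
mixtures (and reference-only controls) focused on a window around each
novel junction, writes the standard file formats (FASTA, GTF, MAF, BAM),
and runs the discovery + filter cascade per case sample.  Sensitivity is
the fraction of injected junctions recovered with exact boundaries.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import simulator as sim
from .io_formats import PipelineConfig, build_annotation_index, write_maf
from .pipeline import run_pipeline

log = logging.getLogger(__name__)

#: genomic half-window around each novel junction over which case and
#: control reads are simulated; wide enough that depth at the junction is
#: unaffected by edge effects
READ_WINDOW = 600


@dataclass
class BenchmarkResult:
    sensitivity: float
    n_truth: int
    n_called: int
    fraction: float
    coverage: float
    seed: int
    per_event: list = field(default_factory=list)


def run_sensitivity_benchmark(
    coverage: float = 200.0,
    fraction: float = 0.25,
    n_events: int = 20,
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
    n_controls: int = 2,
    locus_kwargs: Optional[dict] = None,
    workdir=None,
) -> BenchmarkResult:
    """Measure pipeline sensitivity on one simulated locus.

    Each injected exon extension is treated as its own case sample (one
    mutation, one read mixture); controls carry reference-origin reads
    only.  Files are written to ``workdir`` (a temporary directory by
    default) and read back through the standard format paths, so the
    measurement exercises the full I/O + discovery + filter stack.
    """
    import pyfaidx
    import pysam

    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    locus = sim.simulate_gene_locus(seed=int(rng.integers(2**31)), **(locus_kwargs or {}))
    n_exons = len(locus.gene.exons)
    if n_events > n_exons - 2:
        raise ValueError("more events requested than internal exons available")
    exon_indices = rng.choice(np.arange(1, n_exons - 1), size=n_events, replace=False)
    truth = []
    for i, idx in enumerate(sorted(int(x) for x in exon_indices)):
        end = "3p" if i % 2 == 0 else "5p"
        shift = int(rng.integers(5, 51))
        truth.append(sim.inject_exon_extension(locus, idx, shift, end))

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        fasta = base / "genome.fa"
        gtf = base / "gene.gtf"
        sim.write_fasta(locus, fasta)
        sim.write_gtf([locus.gene], gtf)
        sim.write_truth_table(truth, base / "truth.tsv")
        write_maf([t.mutation for t in truth], base / "mutations.maf")
        genome = pyfaidx.Fasta(str(fasta))
        annotation = build_annotation_index(gtf)

        from .pipeline import train_models

        models = train_models(annotation, genome)

        n_called = 0
        per_event = []
        called_keys = []
        for t in truth:
            _, js, je = t.junction
            window = (js - READ_WINDOW, je + READ_WINDOW)
            case_reads = sim.simulate_read_mixture(
                locus,
                locus.gene,
                t.altered_transcript,
                fraction=fraction,
                coverage=coverage,
                seed=int(rng.integers(2**31)),
                window=window,
            )
            case_bam = sim.write_alignments(
                case_reads, locus, base / f"case_{t.mutation.sample_id}.bam"
            )
            control_paths = []
            for ci in range(n_controls):
                ctrl_reads = sim.simulate_read_mixture(
                    locus,
                    locus.gene,
                    locus.gene,
                    fraction=0.0,
                    coverage=coverage,
                    seed=int(rng.integers(2**31)),
                    window=window,
                )
                control_paths.append(
                    sim.write_alignments(
                        ctrl_reads,
                        locus,
                        base / f"ctrl{ci}_{t.mutation.sample_id}.bam",
                    )
                )
            with pysam.AlignmentFile(case_bam) as bam:
                result = run_pipeline(
                    config,
                    [t.mutation],
                    bam,
                    control_paths,
                    annotation,
                    genome,
                    models=models,
                )
            keys = {
                e.candidate.junction.key for e in result.events if e.candidate
            }
            hit = t.junction in keys
            n_called += hit
            called_keys.extend(keys)
            per_event.append(
                {
                    "sample": t.mutation.sample_id,
                    "junction": t.junction,
                    "shift_bp": t.shift_bp,
                    "recovered": bool(hit),
                    "n_events_reported": len(result.events),
                }
            )

    sensitivity = sim.evaluate_sensitivity(called_keys, truth)
    return BenchmarkResult(
        sensitivity=sensitivity,
        n_truth=len(truth),
        n_called=n_called,
        fraction=fraction,
        coverage=coverage,
        seed=seed,
        per_event=per_event,
    )


def sensitivity_curve(
    coverage: float,
    fractions: Sequence[float] = sim.MIXTURE_GRID,
    n_events: int = 20,
    seed: int = 0,
    **kwargs,
) -> list:
    """Sensitivity across the mixture-fraction grid (one locus per point)."""
    rows = []
    for i, f in enumerate(fractions):
        res = run_sensitivity_benchmark(
            coverage=coverage, fraction=f, n_events=n_events, seed=seed + i, **kwargs
        )
        rows.append(res)
    return rows
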