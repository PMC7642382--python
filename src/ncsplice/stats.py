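"""Statistical framework for splice-site discovery.

Contains the power model for required read depth (Gaussian-approximated
one-sided binomial test), the expected-artifact and Poisson-tail
calculations behind the minimum supporting-read threshold, the
long-intron bias model for new-exon creation, Tukey's expression-outlier
score, and Fisher's exact test for enrichment of hits in cancer genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .candidate_filters import bh_fdr

#: Conventional one-sided Z-scores: 5% type-I error and 80% power.
DEFAULT_Z_ALPHA = 1.645
DEFAULT_Z_BETA = 0.84

#: A new exon needs a 9-nt donor and a 23-nt acceptor motif: a joint event
#: of 32 specific nucleotides.
JOINT_MOTIF_BASES = 32
MOTIF_PROBABILITY = 4.0 ** -JOINT_MOTIF_BASES


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the required-depth power formula."""

    j0: float  # null junction allele fraction
    j1: float  # alternative junction allele fraction
    z_alpha: float = DEFAULT_Z_ALPHA
    z_beta: float = DEFAULT_Z_BETA

    def __post_init__(self) -> None:
        if not 0.0 < self.j0 < self.j1 < 1.0:
            raise ValueError("require 0 < j0 < j1 < 1")
        if not (math.isfinite(self.z_alpha) and math.isfinite(self.z_beta)):
            raise ValueError("z-scores must be finite")


@dataclass(frozen=True)
class IntronBiasQuery:
    """Long vs short intron comparison for the new-exon bias ratio."""

    long_len: int  # bp
    short_len: int  # bp
    exon_len: int  # bp

    def __post_init__(self) -> None:
        if self.short_len <= self.exon_len + 31:
            raise ValueError("short intron must exceed exon_len + 31")
        if self.long_len < self.short_len:
            raise ValueError("long_len must be >= short_len")


@dataclass
class OutlierResult:
    """Tukey outlier call for one gene's expression value."""

    gene_id: str
    x: float
    q1: float
    q3: float
    iqr: float
    score: Optional[float]
    tail: str  # "upper" | "lower" | "none"
    degenerate: bool = False
    p: Optional[float] = None
    q: Optional[float] = None

    OUTLIER_THRESHOLD = 1.5

    @property
    def is_outlier(self) -> bool:
        return self.score is not None and abs(self.score) > self.OUTLIER_THRESHOLD


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 table: genes with hits vs genome totals, non-cancer vs cancer."""

    n1: int  # non-cancer genes with hits
    n2: int  # cancer genes with hits
    t1: int  # genome-wide non-cancer genes
    t2: int  # genome-wide cancer genes

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.t1, self.t2) < 0:
            raise ValueError("table entries must be non-negative")


def required_depth(params: PowerParams) -> int:
    """Smallest read depth giving the target power for a one-sided test.

    R >= ((z_alpha*sqrt(j0(1-j0)) + z_beta*sqrt(j1(1-j1))) / (j1-j0))^2,
    the Gaussian approximation for a one-sided binomial test of the
    junction allele fraction j1 against the null j0.  Returns the ceiling
    of the right-hand side.
    """
    num = params.z_alpha * math.sqrt(params.j0 * (1 - params.j0)) + params.z_beta * math.sqrt(
        params.j1 * (1 - params.j1)
    )
    rhs = (num / (params.j1 - params.j0)) ** 2
    return math.ceil(rhs)


def power_curve(j0: float, j1_values: Sequence[float], power_levels=(0.80, 0.90, 0.95)):
    """Required depth as a function of alternative JAF for several power levels.

    Returns a list of dict rows (j1, power, required_depth) suitable for
    a TSV dump.
    """
    rows = []
    for power in power_levels:
        z_beta = float(sps.norm.ppf(power))
        for j1 in j1_values:
            rows.append(
                {
                    "j1": j1,
                    "power": power,
                    "required_depth": required_depth(
                        PowerParams(j0=j0, j1=j1, z_beta=z_beta)
                    ),
                }
            )
    return rows


def expected_artifact_reads(depth: int, mean_quality: float) -> float:
    """Expected artifactual supporting reads: depth * 10^(-Q/10)."""
    if depth < 0 or mean_quality < 0:
        raise ValueError("depth and quality must be non-negative")
    return depth * 10.0 ** (-mean_quality / 10.0)


def poisson_tail(mean: float, m: int) -> float:
    """P(X >= m) for X ~ Poisson(mean).

    The chance of seeing at least m artifact reads by chance; with the
    expected 2 artifact reads at 200x depth, requiring 5 supporting reads
    keeps this at ~5%.
    """
    if mean < 0 or m < 0:
        raise ValueError("mean and m must be non-negative")
    if m == 0:
        return 1.0
    return float(sps.poisson.sf(m - 1, mean))


def new_exon_probability(intron_len: int, exon_len: int, linearized: bool = False) -> float:
    """Probability that an intron can host a new exon of characteristic size.

    A donor (9 nt) and acceptor (23 nt) motif must both arise, separated
    by an exon-sized distance E inside an intron of length L: roughly
    L - E - 31 placements, each succeeding with probability 4^-32.
    Exact form 1 - (1 - 4^-32)^(L-E-31); ``linearized`` selects the
    first-order expansion (L - E - 31) * 4^-32.
    """
    placements = intron_len - exon_len - 31
    if placements <= 0:
        if placements < 0:
            import logging

            logging.getLogger(__name__).warning(
                "intron shorter than exon_len + 31; no placements possible"
            )
        return 0.0
    if linearized:
        return placements * MOTIF_PROBABILITY
    return -math.expm1(placements * math.log1p(-MOTIF_PROBABILITY))


def intron_bias_ratio(query: IntronBiasQuery) -> float:
    """Fold bias of long vs short introns toward new-exon creation.

    (L_long - E - 31) / (L_short - E - 31): the ratio of available motif
    placements, hence of new-exon probabilities under the linearized
    model.
    """
    denom = query.short_len - query.exon_len - 31
    if denom <= 0:
        raise ValueError("short intron leaves no motif placements")
    return (query.long_len - query.exon_len - 31) / denom


def tukey_outlier(
    x: float, cohort: Sequence[float], gene_id: str = "", with_p: bool = False
) -> OutlierResult:
    """Tukey fence outlier score of ``x`` against a cohort of log2 values.

    score = (x - Q3)/IQR above the third quartile, (x - Q1)/IQR below the
    first; |score| > 1.5 flags an outlier.  Quartiles use linear
    interpolation (the common "type 7" convention).  The optional p-value
    is a reconstruction: a normal model centred at the median with
    sigma = IQR/1.349, one-sided by tail.
    """
    arr = np.asarray(cohort, dtype=float)
    if arr.size < 4:
        raise ValueError("cohort must contain at least 4 values")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return OutlierResult(
            gene_id=gene_id, x=x, q1=float(q1), q3=float(q3), iqr=0.0,
            score=None, tail="none", degenerate=True,
        )
    if x > q3:
        tail, score = "upper", (x - q3) / iqr
    elif x < q1:
        tail, score = "lower", (x - q1) / iqr
    else:
        tail, score = "none", 0.0
    p = None
    if with_p and tail != "none":
        sigma = iqr / 1.349
        med = float(np.median(arr))
        if tail == "upper":
            p = float(sps.norm.sf(x, loc=med, scale=sigma))
        else:
            p = float(sps.norm.cdf(x, loc=med, scale=sigma))
    return OutlierResult(
        gene_id=gene_id, x=x, q1=float(q1), q3=float(q3), iqr=float(iqr),
        score=float(score), tail=tail, p=p,
    )


def outlier_table(expression, gene_samples: dict, with_p: bool = True):
    """Score a set of (gene, sample) pairs against the full cohort per gene.

    ``expression`` is a gene x sample DataFrame of log2 values;
    ``gene_samples`` maps gene_id -> sample_id of the case carrying the
    splice-creating mutation.  Returns a list of OutlierResult with
    BH-corrected q-values across genes.
    """
    results = []
    for gene, sample in sorted(gene_samples.items()):
        if gene not in expression.index or sample not in expression.columns:
            continue
        row = expression.loc[gene].astype(float)
        res = tukey_outlier(float(row[sample]), row.values, gene_id=gene, with_p=with_p)
        results.append(res)
    with_pvals = [r for r in results if r.p is not None]
    if with_pvals:
        qs = bh_fdr([r.p for r in with_pvals])
        for r, q in zip(with_pvals, qs):
            r.q = q
    return results


def fisher_enrichment(table: EnrichmentTable):
    """Two-sided Fisher exact test for overrepresentation in cancer genes.

    Returns (odds_ratio, p); the odds ratio is (n2/n1)/(t2/t1), hits per
    cancer gene relative to the genome-wide cancer-gene fraction.  The
    p-value sums hypergeometric probabilities of all tables with the same
    margins that are no more probable than the observed one.
    """
    if table.n1 + table.n2 == 0 or table.t1 + table.t2 == 0:
        raise ValueError("a table margin is zero; the test is undefined")
    if table.n1 == 0 or table.t2 == 0:
        odds = math.inf if table.n2 > 0 else math.nan
    else:
        odds = (table.n2 / table.n1) / (table.t2 / table.t1)
    _, p = sps.fisher_exact(
        [[table.n1, table.n2], [table.t1, table.t2]], alternative="two-sided"
    )
    return odds, float(p)
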