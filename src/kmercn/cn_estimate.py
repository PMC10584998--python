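"""Copy-number estimation from k-mer frequency tables.

The estimator is a median ratio: the median read frequency of gene k-mers,
divided by the median read frequency of flanking k-mers (the local diploid
depth-of-coverage proxy), times the ploidy. Medians make the estimate
robust to dropout and off-target hits of individual k-mers, and the ratio
cancels overall sequencing depth, which is why estimates agree across
coverages and technologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EstimationError
from .kmer_count import FrequencyTable, table_as_vectors
from .kmer_select import KmerDatabase

DEFAULT_PLOIDY = 2
#: Below this many gene k-mers the median is dominated by a handful of
#: sites and calls become unreliable (paralog-heavy genes hit this regime).
LOW_KMER_THRESHOLD = 500
#: Relative 5'/3' flank median divergence that suggests a CNV inside a flank.
FLANK_DIVERGENCE = 0.25


@dataclass(slots=True)
class CopyNumberEstimate:
    gene_name: str
    sample_id: str
    median_gene_freq: float
    median_flank_freq: float
    cn_decimal: float
    cn_integer: int
    n_gene_kmers: int
    n_flank_kmers: int
    warnings: list[str] = field(default_factory=list)


@dataclass(slots=True)
class NormalizedProfile:
    """Per-k-mer normalized frequencies, plot-ready.

    ``rows`` has one row per database k-mer ordered by (chrom, pos) with
    columns chrom, pos (0-based first-copy coordinate), type, kmer,
    raw_count, normalized. The median of normalized gene values equals
    ``cn_decimal``; flank values have median equal to the ploidy.
    """

    gene_name: str
    sample_id: str
    cn_decimal: float
    rows: pd.DataFrame


def round_cn(cn_decimal: float) -> int:
    """Nearest integer; exact .5 ties round away from zero."""
    if cn_decimal < 0:
        raise EstimationError(f"negative copy number {cn_decimal}")
    return int(math.floor(cn_decimal + 0.5))


def _median(values) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def estimate_cn(
    table: FrequencyTable,
    db: KmerDatabase,
    ploidy: int = DEFAULT_PLOIDY,
    low_kmer_threshold: int = LOW_KMER_THRESHOLD,
) -> CopyNumberEstimate:
    """Median-ratio copy number for one gene in one sample.

    cn_decimal = ploidy * median(gene k-mer counts) / median(flank counts),
    with 5' and 3' flank counts pooled into a single denominator. Warnings
    flag a 5'/3' flank divergence above 25% (possible CNV inside a flank)
    and gene k-mer sets below ``low_kmer_threshold``.
    """
    gene, f5, f3 = table_as_vectors(table, db)
    if not f5 and not f3:
        raise ConfigError("database has no flank k-mers")
    flank = f5 + f3
    median_gene = _median(gene)
    median_flank = _median(flank)
    if median_flank == 0:
        raise EstimationError("no coverage in flanking reference")

    warn: list[str] = []
    if f5 and f3:
        m5, m3 = _median(f5), _median(f3)
        if abs(m5 - m3) > FLANK_DIVERGENCE * median_flank:
            warn.append(
                f"flank medians diverge (5'={m5:g}, 3'={m3:g}); "
                "possible CNV inside a flanking region"
            )
    if len(gene) < low_kmer_threshold:
        warn.append(
            f"only {len(gene)} gene k-mers (<{low_kmer_threshold}); "
            "low-confidence estimate"
        )

    # cn_decimal is computed as the median of per-k-mer normalized values so
    # that it is bit-identical to the profile's gene median; mathematically
    # it equals ploidy * median_gene / median_flank.
    cn_decimal = _median([ploidy * c / median_flank for c in gene])
    return CopyNumberEstimate(
        gene_name=db.gene_name,
        sample_id=table.sample_id,
        median_gene_freq=median_gene,
        median_flank_freq=median_flank,
        cn_decimal=cn_decimal,
        cn_integer=round_cn(cn_decimal),
        n_gene_kmers=len(gene),
        n_flank_kmers=len(flank),
        warnings=warn,
    )


def normalize_profile(
    table: FrequencyTable, db: KmerDatabase, ploidy: int = DEFAULT_PLOIDY
) -> NormalizedProfile:
    """Per-k-mer normalized frequencies along the gene and its flanks.

    Each k-mer's raw count is scaled by ploidy / median flank frequency, so
    single-copy flank k-mers hover around the ploidy and gene k-mers around
    the copy number. Multi-copy gene k-mers are plotted at their first-copy
    coordinate. Steps in the gene panel reveal partial duplications whose
    breakpoints fall inside the gene.
    """
    est = estimate_cn(table, db, ploidy=ploidy)
    scale_denominator = est.median_flank_freq
    records = []
    for rec, rtype in (
        [(r, "gene") for r in db.gene_kmers]
        + [(r, "flank_5p") for r in db.flank_kmers_5p]
        + [(r, "flank_3p") for r in db.flank_kmers_3p]
    ):
        chrom, pos, _ = rec.first_position
        count = table.counts[rec.canonical]
        records.append(
            (chrom, pos, rtype, rec.sequence, count, ploidy * count / scale_denominator)
        )
    rows = pd.DataFrame.from_records(
        records, columns=["chrom", "pos", "type", "kmer", "raw_count", "normalized"]
    ).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return NormalizedProfile(
        gene_name=db.gene_name,
        sample_id=table.sample_id,
        cn_decimal=est.cn_decimal,
        rows=rows,
    )


@dataclass(slots=True)
class ConsistencyReport:
    sample_id: str
    cn_sum: int
    cn_total: int
    match: bool
    discrepancy_decimal: float


def combined_consistency(
    cn_a: CopyNumberEstimate,
    cn_b: CopyNumberEstimate,
    cn_total: CopyNumberEstimate,
) -> ConsistencyReport:
    """Check that two per-paralog calls sum to the combined-database call.

    For near-identical paralog pairs the per-gene databases are tiny and
    noisy while the combined database (k-mers shared by both genes) stays
    large; agreement of the sum with the combined call is a useful internal
    control.
    """
    ids = {cn_a.sample_id, cn_b.sample_id, cn_total.sample_id}
    if len(ids) != 1:
        raise ConfigError(f"estimates from different samples: {sorted(ids)}")
    cn_sum = cn_a.cn_integer + cn_b.cn_integer
    return ConsistencyReport(
        sample_id=cn_total.sample_id,
        cn_sum=cn_sum,
        cn_total=cn_total.cn_integer,
        match=cn_sum == cn_total.cn_integer,
        discrepancy_decimal=(cn_a.cn_decimal + cn_b.cn_decimal) - cn_total.cn_decimal,
    )


def parity_fraction(pairs: list[tuple[int, int]]) -> float:
    """Fraction of integer CN pairs that are both even or both odd.

    Co-duplicated genes (carried on one amplified segment) show elevated
    parity even when their absolute copy numbers differ.
    """
    if not pairs:
        raise ConfigError("empty pair list")
    same = sum(1 for a, b in pairs if (a - b) % 2 == 0)
    return same / len(pairs)


def concordance_and_correlation(
    x: list[float], y: list[float]
) -> tuple[float, float]:
    """(integer concordance, Pearson r on decimals) between two call sets.

    Concordance is the fraction of samples whose rounded copy numbers
    agree; r is computed on the raw decimal values. With zero variance in
    either input r is undefined and returned as NaN.
    """
    if len(x) != len(y) or len(x) < 2:
        raise ConfigError("need two equal-length lists of >= 2 values")
    concordance = sum(
        1 for a, b in zip(x, y) if round_cn(a) == round_cn(b)
    ) / len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return concordance, float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return concordance, r
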