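"""Synthetic genomes and reads for end-to-end validation of the pipeline.

The generator emulates a tandem multi-copy gene locus embedded in unique
background sequence (amylase-like): a reference genome carrying
``n_ref_copies`` identical gene copies, an individual genome carrying an
arbitrary total copy number, and whole-genome shotgun reads with uniform
start positions, random strand and i.i.d. substitution errors. Three read
regimes cover the technologies the estimator is meant to serve: short
accurate reads (Illumina-like), long noisy reads (Nanopore-like) and long
accurate reads (PacBio-like).

All sequence is drawn uniformly over ACGT from a seeded generator, so GC is
close to 50% and nearly every k-mer passes the GC filter; uniqueness of the
background is guaranteed with overwhelming probability at k = 25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._sequence import revcomp
from .errors import ConfigError
from .kmer_count import count_sequences
from .cn_estimate import CopyNumberEstimate, estimate_cn
from .kmer_select import KmerDatabase, build_database, build_genome_index
from .regions import FLANK_3P, FLANK_5P, GENE_COPY, RegionSpec

CHROM = "chrS"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Sub-stream labels so stages can be re-run independently from one master seed.
_STAGE_REFERENCE = 11
_STAGE_DIVERGENCE = 13
_STAGE_READS = 17


@dataclass(frozen=True, slots=True)
class SyntheticSpec:
    """Study conditions for one synthetic experiment.

    Defaults describe the Illumina-like baseline regime: a 4 kb gene
    present in 3 tandem reference copies inside 60 kb of unique background,
    24 kb flanks, 150 bp single-end reads at 30x with 0.1% substitution
    error. Flanks are deliberately wide: the flank k-mer median is the
    depth-of-coverage baseline and its sampling variance shrinks with the
    genomic span it averages over, exactly as with real data where flanking
    regions need to be large.
    """

    seed: int = 1
    background_len: int = 60_000
    gene_len: int = 4_000
    n_ref_copies: int = 3
    flank_len: int = 24_000
    individual_cn: int = 6
    read_len: int = 150
    coverage: float = 30.0
    error_rate: float = 0.001
    paired: bool = False

    def __post_init__(self) -> None:
        if self.background_len < 2 * self.flank_len + self.n_ref_copies * self.gene_len:
            raise ConfigError(
                "background too short: need >= 2*flank_len + n_ref_copies*gene_len"
            )
        if not (0 <= self.error_rate < 0.25):
            raise ConfigError(f"error_rate {self.error_rate} outside [0, 0.25)")
        if self.n_ref_copies < 1 or self.gene_len < 1 or self.flank_len < 1:
            raise ConfigError("gene/flank/copy parameters must be positive")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _core_sequences(spec: SyntheticSpec) -> tuple[str, str, str]:
    """(left background, gene, right background) — shared by reference and
    individual so that an individual differs from the reference only in the
    gene cluster."""
    rng = np.random.default_rng([_STAGE_REFERENCE, spec.seed])
    left_len = spec.background_len // 2
    left = _random_dna(rng, left_len)
    gene = _random_dna(rng, spec.gene_len)
    right = _random_dna(rng, spec.background_len - left_len)
    return left, gene, right


def make_reference(spec: SyntheticSpec) -> tuple[dict[str, str], list[RegionSpec]]:
    """Reference genome with ``n_ref_copies`` tandem gene copies + region config."""
    left, gene, right = _core_sequences(spec)
    genome = {CHROM: left + gene * spec.n_ref_copies + right}
    start = len(left)
    regions = [
        RegionSpec(CHROM, start - spec.flank_len, start, "flank5", FLANK_5P)
    ]
    for i in range(spec.n_ref_copies):
        regions.append(
            RegionSpec(
                CHROM,
                start + i * spec.gene_len,
                start + (i + 1) * spec.gene_len,
                f"gene_copy{i + 1}",
                GENE_COPY,
            )
        )
    cluster_end = start + spec.n_ref_copies * spec.gene_len
    regions.append(
        RegionSpec(CHROM, cluster_end, cluster_end + spec.flank_len, "flank3", FLANK_3P)
    )
    return genome, regions


def make_individual(spec: SyntheticSpec, cn: int | None = None) -> dict[str, str]:
    """Diploid individual genome carrying ``cn`` total gene copies.

    Two haplotype sequences are returned: ``hapA`` is the reference layout
    with the gene cluster replaced by ``cn`` tandem copies (cn = 0 deletes
    the gene entirely) and ``hapB`` carries the background and flanks only.
    Putting every variable copy on one haplotype is without loss of
    generality — copies are identical and the estimator only sees totals —
    while the duplicated flanks make the flank k-mer frequency a true
    diploid depth baseline, as in real data.
    """
    if cn is None:
        cn = spec.individual_cn
    if cn < 0:
        raise ConfigError(f"copy number must be >= 0, got {cn}")
    left, gene, right = _core_sequences(spec)
    return {"hapA": left + gene * cn + right, "hapB": left + right}


def mutate_sequence(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct random positions."""
    if n_subs == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    idx = np.searchsorted(_BASES, arr[pos])
    arr[pos] = _BASES[(idx + rng.integers(1, 4, n_subs)) % 4]
    return arr.tobytes().decode()


def simulate_reads(
    genome: dict[str, str] | str,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> list[tuple[str, str, str]]:
    """Shotgun reads as (name, sequence, quality) tuples.

    n_reads = ceil(coverage * genome_len / read_len); start positions and
    strands uniform; substitution errors i.i.d. per base; constant quality
    string. Deterministic for a given seed.
    """
    seqs = [genome] if isinstance(genome, str) else list(genome.values())
    rl = spec.read_len
    if any(rl > len(s) for s in seqs):
        raise ConfigError(f"read_len {rl} exceeds a genome sequence length")
    if spec.coverage <= 0:
        raise ConfigError(f"coverage must be positive, got {spec.coverage}")
    rng = np.random.default_rng(
        [_STAGE_READS, spec.seed if seed is None else seed]
    )
    total_len = sum(len(s) for s in seqs)
    n_reads = math.ceil(spec.coverage * total_len / rl)
    # Reads never span sequence boundaries: each read is assigned to a
    # sequence with probability proportional to its number of start windows,
    # then placed uniformly within it.
    windows = np.array([len(s) - rl + 1 for s in seqs], dtype=float)
    which = rng.choice(len(seqs), size=n_reads, p=windows / windows.sum())
    strands = rng.integers(0, 2, n_reads)
    n_errors = (
        rng.binomial(rl, spec.error_rate, n_reads)
        if spec.error_rate > 0
        else np.zeros(n_reads, dtype=int)
    )
    qual = "I" * rl
    reads = []
    for i in range(n_reads):
        seq = seqs[which[i]]
        start = int(rng.integers(0, len(seq) - rl + 1))
        r = seq[start : start + rl]
        if strands[i]:
            r = revcomp(r)
        if n_errors[i]:
            r = mutate_sequence(r, int(n_errors[i]), rng)
        reads.append((f"read_{i}", r, qual))
    return reads


# ---------------------------------------------------------------------------
# End-to-end harnesses


def recover_cn(
    spec: SyntheticSpec,
    cn: int | None = None,
    mm1: bool = True,
    n_flank: int | None = None,
) -> dict:
    """Full pipeline on one synthetic sample: reference -> database ->
    individual -> reads -> counts -> estimate. Returns true vs estimated CN."""
    if cn is None:
        cn = spec.individual_cn
    genome, regions = make_reference(spec)
    db = build_database(
        genome, regions, gene_name="synth", mm1=mm1, n_flank=n_flank,
        reference_name=f"synthetic(seed={spec.seed})",
    )
    individual = make_individual(spec, cn)
    reads = simulate_reads(individual, spec)
    table = count_sequences((r[1] for r in reads), db, sample_id=f"sim{spec.seed}")
    est = estimate_cn(table, db)
    return {
        "true_cn": cn,
        "cn_decimal": est.cn_decimal,
        "cn_integer": est.cn_integer,
        "estimate": est,
        "db": db,
    }


def _shared_db(spec: SyntheticSpec, n_flank: int | None = None) -> KmerDatabase:
    genome, regions = make_reference(spec)
    return build_database(
        genome, regions, gene_name="synth", n_flank=n_flank,
        reference_name=f"synthetic(seed={spec.seed})",
    )


def _estimate_one(
    spec: SyntheticSpec, db: KmerDatabase, cn: int, read_seed: int
) -> CopyNumberEstimate:
    individual = make_individual(spec, cn)
    reads = simulate_reads(individual, spec, seed=read_seed)
    table = count_sequences((r[1] for r in reads), db, sample_id=f"s{read_seed}")
    return estimate_cn(table, db)


def cn_recovery_sweep(
    spec: SyntheticSpec,
    cns: list[int],
    n_trials: int,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Recovery of known copy numbers over repeated read simulations.

    One reference and database (from ``spec.seed``) are shared across the
    sweep; each trial redraws the shotgun reads. Returns a tidy frame with
    true and estimated copy numbers per trial.
    """
    db = _shared_db(spec)
    rows = []
    for cn in cns:
        for trial in range(n_trials):
            read_seed = (base_seed * 1_000_003 + cn * 1_009 + trial) % (2**31 - 1)
            est = _estimate_one(spec, db, cn, read_seed)
            rows.append(
                {
                    "cn_true": cn,
                    "trial": trial,
                    "read_seed": read_seed,
                    "cn_decimal": est.cn_decimal,
                    "cn_integer": est.cn_integer,
                }
            )
    return pd.DataFrame(rows)


def coverage_invariance_trials(
    spec: SyntheticSpec,
    coverages: tuple[float, float] = (10.0, 40.0),
    n_trials: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Same individual sequenced at two depths; reports the decimal CN gap."""
    db = _shared_db(spec)
    rows = []
    for trial in range(n_trials):
        seed = (base_seed * 7_001 + trial) % (2**31 - 1)
        ests = [
            _estimate_one(replace(spec, coverage=c), db, spec.individual_cn, seed)
            for c in coverages
        ]
        rows.append(
            {
                "trial": trial,
                "cn_low_cov": ests[0].cn_decimal,
                "cn_high_cov": ests[1].cn_decimal,
                "delta": abs(ests[0].cn_decimal - ests[1].cn_decimal),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paralog pair (SMN-style) fixtures


def make_paralog_reference(
    spec: SyntheticSpec, divergence: float = 0.001
) -> tuple[dict[str, str], dict[str, list[RegionSpec]]]:
    """Reference with two near-identical gene variants A and B in tandem.

    ``divergence`` is the per-base substitution divergence between the two
    variants (0.001 emulates a 99.9%-identical paralog pair). Returns the
    genome and region configs for the per-variant databases ("a", "b") and
    the combined two-copy database ("combined").
    """
    left, gene_a, right = _core_sequences(spec)
    rng = np.random.default_rng([_STAGE_DIVERGENCE, spec.seed])
    n_subs = max(1, round(spec.gene_len * divergence))
    gene_b = mutate_sequence(gene_a, n_subs, rng)
    genome = {CHROM: left + gene_a + gene_b + right}
    a_start = len(left)
    b_start = a_start + spec.gene_len
    b_end = b_start + spec.gene_len
    f5 = RegionSpec(CHROM, a_start - spec.flank_len, a_start, "flank5", FLANK_5P)
    f3 = RegionSpec(CHROM, b_end, b_end + spec.flank_len, "flank3", FLANK_3P)
    reg_a = RegionSpec(CHROM, a_start, a_start + spec.gene_len, "geneA", GENE_COPY)
    reg_b = RegionSpec(CHROM, b_start, b_end, "geneB", GENE_COPY)
    return genome, {
        "a": [f5, reg_a, f3],
        "b": [f5, reg_b, f3],
        "combined": [f5, reg_a, reg_b, f3],
    }


def make_paralog_individual(
    spec: SyntheticSpec, cn_a: int, cn_b: int, divergence: float = 0.001
) -> dict[str, str]:
    """Diploid individual with cn_a copies of variant A and cn_b of variant B.

    Same haplotype convention as :func:`make_individual`: all variable
    copies on ``hapA``, background-only ``hapB``.
    """
    left, gene_a, right = _core_sequences(spec)
    rng = np.random.default_rng([_STAGE_DIVERGENCE, spec.seed])
    n_subs = max(1, round(spec.gene_len * divergence))
    gene_b = mutate_sequence(gene_a, n_subs, rng)
    return {
        "hapA": left + gene_a * cn_a + gene_b * cn_b + right,
        "hapB": left + right,
    }


def paralog_databases(
    spec: SyntheticSpec, divergence: float = 0.001, k: int = 25
) -> dict[str, KmerDatabase]:
    """Per-variant ("a", "b") and combined databases for the paralog pair.

    Per-variant databases are built without the Hamming-1 filter — every
    variant-specific k-mer is by construction one substitution away from the
    other paralog, so the filter would empty the set. The combined database
    keeps the filter on.
    """
    genome, configs = make_paralog_reference(spec, divergence)
    index = build_genome_index(genome, k)
    return {
        name: build_database(
            genome,
            regs,
            gene_name=name,
            k=k,
            mm1=(name == "combined"),
            n_flank=None,
            index=index,
            reference_name=f"paralog(seed={spec.seed})",
        )
        for name, regs in configs.items()
    }


def paralog_trial(
    spec: SyntheticSpec,
    cn_a: int,
    cn_b: int,
    read_seed: int,
    divergence: float = 0.001,
    dbs: dict[str, KmerDatabase] | None = None,
) -> dict:
    """One SMN-style trial: per-variant and combined estimates side by side."""
    if dbs is None:
        dbs = paralog_databases(spec, divergence)
    individual = make_paralog_individual(spec, cn_a, cn_b, divergence)
    reads = simulate_reads(individual, spec, seed=read_seed)

    seqs = [r[1] for r in reads]
    sample = f"p{read_seed}"
    ests = {
        name: estimate_cn(count_sequences(seqs, db, sample_id=sample), db)
        for name, db in dbs.items()
    }
    return {
        "cn_a_true": cn_a,
        "cn_b_true": cn_b,
        "total_true": cn_a + cn_b,
        "cn_a": ests["a"],
        "cn_b": ests["b"],
        "combined": ests["combined"],
        "dbs": dbs,
    }


def paralog_sweep(
    spec: SyntheticSpec,
    pairs: list[tuple[int, int]],
    n_trials: int,
    base_seed: int = 0,
    divergence: float = 0.001,
) -> pd.DataFrame:
    """Repeated paralog trials sharing one reference and database set."""
    dbs = paralog_databases(spec, divergence)
    rows = []
    for cn_a, cn_b in pairs:
        for trial in range(n_trials):
            seed = (base_seed * 999_983 + cn_a * 10_007 + cn_b * 101 + trial) % (
                2**31 - 1
            )
            r = paralog_trial(spec, cn_a, cn_b, seed, divergence, dbs=dbs)
            rows.append(
                {
                    "cn_a_true": cn_a,
                    "cn_b_true": cn_b,
                    "total_true": cn_a + cn_b,
                    "cn_a_est": r["cn_a"].cn_decimal,
                    "cn_b_est": r["cn_b"].cn_decimal,
                    "cn_a_int": r["cn_a"].cn_integer,
                    "cn_b_int": r["cn_b"].cn_integer,
                    "combined_est": r["combined"].cn_decimal,
                    "combined_int": r["combined"].cn_integer,
                }
            )
    return pd.DataFrame(rows)
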