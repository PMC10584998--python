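"""Build per-gene k-mer databases from a reference genome.

A copy-number database for one gene holds two k-mer sets:

* *gene k-mers* — present in every reference copy of the gene, occurring in
  the whole reference exactly as many times as the gene has reference
  copies, with no Hamming-1 neighbor anywhere else (optional), and with
  moderate GC content. Their frequency in a sample's reads scales with the
  sample's gene copy number.
* *flank k-mers* — single-copy k-mers from the regions immediately 5' and
  3' of the gene cluster. Their read frequency measures the local diploid
  depth of coverage and serves as the normalization denominator.

All counting is strand-collapsed: k-mers are keyed by their canonical form
(the lexicographic minimum of the k-mer and its reverse complement), because
sequencing reads sample both strands.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._sequence import canonical, gc_percent, hamming_neighbors, revcomp
from .errors import ConfigError, CoordinateError
from .regions import FLANK_3P, FLANK_5P, GENE_COPY, RegionSpec

_VALID_RUN = re.compile(r"[ACGT]+")

DEFAULT_K = 25
DEFAULT_GC_BOUNDS = (20.0, 65.0)
DEFAULT_N_FLANK = 2000


@dataclass(frozen=True, slots=True)
class KmerRecord:
    """A k-mer with its canonical form, reference positions and filters' inputs.

    ``positions`` are 0-based (chrom, coordinate, strand) tuples for every
    occurrence inside the configured regions; ``genome_frequency`` is the
    strand-collapsed count over the whole reference.
    """

    sequence: str
    canonical: str
    positions: tuple[tuple[str, int, str], ...]
    gc_percent: float
    genome_frequency: int = 0

    @property
    def first_position(self) -> tuple[str, int, str]:
        return self.positions[0]


@dataclass(slots=True)
class KmerDatabase:
    """Selected gene-specific and flanking k-mers for one target gene."""

    gene_name: str
    k: int
    n_ref_copies: int
    gene_kmers: list[KmerRecord]
    flank_kmers_5p: list[KmerRecord]
    flank_kmers_3p: list[KmerRecord]
    mm1_applied: bool
    gc_bounds: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene = {r.canonical for r in self.gene_kmers}
        flank = {r.canonical for r in self.flank_kmers_5p} | {
            r.canonical for r in self.flank_kmers_3p
        }
        if gene & flank:
            raise ConfigError("gene and flank k-mer sets overlap")

    @property
    def flank_kmers(self) -> list[KmerRecord]:
        return self.flank_kmers_5p + self.flank_kmers_3p

    @property
    def all_records(self) -> list[KmerRecord]:
        return self.gene_kmers + self.flank_kmers_5p + self.flank_kmers_3p

    def key_set(self) -> frozenset[str]:
        """Canonical k-mers to look up while scanning reads."""
        return frozenset(r.canonical for r in self.all_records)

    def type_of(self) -> dict[str, str]:
        """Map canonical k-mer -> 'gene' / 'flank_5p' / 'flank_3p'."""
        out = {r.canonical: "gene" for r in self.gene_kmers}
        out.update({r.canonical: "flank_5p" for r in self.flank_kmers_5p})
        out.update({r.canonical: "flank_3p" for r in self.flank_kmers_3p})
        return out


def _sort_records(records: Iterable[KmerRecord]) -> list[KmerRecord]:
    return sorted(records, key=lambda r: (r.first_position[0], r.first_position[1], r.sequence))


def extract_region_kmers(
    genome: Mapping[str, str], region: RegionSpec, k: int
) -> list[KmerRecord]:
    """Every k-length window of ``region`` with its position.

    Windows containing non-ACGT characters are omitted. A region shorter
    than k yields an empty list with a warning.
    """
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    region.validate_against(genome)
    if len(region) < k:
        warnings.warn(
            f"region {region.label} ({len(region)} bp) shorter than k={k}",
            stacklevel=2,
        )
        return []
    seq = genome[region.chrom][region.start : region.end]
    out: list[KmerRecord] = []
    for run in _VALID_RUN.finditer(seq):
        run_start, run_seq = run.start(), run.group()
        for i in range(len(run_seq) - k + 1):
            kmer = run_seq[i : i + k]
            pos = region.start + run_start + i
            out.append(
                KmerRecord(
                    sequence=kmer,
                    canonical=canonical(kmer),
                    positions=((region.chrom, pos, "+"),),
                    gc_percent=gc_percent(kmer),
                )
            )
    return out


def intersect_copy_kmers(per_copy_sets: Sequence[list[KmerRecord]]) -> list[KmerRecord]:
    """Canonical k-mers present in every gene copy, positions merged.

    With a single input set this is the identity (up to deterministic
    ordering). Mismatched k across sets is a configuration error.
    """
    if not per_copy_sets:
        raise ConfigError("no k-mer sets to intersect")
    lengths = {len(r.sequence) for s in per_copy_sets for r in s}
    if len(lengths) > 1:
        raise ConfigError(f"k-mer sets built with different k: {sorted(lengths)}")
    common: set[str] | None = None
    for copy_set in per_copy_sets:
        keys = {r.canonical for r in copy_set}
        common = keys if common is None else common & keys
    assert common is not None
    merged: dict[str, KmerRecord] = {}
    for copy_set in per_copy_sets:
        for rec in copy_set:
            if rec.canonical not in common:
                continue
            if rec.canonical in merged:
                prev = merged[rec.canonical]
                merged[rec.canonical] = replace(
                    prev, positions=tuple(sorted(set(prev.positions + rec.positions)))
                )
            else:
                merged[rec.canonical] = rec
    return _sort_records(merged.values())


def build_genome_index(genome: Mapping[str, str], k: int) -> dict[str, int]:
    """Canonical k-mer -> strand-collapsed occurrence count over the reference.

    Each forward window counted once under its canonical form equals the
    strand-collapsed total (a window and its reverse-complement partner are
    the same event). Windows with ambiguity codes are skipped.
    """
    if not genome or all(not s for s in genome.values()):
        raise ConfigError("empty reference genome")
    index: dict[str, int] = {}
    for seq in genome.values():
        for run in _VALID_RUN.finditer(seq):
            run_seq = run.group()
            rc = revcomp(run_seq)
            n = len(run_seq)
            for i in range(n - k + 1):
                fwd = run_seq[i : i + k]
                bwd = rc[n - k - i : n - i]
                key = fwd if fwd <= bwd else bwd
                index[key] = index.get(key, 0) + 1
    return index


def filter_unique(
    candidates: Iterable[KmerRecord],
    index: Mapping[str, int],
    n_copies: int,
    mm1: bool = True,
) -> list[KmerRecord]:
    """Keep k-mers whose genome-wide frequency equals the reference copy count.

    With ``mm1`` enabled, additionally drop any k-mer that has a Hamming-1
    neighbor (of itself or its reverse complement, canonically collapsed)
    occurring anywhere in the reference — such k-mers are one sequencing
    error away from off-target sequence and would pick up stray counts.
    """
    if n_copies <= 0:
        raise ConfigError(f"n_copies must be positive, got {n_copies}")
    kept: list[KmerRecord] = []
    for rec in candidates:
        freq = index.get(rec.canonical, 0)
        if freq != n_copies:
            continue
        if mm1:
            # Neighbors of revcomp(kmer) canonicalize to the same set as
            # neighbors of kmer, so one enumeration suffices.
            hit = False
            for nb in hamming_neighbors(rec.sequence):
                cnb = canonical(nb)
                if cnb != rec.canonical and index.get(cnb, 0) > 0:
                    hit = True
                    break
            if hit:
                continue
        kept.append(replace(rec, genome_frequency=freq))
    return _sort_records(kept)


def filter_gc(
    candidates: Iterable[KmerRecord],
    low: float = DEFAULT_GC_BOUNDS[0],
    high: float = DEFAULT_GC_BOUNDS[1],
) -> list[KmerRecord]:
    """Keep k-mers with GC percent in [low, high], bounds inclusive."""
    if not (0 <= low <= high <= 100):
        raise ConfigError(f"invalid GC bounds ({low}, {high})")
    return _sort_records(r for r in candidates if low <= r.gc_percent <= high)


def select_flank_kmers(
    genome: Mapping[str, str],
    gene_regions: Sequence[RegionSpec],
    flank_regions: tuple[RegionSpec, RegionSpec],
    index: Mapping[str, int],
    n_target: int | None = DEFAULT_N_FLANK,
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[KmerRecord], list[KmerRecord]]:
    """Pick up to n_target/2 unique, GC-passing flank k-mers per side.

    Candidates are taken nearest the gene boundary first; only single-copy
    (genome frequency 1) k-mers qualify, since the flank median stands in
    for the diploid depth of coverage. If one side runs short the other is
    not topped up — a warning is emitted instead. ``n_target=None`` keeps
    every qualifying flank k-mer.
    """
    flank_5p, flank_3p = flank_regions
    for fr in (flank_5p, flank_3p):
        for gr in gene_regions:
            if fr.chrom == gr.chrom and fr.start < gr.end and gr.start < fr.end:
                raise ConfigError(
                    f"flank region {fr.label} overlaps gene region {gr.label}"
                )
    per_side = None if n_target is None else n_target // 2
    result: list[list[KmerRecord]] = []
    for region, nearest_first_desc in ((flank_5p, True), (flank_3p, False)):
        candidates = extract_region_kmers(genome, region, _infer_k(index))
        # 5' flank: highest coordinate is adjacent to the gene; 3' flank:
        # lowest coordinate is adjacent.
        candidates.sort(key=lambda r: r.first_position[1], reverse=nearest_first_desc)
        chosen: dict[str, KmerRecord] = {}
        low, high = gc_bounds
        for rec in candidates:
            if per_side is not None and len(chosen) >= per_side:
                break
            if rec.canonical in exclude or rec.canonical in chosen:
                continue
            if index.get(rec.canonical, 0) != 1:
                continue
            if not (low <= rec.gc_percent <= high):
                continue
            chosen[rec.canonical] = replace(rec, genome_frequency=1)
        if per_side is not None and len(chosen) < per_side:
            warnings.warn(
                f"flank {region.label}: only {len(chosen)} of {per_side} "
                "requested k-mers available",
                stacklevel=2,
            )
        result.append(_sort_records(chosen.values()))
    if not result[0] and not result[1]:
        raise ConfigError("no usable flank k-mers on either side")
    return result[0], result[1]


def _infer_k(index: Mapping[str, int]) -> int:
    for key in index:
        return len(key)
    raise ConfigError("empty genome index")


def build_database(
    genome: Mapping[str, str],
    regions: Sequence[RegionSpec],
    gene_name: str | None = None,
    k: int = DEFAULT_K,
    mm1: bool = True,
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS,
    n_flank: int | None = DEFAULT_N_FLANK,
    reference_name: str = "reference",
    index: Mapping[str, int] | None = None,
) -> KmerDatabase:
    """Compose extract -> intersect -> uniqueness -> GC -> flank selection.

    ``regions`` must contain at least one ``gene_copy`` interval and one
    flank interval of each role. A combined database for two near-identical
    paralogs is built by listing one ``gene_copy`` region per paralog: the
    intersection then requires presence in both genes and the expected
    genome frequency is the total copy count.

    A precomputed ``index`` (from :func:`build_genome_index` with the same
    k) may be passed to amortize the reference scan across databases.
    """
    gene_regions = [r for r in regions if r.role == GENE_COPY]
    f5 = [r for r in regions if r.role == FLANK_5P]
    f3 = [r for r in regions if r.role == FLANK_3P]
    if not gene_regions:
        raise ConfigError("no gene_copy region configured")
    if len(f5) != 1 or len(f3) != 1:
        raise ConfigError("exactly one flank_5p and one flank_3p region required")
    if gene_name is None:
        gene_name = gene_regions[0].label

    if index is None:
        index = build_genome_index(genome, k)
    n_copies = len(gene_regions)

    per_copy = [extract_region_kmers(genome, r, k) for r in gene_regions]
    candidates = intersect_copy_kmers(per_copy)
    if not candidates:
        raise ConfigError("no k-mers shared by all gene copies (intersection stage)")
    unique = filter_unique(candidates, index, n_copies, mm1=mm1)
    if not unique:
        raise ConfigError("uniqueness filter eliminated all gene k-mers")
    gene_kmers = filter_gc(unique, *gc_bounds)
    if not gene_kmers:
        raise ConfigError("GC filter eliminated all gene k-mers")

    gene_keys = frozenset(r.canonical for r in gene_kmers)
    flank_5p_kmers, flank_3p_kmers = select_flank_kmers(
        genome,
        gene_regions,
        (f5[0], f3[0]),
        index,
        n_target=n_flank,
        gc_bounds=gc_bounds,
        exclude=gene_keys,
    )
    return KmerDatabase(
        gene_name=gene_name,
        k=k,
        n_ref_copies=n_copies,
        gene_kmers=gene_kmers,
        flank_kmers_5p=flank_5p_kmers,
        flank_kmers_3p=flank_3p_kmers,
        mm1_applied=mm1,
        gc_bounds=tuple(float(b) for b in gc_bounds),
        provenance={
            "reference": reference_name,
            "regions": [
                (r.label, r.role, r.chrom, r.start, r.end) for r in regions
            ],
        },
    )
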