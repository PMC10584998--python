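"""Count database k-mers directly in raw sequencing reads.

Reads are never aligned: every k-length window of every read is collapsed to
its canonical form and, if it belongs to the database key set, counted. The
same sliding-window loop serves short Illumina reads and long
Nanopore/PacBio reads; base qualities are ignored and no filtering is
applied, so the counts reflect the raw data as sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ._sequence import revcomp
from .errors import ConfigError
from .kmer_select import KmerDatabase

_INVALID = str.maketrans("", "", "ACGT")


@dataclass(slots=True)
class FrequencyTable:
    """Observed counts for every database k-mer in one sample.

    Every database key is present (zero allowed); counts are independent of
    read order and of how the reads are split across files.
    """

    sample_id: str
    counts: dict[str, int]
    n_reads_scanned: int = 0
    n_bases_scanned: int = 0

    def add(self, other: "FrequencyTable") -> "FrequencyTable":
        merged = dict(self.counts)
        for key, val in other.counts.items():
            merged[key] = merged.get(key, 0) + val
        return FrequencyTable(
            sample_id=self.sample_id,
            counts=merged,
            n_reads_scanned=self.n_reads_scanned + other.n_reads_scanned,
            n_bases_scanned=self.n_bases_scanned + other.n_bases_scanned,
        )


def scan_sequence(seq: str, lookup: frozenset[str] | set[str], k: int) -> dict[str, int]:
    """Canonical-window hits of one sequence against the database key set.

    Windows containing non-ACGT characters contribute nothing; a sequence
    shorter than k contributes no windows.
    """
    if not lookup:
        raise ConfigError("empty k-mer lookup set")
    hits: dict[str, int] = {}
    n = len(seq)
    if n < k:
        return hits
    if seq.translate(_INVALID):
        # Rare path: split on invalid characters and scan each clean run.
        start = 0
        for i, ch in enumerate(seq):
            if ch not in "ACGT":
                if i - start >= k:
                    _scan_clean(seq[start:i], lookup, k, hits)
                start = i + 1
        if n - start >= k:
            _scan_clean(seq[start:], lookup, k, hits)
        return hits
    _scan_clean(seq, lookup, k, hits)
    return hits


def _scan_clean(seq: str, lookup, k: int, hits: dict[str, int]) -> None:
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        bwd = rc[n - k - i : n - i]
        key = fwd if fwd <= bwd else bwd
        if key in lookup:
            hits[key] = hits.get(key, 0) + 1


def count_sequences(
    seqs: Iterable[str], db: KmerDatabase, sample_id: str = "sample"
) -> FrequencyTable:
    """Accumulate canonical k-mer counts over an iterable of read sequences."""
    lookup = db.key_set()
    counts = dict.fromkeys(lookup, 0)
    n_reads = 0
    n_bases = 0
    k = db.k
    for seq in seqs:
        seq = seq.upper()
        n_reads += 1
        n_bases += len(seq)
        for key, inc in scan_sequence(seq, lookup, k).items():
            counts[key] += inc
    return FrequencyTable(
        sample_id=sample_id,
        counts=counts,
        n_reads_scanned=n_reads,
        n_bases_scanned=n_bases,
    )


def count_database_kmers(
    read_files: Iterable[str], db: KmerDatabase, sample_id: str = "sample"
) -> FrequencyTable:
    """Stream one or more FASTQ/FASTA files (plain or gzipped) and count.

    Multiple files accumulate into a single table; pairing information and
    quality strings are ignored.
    """
    from .io import read_reads  # local import to avoid a cycle

    return count_sequences(read_reads(read_files), db, sample_id=sample_id)


def table_as_vectors(
    table: FrequencyTable, db: KmerDatabase
) -> tuple[list[int], list[int], list[int]]:
    """Counts split into (gene, flank_5p, flank_3p) in database order."""
    missing = [r.canonical for r in db.all_records if r.canonical not in table.counts]
    if missing:
        raise ConfigError(
            f"frequency table missing {len(missing)} database k-mers "
            f"(first: {missing[0]})"
        )
    gene = [table.counts[r.canonical] for r in db.gene_kmers]
    f5 = [table.counts[r.canonical] for r in db.flank_kmers_5p]
    f3 = [table.counts[r.canonical] for r in db.flank_kmers_3p]
    return gene, f5, f3
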