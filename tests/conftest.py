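"""Shared fixtures: a scaled-down synthetic locus and hand-built toy tables.

The "small" locus (600 bp gene x 3 copies, 1.2 kb flanks, 6 kb background)
keeps unit tests fast; it exercises the same code paths as the full-size
default conditions used in the end-to-end accuracy tests.
"""

from __future__ import annotations

import itertools

import pytest

from kmercn._sequence import canonical
from kmercn.kmer_count import FrequencyTable
from kmercn.kmer_select import KmerDatabase, KmerRecord, build_database
from kmercn.simulate import SyntheticSpec, make_reference


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        seed=7,
        background_len=6_000,
        gene_len=600,
        n_ref_copies=3,
        flank_len=1_200,
        read_len=100,
        coverage=20.0,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_db(small_spec, small_reference) -> KmerDatabase:
    genome, regions = small_reference
    return build_database(genome, regions, gene_name="toy", n_flank=2000)


def _distinct_kmers(n: int, k: int = 25) -> list[str]:
    """Deterministic distinct k-mers whose canonical forms are distinct."""
    out: list[str] = []
    seen: set[str] = set()
    for combo in itertools.product("ACGT", repeat=8):
        if len(out) == n:
            break
        kmer = ("".join(combo) + "ACGTACGTACGTACGTA")[:k]
        c = canonical(kmer)
        if c not in seen:
            seen.add(c)
            out.append(kmer)
    assert len(out) == n
    return out


def make_toy_db(n_gene: int = 5, n_f5: int = 4, n_f3: int = 4) -> KmerDatabase:
    """Database with fabricated k-mers at consecutive fake coordinates."""
    kmers = _distinct_kmers(n_gene + n_f5 + n_f3)

    def rec(seq: str, pos: int, freq: int) -> KmerRecord:
        return KmerRecord(
            sequence=seq,
            canonical=canonical(seq),
            positions=(("chrT", pos, "+"),),
            gc_percent=100.0 * (seq.count("G") + seq.count("C")) / len(seq),
            genome_frequency=freq,
        )

    gene = [rec(s, 1000 + i, 1) for i, s in enumerate(kmers[:n_gene])]
    f5 = [rec(s, 100 + i, 1) for i, s in enumerate(kmers[n_gene : n_gene + n_f5])]
    f3 = [rec(s, 2000 + i, 1) for i, s in enumerate(kmers[n_gene + n_f5 :])]
    return KmerDatabase(
        gene_name="toy",
        k=25,
        n_ref_copies=1,
        gene_kmers=gene,
        flank_kmers_5p=f5,
        flank_kmers_3p=f3,
        mm1_applied=False,
        gc_bounds=(0.0, 100.0),
        provenance={"reference": "toy"},
    )


def make_table(db: KmerDatabase, gene_counts, f5_counts, f3_counts) -> FrequencyTable:
    counts = {}
    for recs, vals in (
        (db.gene_kmers, gene_counts),
        (db.flank_kmers_5p, f5_counts),
        (db.flank_kmers_3p, f3_counts),
    ):
        assert len(recs) == len(vals)
        for r, v in zip(recs, vals):
            counts[r.canonical] = v
    return FrequencyTable(sample_id="t", counts=counts, n_reads_scanned=1, n_bases_scanned=1)
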