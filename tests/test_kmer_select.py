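"""Database construction: extraction, intersection, uniqueness, GC, flanks."""

import warnings

import pytest

from kmercn._sequence import canonical
from kmercn.errors import ConfigError, CoordinateError
from kmercn.kmer_select import (
    build_genome_index,
    extract_region_kmers,
    filter_gc,
    filter_unique,
    intersect_copy_kmers,
)
from kmercn.regions import GENE_COPY, RegionSpec
from kmercn import io

from oracles import strand_collapsed_frequency, window_counter


def _region(start, end, chrom="chr1", role=GENE_COPY, label="r"):
    return RegionSpec(chrom, start, end, label, role)


class TestExtractRegionKmers:
    def test_window_count(self):
        import numpy as np

        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1024))
        genome = {"chr1": seq}
        recs = extract_region_kmers(genome, _region(0, 1024), 25)
        assert len(recs) == 1000
        assert recs[0].sequence == seq[:25]
        assert recs[0].positions == (("chr1", 0, "+"),)

    def test_short_periodic_region(self):
        genome = {"chr1": "ACGT" * 7}
        recs = extract_region_kmers(genome, _region(0, 28), 25)
        assert len(recs) == 4
        assert recs[0].sequence == "ACGTACGTACGTACGTACGTACGTA"

    def test_ambiguity_voids_overlapping_windows(self):
        import numpy as np

        rng = np.random.default_rng(1)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 200)))
        seq[100] = "N"
        genome = {"chr1": "".join(seq)}
        recs = extract_region_kmers(genome, _region(0, 200), 25)
        assert len(recs) == (200 - 25 + 1) - 25
        assert all("N" not in r.sequence for r in recs)

    def test_region_errors(self):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(CoordinateError):
            extract_region_kmers(genome, _region(0, 500), 25)
        with pytest.raises(CoordinateError):
            extract_region_kmers(genome, _region(0, 50, chrom="chrX"), 25)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert extract_region_kmers(genome, _region(0, 10), 25) == []
        assert any("shorter than k" in str(w.message) for w in caught)


class TestIntersectCopyKmers:
    def test_identical_copies_yield_single_copy_set(self, small_reference):
        genome, regions = small_reference
        copies = [r for r in regions if r.role == GENE_COPY]
        sets = [extract_region_kmers(genome, r, 25) for r in copies]
        inter = intersect_copy_kmers(sets)
        assert {r.canonical for r in inter} == {r.canonical for r in sets[0]}
        # positions merged from all three copies
        assert all(len(r.positions) == 3 for r in inter)

    def test_single_set_identity(self, small_reference):
        genome, regions = small_reference
        copy = next(r for r in regions if r.role == GENE_COPY)
        s = extract_region_kmers(genome, copy, 25)
        inter = intersect_copy_kmers([s])
        assert {r.canonical for r in inter} == {r.canonical for r in s}

    def test_substitution_excludes_overlapping_windows(self):
        import numpy as np

        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        mutated = seq[:150] + ("A" if seq[150] != "A" else "C") + seq[151:]
        genome = {"c1": seq, "c2": mutated}
        s1 = extract_region_kmers(genome, _region(0, 300, chrom="c1"), 25)
        s2 = extract_region_kmers(genome, _region(0, 300, chrom="c2"), 25)
        inter = intersect_copy_kmers([s1, s2])
        # exactly the 25 windows overlapping position 150 differ
        assert len(inter) == len(s1) - 25

    def test_mismatched_k_rejected(self):
        genome = {"chr1": "ACGTACGTACGT" * 10}
        s1 = extract_region_kmers(genome, _region(0, 60), 10)
        s2 = extract_region_kmers(genome, _region(0, 60), 12)
        with pytest.raises(ConfigError):
            intersect_copy_kmers([s1, s2])
        with pytest.raises(ConfigError):
            intersect_copy_kmers([])


class TestGenomeIndex:
    def test_palindromic_toy_example(self):
        index = build_genome_index({"s": "ACGTACGT"}, 4)
        assert index["ACGT"] >= 2

    def test_absent_kmer_is_zero(self):
        index = build_genome_index({"s": "ACGTACGT"}, 4)
        assert index.get("GGGG", 0) == 0

    def test_total_counts_conserved(self):
        genome = {"a": "ACGTNACGTACGT", "b": "TTTTACGT"}
        index = build_genome_index(genome, 4)
        n_valid = (4 - 4 + 1) + (8 - 4 + 1) + (8 - 4 + 1)  # runs split by N
        assert sum(index.values()) == n_valid

    def test_matches_bruteforce_oracle(self, small_reference):
        genome, _ = small_reference
        seqs = list(genome.values())
        index = build_genome_index(genome, 25)
        counter = window_counter(seqs, 25)
        # every indexed canonical count equals the two-strand scan count
        for kmer, count in list(index.items())[::97] + [("A" * 25, 0)]:
            expected = strand_collapsed_frequency(seqs, kmer)
            assert index.get(canonical(kmer), 0) == expected, kmer
        assert sum(index.values()) == sum(counter.values())

    def test_empty_genome_rejected(self):
        with pytest.raises(ConfigError):
            build_genome_index({}, 25)


class TestFilters:
    def _rec(self, seq, freq=0):
        from kmercn.kmer_select import KmerRecord

        return KmerRecord(
            sequence=seq,
            canonical=canonical(seq),
            positions=(("chr1", 0, "+"),),
            gc_percent=100.0 * (seq.count("G") + seq.count("C")) / len(seq),
            genome_frequency=freq,
        )

    def test_frequency_must_equal_copy_number(self):
        rec = self._rec("ACGTTGCAACGTTGCAACGTTGCAA")
        index = {rec.canonical: 3}
        assert filter_unique([rec], index, 3, mm1=False)
        assert not filter_unique([rec], dict(index, **{rec.canonical: 4}), 3, mm1=False)

    def test_mm1_neighbor_anywhere_disqualifies(self):
        seq = "ACGTTGCAACGTTGCAACGTTGCAA"
        rec = self._rec(seq)
        neighbor = "T" + seq[1:]
        index = {canonical(seq): 3, canonical(neighbor): 1}
        assert not filter_unique([rec], index, 3, mm1=True)
        kept = filter_unique([rec], index, 3, mm1=False)
        assert [r.canonical for r in kept] == [rec.canonical]
        assert kept[0].genome_frequency == 3

    def test_bad_copy_number_rejected(self):
        with pytest.raises(ConfigError):
            filter_unique([], {}, 0)

    def test_gc_bounds_inclusive(self):
        polyA = self._rec("A" * 25)
        mid = self._rec("G" * 12 + "A" * 13)  # 48%
        high = self._rec("G" * 17 + "A" * 8)  # 68%
        exactly20 = self._rec("G" * 5 + "A" * 20)  # 20%
        kept = filter_gc([polyA, mid, high, exactly20], 20, 65)
        seqs = {r.sequence for r in kept}
        assert seqs == {mid.sequence, exactly20.sequence}

    def test_gc_full_range_is_identity_and_commutes(self, small_reference):
        genome, regions = small_reference
        copies = [r for r in regions if r.role == GENE_COPY]
        cands = intersect_copy_kmers(
            [extract_region_kmers(genome, r, 25) for r in copies]
        )
        index = build_genome_index(genome, 25)
        assert {r.canonical for r in filter_gc(cands, 0, 100)} == {
            r.canonical for r in cands
        }
        a = filter_gc(filter_unique(cands, index, 3), 20, 65)
        b = filter_unique(filter_gc(cands, 20, 65), index, 3)
        assert [r.canonical for r in a] == [r.canonical for r in b]


class TestBuildDatabase:
    def test_database_invariants_on_synthetic_locus(self, small_db, small_reference):
        genome, _ = small_reference
        db = small_db
        assert db.n_ref_copies == 3
        assert db.gene_kmers, "gene set must not be empty"
        assert all(r.genome_frequency == 3 for r in db.gene_kmers)
        assert all(r.genome_frequency == 1 for r in db.flank_kmers)
        gene_keys = {r.canonical for r in db.gene_kmers}
        flank_keys = {r.canonical for r in db.flank_kmers}
        assert not gene_keys & flank_keys
        assert len(gene_keys) == len(db.gene_kmers)
        low, high = db.gc_bounds
        assert all(low <= r.gc_percent <= high for r in db.gene_kmers)

    def test_flank_counts_capped_by_target(self, small_db):
        assert len(small_db.flank_kmers_5p) == 1000
        assert len(small_db.flank_kmers_3p) == 1000

    def test_gene_frequencies_against_scan_oracle(self, small_db, small_reference):
        genome, _ = small_reference
        seqs = list(genome.values())
        for rec in small_db.gene_kmers[::37]:
            assert strand_collapsed_frequency(seqs, rec.sequence) == 3

    def test_rebuild_is_byte_identical(self, small_spec, small_reference, tmp_path):
        from kmercn.kmer_select import build_database

        genome, regions = small_reference
        paths = []
        for i in (1, 2):
            db = build_database(genome, regions, gene_name="toy", n_flank=2000)
            p = tmp_path / f"db{i}.tsv"
            io.write_kdb(db, str(p))
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_short_flank_warns(self, small_reference):
        from kmercn.kmer_select import build_database

        genome, regions = small_reference
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            build_database(genome, regions, gene_name="toy", n_flank=10_000)
        assert any("requested k-mers available" in str(w.message) for w in caught)

    def test_missing_roles_rejected(self, small_reference):
        from kmercn.kmer_select import build_database

        genome, regions = small_reference
        only_gene = [r for r in regions if r.role == GENE_COPY]
        with pytest.raises(ConfigError):
            build_database(genome, only_gene)
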