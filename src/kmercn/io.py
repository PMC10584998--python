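"""Readers and writers for every on-disk format the pipeline touches.

Conventions: user-facing coordinates are 1-based inclusive and converted at
this boundary only (everything in memory is 0-based half-open); gzip is
detected from magic bytes, never the file name; all writers are atomic
(write to a temporary file, rename into place) and emit deterministically
ordered output.
"""

from __future__ import annotations

import gzip
import json
import os
import tempfile
from contextlib import contextmanager
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError
from .kmer_count import FrequencyTable
from .kmer_select import KmerDatabase, KmerRecord
from .regions import ROLES, RegionSpec

GZIP_MAGIC = b"\x1f\x8b"


def xopen(path: str, mode: str = "rt"):
    """Open plain or gzipped text transparently (gzip sniffed from magic bytes)."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == GZIP_MAGIC:
            return gzip.open(path, mode)
        return open(path, mode)
    raise ValueError("xopen is read-only; use atomic_write for output")


@contextmanager
def atomic_write(path: str, gzipped: bool = False):
    """Write to a temp file in the target directory, rename on success."""
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp.", suffix="~")
    os.close(fd)
    try:
        fh = gzip.open(tmp, "wt") if gzipped else open(tmp, "w")
        try:
            yield fh
        finally:
            fh.close()
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Stream (id, upper-cased sequence) records; id is taken up to the
    first whitespace."""
    with xopen(path) as fh:
        n = 0
        for record in SeqIO.parse(fh, "fasta"):
            n += 1
            yield record.id, str(record.seq).upper()
        if n == 0:
            raise FormatError(f"{path}: no FASTA records found")


def load_fasta(path: str) -> dict[str, str]:
    genome: dict[str, str] = {}
    for name, seq in read_fasta(path):
        if name in genome:
            raise FormatError(f"{path}: duplicate sequence id {name!r}")
        genome[name] = seq
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with atomic_write(path) as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads(paths: Iterable[str] | str) -> Iterator[str]:
    """Stream read sequences from FASTQ or FASTA files (plain or gzipped).

    Multiple files are chained; ids and qualities are discarded. Malformed
    records raise :class:`FormatError` naming the file and record index.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    for path in paths:
        with xopen(path) as fh:
            first = fh.read(1)
            if not first:
                continue  # empty file: zero reads, no error
            fh.seek(0)
            if first == ">":
                for _, seq in _fasta_reads(fh, path):
                    yield seq
            elif first == "@":
                idx = 0
                try:
                    for _title, seq, _qual in FastqGeneralIterator(fh):
                        idx += 1
                        yield seq.upper()
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: malformed FASTQ near record {idx + 1}: {exc}"
                    ) from exc
            else:
                raise FormatError(
                    f"{path}: not FASTA or FASTQ (starts with {first!r})"
                )


def _fasta_reads(fh, path: str) -> Iterator[tuple[str, str]]:
    for record in SeqIO.parse(fh, "fasta"):
        yield record.id, str(record.seq).upper()


# ---------------------------------------------------------------------------
# Region configuration

_REGION_COLUMNS = ["gene", "role", "chrom", "start", "end"]


def read_regions(path: str) -> dict[str, list[RegionSpec]]:
    """Region configuration: TSV or JSON, 1-based inclusive coordinates.

    Returns a mapping gene name -> region list, in file order.
    """
    with xopen(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head in ("[", "{"):
            entries = json.load(fh)
            if isinstance(entries, dict):
                entries = entries.get("regions", [])
            df = pd.DataFrame(entries)
        else:
            df = pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(_REGION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing region columns {sorted(missing)}")
    out: dict[str, list[RegionSpec]] = {}
    for row in df.itertuples(index=False):
        role = str(row.role)
        if role not in ROLES:
            raise FormatError(f"{path}: unknown role {role!r}")
        start1, end1 = int(row.start), int(row.end)
        if start1 < 1 or end1 < start1:
            raise FormatError(f"{path}: bad 1-based interval {start1}-{end1}")
        out.setdefault(str(row.gene), []).append(
            RegionSpec(str(row.chrom), start1 - 1, end1, f"{row.gene}:{role}", role)
        )
    return out


def write_regions(regions: list[RegionSpec], gene: str, path: str) -> None:
    with atomic_write(path) as fh:
        fh.write("\t".join(_REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(f"{gene}\t{r.role}\t{r.chrom}\t{r.start + 1}\t{r.end}\n")


# ---------------------------------------------------------------------------
# K-mer database TSV

_KDB_COLUMNS = ["kmer", "canonical", "type", "chrom", "pos", "gc_percent", "genome_frequency"]


def write_kdb(db: KmerDatabase, path: str) -> None:
    """Serialize a database with '#key=value' metadata lines, then one row
    per k-mer; multi-copy positions are 'chrom:pos' joined by ';' (1-based)."""
    with atomic_write(path) as fh:
        fh.write(f"#gene={db.gene_name}\n")
        fh.write(f"#k={db.k}\n")
        fh.write(f"#n_ref_copies={db.n_ref_copies}\n")
        fh.write(f"#gc_bounds={db.gc_bounds[0]:g},{db.gc_bounds[1]:g}\n")
        fh.write(f"#mm1={'true' if db.mm1_applied else 'false'}\n")
        fh.write(f"#reference={db.provenance.get('reference', 'unknown')}\n")
        fh.write(f"#regions={json.dumps(db.provenance.get('regions', []))}\n")
        fh.write("\t".join(_KDB_COLUMNS) + "\n")
        for rtype, records in (
            ("gene", db.gene_kmers),
            ("flank_5p", db.flank_kmers_5p),
            ("flank_3p", db.flank_kmers_3p),
        ):
            for rec in records:
                pos_str = ";".join(f"{c}:{p + 1}" for c, p, _ in rec.positions)
                fh.write(
                    f"{rec.sequence}\t{rec.canonical}\t{rtype}\t"
                    f"{rec.first_position[0]}\t{pos_str}\t{rec.gc_percent}\t"
                    f"{rec.genome_frequency}\n"
                )


def read_kdb(path: str) -> KmerDatabase:
    meta: dict[str, str] = {}
    gene: list[KmerRecord] = []
    f5: list[KmerRecord] = []
    f3: list[KmerRecord] = []
    seen: set[str] = set()
    with xopen(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if not header_seen:
                if line.split("\t") != _KDB_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: unexpected column header")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(_KDB_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_KDB_COLUMNS)} columns")
            kmer, canon, rtype, _chrom, pos_str, gc_str, freq_str = fields
            if "k" in meta and len(kmer) != int(meta["k"]):
                raise FormatError(
                    f"{path}:{lineno}: k-mer length {len(kmer)} != k={meta['k']}"
                )
            if canon in seen:
                raise FormatError(f"{path}:{lineno}: duplicate k-mer {kmer}")
            seen.add(canon)
            positions = []
            for token in pos_str.split(";"):
                chrom, _, p = token.rpartition(":")
                positions.append((chrom, int(p) - 1, "+"))
            rec = KmerRecord(
                sequence=kmer,
                canonical=canon,
                positions=tuple(positions),
                gc_percent=float(gc_str),
                genome_frequency=int(freq_str),
            )
            if rtype == "gene":
                gene.append(rec)
            elif rtype == "flank_5p":
                f5.append(rec)
            elif rtype == "flank_3p":
                f3.append(rec)
            else:
                raise FormatError(f"{path}:{lineno}: unknown k-mer type {rtype!r}")
    for key in ("k", "n_ref_copies"):
        if key not in meta:
            raise FormatError(f"{path}: missing '#{key}=' metadata line")
    low, _, high = meta.get("gc_bounds", "20,65").partition(",")
    regions = json.loads(meta.get("regions", "[]"))
    return KmerDatabase(
        gene_name=meta.get("gene", "unknown"),
        k=int(meta["k"]),
        n_ref_copies=int(meta["n_ref_copies"]),
        gene_kmers=gene,
        flank_kmers_5p=f5,
        flank_kmers_3p=f3,
        mm1_applied=meta.get("mm1", "true") == "true",
        gc_bounds=(float(low), float(high)),
        provenance={
            "reference": meta.get("reference", "unknown"),
            "regions": [tuple(r) for r in regions],
        },
    )


# ---------------------------------------------------------------------------
# Counts / estimates / profiles


def write_counts(table: FrequencyTable, db: KmerDatabase, path: str) -> None:
    types = db.type_of()
    with atomic_write(path) as fh:
        fh.write(f"#sample_id={table.sample_id}\n")
        fh.write(f"#n_reads_scanned={table.n_reads_scanned}\n")
        fh.write(f"#n_bases_scanned={table.n_bases_scanned}\n")
        fh.write("kmer\ttype\tchrom\tpos\tcount\n")
        for rec in db.all_records:
            chrom, pos, _ = rec.first_position
            fh.write(
                f"{rec.canonical}\t{types[rec.canonical]}\t{chrom}\t{pos + 1}\t"
                f"{table.counts[rec.canonical]}\n"
            )


def read_counts(path: str) -> FrequencyTable:
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if line.startswith("kmer\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            counts[fields[0]] = int(fields[4])
    return FrequencyTable(
        sample_id=meta.get("sample_id", "sample"),
        counts=counts,
        n_reads_scanned=int(meta.get("n_reads_scanned", 0)),
        n_bases_scanned=int(meta.get("n_bases_scanned", 0)),
    )


def write_estimate_tsv(estimates, path: str, ploidy: int = 2) -> None:
    """One row per CopyNumberEstimate; the tie rule is logged so integer
    calls can be audited."""
    if not isinstance(estimates, (list, tuple)):
        estimates = [estimates]
    with atomic_write(path) as fh:
        fh.write(f"#ploidy={ploidy}\n")
        fh.write("#rounding=nearest-integer, .5 away from zero\n")
        fh.write(
            "gene\tsample\tn_gene_kmers\tn_flank_kmers\tmedian_gene\t"
            "median_flank\tcn_decimal\tcn_integer\twarnings\n"
        )
        for e in estimates:
            fh.write(
                f"{e.gene_name}\t{e.sample_id}\t{e.n_gene_kmers}\t"
                f"{e.n_flank_kmers}\t{e.median_gene_freq:g}\t"
                f"{e.median_flank_freq:g}\t{e.cn_decimal:.4f}\t{e.cn_integer}\t"
                f"{'; '.join(e.warnings) if e.warnings else '.'}\n"
            )


def estimate_as_dict(e) -> dict:
    return {
        "gene": e.gene_name,
        "sample": e.sample_id,
        "n_gene_kmers": e.n_gene_kmers,
        "n_flank_kmers": e.n_flank_kmers,
        "median_gene_freq": e.median_gene_freq,
        "median_flank_freq": e.median_flank_freq,
        "cn_decimal": round(e.cn_decimal, 4),
        "cn_integer": e.cn_integer,
        "warnings": e.warnings,
    }


def write_profile_tsv(profile, path: str) -> None:
    rows = profile.rows.copy()
    rows["pos"] = rows["pos"] + 1  # 1-based for users
    with atomic_write(path) as fh:
        fh.write(f"#gene={profile.gene_name}\n")
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#cn_decimal={profile.cn_decimal:.4f}\n")
        rows.to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path: str):
    """(rows DataFrame with 0-based pos, metadata dict)."""
    import io as _stdio

    meta: dict[str, str] = {}
    body: list[str] = []
    with xopen(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].rstrip("\n").partition("=")
                meta[key] = val
            else:
                body.append(line)
    rows = pd.read_csv(_stdio.StringIO("".join(body)), sep="\t")
    rows["pos"] = rows["pos"] - 1
    return rows, meta


def write_fastq(reads, path: str) -> None:
    """Write (name, sequence, quality) tuples; gzipped when path ends .gz."""
    with atomic_write(path, gzipped=path.endswith(".gz")) as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader for exon shading: (chrom, start, end, name)."""
    out = []
    with xopen(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line with <3 fields")
            name = fields[3] if len(fields) > 3 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out
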