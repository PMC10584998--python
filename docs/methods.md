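# Methods

## Model

`kmercn` estimates the total copy number (CN) of a target gene in one
sequenced individual without alignment. The signal is the frequency of
carefully chosen 25-mers in the raw reads:

* **Gene k-mers** occur in the reference exactly `n_ref` times — once per
  reference copy of the gene — and nowhere else. In a sample their read
  frequency is proportional to (sample copy number) × (depth of coverage
  per copy).
* **Flank k-mers** are single-copy k-mers from the regions flanking the
  gene cluster. Their read frequency is proportional to the local diploid
  depth of coverage.

The estimator is a median ratio:

```
CN = ploidy × median(gene k-mer counts) / median(flank k-mer counts)
```

with ploidy 2 by default. Decimal CN is reported as-is; the integer call
rounds to the nearest integer, with exact .5 ties rounded away from zero
(the tie rule is logged in every output so calls can be audited). Medians
make the estimate robust to individual k-mer dropout and off-target hits;
the ratio cancels overall sequencing depth, which is why estimates agree
across coverages and across short-read/long-read technologies — sequencing
errors thin gene and flank counts by the same per-window survival factor
(1 − e)^k, so they cancel too.

## K-mer selection

For each gene, candidate 25-mers are extracted by a sliding window from
every reference copy of the gene; the per-copy sets are intersected
(canonically, i.e. strand-collapsed) so only k-mers present in *all*
copies survive. Filters then require:

1. **Uniqueness**: the k-mer's strand-collapsed frequency in the whole
   reference equals `n_ref` (the gene's reference copy count).
2. **Hamming-1 isolation** (optional, on by default): no sequence at
   Hamming distance 1 from the k-mer or its reverse complement occurs
   anywhere in the reference. A k-mer violating this is one sequencing
   error away from off-target sequence. Substitution neighbors only;
   indel neighbors are not enumerated — the filter models mismatches, and
   single indels in reads shift the frame so rarely into a database hit
   that the extra cost is not justified.
3. **GC content** within [20, 65] percent, bounds inclusive (extreme-GC
   k-mers have biased representation in real libraries). Flank k-mers are
   GC-filtered with the same bounds, so numerator and denominator carry
   the same selection bias, if any.

Flank k-mers must be single-copy (frequency 1) and are chosen nearest the
gene boundary first, half from each side; the default target is 2000
total, the recommended minimum. A canonical k-mer qualifying for both the
gene and a flank set is assigned to the gene set (the sets are disjoint by
construction). All outputs are sorted by (chrom, position, sequence), so
rebuilding a database from the same inputs is byte-identical.

For a pair of near-identical paralogs, two kinds of database are useful:
per-variant databases (one `gene_copy` region, built *without* the
Hamming-1 filter, since every variant-discriminating k-mer is by
definition one substitution from the other paralog) and a combined
database listing both genes as copies of one unit, which keeps the
thousands of shared k-mers and genotypes the total CN of the pair.

## Counting

Reads are streamed one record at a time (FASTQ or FASTA, gzip sniffed
from magic bytes); every 25-window is collapsed to its canonical form and
counted if it is a database key. No quality filtering, no pairing logic,
no error correction: long noisy reads go through the identical loop.
Windows containing non-ACGT characters are skipped. Counts are invariant
to read order, to splitting reads across files, and to
reverse-complementing reads, and are additive across read sets; the test
suite verifies all of these plus exact agreement with a brute-force
substring scanner built on independent primitives.

## Estimation details

* 5' and 3' flank counts are pooled into a single median (one
  denominator). A warning is emitted when the per-side medians differ by
  more than 25% of the pooled median — a CNV inside a flank would bias
  the baseline.
* A warning marks estimates from fewer than 500 gene k-mers (configurable).
  Per-variant paralog databases typically fall far below this; their calls
  are reported but flagged.
* `cn_decimal` is computed as the median of the per-k-mer normalized
  values (ploidy × count / flank median), which is mathematically the
  median ratio above and makes the normalized profile's gene median equal
  the reported CN bit-for-bit.
* Zero flank median is a hard error (no coverage baseline); zero gene
  median is a valid homozygous-deletion call (CN 0).
* Even-length medians use the mean of the two central order statistics.

The per-k-mer normalized profile (position, raw count, normalized value)
is exported for plotting; a step in the gene panel localizes a
duplication breakpoint inside the gene. Breakpoint calling is left to
visual inspection: the integer call follows the median-determining
majority segment of the gene.

No regression recalibration of high copy numbers is applied; the decimal
estimate is reported unchanged. If a user has matched experimental calls,
a post-hoc linear correction can be fitted with ordinary least squares on
the decimal values, but it is deliberately not part of the estimator.

## Synthetic data

The simulator emulates a tandem multi-copy locus in unique background:

| parameter | default | meaning |
|---|---|---|
| `gene_len` | 4 000 bp | length of the repeated unit |
| `n_ref_copies` | 3 | copies in the reference |
| `flank_len` | 24 000 bp | flank span per side |
| `background_len` | 60 000 bp | unique sequence incl. flanks |
| `read_len` / `coverage` / `error_rate` | 150 bp / 30× / 0.1% | Illumina-like regime |

Long-read regimes are the same generator with `read_len=2000,
error_rate=0.05` (Nanopore-like) or `read_len=2000, error_rate≈0.01`
(PacBio-like). Reads have uniform start positions and strands, i.i.d.
substitution errors, constant quality strings; a single master seed
drives per-stage substreams so stages can be re-run independently.

An individual is simulated as a **diploid pair of sequences**: one
haplotype carries all the variable gene copies in tandem, the other only
background. This makes the flank k-mer frequency a true diploid baseline
— with a single haplotype, ploidy-2 normalization could only ever produce
even CNs. Since copies are identical, putting them on one haplotype is
without loss of generality. Reads never span the boundary between the two
haplotype sequences.

The flanks are deliberately wide. The flank median is a sample statistic
of the depth field, and its sampling variance shrinks with the genomic
span it averages over, not just the number of k-mers; with short flanks
the baseline noise alone exceeds half a copy at CN ≥ 10. The 24 kb
default per side keeps the CN-12 estimate's spread near 0.1 copies at
30×, mirroring the practical advice that flanking regions for real genes
need to be rather large. Recovery sweeps share one reference and database
across trials and redraw only the reads — read sampling is the stochastic
process under test.

What the simulator does **not** model: platform-specific error profiles
(homopolymer indels, quality-dependent errors), GC-dependent coverage
bias, library insert-size structure, mappability structure of real
genomes, and population haplotype diversity. Passing the synthetic sweeps
therefore demonstrates correctness of the selection/counting/estimation
machinery and the estimator's statistical behavior, not robustness to
every real-data artifact; the GC filter, for instance, is nearly inert on
uniform-random sequence (GC ≈ 50%) but load-bearing on real genomes.

## Numerical and design choices

* Canonical form = lexicographic min of k-mer and reverse complement; all
  counting (reference and reads) is strand-collapsed. Odd k guarantees no
  palindromes.
* Coordinates are 0-based half-open in memory, 1-based inclusive in every
  file and log; conversion lives in the I/O layer only.
* Multi-copy gene k-mers keep positions in every copy; profiles plot them
  at the first-copy coordinate.
* Windows containing ambiguity codes are void everywhere (reference
  index, region extraction, read scanning).
* Writers are atomic (temp file + rename): a failed run never leaves a
  truncated output.
* Problem sizes in the validation suite (60 kb background, 20 trials per
  CN, ≤ 1 Mb oracle references) were chosen so a full run completes in
  minutes on one CPU while leaving each statistical check well-powered.

## Known limitations

* Per-variant calls for paralog pairs at ~99.9% identity rest on tens of
  k-mers and are low-confidence by construction; the combined database is
  the reliable quantity, with per-variant calls as a flagged supplement.
* The Hamming-1 filter does not consider indel neighbors.
* No confidence intervals on CN; the decimal/integer pair plus warnings
  is the full output.
* Flank selection has no exclusion radius around unannotated segmental
  duplications abutting the gene; if a flank harbors hidden copy-variable
  sequence the divergence warning is the only guard.
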