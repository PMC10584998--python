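"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the package's translate-based canonical machinery:
reverse complements come from Bio.Seq and occurrence counting from
str.find, so agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

from collections import Counter

from Bio.Seq import Seq


def bio_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrences of needle in haystack via str.find."""
    n = 0
    start = haystack.find(needle)
    while start != -1:
        n += 1
        start = haystack.find(needle, start + 1)
    return n


def strand_collapsed_frequency(sequences: list[str], kmer: str) -> int:
    """Occurrences of a k-mer on either strand over a set of sequences.

    Counts forward occurrences of the k-mer plus forward occurrences of its
    reverse complement (equivalent to scanning both strands and collapsing
    canonically, for non-palindromic k-mers — guaranteed for odd k).
    """
    rc = bio_revcomp(kmer)
    assert rc != kmer
    total = 0
    for seq in sequences:
        total += count_occurrences(seq, kmer)
        total += count_occurrences(seq, rc)
    return total


def window_counter(sequences: list[str], k: int) -> Counter:
    """Counter of every valid forward k-window over a set of sequences."""
    counts: Counter = Counter()
    valid = set("ACGT")
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if not set(w) - valid:
                counts[w] += 1
    return counts
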