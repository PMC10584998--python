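"""Low-level DNA string primitives: complement, canonical form, GC, Hamming balls.

Everything operates on upper-case ACGT strings; windows containing any other
character are considered void by callers.
"""

from __future__ import annotations

from .errors import ConfigError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGT")
_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    Collapses strand: a k-mer and its reverse complement map to the same
    representative, which is how both reference counting and read counting
    are keyed throughout the package.
    """
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def gc_percent(seq: str) -> float:
    """GC content as a percentage in [0, 100]."""
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def is_acgt(seq: str) -> bool:
    return not set(seq) - VALID_BASES


def hamming_neighbors(kmer: str) -> set[str]:
    """All strings at Hamming distance exactly 1 from ``kmer``.

    The input itself is excluded; for a k-mer of length k there are exactly
    3k neighbors. Raises :class:`ConfigError` on ambiguity codes.
    """
    if not is_acgt(kmer):
        raise ConfigError(f"ambiguity code in k-mer {kmer!r}")
    out: set[str] = set()
    for i, base in enumerate(kmer):
        prefix, suffix = kmer[:i], kmer[i + 1 :]
        for alt in _ALPHABET:
            if alt != base:
                out.add(prefix + alt + suffix)
    return out
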