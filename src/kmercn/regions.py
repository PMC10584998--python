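"""Genomic region descriptions for target genes and their flanks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ConfigError, CoordinateError

GENE_COPY = "gene_copy"
FLANK_5P = "flank_5p"
FLANK_3P = "flank_3p"
ROLES = (GENE_COPY, FLANK_5P, FLANK_3P)


@dataclass(frozen=True, slots=True)
class RegionSpec:
    """A labeled genomic interval, 0-based half-open internally.

    User-facing files use 1-based inclusive coordinates; conversion happens
    in :mod:`kmercn.io` only.
    """

    chrom: str
    start: int
    end: int
    label: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown region role {self.role!r}")
        if not (0 <= self.start < self.end):
            raise ConfigError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, genome: Mapping[str, str]) -> None:
        """Check the interval fits inside the reference it will be cut from."""
        if self.chrom not in genome:
            raise CoordinateError(f"sequence {self.chrom!r} not in reference")
        if self.end > len(genome[self.chrom]):
            raise CoordinateError(
                f"{self.chrom}:{self.start}-{self.end} exceeds sequence "
                f"length {len(genome[self.chrom])}"
            )
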