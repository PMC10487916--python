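"""Genomic intervals in 1-based inclusive coordinates.

Every coordinate that moves through the pipeline — array probes, cytobands,
gene and miRNA annotations, aberration calls — is expressed as a 1-based
inclusive span, the convention used by cytogenetic region tables (size =
stop - start + 1).  BED input, which is 0-based half-open, is converted at
the I/O boundary (see :mod:`mircna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous chromosomal span, 1-based and inclusive at both ends."""

    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise ValueError(
                f"stop ({self.stop}) must be >= start ({self.start})"
            )

    @property
    def size(self) -> int:
        return self.stop - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.stop
            and other.start <= self.stop
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of base pairs shared by the two intervals (0 if disjoint)."""
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.stop, other.stop) - max(self.start, other.start) + 1)


def interval_size(interval: GenomicInterval) -> int:
    """Size in base pairs of a 1-based inclusive interval (stop - start + 1)."""
    return interval.size
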