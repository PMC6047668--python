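"""Shared coordinate, coverage-track, and parameter types.

Coordinates are 0-based half-open (BED convention) throughout; the center of
an interval is ``floor((start + end) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterator, Mapping

import numpy as np

MARKS = ("H3K4me2", "H3K4me3", "H3K27ac")


class CompositionClass(str, Enum):
    """Flanking-sequence composition planted around a synthetic peak."""

    GC_RICH = "GC_RICH"
    AT_RICH = "AT_RICH"
    WCGW_SEEDED = "WCGW_SEEDED"
    NEUTRAL = "NEUTRAL"


class ChromatinState(str, Enum):
    PROMOTER = "PROMOTER"
    ENHANCER = "ENHANCER"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class CoverageTrack:
    """Fixed-width binned signal for one histone mark in one condition.

    Parameters
    ----------
    data
        Mapping of contig name to a 1-D array of non-negative bin values.
        Bin ``i`` covers bases ``[i * bin_size, (i + 1) * bin_size)``.
    bin_size
        Bin width in bases.
    library_total
        Summed raw signal used for per-million normalization. Computed from
        ``data`` when omitted.
    """

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        bin_size: int,
        library_total: float | None = None,
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for contig, values in self.data.items():
            if values.ndim != 1:
                raise ValueError(f"track for {contig} must be 1-D")
            if np.any(values < 0):
                raise ValueError(f"negative signal values on {contig}")
        self.bin_size = int(bin_size)
        if library_total is None:
            library_total = float(sum(v.sum() for v in self.data.values()))
        self.library_total = float(library_total)

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self.data)

    def contig_length(self, contig: str) -> int:
        return len(self.data[contig]) * self.bin_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.contigs == other.contigs
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.data)
        )

    def __repr__(self) -> str:
        return (
            f"CoverageTrack({len(self.data)} contig(s), bin_size={self.bin_size}, "
            f"library_total={self.library_total:g})"
        )


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with field-level defaults.

    ``fold_threshold`` (3.0) and ``secondary_fold_threshold`` (1.5) gate
    region calling; ``half_width`` (250 bp) sets the sequence window around
    peak centers; ``promoter_tss_distance`` (2 kb) anchors promoter calls to
    annotated TSSs; ``pseudocount`` (1 signal-per-million) stabilizes fold
    changes at low coverage.
    """

    fold_threshold: float = 3.0
    secondary_fold_threshold: float = 1.5
    half_width: int = 250
    kmer_lengths: frozenset[int] = field(default_factory=lambda: frozenset({4, 6}))
    top_n: int = 10
    promoter_tss_distance: int = 2000
    pseudocount: float = 1.0
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        self.kmer_lengths = frozenset(int(k) for k in self.kmer_lengths)
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not self.kmer_lengths <= frozenset(range(1, 13)):
            raise ValueError("kmer_lengths must be within 1..12")
        if self.strand_mode not in ("forward", "both"):
            raise ValueError("strand_mode must be 'forward' or 'both'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown analysis parameter(s): {sorted(unknown)}")
        return cls(**dict(mapping))


def iter_contig_bins(track: CoverageTrack) -> Iterator[tuple[str, int, int, float]]:
    """Yield (contig, start, end, value) per bin, in coordinate order."""
    for contig, values in track.data.items():
        for i, v in enumerate(values):
            yield contig, i * track.bin_size, (i + 1) * track.bin_size, float(v)
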