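"""Core data carriers shared by every analysis stage.

Coordinate conventions
----------------------
Annotation records (:class:`Origin`, :class:`GeneAnnotation`) use 1-based
closed coordinates, matching GFF3 and the origin tables the pipeline consumes.
Binned tracks are 0-based internally: position ``p`` (1-based) falls in bin
``(p - 1) // bin_size``.  All conversions happen through
:meth:`GenomicTrack.bin_index`; nothing else converts coordinates.

Missing data are carried as NaN and propagated, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["GenomicTrack", "Origin", "GeneAnnotation", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input record or track violates its contract."""


@dataclass
class GenomicTrack:
    """Per-chromosome binned numeric signal with a fixed bin size.

    The universal carrier for read coverage, copy number, ChIP and damage
    signals.  ``data`` maps chromosome name to a float array with one value
    per bin (the last bin may cover a partial window); NaN marks missing bins.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin holding 1-based position ``pos``."""
        idx = (pos - 1) // self.bin_size
        if not 0 <= idx < self.n_bins(chrom):
            raise ValidationError(
                f"position {pos} outside chromosome {chrom!r} "
                f"({self.n_bins(chrom)} bins of {self.bin_size} bp)"
            )
        return idx

    def same_binning(self, other: "GenomicTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chromosomes == other.chromosomes
            and all(self.n_bins(c) == other.n_bins(c) for c in self.data)
        )

    def require_same_binning(self, other: "GenomicTrack") -> None:
        if not self.same_binning(other):
            raise ValidationError(
                f"binning mismatch between {self.label or 'track'} and "
                f"{other.label or 'track'}"
            )

    def copy_like(self, data: Mapping[str, np.ndarray], label: str = "") -> "GenomicTrack":
        """New track with this track's binning and the given per-chrom arrays."""
        return GenomicTrack(self.bin_size, dict(data), label=label or self.label)

    def values(self) -> np.ndarray:
        """All bin values concatenated in chromosome order."""
        return np.concatenate([self.data[c] for c in self.data]) if self.data else np.array([])

    def total(self) -> float:
        """Genome-wide sum over non-missing bins."""
        return float(np.nansum(self.values()))

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.data.items())


@dataclass(frozen=True)
class Origin:
    """Annotated replication origin.

    ``t_rep`` is the origin's average replication time (minutes) in an
    unperturbed S phase; small values mark early origins.  ``status`` follows
    OriDB-style vocabulary.
    """

    id: str
    chrom: str
    pos: int
    t_rep: float
    status: str = "confirmed"

    _STATUSES = frozenset({"confirmed", "likely", "dormant"})

    def __post_init__(self) -> None:
        if self.t_rep <= 0:
            raise ValidationError(f"origin {self.id}: t_rep must be > 0, got {self.t_rep}")
        if self.pos < 1:
            raise ValidationError(f"origin {self.id}: position must be >= 1, got {self.pos}")
        if self.status not in self._STATUSES:
            raise ValidationError(
                f"origin {self.id}: unknown status {self.status!r} "
                f"(expected one of {sorted(self._STATUSES)})"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene with strand, 1-based closed coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
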