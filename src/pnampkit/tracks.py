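"""Binned genomic tracks, intervals and alignment records.

The whole pipeline works on fixed-width bins (100 bp by default, matching
strand-specific ribonucleotide-cleavage count tables).  A :class:`BinnedTrack`
carries one value per bin plus a boolean mask; masked bins (repeats such as Ty
elements or tandem gene arrays) are excluded from every sum, mean and
normalization downstream.  Coordinates are 0-based half-open everywhere
internally; a position ``p`` belongs to bin ``floor(p / bin_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

Strand = Literal["watson", "crick", "unstranded"]

_VALID_STRANDS = ("watson", "crick", "unstranded")


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin values with a strand label and mask.

    Parameters
    ----------
    chrom
        Chromosome name.
    bin_size
        Bin width in base pairs (> 0).
    values
        One value per bin, ordered by bin coordinate.
    strand
        ``"watson"``, ``"crick"`` or ``"unstranded"``.
    mask
        Per-bin boolean; ``True`` marks a bin excluded from computation.
    chrom_length
        Optional chromosome length in bp.  When given it must satisfy
        ``len(values) == ceil(chrom_length / bin_size)``; the final bin may be
        truncated (shorter than ``bin_size``).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    strand: Strand = "unstranded"
    mask: Optional[np.ndarray] = None
    chrom_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {self.bin_size}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have the same length")
        if self.chrom_length is not None:
            expected = math.ceil(self.chrom_length / self.bin_size)
            if len(self.values) != expected:
                raise ValueError(
                    f"{len(self.values)} bins inconsistent with chrom_length "
                    f"{self.chrom_length} at bin_size {self.bin_size} "
                    f"(expected {expected})"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def last_bin_truncated(self) -> bool:
        """True when the chromosome length is not a multiple of bin_size."""
        if self.chrom_length is None:
            return False
        return self.chrom_length % self.bin_size != 0

    def bin_of(self, position: int) -> int:
        """Bin index of a base-pair position (0-based)."""
        if position < 0:
            raise ValueError(f"negative position {position}")
        return position // self.bin_size

    def bin_start(self, index: int) -> int:
        return index * self.bin_size

    def bin_centers(self) -> np.ndarray:
        """Midpoint coordinate of every bin (truncated last bin included)."""
        starts = np.arange(self.n_bins) * self.bin_size
        ends = starts + self.bin_size
        if self.chrom_length is not None:
            ends = np.minimum(ends, self.chrom_length)
        return (starts + ends) / 2.0

    # -- mask-aware statistics --------------------------------------------
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def unmasked_sum(self) -> float:
        return float(self.values[~self.mask].sum())

    def unmasked_mean(self) -> float:
        unmasked = self.values[~self.mask]
        if unmasked.size == 0:
            raise ValueError("all bins masked")
        return float(unmasked.mean())

    # -- derivation helpers ------------------------------------------------
    def with_values(
        self, values: np.ndarray, mask: Optional[np.ndarray] = None
    ) -> "BinnedTrack":
        """New track on the same grid; masks propagate (OR with existing)."""
        new_mask = self.mask.copy()
        if mask is not None:
            new_mask |= np.asarray(mask, dtype=bool)
        return replace(self, values=np.asarray(values, dtype=float), mask=new_mask)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )

    def copy(self) -> "BinnedTrack":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


def require_same_grid(*tracks: BinnedTrack) -> None:
    first = tracks[0]
    for other in tracks[1:]:
        if not first.same_grid(other):
            raise ValueError(
                f"tracks on different grids: {first.chrom}/{first.bin_size}bp/"
                f"{first.n_bins} bins vs {other.chrom}/{other.bin_size}bp/"
                f"{other.n_bins} bins"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """A single-end placement with Bowtie2-style AS/XS scores.

    ``primary_score`` is the score of the reported placement (AS) and
    ``secondary_score`` that of the next-best placement (XS), absent for
    uniquely aligned reads.  ``five_prime_pos`` is the 5' end of read 1,
    i.e. the alkaline-cleavage position in a Pu-seq library.
    """

    read_id: str
    chrom: str
    five_prime_pos: int
    strand: Strand
    primary_score: Optional[float] = None
    secondary_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError(f"negative position for read {self.read_id}")
        if self.strand not in ("watson", "crick"):
            raise ValueError("alignment strand must be watson or crick")


def mask_intervals(
    track: BinnedTrack, repeats: Iterable[GenomicInterval]
) -> BinnedTrack:
    """Mask every bin overlapping any interval by at least 1 bp.

    Values are untouched; the operation is idempotent and order-independent.
    Intervals on a different chromosome, or extending past the chromosome
    end when the track knows its length, are rejected.
    """
    out = track.copy()
    chrom_end = (
        track.chrom_length
        if track.chrom_length is not None
        else track.n_bins * track.bin_size
    )
    for iv in repeats:
        if iv.chrom != track.chrom:
            raise ValueError(
                f"interval on {iv.chrom}, track on {track.chrom}"
            )
        if iv.end > chrom_end:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) outside chromosome "
                f"(length {chrom_end})"
            )
        first = iv.start // track.bin_size
        last = (iv.end - 1) // track.bin_size  # inclusive; >=1 bp overlap
        out.mask[first : last + 1] = True
    return out
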