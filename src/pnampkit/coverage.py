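"""Read-depth based copy-number estimation.

Whole-genome long-read coverage of a clone carrying extra tandem copies of a
segment piles the copies onto the single reference copy, so the normalized
read count over the segment approximates its copy number.  Normalization
divides each position's count by the average count of the entire genome
(masked repeat positions excluded from the average).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .tracks import GenomicInterval


@dataclass
class CoverageTrack:
    """Per-base (or binned) read counts over one chromosome/genome."""

    chrom: str
    values: np.ndarray
    mask: Optional[np.ndarray] = None
    step: int = 1  # bp per value; 1 = per-nucleotide

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have the same length")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    def mask_intervals(self, repeats: Iterable[GenomicInterval]) -> "CoverageTrack":
        out = replace(self, values=self.values.copy(), mask=self.mask.copy())
        for iv in repeats:
            if iv.chrom != self.chrom:
                raise ValueError(f"interval on {iv.chrom}, track on {self.chrom}")
            first = iv.start // self.step
            last = (iv.end - 1) // self.step
            out.mask[first : last + 1] = True
        return out


def normalized_read_count(cov: CoverageTrack) -> CoverageTrack:
    """Divide every position by the genome-wide unmasked mean count."""
    unmasked = cov.values[~cov.mask]
    if unmasked.size == 0:
        raise ValueError("all positions masked")
    mean = unmasked.mean()
    if mean == 0:
        raise ValueError("zero mean coverage")
    return replace(cov, values=cov.values / mean, mask=cov.mask.copy())


def segment_mean(normcov: CoverageTrack, region: GenomicInterval) -> float:
    """Mean normalized count over a region, masked positions excluded."""
    if region.chrom != normcov.chrom:
        raise ValueError(f"region on {region.chrom}, track on {normcov.chrom}")
    lo = region.start // normcov.step
    hi = -(-region.end // normcov.step)
    if hi > len(normcov.values):
        raise ValueError("region outside genome")
    values = normcov.values[lo:hi]
    keep = ~normcov.mask[lo:hi]
    if not keep.any():
        raise ValueError("region fully masked")
    return float(values[keep].mean())
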