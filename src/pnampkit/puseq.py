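"""Polymerase-usage analysis: strand counts -> usage -> initiation index & RFD.

The chain mirrors how polymerase-usage sequencing data are processed.  Raw
strand-specific 100-bp bin counts from a Pol-epsilon mutant, a Pol-delta
mutant and a wild-type-polymerase control strain are total-count normalized,
then the mutant tracks are divided by the control track to give relative
polymerase usage: E_w(x), E_c(x), D_w(x), D_c(x).  Bidirectional initiation
leaves a signature in the differentials of the four tracks — Pol-epsilon
usage rises on Watson and falls on Crick across an origin while Pol-delta
does the opposite — which the initiation index combines into a single signed
per-bin statistic:

    Ini(x) = dEw(x) - dEc(x) - dDw(x) + dDc(x)

evaluated only where all four differentials agree with initiation (positive
Ini) or with fork merging (negative Ini), then scaled by the standard
deviation of the series so peak heights are in Z units while signs are
preserved.  Replication fork directionality is the rightward-minus-leftward
fork signal over their sum, bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .tracks import AlignmentRecord, BinnedTrack, require_same_grid


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the usage -> initiation-index pipeline.

    m is the moving-average half-width (window 2m+1 bins); peak_threshold
    is in Z units of the normalized initiation index.
    """

    m: int = 3
    bin_size: int = 100
    peak_threshold: float = 1.0
    min_peak_separation: int = 10

    def __post_init__(self) -> None:
        if self.m < 0 or int(self.m) != self.m:
            raise ValueError("m must be a non-negative integer")


@dataclass
class UsageSet:
    """Relative polymerase usage of Pol epsilon/delta on Watson/Crick."""

    ew: BinnedTrack
    ec: BinnedTrack
    dw: BinnedTrack
    dc: BinnedTrack

    def __post_init__(self) -> None:
        require_same_grid(self.ew, self.ec, self.dw, self.dc)

    def tracks(self) -> Tuple[BinnedTrack, BinnedTrack, BinnedTrack, BinnedTrack]:
        return self.ew, self.ec, self.dw, self.dc


@dataclass
class IniTrack:
    """Initiation-index track plus the bins where a sign-condition set held."""

    track: BinnedTrack
    defined_mask: np.ndarray  # True where either condition set held
    sd: float  # standard deviation used for Z scaling

    @property
    def values(self) -> np.ndarray:
        return self.track.values


@dataclass(frozen=True)
class PeakCall:
    """A called initiation site: bin-center position (bp) and Z height."""

    position: float
    height: float
    bin_index: int


# ---------------------------------------------------------------------------
# read-level operations


def exclude_ambiguous_alignments(
    records: Sequence[AlignmentRecord],
) -> List[AlignmentRecord]:
    """Drop reads whose best and second-best placements score equally.

    A record is removed iff a secondary score is present and equals the
    primary score; uniquely aligned reads (no secondary score) are kept.
    """
    return [
        r
        for r in records
        if not (
            r.secondary_score is not None
            and r.primary_score is not None
            and r.secondary_score == r.primary_score
        )
    ]


def bin_five_prime_ends(
    records: Sequence[AlignmentRecord],
    chrom_length: int,
    bin_size: int = 100,
) -> Tuple[BinnedTrack, BinnedTrack]:
    """Count read 5' ends per bin, separately for Watson and Crick.

    The 5' end of read 1 marks the alkaline-cleavage (ribonucleotide)
    position; bin = floor(pos / bin_size).
    """
    n_bins = -(-chrom_length // bin_size)
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "chr"
    positions = np.array([r.five_prime_pos for r in records], dtype=np.int64)
    if positions.size and (positions.min() < 0 or positions.max() >= chrom_length):
        raise ValueError("alignment position outside chromosome")
    is_watson = np.array([r.strand == "watson" for r in records], dtype=bool)
    tracks = []
    for sel, strand in ((is_watson, "watson"), (~is_watson, "crick")):
        counts = np.bincount(positions[sel] // bin_size, minlength=n_bins).astype(float)
        tracks.append(
            BinnedTrack(chrom, bin_size, counts, strand, chrom_length=chrom_length)
        )
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# track-level operations


def normalize_by_total(raw: BinnedTrack) -> BinnedTrack:
    """Divide by the total over unmasked bins so the track sums to 1."""
    total = raw.unmasked_sum()
    if not np.isfinite(total) or total <= 0 or (~raw.mask).sum() == 0:
        raise ValueError("empty dataset: no unmasked signal to normalize")
    return raw.with_values(raw.values / total)


def relative_polymerase_usage(
    mutant_norm: BinnedTrack, control_norm: BinnedTrack
) -> BinnedTrack:
    """Per-bin mutant/control ratio; control-zero bins become masked."""
    require_same_grid(mutant_norm, control_norm)
    zero = control_norm.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, 0.0, mutant_norm.values / np.where(zero, 1.0, control_norm.values))
    out = mutant_norm.with_values(ratio, mask=zero)
    out.mask |= control_norm.mask
    return out


def smooth(track: BinnedTrack, m: int) -> BinnedTrack:
    """Centered moving average of 2m+1 bins, mask-aware.

    Each unmasked bin becomes the mean of the unmasked bins within m bins
    of it; the window shrinks at chromosome ends and around masked bins.
    Masked bins stay masked (value 0).  m=0 is the identity.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return track.copy()
    n = track.n_bins
    values, mask = track.values, track.mask
    # each window is summed independently in ascending coordinate order, so
    # results are reproducible to the bit regardless of track length
    means = np.zeros(n)
    for i in range(n):
        if mask[i]:
            continue
        acc = 0.0
        cnt = 0
        for j in range(max(0, i - m), min(n, i + m + 1)):
            if not mask[j]:
                acc += values[j]
                cnt += 1
        if cnt:
            means[i] = acc / cnt
    return track.with_values(means)


def usage_fraction(
    e: BinnedTrack, d: BinnedTrack
) -> Tuple[BinnedTrack, BinnedTrack]:
    """Normalize usage to fractions E/(E+D) and D/(E+D); E+D=0 bins masked."""
    require_same_grid(e, d)
    total = e.values + d.values
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    e_frac = e.with_values(np.where(zero, 0.0, e.values / safe), mask=zero | d.mask)
    d_frac = d.with_values(np.where(zero, 0.0, d.values / safe), mask=zero | e.mask)
    return e_frac, d_frac


def _differential(track: BinnedTrack) -> BinnedTrack:
    """Forward difference d f(x) = f(x+1) - f(x), stored at x.

    The last bin, and any bin where either endpoint is masked, is masked
    with value 0.
    """
    values = np.zeros_like(track.values)
    values[:-1] = track.values[1:] - track.values[:-1]
    mask = np.zeros(track.n_bins, dtype=bool)
    mask[-1] = True
    mask[:-1] = track.mask[1:] | track.mask[:-1]
    return track.with_values(values, mask=mask)


def initiation_index(usage: UsageSet, params: AnalysisParams = AnalysisParams()) -> IniTrack:
    """Compute the normalized initiation index from a usage set.

    Pipeline: (1) smooth each usage track (half-width m); (2) forward
    difference; (3) smooth each differential (m again); (4) where all four
    differentials carry the initiation signature (dEw>0, dEc<0, dDw<0,
    dDc>0) set Ini = dEw - dEc - dDw + dDc, where all four carry the
    merging signature (signs reversed) likewise (giving a negative value),
    else 0; (5) divide by the standard deviation of the resulting series
    (the literal effect of Z-normalizing and subtracting Z(0), which keeps
    the signs).  ``defined_mask`` records the step-4 hits.
    """
    m = params.m
    n = usage.ew.n_bins
    if n < 2 * m + 2:
        raise ValueError(f"track too short: need >= {2 * m + 2} bins, have {n}")
    deltas = []
    for track in usage.tracks():
        deltas.append(smooth(_differential(smooth(track, m)), m))
    dew, dec, ddw, ddc = (t.values for t in deltas)
    undefined = np.zeros(n, dtype=bool)
    for t in deltas:
        undefined |= t.mask

    init_cond = (dew > 0) & (dec < 0) & (ddw < 0) & (ddc > 0) & ~undefined
    merge_cond = (dew < 0) & (dec > 0) & (ddw > 0) & (ddc < 0) & ~undefined
    defined = init_cond | merge_cond
    ini = np.where(defined, dew - dec - ddw + ddc, 0.0)

    # Z scaling over the analyzed (unmasked) series, zeros included
    analysis_mask = usage.ew.mask | usage.ec.mask | usage.dw.mask | usage.dc.mask
    population = ini[~analysis_mask]
    sd = float(population.std()) if population.size else 0.0
    if sd > 0:
        ini = ini / sd
    track = usage.ew.with_values(ini, mask=analysis_mask)
    return IniTrack(track=track, defined_mask=defined, sd=sd)


def rfd(
    usage: UsageSet,
    params: AnalysisParams = AnalysisParams(),
    use_delta: bool = False,
) -> BinnedTrack:
    """Replication fork directionality from smoothed polymerase usage.

    Default: RFD = (Ew - Ec - Dw + Dc) / (Ew + Ec + Dw + Dc), the rightward
    minus leftward fork signal over their sum, bounded in [-1, 1] for
    non-negative usage.  ``use_delta=True`` substitutes the differentials of
    the Pol-delta tracks for Dw/Dc (an alternative form that is not bounded
    and is kept only for comparison).  Zero-denominator bins are masked.
    """
    ew = smooth(usage.ew, params.m)
    ec = smooth(usage.ec, params.m)
    dw = smooth(usage.dw, params.m)
    dc = smooth(usage.dc, params.m)
    if use_delta:
        dw = smooth(_differential(dw), params.m)
        dc = smooth(_differential(dc), params.m)
    num = ew.values - ec.values - dw.values + dc.values
    den = ew.values + ec.values + dw.values + dc.values
    zero = den == 0
    values = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    out = ew.with_values(values, mask=zero | ec.mask | dw.mask | dc.mask)
    return out


def call_origin_peaks(
    ini: IniTrack, params: AnalysisParams = AnalysisParams()
) -> List[PeakCall]:
    """Call initiation peaks from a normalized initiation-index track.

    Local maxima with height >= peak_threshold are selected greedily by
    height; any maximum within min_peak_separation bins of an accepted peak
    is suppressed.  Only positive (initiation-side) peaks are called.
    """
    values = ini.values
    n = len(values)
    candidates = []
    for i in range(n):
        if ini.track.mask[i] or values[i] < params.peak_threshold:
            continue
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < n - 1 else -np.inf
        if values[i] >= left and values[i] >= right:
            candidates.append(i)
    candidates.sort(key=lambda i: values[i], reverse=True)
    accepted: List[int] = []
    for i in candidates:
        if all(abs(i - j) >= params.min_peak_separation for j in accepted):
            accepted.append(i)
    centers = ini.track.bin_centers()
    return sorted(
        (PeakCall(position=float(centers[i]), height=float(values[i]), bin_index=i)
         for i in accepted),
        key=lambda p: p.position,
    )


# ---------------------------------------------------------------------------
# convenience chain


def usage_from_counts(
    eps_watson: BinnedTrack,
    eps_crick: BinnedTrack,
    delta_watson: BinnedTrack,
    delta_crick: BinnedTrack,
    control_watson: BinnedTrack,
    control_crick: BinnedTrack,
) -> UsageSet:
    """Raw strain counts -> relative polymerase usage (normalize + divide)."""
    ctrl_w = normalize_by_total(control_watson)
    ctrl_c = normalize_by_total(control_crick)
    return UsageSet(
        ew=relative_polymerase_usage(normalize_by_total(eps_watson), ctrl_w),
        ec=relative_polymerase_usage(normalize_by_total(eps_crick), ctrl_c),
        dw=relative_polymerase_usage(normalize_by_total(delta_watson), ctrl_w),
        dc=relative_polymerase_usage(normalize_by_total(delta_crick), ctrl_c),
    )
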