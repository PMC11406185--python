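"""Synthetic replication, sequencing and assay data.

This module generates data with the statistical structure the analysis
modules assume:

* a stochastic origin-firing / fork-progression model producing, per bin,
  the fraction of cells replicated by a rightward-moving fork and hence the
  polymerase of synthesis on each strand (leading strand = Pol epsilon,
  lagging = Pol delta);
* strand-specific ribonucleotide-cleavage 5'-end counts for the two
  polymerase-mutant strains and the wild-type-polymerase control, Poisson
  sampled around those truths with an optional shared library bias;
* nanopore-like reads drawn from haplotypes carrying ``k`` tandem copies of
  a target segment between two flanks;
* per-base coverage for clones carrying extra segment copies;
* two-plate colony counts of a reconstitution assay; and
* a per-cell copy-number model for iterated duplication with occasional
  recombinational collapse.

Every generator takes a :class:`SimConfig`; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .assay import ColonyCounts
from .coverage import CoverageTrack
from .io import make_seq_record
from .tracks import BinnedTrack, GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class OriginSpec:
    """A replication origin: position, firing probability and timing.

    ``efficiency`` is the probability of firing per cell cycle.  Firing
    times follow a normal law truncated at zero; a strong early origin has
    high efficiency and small ``firing_time_mean``, while distributive
    initiation is modelled as many low-efficiency origins spread over a
    window.
    """

    position: int
    efficiency: float
    firing_time_mean: float = 10.0
    firing_time_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be in [0,1], got {self.efficiency}")
        if self.firing_time_sd < 0:
            raise ValueError("firing_time_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation configuration.

    depth is the expected read count per strand per bin in the control
    strain; fork_speed is in bp per time unit; bias_profile, when given, is
    a per-bin multiplicative library bias shared by all strains.
    """

    n_cells: int = 1000
    depth: float = 100.0
    fork_speed: float = 1000.0
    seed: int = 0
    bias_profile: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be > 0")

    def rng(self, stage: int = 0) -> np.random.Generator:
        # independent stream per pipeline stage, all keyed to one seed
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class ForkField:
    """Ground truth behind the polymerase-usage tracks.

    ``rightward_fraction`` holds, per bin, the fraction of cells in which
    that bin was replicated by a rightward-moving fork.  On the Watson
    strand a rightward fork synthesizes the leading strand (Pol epsilon);
    on the Crick strand Pol epsilon usage equals the leftward fraction.
    """

    rightward_fraction: BinnedTrack
    eps_fraction_watson: BinnedTrack
    eps_fraction_crick: BinnedTrack
    origins: Tuple[OriginSpec, ...] = ()
    n_cells: int = 0

    def __post_init__(self) -> None:
        rf = self.rightward_fraction.values
        if np.any((rf < 0) | (rf > 1)):
            raise ValueError("rightward_fraction must lie in [0,1]")
        # leading/lagging assignment is definitional; assert consistency
        if not np.allclose(self.eps_fraction_watson.values, rf):
            raise ValueError("Pol-epsilon Watson fraction must equal rightward fraction")
        if not np.allclose(self.eps_fraction_crick.values, 1.0 - rf):
            raise ValueError("Pol-epsilon Crick fraction must equal leftward fraction")


def simulate_replication(
    chrom_length: int,
    origins: Sequence[OriginSpec],
    cfg: SimConfig,
    bin_size: int = 100,
    chrom: str = "chrsim",
) -> ForkField:
    """Simulate origin firing and bidirectional fork progression.

    Per cell, each origin fires with probability ``efficiency`` at a
    truncated-normal time; forks move outward at ``cfg.fork_speed`` and each
    bin is replicated by the first-arriving fork (passive replication
    included, forks implicitly annihilating where they meet).  Cells in
    which no origin fired are re-drawn, so every cell finishes replication.
    """
    if not origins:
        raise ValueError("unreplicated genome: no origins supplied")
    effs = np.array([o.efficiency for o in origins])
    if not np.any(effs > 0):
        raise ValueError("unreplicated genome: no origin can fire")
    positions = np.array([o.position for o in origins], dtype=float)
    if np.any((positions < 0) | (positions >= chrom_length)):
        raise ValueError("origin position outside chromosome")

    rng = cfg.rng(stage=1)
    n_cells, n_orig = cfg.n_cells, len(origins)
    fired = rng.random((n_cells, n_orig)) < effs
    # condition on at least one origin firing per cell
    for _ in range(100_000):
        empty = ~fired.any(axis=1)
        if not empty.any():
            break
        fired[empty] = rng.random((int(empty.sum()), n_orig)) < effs
    else:  # pragma: no cover - unreachable for efficiency > 0
        raise ValueError("unreplicated genome: firing never succeeded")

    times = np.empty((n_cells, n_orig))
    for j, o in enumerate(origins):
        if o.firing_time_sd == 0:
            times[:, j] = o.firing_time_mean
        else:
            a = (0.0 - o.firing_time_mean) / o.firing_time_sd
            times[:, j] = stats.truncnorm.rvs(
                a, np.inf, loc=o.firing_time_mean, scale=o.firing_time_sd,
                size=n_cells, random_state=rng,
            )
    times = np.where(fired, times, np.inf)

    n_bins = -(-chrom_length // bin_size)
    starts = np.arange(n_bins) * bin_size
    ends = np.minimum(starts + bin_size, chrom_length)
    centers = (starts + ends) / 2.0

    rightward_cells = np.zeros(n_bins)
    chunk = max(1, 2_000_000 // (n_orig * n_bins))
    for lo in range(0, n_cells, chunk):
        t = times[lo : lo + chunk]  # (c, o)
        # arrival[c, o, b] = firing time + travel time of the fork to bin b
        travel = np.abs(centers[None, :] - positions[:, None]) / cfg.fork_speed
        arrival = t[:, :, None] + travel[None, :, :]
        winner = np.argmin(arrival, axis=1)  # (c, b)
        rightward = centers[None, :] >= positions[winner]
        rightward_cells += rightward.sum(axis=0)

    rf = rightward_cells / n_cells
    rf_track = BinnedTrack(chrom, bin_size, rf, "unstranded", chrom_length=chrom_length)
    return ForkField(
        rightward_fraction=rf_track,
        eps_fraction_watson=rf_track.with_values(rf),
        eps_fraction_crick=rf_track.with_values(1.0 - rf),
        origins=tuple(origins),
        n_cells=n_cells,
    )


@dataclass
class PuseqCounts:
    """Raw strand-specific bin counts for the three strains."""

    eps_watson: BinnedTrack
    eps_crick: BinnedTrack
    delta_watson: BinnedTrack
    delta_crick: BinnedTrack
    control_watson: BinnedTrack
    control_crick: BinnedTrack

    def as_dict(self) -> dict:
        return {
            ("eps", "watson"): self.eps_watson,
            ("eps", "crick"): self.eps_crick,
            ("delta", "watson"): self.delta_watson,
            ("delta", "crick"): self.delta_crick,
            ("control", "watson"): self.control_watson,
            ("control", "crick"): self.control_crick,
        }


def simulate_puseq_counts(field: ForkField, cfg: SimConfig) -> PuseqCounts:
    """Poisson-sample ribonucleotide-cleavage 5'-end counts per strain.

    The expected mutant count on a strand at bin x is
    ``depth * bias(x) * P(strand at x synthesized by that mutant
    polymerase)``; the wild-type-polymerase control has expectation
    ``depth * bias(x)`` on both strands, so dividing normalized mutant data
    by normalized control data cancels any shared library bias.
    """
    rf = field.rightward_fraction
    n_bins = rf.n_bins
    bias = (
        np.ones(n_bins)
        if cfg.bias_profile is None
        else np.asarray(cfg.bias_profile, dtype=float)
    )
    if bias.shape != (n_bins,):
        raise ValueError("bias_profile length must match bin count")
    if np.any(bias < 0):
        raise ValueError("bias_profile must be non-negative")

    eps_w = field.eps_fraction_watson.values  # = rightward fraction
    eps_c = field.eps_fraction_crick.values
    expectations = {
        ("eps", "watson"): cfg.depth * bias * eps_w,
        ("eps", "crick"): cfg.depth * bias * eps_c,
        ("delta", "watson"): cfg.depth * bias * (1.0 - eps_w),
        ("delta", "crick"): cfg.depth * bias * (1.0 - eps_c),
        ("control", "watson"): cfg.depth * bias,
        ("control", "crick"): cfg.depth * bias,
    }
    rng = cfg.rng(stage=2)
    tracks = {}
    for key, lam in expectations.items():
        counts = rng.poisson(lam).astype(float)
        tracks[key] = BinnedTrack(
            rf.chrom, rf.bin_size, counts, key[1],
            mask=rf.mask.copy(), chrom_length=rf.chrom_length,
        )
    return PuseqCounts(
        eps_watson=tracks[("eps", "watson")],
        eps_crick=tracks[("eps", "crick")],
        delta_watson=tracks[("delta", "watson")],
        delta_crick=tracks[("delta", "crick")],
        control_watson=tracks[("control", "watson")],
        control_crick=tracks[("control", "crick")],
    )


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_tandem_reads(
    unit: str,
    copies: int,
    flank_left: str,
    flank_right: str,
    n_reads: int,
    length_dist: Union[int, Tuple[float, float]],
    cfg: SimConfig,
    full_span_fraction: float = 0.2,
    error_rate: float = 0.0,
) -> List[SeqRecord]:
    """Draw reads from ``flank_left + unit*copies + flank_right``.

    ``length_dist`` is either a fixed read length or a ``(mean, sd)`` pair
    of a normal law truncated at 50 bp.  A ``full_span_fraction`` of reads
    is guaranteed to cover the whole tandem array plus a flank margin (for
    junction-query tests).  Read names encode the true start/length and
    whether the read spans the array or was clipped at a haplotype end.
    Substitution errors are applied uniformly at ``error_rate``.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if len(unit) == 0:
        raise ValueError("unit must be non-empty")
    haplotype = flank_left + unit * copies + flank_right
    hap_len = len(haplotype)
    array_start = len(flank_left)
    array_end = array_start + len(unit) * copies
    margin = min(1000, len(flank_left), len(flank_right))

    rng = cfg.rng(stage=3)
    n_span = int(round(full_span_fraction * n_reads))
    records: List[SeqRecord] = []
    for i in range(n_reads):
        spanning = i < n_span
        if spanning:
            start = int(rng.integers(0, max(1, array_start - margin + 1)))
            end = int(rng.integers(min(array_end + margin, hap_len), hap_len + 1))
            length = end - start
            clipped = False
        else:
            if isinstance(length_dist, (int, np.integer)):
                length = int(length_dist)
            else:
                mean, sd = length_dist
                length = int(max(50, rng.normal(mean, sd)))
            start = int(rng.integers(0, hap_len))
            clipped = start + length > hap_len
            length = min(length, hap_len - start)
        seq = haplotype[start : start + length]
        if error_rate > 0:
            seq = _substitute(seq, error_rate, rng)
        name = (
            f"read{i:05d}|start={start}|len={length}"
            f"|span={int(spanning)}|clipped={int(clipped)}"
        )
        records.append(make_seq_record(seq, name))
    return records


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def simulate_coverage(
    genome_length: int,
    segment: GenomicInterval,
    copies: int,
    depth: float,
    cfg: SimConfig,
) -> CoverageTrack:
    """Per-base Poisson coverage for a clone with ``copies`` segment copies.

    Expected coverage is ``depth`` genome-wide and ``depth * copies`` inside
    the segment, emulating read mapping of a clone whose extra tandem copies
    all pile onto the single reference copy.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if segment.end > genome_length:
        raise ValueError("segment outside genome")
    lam = np.full(genome_length, float(depth))
    lam[segment.start : segment.end] *= copies
    rng = cfg.rng(stage=4)
    return CoverageTrack(segment.chrom, rng.poisson(lam).astype(float))


def simulate_colony_assay(
    true_rate: float,
    n_sc_cfu: int,
    plating_ratio: int = 10,
    cfg: SimConfig = SimConfig(),
) -> ColonyCounts:
    """Two-plate reconstitution assay: all plated CFUs form colonies on the
    complete medium; selective-plate colonies are Binomial(ratio*n, rate)."""
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError("true_rate must be in [0,1]")
    if plating_ratio <= 0:
        raise ValueError("plating_ratio must be > 0")
    if n_sc_cfu < 0:
        raise ValueError("n_sc_cfu must be >= 0")
    rng = cfg.rng(stage=5)
    n_scura = int(rng.binomial(plating_ratio * n_sc_cfu, true_rate))
    return ColonyCounts(n_sc=n_sc_cfu, n_scura=n_scura, plating_ratio=plating_ratio)


def simulate_iterative_pnamp(
    p_dup: float,
    p_del: float,
    n_cycles: int,
    n_cells: int,
    cfg: SimConfig = SimConfig(),
) -> np.ndarray:
    """Per-cell copy number after iterated duplication cycles.

    Each cycle doubles the copy number with probability ``p_dup``; a
    subsequent recombinational collapse occurs with probability ``p_del``
    and drops the copy number to a uniform value in [1, current-1].
    Returns the per-cell copy numbers (length ``n_cells``).
    """
    for name, p in (("p_dup", p_dup), ("p_del", p_del)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1]")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    rng = cfg.rng(stage=6)
    copies = np.ones(n_cells, dtype=np.int64)
    for _ in range(n_cycles):
        dup = rng.random(n_cells) < p_dup
        copies[dup] *= 2
        collapse = (rng.random(n_cells) < p_del) & (copies >= 2)
        if collapse.any():
            copies[collapse] = rng.integers(1, copies[collapse])
    return copies


def load_sim_config(path) -> Tuple[SimConfig, List[OriginSpec], dict]:
    """Load a YAML simulation config.

    Expected layout::

        chrom_length: 50000
        bin_size: 100
        sim: {n_cells: 2000, depth: 200, fork_speed: 1000, seed: 1}
        origins:
          - {position: 15000, efficiency: 0.9,
             firing_time_mean: 10, firing_time_sd: 3}

    Returns (SimConfig, origins, extras) where extras holds the remaining
    top-level keys (chrom_length, bin_size, ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = SimConfig(**raw.get("sim", {}))
    origins = [OriginSpec(**o) for o in raw.get("origins", [])]
    extras = {k: v for k, v in raw.items() if k not in ("sim", "origins")}
    return cfg, origins, extras
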