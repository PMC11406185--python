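"""Genetic-assay arithmetic: reconstitution rates, fold changes, proportions,
iterative-duplication expectations and qPCR-style relative copy number.

The central statistic is the reconstitution rate of a two-plate assay in
which 50-300 colony-forming units are spread on complete medium and a
``plating_ratio`` (default 10) multiple on selective medium:

    rate = n_selective / (plating_ratio * n_complete)

A zero selective-plate count is reported as a detection-limit upper bound
(rate < 1/(ratio*n)) rather than zero, and fold changes against such a bound
are themselves lower bounds (">x-fold").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ColonyCounts:
    """Colony counts of the two-plate assay."""

    n_sc: int
    n_scura: int
    plating_ratio: int = 10

    def __post_init__(self) -> None:
        if self.n_sc < 0 or self.n_scura < 0:
            raise ValueError("colony counts must be >= 0")
        if self.plating_ratio <= 0:
            raise ValueError("plating_ratio must be > 0")


@dataclass(frozen=True)
class RateEstimate:
    """A reconstitution-rate estimate; ``is_upper_bound`` marks a detection
    limit from a zero selective-plate count."""

    rate: float
    is_upper_bound: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0,1], got {self.rate}")


@dataclass(frozen=True)
class FoldChange:
    """A ratio of two rates; ``is_lower_bound`` marks '>x-fold' results
    obtained against a detection-limit denominator."""

    fold: float
    is_lower_bound: bool = False

    def __str__(self) -> str:
        prefix = ">" if self.is_lower_bound else ""
        return f"{prefix}{self.fold:g}-fold"


def reconstitution_rate(c: ColonyCounts) -> RateEstimate:
    """Rate = n_scura / (plating_ratio * n_sc); detection limit when zero.

    With no colony on the selective plate, the rate is below one colony's
    worth, so 1/(ratio*n_sc) is reported with ``is_upper_bound=True``.
    """
    if c.n_sc == 0:
        raise ValueError("no viable count: n_sc must be > 0")
    denom = c.plating_ratio * c.n_sc
    if c.n_scura == 0:
        return RateEstimate(rate=1.0 / denom, is_upper_bound=True)
    return RateEstimate(rate=c.n_scura / denom)


def fold_change(a: RateEstimate, b: RateEstimate) -> FoldChange:
    """a.rate / b.rate; a lower bound when b is a detection limit."""
    if b.rate == 0:
        raise ValueError("cannot divide by a zero rate")
    return FoldChange(fold=a.rate / b.rate, is_lower_bound=b.is_upper_bound)


def proportion_with_ci(
    k: int, n: int, alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """Fraction k/n with a Wilson score interval (default 95%)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    return k / n, (float(low), float(high))


def expected_copies_after_cycles(n_cycles: int) -> int:
    """Copy number after perfect iterated duplication: 2**n_cycles."""
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    return 2**n_cycles


def relative_copy_number(
    target_q: float, ref_q: float, calib_target_q: float, calib_ref_q: float
) -> float:
    """qPCR relative copy number: target/reference quantity ratio,
    calibrated to a single-copy clone's ratio."""
    for name, q in (
        ("target_q", target_q),
        ("ref_q", ref_q),
        ("calib_target_q", calib_target_q),
        ("calib_ref_q", calib_ref_q),
    ):
        if q <= 0:
            raise ValueError(f"{name} must be > 0")
    return (target_q / ref_q) / (calib_target_q / calib_ref_q)


def segment_length(pos_a: float, pos_b: float) -> float:
    """Length of the segment delimited by two coordinates (same units)."""
    if pos_a == pos_b:
        raise ValueError("positions must differ")
    return abs(pos_b - pos_a)
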