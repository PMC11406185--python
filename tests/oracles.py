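"""Independent brute-force reference implementations used only by tests.

These are written as straight-line loops directly from the definitions of
the operations they check, and deliberately share no code with the package.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


def brute_windowed_mean(
    values: np.ndarray, mask: np.ndarray, m: int
) -> np.ndarray:
    """Centered moving average over available unmasked neighbors."""
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        if mask[i]:
            continue
        acc, cnt = 0.0, 0
        for j in range(max(0, i - m), min(n, i + m + 1)):
            if not mask[j]:
                acc += values[j]
                cnt += 1
        out[i] = acc / cnt if cnt else 0.0
    return out


def brute_initiation_index(
    ew: np.ndarray,
    ec: np.ndarray,
    dw: np.ndarray,
    dc: np.ndarray,
    mask: np.ndarray,
    m: int,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Straight-line initiation-index pipeline.

    Steps: smooth usage (m) -> forward difference at x -> smooth (m) ->
    sign-condition gate and signed combination -> divide by SD over the
    unmasked series.  Returns (ini, defined, sd).
    """
    n = len(ew)
    smoothed = [brute_windowed_mean(t, mask, m) for t in (ew, ec, dw, dc)]
    delta_mask = np.zeros(n, dtype=bool)
    delta_mask[-1] = True
    for i in range(n - 1):
        if mask[i] or mask[i + 1]:
            delta_mask[i] = True
    deltas = []
    for s in smoothed:
        d = np.zeros(n)
        for i in range(n - 1):
            d[i] = s[i + 1] - s[i]
        d[delta_mask] = 0.0
        deltas.append(brute_windowed_mean(d, delta_mask, m))
    dew, dec_, ddw, ddc = deltas
    ini = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        if delta_mask[i]:
            continue
        is_init = dew[i] > 0 and dec_[i] < 0 and ddw[i] < 0 and ddc[i] > 0
        is_merge = dew[i] < 0 and dec_[i] > 0 and ddw[i] > 0 and ddc[i] < 0
        if is_init or is_merge:
            defined[i] = True
            ini[i] = dew[i] - dec_[i] - ddw[i] + ddc[i]
    population = ini[~mask]
    sd = float(population.std()) if population.size else 0.0
    if sd > 0:
        ini = ini / sd
    return ini, defined, sd


def brute_histogram(positions: np.ndarray, n_bins: int, bin_size: int) -> np.ndarray:
    counts = np.zeros(n_bins)
    for p in positions:
        counts[p // bin_size] += 1
    return counts


def brute_region_mean(
    values: np.ndarray, mask: np.ndarray, start: int, end: int
) -> float:
    acc, cnt = 0.0, 0
    for i in range(start, end):
        if not mask[i]:
            acc += values[i]
            cnt += 1
    return acc / cnt


def two_origin_race_rightward_probability(
    x: float,
    weak_pos: float,
    weak_eff: float,
    left_pos: float,
    right_pos: float,
) -> float:
    """Closed-form P(bin at x replicated rightward) for one weak origin
    flanked by two always-firing backups, all firing simultaneously.

    The nearest fired origin wins; direction is rightward iff its position
    is at or left of x.
    """
    def winner(origins: List[float]) -> float:
        return min(origins, key=lambda p: abs(x - p))

    p_right_if_fired = 1.0 if winner([left_pos, weak_pos, right_pos]) <= x else 0.0
    p_right_if_not = 1.0 if winner([left_pos, right_pos]) <= x else 0.0
    return weak_eff * p_right_if_fired + (1 - weak_eff) * p_right_if_not
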