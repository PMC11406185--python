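"""Reconstitution-rate statistics of the two-plate colony assay.

Cells are spread on complete medium (SC) and, at a 10-fold higher CFU count,
on selective medium (SC-Ura); the reconstitution rate is
n_selective / (10 * n_complete).  Zero selective counts become detection
limits and fold changes against them become lower bounds.
"""

import pnampkit as pk

# a strong duplication induction: 150 selective colonies from 100 plated CFUs
strong = pk.reconstitution_rate(pk.ColonyCounts(n_sc=100, n_scura=150))
print(f"paired-nicking rate: {strong.rate:.1%}")

# a mock control with no selective colonies: only an upper bound is known
mock = pk.reconstitution_rate(pk.ColonyCounts(n_sc=2_000_000, n_scura=0))
print(f"mock rate: <{mock.rate:.6%} (detection limit)")

fc = pk.fold_change(pk.RateEstimate(0.0038), mock)
print(f"splint vs mock: {fc}")

fc = pk.fold_change(pk.RateEstimate(0.0038), pk.RateEstimate(0.000015))
print(f"with vs without paired nicking: {fc.fold:.1f}-fold")

frac, (low, high) = pk.proportion_with_ci(3, 40)
print(f"clones with duplication: {frac:.1%} (95% CI {low:.1%}-{high:.1%})")

print(f"expected copies after 3 duplication cycles: "
      f"{pk.expected_copies_after_cycles(3)}")

copy_number = pk.relative_copy_number(
    target_q=2.1, ref_q=1.0, calib_target_q=1.05, calib_ref_q=1.0
)
print(f"qPCR relative copy number: {copy_number:.2f}")
# 15% is the scale of an efficient induction; the mock bound propagates into
# a '>38000-fold' style statement rather than a division by zero.
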