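"""Primer efficiency and relative quantification from a dilution series.

A 2-fold serial dilution whose Ct rises by exactly one cycle per step implies
perfect doubling per cycle: slope -1/log10(2) = -3.3219 and 100% efficiency.
Unknown samples are quantified by inverting the fitted line and normalized to
a reference gene.
"""

from flyclock.qpcr import fit_standard_curve, normalize_to_reference, relative_quantity

curve = fit_standard_curve(
    dilutions=[1, 0.5, 0.25, 0.125, 0.0625], cts=[20, 21, 22, 23, 24]
)
print(f"slope {curve.slope:.4f}  efficiency {curve.efficiency * 100:.1f}%  R^2 {curve.r_squared:.4f}")

target_q = relative_quantity(21.5, curve)
reference_q = relative_quantity(22.5, curve)
print(f"target quantity {target_q:.4f}, reference quantity {reference_q:.4f}")
print(f"normalized level {normalize_to_reference(target_q, reference_q):.3f}")
# one Ct earlier than the reference at 100% efficiency means exactly twice
# as much template, so the normalized level is 2.0.
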