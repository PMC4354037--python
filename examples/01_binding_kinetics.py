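"""Signal-complex kinetics: why high salt + high nucleotide discriminates bases.

Simulates the labelled-polymerase signal complex (SC = binary + ternary +
post-chemistry enzyme/DNA complexes) for correct vs mismatch nucleotides at
a fast DNA off-rate (high ionic strength), and scans the off-rate to show
where discrimination appears.
"""

import numpy as np

from kinflow import kinetics as kin

correct, mismatch = kin.fig2_rate_constants(k_off_dna=500.0)
t = np.linspace(0.0, 2.0, 2000)

print("k-1 = 500 1/s (high salt), k_pol = 9 1/s, K_d,app = 30 uM")
for conc in (5.0, 500.0):
    tc_c = kin.simulate_timecourse(correct, kin.fig2_mix(conc), t, mode="clamped")
    tc_m = kin.simulate_timecourse(
        mismatch, kin.fig2_mix(conc, is_correct=False), t, mode="clamped"
    )
    print(
        f"  [N] = {conc:5.0f} uM:  correct max %SC = {tc_c.percent_sc_series.max():.3f}   "
        f"mismatch plateau = {tc_m.percent_sc_series[-1]:.3f}"
    )
print("-> the correct nucleotide pulls up to ~0.8 of the enzyme into the")
print("   signal complex at 500 uM while a mismatch stays at the ~0.2 binding")
print("   equilibrium: that gap is the base-calling signal.\n")

table = kin.parameter_scan(
    correct, mismatch, kin.fig2_mix(100.0), "k_off_dna", np.array([0.2, 100.0, 500.0])
)
print("off-rate scan at 100 uM nucleotide (max %SC):")
for v in (0.2, 100.0, 500.0):
    sub = table[table.value == v].set_index("label")
    print(
        f"  k-1 = {v:6.1f} 1/s:  correct {sub.loc['correct', 'max_percent_sc']:.3f}  "
        f"mismatch {sub.loc['mismatch', 'max_percent_sc']:.3f}"
    )
print("-> at slow off-rates (low salt) both classes saturate near 100% SC and")
print("   are indistinguishable; discrimination requires a fast off-rate.")
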