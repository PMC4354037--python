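"""Pre-steady-state analysis: k_pol, K_d,app and the discrimination value.

Emulates a rapid-quench experiment with the full ODE model (preincubated
enzyme.DNA, single turnover), fits each product time course to a rising
exponential, fits the rates to a hyperbola, and combines the specificity
constants into a discrimination value.
"""

import numpy as np

from kinflow import fitting as fit
from kinflow import kinetics as kin

K_POL, KD_APP = 9.15, 29.1  # 1/s, uM - quench-flow values for correct dCTP
MISMATCH_SLOPE = 4.6e-6  # 1/(uM s) - linear specificity of the mismatch

concs = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 150.0, 300.0])
rates_obs = []
for conc in concs:
    rates = kin.RateConstants.from_kd(
        k_on_dna=10.0, k_off_dna=0.01, k_pol=K_POL, kd_app_nt=KD_APP, k_on_nt=1000.0
    )
    mix = kin.ReactionMix(enzyme_total=1.0, dna_total=0.2, nucleotide=conc)
    k_guess = K_POL * conc / (KD_APP + conc)
    t = np.linspace(0, 6.0 / k_guess, 60)
    tc = kin.simulate_timecourse(rates, mix, t, preincubated=True)
    f = fit.fit_single_exponential(fit.ProductCurve(times=t, product=tc.product_series))
    rates_obs.append(f.rate)
    print(f"  [S] = {conc:5.0f} uM -> k_obs = {f.rate:7.3f} 1/s")

hyp = fit.fit_hyperbolic(concs, rates_obs)
print(f"\nhyperbolic fit: k_pol = {hyp.k_max:.3f} 1/s (truth {K_POL}), "
      f"K_d,app = {hyp.kd_app:.2f} uM (truth {KD_APP})")

res = fit.specificity_and_discrimination(hyp.k_max, hyp.kd_app, MISMATCH_SLOPE)
print(f"specificity constant k_pol/K_d,app = {res.specificity_correct:.3e} 1/(uM s)")
print(f"discrimination (correct/mismatch)  = {res.discrimination:.3e}")
print("-> a ~3.1e-1 specificity against a 4.6e-6 mismatch slope means the")
print("   polymerase prefers the correct nucleotide ~7e4-fold, the fidelity")
print("   margin the sequencing chemistry relies on.")
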