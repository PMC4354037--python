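"""Cyclic-sequencing speed: how many bases does one flow deliver?

Exact rational arithmetic for the expected sequencing speed under a cyclic
flow order, plus a Monte-Carlo check on simulated templates.
"""

import numpy as np

from kinflow import evaluate as ev
from kinflow import simulate as sim

model = ev.SpeedModelInput()  # G,T,A,C order, uniform bases, genome n-mer mix
res = ev.cyclic_speed(model)
print(f"flow order {model.flow_order}, n-mer mix "
      f"{[float(p) for p in model.nmer_distribution]} (>=3-mers count 3 bases)")
print(f"bases per matching flow : {res.bases_per_matching_flow} "
      f"= {float(res.bases_per_matching_flow):.4g}")
print(f"flows per matching flow : {res.flows_per_matching_flow}")
print(f"bases per flow          : {res.bases_per_flow} "
      f"= {float(res.bases_per_flow):.4g}")
print(f"-> {44 * float(res.bases_per_flow):.1f} bases expected from a 44-flow run\n")

rng = np.random.default_rng(0)
rates = []
for _ in range(500):
    seq = "".join(rng.choice(list("ACGT"), size=200))
    rates.append(sim.expected_flowgram(seq, "GTAC", 44).sum() / 44)
print(f"Monte-Carlo on uniform random templates: {np.mean(rates):.3f} bases/flow")
print("   (uniform templates have geometric homopolymers - slightly more")
print("   multi-mers than the genome mix, hence a slightly higher speed)")
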