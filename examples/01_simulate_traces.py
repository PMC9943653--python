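"""Simulate a cohort of smFRET traces from the three-state site-exposure model.

Generates 50 traces of a nucleosome with an outer-region binding site (P26
rate triple, k21 = 100 /s) at 10 nM TF and summarizes what the camera sees.
"""

import numpy as np

import siteexposure as se
from siteexposure.presets import DEFAULT_K21, KINETIC_PARAMS

rates = KINETIC_PARAMS["P26"].to_rateset(DEFAULT_K21)
emission = se.EmissionModel()  # E_high=0.75, E_low=0.15, sd=0.08, 0.1 s frames

traces, meta = se.simulate_experiment(
    rates, conc_list=[10.0], n_traces=50, duration=120.0,
    emission=emission, seed=1, label="P26",
)

eff = np.concatenate([t.efficiency for t in traces])
low_frac = np.mean(eff < 0.5 * (emission.e_high + emission.e_low))
print(f"simulated {len(traces)} traces x {len(traces[0])} frames at 10 nM")
print(f"fraction of frames in the low-FRET (TF-trapped, unwrapped) state: {low_frac:.3f}")

# the equilibrium expectation from the closed-form rates
k_hl = se.k_high_to_low(2.5, 0.11, 10.0)
k_lh = se.k_low_to_high(0.66, 0.11, 2.5, 10.0)
print(f"closed-form apparent rates: k_HL = {k_hl:.3f} /s, k_LH = {k_lh:.3f} /s")
print(f"expected low-FRET occupancy k_HL/(k_HL+k_LH) = {k_hl / (k_hl + k_lh):.3f}")
print("the simulated occupancy should match the closed-form expectation; the")
print("~10 ms unwrapping flickers without binding are invisible at 0.1 s frames")
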