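"""Recover (k12, k32, kon_eff) from a simulated concentration series.

Runs the full simulate -> idealize -> dwell -> global-fit chain at the P36
(inner-region) rate triple over 50-500 nM, at reduced cohort size for speed,
and compares the recovered triple with the ground truth.
"""

import siteexposure as se
from siteexposure.globalfit import global_fit_site_exposure
from siteexposure.pipeline import analyze_traces
from siteexposure.presets import DEFAULT_K21, KINETIC_CONC_GRIDS, KINETIC_PARAMS

truth = KINETIC_PARAMS["P36"]
rates = truth.to_rateset(DEFAULT_K21)
emission = se.EmissionModel()

traces, _ = se.simulate_experiment(
    rates, KINETIC_CONC_GRIDS["P36"], n_traces=100, duration=120.0,
    emission=emission, seed=5, label="P36",
)
series = analyze_traces(traces, emission, seed=6,
                        dwell_cfg={"bootstrap_reps": 60}, label="P36")
for pt in series.points:
    print(f"  {pt.conc:6.0f} nM: k_HL = {pt.k_hl:.3f} +- {pt.k_hl_se:.3f} /s, "
          f"k_LH = {pt.k_lh:.3f} +- {pt.k_lh_se:.3f} /s  ({pt.n_events} events)")

fit = global_fit_site_exposure(series, n_boot=200, seed=7, label="P36")
p = fit.params
print(f"recovered: k12 = {p.k12:.2f} /s (truth {truth.k12}), "
      f"k32 = {p.k32:.2f} /s (truth {truth.k32}), "
      f"kon_eff = {p.kon_eff:.4f} /nM/s (truth {truth.kon_eff})")
print(f"derived:   KD_eff = {fit.kd_eff:.0f} nM, c_cross = {fit.c_cross:.0f} nM")
print("k_HL saturating toward k12 while k_LH falls with concentration is the")
print("signature of the unwrapping-limited (inner-region) regime")
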