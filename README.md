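# siteexposure

Kinetic analysis of transcription-factor (TF) binding within partially
unwrapping nucleosomes, for single-molecule FRET (smFRET) and ensemble FRET
experiments.  The package is aimed at chromatin biophysicists who want to go
from FRET trace tables and titration curves to site-exposure rate constants,
binding isotherms, and a relative free-energy profile of TF occupancy — and
at method developers who want every estimator in that chain testable against
synthetic data with known ground truth.

## The model

Nucleosomal DNA transiently unwraps from the histone octamer, exposing
buried binding sites (the site-exposure mechanism).  A TF can only bind
while the site is exposed, giving the three-state scheme

```
          k12              k23·[TF]
   N1  <------->  N2  <----------->  N3
 (wrapped) k21  (exposed)    k32   (TF bound)
  high FRET      low FRET         low FRET
```

Because rewrapping is fast (`k21` on the ~10 ms scale) the exposed-unbound
intermediate is nearly invisible and the observable FRET dynamics collapse
onto two apparent rates with closed forms

```
k_HL([TF]) = k12 / (1 + k12 / (kon_eff·[TF]))      kon_eff = (k12/k21)·k23
k_LH([TF]) = k32 / (1 + kon_eff·[TF] / k12)
```

Fitting both curves jointly across TF concentrations recovers the
identifiable triple `(k12, k32, kon_eff)`; derived from it are
`KD_eff = k32/kon_eff` (the apparent dissociation constant, comparable to
ensemble `S1/2` values) and `c_cross = k12/kon_eff = k21/k23`, the
concentration separating the direct-readout ("outer region") regime from
the unwrapping-limited ("inner region") regime.  Relative occupancy free
energies follow as `ΔΔG = k_B T · ln(S1/2 / S1/2,ref)` and can be compared
against a nucleosome-unwrapping free-energy landscape.

## What's in the package

| module | role |
| --- | --- |
| `siteexposure.kinetics` | rate matrices, master-equation propagation, eigen-solutions, closed-form rates, regime metrics |
| `siteexposure.simulate` | Gillespie state paths, camera-binned noisy FRET traces, cohorts, titration generator |
| `siteexposure.idealize` | two-state ML Gaussian-HMM idealization (+ threshold cross-check, bleach truncation) |
| `siteexposure.dwell` | censored/truncated dwell extraction, exponential-mixture MLE, model selection, per-concentration rates |
| `siteexposure.globalfit` | joint `(k12, k32, kon_eff)` fit, linear two-state fit, fold changes |
| `siteexposure.isotherm` | single/double binding-isotherm fits, F-test model selection, ratio-A conversion |
| `siteexposure.landscape` | ΔΔG profiles, mapping onto the unwrapping coordinate, KS/permutation comparison |
| `siteexposure.pipeline` / `config` / `io` / `cli` | YAML-configured end-to-end runs, CSV/TSV/JSON I/O, thin `siteexposure` CLI |

`examples/` contains one short narrative script per capability.

## Worked example

Recover the rate triple of an inner-region construct (P36: binding site
ending 36 bp into the nucleosome) from simulated traces
(`examples/03_global_kinetic_fit.py`):

```
$ python examples/03_global_kinetic_fit.py
      50 nM: k_HL = 0.161 +- 0.004 /s, k_LH = 0.786 +- 0.020 /s  (2953 events)
     100 nM: k_HL = 0.275 +- 0.006 /s, k_LH = 0.678 +- 0.015 /s  (4297 events)
     250 nM: k_HL = 0.481 +- 0.009 /s, k_LH = 0.490 +- 0.010 /s  (5222 events)
     500 nM: k_HL = 0.603 +- 0.013 /s, k_LH = 0.327 +- 0.006 /s  (4639 events)
recovered: k12 = 0.94 /s (truth 0.9), k32 = 0.97 /s (truth 1.03), kon_eff = 0.0038 /nM/s (truth 0.004)
derived:   KD_eff = 254 nM, c_cross = 246 nM
```

Reading the numbers: the high→low rate `k_HL` rises but saturates toward
the unwrapping rate `k12` while the low→high rate `k_LH` *falls* with
concentration — the TF rebinds faster than the nucleosome can rewrap, so a
single unwrapping episode hosts many binding events.  A plain two-state
binding model cannot produce either behaviour; the three-state fit recovers
the generating parameters to within a few percent.  `KD_eff ≈ 250 nM` is
the effective affinity an occupancy measurement would see.

The CLI exposes the same stages (`siteexposure simulate | idealize | dwell |
fit-kinetics | fit-titration | landscape | run`), e.g.:

```sh
siteexposure simulate --k12 2.5 --k23 4.4 --k32 0.66 -c 1 -c 5 -c 10 \
    --n-traces 50 --seed 1 --out traces.csv
siteexposure dwell traces.csv --out rates.csv
siteexposure fit-kinetics rates.csv
```

## Data notes

Trace tables are tidy CSV (`trace_id, conc_nM, frame, time_s, fret_e`, or
`donor`/`acceptor` columns), titrations are CSV
(`conc_nM, fret_e, replicate`), landscapes are TSV (`bp, ddg_kBT`).  The
published unwrapping landscape is not redistributed;
`synthetic_unwrapping_landscape()` provides a labelled synthetic stand-in
for testing, and `read_landscape_table()` accepts a user-supplied table.
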