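# cadhesion

Analysis pipeline for quantifying how an ectodomain-binding antibody alters
cadherin adhesion, turnover and signalling — the kind of multi-modal dataset
produced when a P-cadherin-targeting antibody traps the adhesive bond in its
X-dimer conformation and triggers endocytosis.  The package implements the
full quantitative chain around such experiments:

* **Single-molecule AFM force spectroscopy** — thermal-fluctuation spring
  calibration (k = k_B·T / var(deflection)), rupture-event detection on
  retract traces, worm-like-chain (WLC, Marko–Siggia) validation of the PEG
  tether stretch with r²/contour-length gates against nonspecific adhesion,
  Freedman–Diaconis histogramming, and EM Gaussian-mixture fits of the
  unbinding forces with the component count selected by BIC
  (BIC = (3k−1)·ln n − 2·ln L̂).
* **MD/SMD trajectory observables** — Kabsch superposition, RMSD traces and
  two-pass RMSF profiles, Shrake–Rupley SASA on a deterministic spiral
  lattice, interfacial burial ΔSASA = SASA(A) + SASA(B) − SASA(AB),
  charged-atom distances with the median < 4 Å salt-bridge stability rule,
  occupancy (≥ 40%) and episode (> 0.2 ns) filters, conversion-time
  (smoothed RMSD minimum) and dissociation-time (ΔSASA reaching zero)
  estimators, and the pulling-force conversion
  (400 kJ·mol⁻¹·nm⁻¹ ≈ 665 pN).
* **FRAP kinetics** — pre-bleach normalization, single-exponential recovery
  y = A·(1 − e^(−k(t−t₀))) fitted on post-bleach frames, mobile fraction A
  and half-time t½ = ln 2 / k, with the R² > 0.7 inclusion gate.
* **Biochemical quantification** — phos-tag phosphorylation fractions,
  co-IP association ratios, surface-biotinylation fractions, the combined
  "effective" surface-cadherin statistic, pixel-cutoff aggregate sizing
  (8-connected components; beads ≥ 30 px, cell aggregates > 5 cells at
  40 px/cell), and a Welch two-sided t-test utility.
* **Synthetic data with planted ground truth** — seeded generators for every
  input (force curves, FRAP traces, observable time series, toy dimer
  trajectories, aggregate masks) whose planted parameters are recorded in a
  ledger, so each estimator can be validated by parameter recovery.

## Worked example

Simulate 200 retract curves whose specific ruptures are drawn from a single
Gaussian at 24.5 ± 9.9 pN (70% specific, 1 pN noise), then run the AFM
stage:

```sh
cadhesion simulate afm --seed 7 --n 200 --mean 24.5 --sd 9.9 \
    --specific-fraction 0.7 --out sim
cadhesion afm --in sim/curves.tsv --out res --stdout
```

prints (abridged):

```json
{
 "bic_by_k": {"1": 970.50, "2": 977.26, "3": 984.83, "4": 994.51},
 "components": [[1.0, 25.74, 8.74]],
 "n_curves": 200,
 "n_events": 200,
 "n_specific": 134,
 "selected_k": 1
}
```

All 200 curves produce a candidate event; 134 pass the WLC specificity
gates (the planted specific fraction was 0.7).  BIC is minimized at one
component, and the recovered peak (25.7 ± 8.7 pN on this 134-event sample)
matches the planted 24.5 ± 9.9 pN distribution.  The same pattern applies
to the other stages: `cadhesion simulate frap | frap`, `simulate traces |
traj`, `simulate masks | quantify`, and `report` merges the per-stage JSON
summaries.

The library API mirrors the CLI: `cadhesion.gen_afm_curves`,
`cadhesion.analyze_curves`, `cadhesion.fit_force_mixture`,
`cadhesion.rmsf_profile`, `cadhesion.delta_sasa`,
`cadhesion.conversion_time`, `cadhesion.analyze_trace` (FRAP),
`cadhesion.aggregate_sizes`, and so on — see `docs/methods.md` for the
models and defaults.

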