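# Methods

This note documents the models, estimators and defaults implemented in
`cadhesion`, the assumptions behind the synthetic-data generators, and the
design choices made where the underlying procedures were genuinely open.

## Units and containers

Trajectory coordinates are in Å with time in ps; AFM separations in nm and
forces in pN; FRAP time in s.  All physical constants and conversions live
in `cadhesion.units` (k_B = 0.0138065 pN·nm·K⁻¹; 1 kJ·mol⁻¹·nm⁻¹ =
1.6605 pN, so a 400 kJ·mol⁻¹·nm⁻¹ pulling force is ≈ 664.2 pN).  The
default temperature everywhere is 298.15 K.

## Force spectroscopy

**Spring calibration.** Thermal-fluctuation (equipartition) method:
k = k_B·T / var(deflection), requiring ≥ 100 mean-centred samples.  With
10⁵ samples the Monte-Carlo error is well under 1%.

**Event detection.** The zero-force baseline and its noise SD are taken
from the final 10% of the retract trace.  The trace is lightly low-passed
(5-sample moving average, standing in for instrument bandwidth limiting)
and a candidate rupture is a drop of more than 3× the baseline noise SD
within 5 samples, starting from a force itself significantly above
baseline.  Nearby candidates are merged and the force is read from the raw
trace at the local peak, relative to baseline.  When a curve holds several
events, the final (largest-extension) one is analysed — the standard
single-molecule convention for serially linked tethers.

**WLC validation.** The tether stretch preceding the final event is fitted
to the Marko–Siggia interpolation F(x) = (k_B·T/p)·[1/(4(1−x/Lc)²) − 1/4 +
x/Lc] by bounded least squares over (p, Lc) with a 3×3 restart grid; the
segment is smoothed with the same 5-sample window before fitting.  A
non-converging fit flags the event rather than raising.  An event is
**specific** iff the fit converged, r² ≥ 0.9 (boundary inclusive) and Lc
falls within [0.5, 1.5]× the nominal tether contour length (default
30 nm).  A long shallow linear ramp is well approximated by a large-Lc WLC
(the low-force limit is linear), so such curves are rejected by the Lc
window; jagged multi-peak adhesion fails the r² gate directly.

**Histograms and mixtures.** Freedman–Diaconis bin width h = 2·IQR·n^(−1/3)
with linearly interpolated quartiles, edges spanning [min, max] with the
last bin padded; zero IQR falls back to the Sturges count.  The histogram
is for reporting only: the Gaussian mixture is fitted on the raw forces by
EM (scikit-learn, 10 restarts per k, best likelihood kept) for k = 1..4,
with BIC(k) = (3k−1)·ln n − 2·ln L̂ selecting k and ties broken toward
smaller k.  Component SDs are floored at 0.5 pN through covariance
regularization, so degenerate point components cannot arise.  Fitting the
raw data rather than binned counts is statistically cleaner and reproduces
the (mean ± sd) parameterization used to describe force distributions.

**Condition comparison** reports the per-component table plus a Welch
two-sided t-test on the pooled raw forces (the unequal-variance form is
the safe default when only "Student t-test" is specified).

## Trajectory observables

**Superposition** is closed-form Kabsch (SVD with determinant correction),
requiring ≥ 3 non-collinear atoms matched by order.  RMSD traces superpose
every frame onto the reference over the chosen selection; a
`superpose=False` path exists for laboratory-frame comparisons.  **RMSF**
uses the standard two-pass scheme: superpose the window frames onto the
first frame, form the mean structure, re-superpose onto the mean, then
RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩, averaged per residue (the default selection is
α-carbons).  For isotropic per-atom jitter of SD σ the expected RMSF is
σ√3, which the toy-dimer generator reproduces within a few percent once
the selection has enough atoms that the fit does not absorb the noise.

**SASA** is Shrake–Rupley with a deterministic golden-angle spiral lattice
(default 960 points — no RNG, so results are exactly reproducible), probe
1.4 Å, and a built-in van der Waals radius table (C 1.70, N 1.55, O 1.52,
S 1.80 Å …).  Neighbour culling uses a k-d tree.  Isolated spheres match
4π(r+probe)² and two-sphere systems match the spherical-cap closed form
within the ~2% lattice error.  **ΔSASA** = SASA(A) + SASA(B) − SASA(AB) is
computed with identical settings for the three terms and clamped at zero
(negatives can only be lattice noise).

**Salt bridges.** Charged-atom distance is the per-frame minimum between
donor atoms (Lys NZ by default) and acceptor oxygens (Asp OD1/OD2, Glu
OE1/OE2) — the minimum rule reflects that either carboxylate oxygen can
carry the contact.  A bridge is **stable** iff the median distance over
the analysis window is strictly below 4.0 Å; the default window is the
last two thirds of the trace, mirroring the convention of analysing the
equilibrated tail of a simulation.  Interaction **occupancy** is the
fraction of frames in contact, persistent at ≥ 40% (inclusive);
**episodes** are maximal contact runs kept when strictly longer than
0.2 ns, with a run of m frames spanning m·dt.

**Event times.** The conversion estimator smooths the RMSD trace with a
centred moving average (default 25 frames) and reports the time of the
global minimum, provided the minimum is interior — some earlier and some
later smoothed value must exceed it by at least one noise SD (estimated
from first differences), so monotone traces yield no event.  The
dissociation estimator reports the first sample at which ΔSASA ≤ ε
(default 25 Å², a noise guard around "reaches zero") and stays there for
5 consecutive frames.  On noiseless traces both estimators are exact
(the ε guard is only meaningful under noise; exactness holds at ε = 0).
On noisy ensembles at the generators' default noise the mean bias is
within one sampling step times the respective window.

## FRAP

Traces are background-subtracted and normalized to the pre-bleach mean
(≥ 3 pre-bleach frames required), then the post-bleach points are fitted
to y = A·(1 − e^(−k(t−t₀))) by bounded nonlinear least squares.  A is
initialized from the tail plateau, k from 3/(post-bleach span), and t₀ at
the bleach frame; t₀ is fitted within ±2 frames of the bleach because the
effective recovery origin sits somewhere inside the bleaching interval —
fixing it exactly at the first post-bleach frame would bias k when the
bleach is not instantaneous.  R² is computed on the fitted points and a
trace enters condition summaries iff R² > 0.7 (strict, configurable);
pure-noise traces land near R² ≈ 0 and are excluded.  t½ = ln 2 / k holds
identically for every fit.  No reference-region photobleaching correction
is applied, and no diffusion-reaction model is offered: the single
exponential is the model of record for turnover-dominated junctional
recovery.

## Quantification

Phosphorylation fraction = phospho/(phospho+unphospho) per replicate;
co-IP association = (p120/pcad) normalized to a reference condition;
surface fraction = surface/lysate.  All are built within a replicate/lane,
so common loading factors cancel exactly.  "Effective" surface cadherin
multiplies the surface fraction by the association ratio per condition and
renormalizes so the reference condition equals 1 (product first, then
normalization), under the assumption that the adapter only binds
surface-resident cadherin.  Aggregate sizing labels 8-connected components
(the ImageJ default connectivity): bead mode keeps components ≥ 30 px and
reports pixels; cell mode converts area to cells by round(area/40 px) and
keeps aggregates with strictly more than 5 cells — area division is the
only operable reading of a ">5 cells" rule on a binary mask.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their parameters and a seed, and every
dataset records its planted truth in a `GroundTruthLedger`.

* **AFM curves**: specific curves are the Marko–Siggia tether stretch
  truncated at a rupture force drawn from the planted mixture (forces
  below 5 pN are resampled — a few-pN rupture sits at the thermal
  detection floor), followed by an instantaneous drop to baseline;
  nonspecific curves are jagged sawtooths or immediate-detachment spikes.
  Generator and fitter share one WLC model deliberately: the acceptance
  question is parameter recovery, not model discrimination.  Rupture is a
  force truncation — no Bell–Evans loading-rate kinetics, because the
  analysis operates per fixed pulling velocity, not on dynamic force
  spectra.
* **FRAP traces**: plateau at 1, bleach drop, exponential recovery, with
  the protocol defaults of 10 pre-bleach and 200 post-bleach frames at
  0.863 s per frame mapped to arbitrary units over a constant background.
* **Observable traces**: the RMSD conversion signature is a symmetric
  piecewise-linear V (default slope 0.005 Å/ps, minimum 1 Å); symmetric
  slopes make the smoothed-minimum estimator exactly unbiased.  The ΔSASA
  dissociation signature is a plateau (800 Å²) with an abrupt 100-ps
  linear fall to zero — interface loss at rupture is fast compared with
  the pulling phase that precedes it.
* **Distance traces**: a two-state Markov telegraph with geometric dwell
  times (mean 10 frames in the bound state) and Gaussian emission around
  the bound/unbound means — the simplest process with a controllable
  stationary occupancy.
* **Toy dimer**: two random carbon blobs under whole-complex rigid motion
  plus isotropic jitter; it validates superposition-based estimators, not
  protein geometry.
* **Masks**: blobs grown by random 4-connected accretion to exact pixel
  counts, placed without 8-contact.

Noise is additive Gaussian everywhere.  None of the generators model
instrument drift, camera noise, photobleaching of the reference region,
force-field physics or solvent — so passing recovery tests demonstrates
the correctness of the estimators under the stated noise model, not
robustness to every artefact of real instruments.

## Problem sizes

The validation suites use the sizes at which the statistical claims are
stable and quick to verify: 1000 rupture forces per condition across 50
seeded replicates for mixture recovery; 20 seeded traces per FRAP
condition; 100-seed ensembles (5-trace ensembles for the per-condition
means) for the event-time estimators; 960-point SASA lattices; and
100-mask brute-force cross-checks for component labelling.

## Known limitations

* The WLC fit assumes a single tether; serially linked multi-tether
  ruptures are analysed only through the final event.
* The conversion-time rule (smoothed interior global minimum) is an
  operationalization; drop-then-rise shapes with very shallow minima near
  the trace edge are reported as absent rather than guessed.
* SASA radii are a fixed built-in table; per-atom parity with any specific
  MD package's radii is not attempted — correctness is anchored to the
  analytic sphere oracles instead.
* Aggregate cell counts are area-derived and hence blind to overlapping
  cells in a projection.
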