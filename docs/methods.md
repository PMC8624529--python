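# Methods

## The problem

Roux-en-Y gastric bypass (RYGB) converts the stomach into a small pouch and
takes the duodenum and proximal jejunum out of the nutrient stream.  For a
drug like metformin — a strong base (pKa 11.5), fully protonated at every
gut pH, absorbed predominantly (~90%) through the paracellular route with
effective permeability that *decreases* down the small intestine — the
bypass removes exactly the segments that absorb best, so naive reasoning
predicts reduced oral exposure.  Clinical observations show the opposite:
metformin exposure increases after RYGB.  This package implements, as open
tested code, the modeling argument that resolves the apparent paradox: a
compartmental absorption-and-transit simulation in which the post-surgery
prediction fails when the remaining gut is given no permeability information
of its own, and succeeds once segmentally measured permeability values are
assigned to the remaining segments.

## Model structure

**Gut transit.**  Nine compartments (stomach, duodenum, jejunum 1–2,
ileum 1–3, caecum, ascending colon), each a well-mixed space with fasted pH,
mean transit time T_i, resting fluid volume V_i and length L_i.  Transfer is
serial and first order with rate 1/T_i.  The stomach empties at 1/T_stomach
and does not absorb.  The RYGB transform sets the stomach to the surgical
pouch (pH 1.3→6.4, T 0.25→0.12 h, V 50→30 mL, L 30→18 cm) and zeroes
T, V, L of the duodenum and jejunum 1, flagging them bypassed.  Flow skips
bypassed compartments — the pouch empties directly into jejunum 2 — and
neither transit time nor fluid is redistributed to the survivors.  Drug
leaving the ascending colon is counted as unabsorbed.

**Absorption.**  Each non-bypassed compartment absorbs with first-order
rate constant

    ka_i = 2 · Peff_i · ASF_i / R_i,     R_i = sqrt(V_i / (π · L_i)),

the surface-to-volume relation of a cylindrical lumen; the radius is derived
from V and L rather than stored, keeping the physiology table the single
source of truth.  ASF is 1 for small-intestinal compartments.

**Colonic absorption** is doubly down-weighted, by design: colonic Peff is
assigned as 0.1 × the ileal value, and the colonic ASF is a further 0.1.
The caecum and ascending colon hold the drug for 18 of the ~22 h of total
transit; with anything less than a ~100-fold cut in absorption rate the
colon would become a major absorption site purely by residence time, which
contradicts the poor colonic absorption of a paracellular hydrophilic
cation (the tight-junction route tightens distally).  Both factors are
configuration values.

**Disposition.**  One compartment, first-order renal elimination:
dX/dt = Σ ka_i·A_i − (CL/Vd)·X, plasma concentration C = X/(Vd·BW).
Metformin is not metabolized, so bioavailability F is the fraction of the
dose absorbed; the linear-PK identity AUC0–∞ = F·Dose/(CL·BW) holds
exactly in-model and is enforced by a cross-module test at 1%.

**Solver.**  Every rate is constant in time, so the complete system
(including cumulative absorbed/eliminated/exited bookkeeping states) is a
linear constant-coefficient ODE, solved exactly by matrix-exponential
propagation on the uniform output grid (default step 0.05 h to 96 h,
≈ 10 terminal half-lives in every scenario).  This is bit-stable and has no
step-size control to fail; the settings tolerances instead bound the
accepted mass-balance residual (relative, default 1e-9) and negative-state
excursion (mg, default 1e-9), and a violation raises an error.

## Permeability inputs

**Perfusion estimation.**  Effective permeability from single-pass
perfusion follows the steady-state disappearance relation
Peff = −Q·ln(C′out/C′in)/(2πRL), with the outlet/inlet concentration ratio
corrected for net water transport by the gravimetric method: the raw ratio
is multiplied by the collected outlet/inlet fluid-mass ratio (density
1 g/mL).  Only samples after the one-hour equilibration enter; per-sample
values are averaged arithmetically, giving a mean and CV.  A corrected
ratio above 1 yields a negative per-sample value that is flagged and
retained, never clamped.

**Species scaling.**  Human jejunal Peff from rat jejunal Peff via the
affine correlation Peff,man = 3.6·Peff,rat + 0.03×10⁻⁴ cm/s.

**Paracellular model.**  A single-pore hindered-diffusion form:
P_para = capacity × (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵), λ the
molecular-to-pore radius ratio (pore radius default 6 Å — a literature
scale for the jejunum, a configuration value, not a claim).  The molecular
radius that places a target fraction (90% for metformin) of total
permeability on the paracellular route is found by bisection on the
monotone fraction.  The electrochemical enhancement a cation enjoys in a
negatively charged pore is deliberately omitted: the only quantitative
constraint available is the 90:10 split, which the fit enforces by
construction.

**Segment assignment.**  Measured values map to compartments as
jejunum → jejunum 1–2, mid small intestine → ileum 1, ileum → ileum 2–3;
the duodenal value is supplied separately (the three-segment perfusion
protocol cannot reach it); colonic compartments get 0.1 × ileal.  The
mapping is configuration-overridable.

## Scenarios and calibration

Four scenarios carry the subject-level parameters (dose, body weight, renal
clearance, volume of distribution): healthy (500 mg, 63.4 kg, 0.5177 L/h/kg,
1.784 L/kg), obese control (1000 mg, 114.6 kg, 0.18, 1.0), and two
post-RYGB cases (1000 mg, 104.0 kg, 0.258, 1.4) differing only in how
permeability is assigned.

The conversion from in vitro apparent permeability to in vivo human Peff is
proprietary to commercial simulators, and the measured rat segmental values
are published only as bar charts, so the permeability *scale* is the one
free parameter: a single multiplier on the profile (ratios preserved),
fitted by bisection against a published predicted AUC0–24 anchor
(control 12,810; adjusted post-RYGB 14,830 ng·h/mL).  Total absorption is
monotone in every compartment's permeability, hence in the multiplier, so
the root is unique.  Every metric other than the anchored AUC0–24 is a
genuine out-of-anchor prediction.

Profile shapes per scenario:

* healthy, control — segmental ratio profile anchored at the jejunum
  (duodenum 1.2 : jejunum 1.0 : mid SI 0.75 : ileum 0.5, colon 0.1 × ileal),
  encoding the distally decreasing permeability of a paracellular compound;
  the ratios are configuration defaults, never asserted as measured truth.
  The healthy scenario shares the control-calibrated multiplier (same
  compound-level permeability source, different subject) and has no
  published numeric surface; it contributes the qualitative
  proximal-dominant regional-absorption check.
* rygb_naive — the *control's* multiplier with a single jejunal-anchored
  value spread uniformly, on the bypass physiology.  No recalibration: the
  scenario exists to show that carrying the pre-surgery permeability
  assumption into the post-surgery gut underestimates absorption.
* rygb_adjusted — the segmental profile on the bypass physiology,
  recalibrated on its own anchor.

## Noncompartmental metrics

Cmax/Tmax from the dense grid with quadratic vertex refinement around the
peak (ties broken to the earliest time); AUC by linear trapezoid with
endpoint interpolation; AUC0–∞ adds C_end/λz, λz fitted log-linearly over
the final 20% of the profile.  Note a structural subtlety: when colonic
trickle absorption is active, the terminal slope is *absorption-limited*
(flip-flop kinetics — the colonic exit rate ≈ 1/13.5 h⁻¹ is slower than
CL/Vd), which the λz fit captures automatically; with colonic absorption
off, λz recovers CL/Vd.  At the 96 h horizon the remaining tail is well
under 0.1% of AUC in every packaged scenario.

## Synthetic data

The perfusion generator inverts the disappearance relation: outlet
concentration Cin·exp(−2πRL·Peff/Q), concentrated by 1/(1−w) under net
water flux w (collected outlet mass scaled by 1−w, so the gravimetric
correction exactly recovers the clean ratio), with mean-one multiplicative
lognormal noise.  Protocol defaults: 0.2 mL/min, 50 µM inlet, R 0.2 cm,
L 10 cm, six samples at 10-min spacing from t = 70 min.  Noise CV defaults
to 10% and net water flux to 2% per interval — chosen once as realistic
combined assay/biological variability for an in-situ perfusion; neither is
printed in a reference and both are spec fields.  The plasma generator
samples a scenario's simulated profile under the same noise model.  What
these generators do *not* emulate: inter-animal variability structure
beyond i.i.d. sample noise, time-varying water flux, pH drift, or any
misspecification of the absorption model itself — so recovery tests
demonstrate estimator correctness under the model's own assumptions, not
robustness to real biological structure.

## Numerical choices

* Bisection tolerances: calibration to 0.5 ng·h/mL on the AUC anchor
  (relative ≈ 4×10⁻⁵); molecular-radius fit to 1×10⁻⁶ on the fraction.
* Unit chain: amounts mg, Peff cm/s (×3600 into the hourly rate constant),
  volumes mL, lengths cm, concentrations ng/mL (mg/L × 1000), AUC ng·h/mL.
* Degenerate inputs error loudly: bypassed compartments have no radius or
  transit rate; a corrected perfusion ratio ≤ 0 has no logarithm; a
  calibration target outside the bracket reports the metric at both bounds.
* Determinism: the pipeline is seed-free and bit-stable; generators are
  deterministic under a fixed seed.

## Known limitations

* The absorption-scale conventions here are not those of commercial ACAT
  implementations (whose ASF models are proprietary); predictions carry a
  shape mismatch of order 10% in Cmax/Tmax even when AUC is anchored.  The
  predicted bioavailability runs ~1% relative above the reference
  predictions for the same anchor.
* Dissolution is instantaneous (dose number ≪ 1 for metformin at its
  solubility); insoluble or slowly dissolving drugs are out of scope.
* No transporter kinetics (the paracellular route dominates for metformin),
  no enterohepatic recirculation, no first-pass metabolism, no fed-state
  physiology, no fluid-volume dynamics (static volumes enter only through
  compartment geometry).
* The transverse and descending colon are not modeled; absorption past the
  ascending colon is treated as zero.
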