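# Methods

This note documents the models implemented in `stochlung`, the choices
made where the underlying study left the design open, and what the
synthetic-data pipeline does and does not establish about real data.

## Problem setting

Patients with severe COPD inhale drugs through devices whose
effectiveness depends on the inhalation maneuver.  The study this
package models recorded, for each subject and device, the
through-device inspiratory vital capacity (IVC_d, L), peak inspiratory
flow (PIF_d, L/s), inhalation time (t_in, s) and breath-hold time
(t_bh, s), twice per device, and converted each maneuver into a
pulmonary deposition fraction (PD) and an extrathoracic deposition
fraction (ETD), both in % of the metered dose, using a stochastic
whole-lung Monte Carlo model.  Repeatability of the deposition values
was then assessed by Bland–Altman statistics, and devices ranked per
subject by the absolute difference between the two computed values.

Only group-level summaries of that study were published (maneuver
means ± SEM per group and device, lung function in % predicted, and
the full Bland–Altman grid).  Those summaries are shipped in
`stochlung.study` and serve as generation targets and as validation
anchors; subject-level values are synthesized.

## Flow-profile reconstruction

The spirometer's raw flow trace is not available, so a profile Q(t) is
reconstructed from the three flow summaries:

* if IVC_d/PIF_d ≥ t_in/2: a symmetric trapezoid with ramp time
  t_ramp = t_in − IVC_d/PIF_d and a plateau at PIF_d.  This family
  reproduces peak, volume and duration exactly and covers every
  group-mean maneuver in the study.
* otherwise (peaky breaths): a linear rise over 0.1·t_in to PIF_d
  followed by an exponential decay whose time constant is solved by a
  bracketed root find so the truncated integral equals IVC_d
  (tolerance < 1e-9 L in the solver, closure asserted to 1e-6 L).

The breath-hold is appended with zero flow.  Exhalation is unrecorded;
it is modeled as a mirrored trapezoid (25 % ramps) of the same duration
(configurable multiplier, default 1.0) and the same volume.  Records
with IVC_d up to 1 % above PIF_d·t_in are accepted (rounding slack) and
clamped to a rectangular profile; anything worse is rejected.

## Airway geometry

The conducting tree is never stored; one stochastic *path* from the
trachea to a terminal bronchiole is sampled per particle:

* Baseline per-generation lengths and diameters follow the classic
  adult symmetric morphometry at a 4,800 mL reference volume (packaged
  CSV, trachea 1.8 cm diameter / 12 cm length down to terminal
  bronchioles of ~0.05–0.06 cm).
* Lengths and diameters are lognormal around the baseline means with
  CV 0.30; the daughter's log-diameter is correlated 0.5 with the
  sampled parent.  Branching angles are uniform on 15–60°; gravity
  angles are sampled with cos φ uniform on [−1, 1]; the terminal
  conducting generation is uniform on 12–17.  None of these
  distribution families were published; all are configurable.
* At each bifurcation a sibling diameter is sampled and the followed
  tube receives the d²-rule share of the parent flow,
  f = d²/(d² + d_sib²).  The followed tube's own diameter is a fresh
  correlated marginal draw, so per-generation path statistics reproduce
  the morphometry table (a flow-weighted choice of the followed
  daughter would size-bias mean path diameters upward by ~7 %, which
  would contradict the table the distributions are defined by).  The
  asymmetry of flow division survives in the flow-fraction
  distribution, which controls residence times and penetration depths.
* The acinus appends 8 partially alveolated duct generations
  (total path depth ~0.8 cm) with the alveolated wall fraction ramping
  0.2 → 1.0; acinar dimensions are deterministic by default.

All linear dimensions are rescaled isotropically by
(V/V_ref)^(1/3).  During a simulation a single scale factor per
maneuver is used, evaluated at the mean inhalation volume
RV + IVC_d/2 (a time-resolved rescaling changes PD by far less than
the Monte Carlo noise at the default particle counts and complicates
the volumetric bookkeeping).

## Deposition physics

Particles are characterized by their aerodynamic diameter (unit
density), with Cunningham slip correction
Cc = 1 + (λ/d)(2.514 + 0.8·e^(−0.55 d/λ)), λ = 0.066 µm, settling
velocity v_s = ρ g d² Cc/(18 µ) and Stokes–Einstein diffusivity at
310 K.  Per-airway deposition probabilities:

* impaction (Yeh–Schum form) at each bifurcation,
  p = 1 − (2/π)arccos(θ St) − (1/π)sin(2 arccos(θ St)) for
  θ St < 1 (else 1), with the Stokes number built from the parent
  tube's mean air speed and diameter;
* settling p = 1 − exp(−4 v_s |cos φ| t/(π D));
* diffusion p = 1 − exp(−k D_diff t / R²) with k = 5.784 (first
  Fourier mode of a cylinder).

Mechanisms combine independently,
p = 1 − (1−p_i)(1−p_s)(1−p_d).  Inside alveolated spaces during the
breath-hold, settling acts over the alveolar radius
(r_alv = 0.014 cm): p = 1 − exp(−v_s t / r_alv), combined with the
diffusive term.

The mouth–throat (extrathoracic) compartment is a single empirical
stage: η = [1 − exp(−a (d²Q)^b)] ⊕ η_diff, with d in µm, Q in L/min,
defaults a = 1.1e-4, b = 1.4, and a small-particle diffusive term
η_diff = 1 − exp(−9·sqrt(D t_ET)/R_ET), t_ET = V_ET/Q, V_ET = 50 mL,
R_ET = 1 cm.

### Device presets and the throat coefficient

The study does not print the particle size distributions it used.  The
shipped presets are literature-informed configuration, not claims:
Foster/Trimbow extrafine pMDI MMAD 1.4 µm, GSD 2.0, emission window
(0, 0.3) s; Respimat soft mist MMAD 4.5 µm, GSD 1.8, window (0, 1.5) s;
density 1 g/cm³.

A breath-flow-only impaction parameter d²Q cannot reproduce the
device physics of the throat: pMDI sprays leave the nozzle at tens of
m/s and deposit 60–70 % of the dose in the mouth–throat of healthy
adults regardless of the (extrafine) particle size, while the slow
mist of the SMI deposits less despite its larger droplets.  Rather
than model plume dynamics (out of scope), each device preset carries a
single empirical throat impaction coefficient `et_coeff` replacing the
default `a`: 8e-3 for the pMDIs, 3e-5 for the soft mist.  Both values
were fixed by hand calculation against the healthy-adult throat
deposition scale above before any end-to-end simulation was run, and
not adjusted afterwards.

With these defaults the simulated Control group lands at
PD ≈ 31 % (pMDI) and ≈ 42 % (SMI), with the SMI above both pMDIs in
PD and below both in ETD, in every group — the study's headline
ordering.  Two documented deviations from the study's printed levels
remain: (i) the COPD groups run higher in PD (≈ 41–54 %) than the
study's ~25–39 % because the only group-dependent driver of throat
deposition in this model is the inspiratory flow, which is lower in
COPD; (ii) absolute levels everywhere depend directly on the assumed
PSDs and throat coefficients.  Orderings are robust to these choices;
levels are not.

## Monte Carlo transport

Per particle: a diameter is drawn from the device lognormal; an entry
time uniform in the emission window (clipped to the inhalation); a
mouth–throat Bernoulli trial with η(d, instantaneous Q); survivors ride
the volumetric flow front along a freshly sampled path.  Crossing
airway *i* costs inhaled volume v_i/F_i (tube volume over cumulative
flow fraction), so the crossing times follow from inverting the
cumulative inhaled-volume curve of the reconstructed profile (1024-
point grid, linear interpolation).  A particle halts where the air
inhaled behind its entry time runs out, sits there for the breath-hold
(alveolar closed forms if the halt is acinar), and retraces its path
during the mirrored exhalation with the same mechanism set (impaction
evaluated with the exhalation flow; no bifurcation-direction
correction).  Particles exiting generation 0 count as exhaled.

Tallies are percent of *tracked* particles; device and mouthpiece
retention is not modeled, so "percent of metered dose" is interpreted
as percent of inhaled dose (documented limitation).  PD + ETD +
exhaled = 100 is asserted to 1e-9 on every run.  Reported standard
errors are binomial, sqrt(p(1−p)/N)·100.

Randomness uses numpy's counter-based Philox generator with a fixed
vectorized draw order; per-maneuver seeds in cohort runs are derived
from crc32 of `subject|device|repetition` mixed with the master seed,
so results are reproducible row-by-row regardless of execution order.
Setting `repetition_seed=False` makes both repetitions share a stream,
which is the configuration in which zero maneuver variability must
yield exactly zero repeatability coefficients.

## Repeatability statistics

For the difference vector d = first − second: bias = mean(d), sd_d
with the n−1 denominator, LoA = bias ± 1.96 sd_d, and
CR = 1.96·sqrt(Σd²/n) — the root-mean-square definition, which is the
only one consistent with all 18 published grid rows (verified
arithmetically from each row's bias and LoA; the package implements
both algebraic routes and tests them against each other to 1e-12).
The bias is tested by a two-sided one-sample t test (df = n−1).  One
published p-value (Control / lung / Trimbow, printed 0.005)
reconstructs to ≈ 0.009 from its own bias and LoA; the standard t test
is implemented and the discrepancy left as published.

Ranking gives rank 1 to the device with the smallest |d| per subject;
ties (measure-zero with continuous inputs) break by the fixed device
order and are logged.  Group comparisons auto-select ANOVA +
Bonferroni-corrected pairwise t tests when every group passes Shapiro
normality at α = 0.05, otherwise Kruskal–Wallis with Dunn's
tie-corrected rank z tests; groups with n < 3 force the nonparametric
branch.

## Synthetic cohort

Per group (Control n = 17, S-COPD n = 13, AE-COPD n = 12 by default —
the published sizes; any synthetic n can be requested): subject-level
parameters are truncated-normal around the published group/device
means with SD = SEM·√(published n) — the between-subject SD the
published SEM implies — with the truncation location adjusted so the
*mean* of the truncated draw equals the published target exactly.  A
latent severity factor (loading 0.6) couples hyperinflation (RV, TGV)
positively and IVC_d/PIF_d negatively, giving the physiological
negative RV–IVC_d correlation.  Lung volumes come from % predicted
times reference volumes (RV 1.8 L, TLC 6.0 L, FRC 3.0 L,
configurable).  The two pMDI products share each subject's physical
pMDI maneuver, as in the study (one placebo pMDI served both).

Repetition 2 equals repetition 1 times mean-one lognormal noise with
intra-subject CV 0.08.  No intra-subject repetition variability was
published; 0.08 was chosen once so that synthetic Bland–Altman CRs
fall in the single-digit percentage-point range of the published grid,
and it is the most consequential knob in the config — all synthetic
repeatability magnitudes scale with it.

Draws violating IVC_d ≤ PIF_d·t_in redraw only t_in (up to 100 tries,
then clamp to 1.02·IVC_d/PIF_d).  Redrawing the whole tuple would
condition the population on feasibility and bias the recovered IVC_d
and PIF_d means by several percent; the t_in repair leaves those
marginals untouched at the cost of a mild upward shift of the
generated t_in mean (≈ 2.6 s vs the published 2.23 s for Control
pMDI), which no recovery target constrains.

### What the synthetic pipeline does and does not show

The generator reproduces the published *group-level* maneuver
statistics and plausible subject-level correlation structure.  It does
not emulate real within-subject maneuver physiology (fatigue, learning
effects, device handling errors), multimodal aerosols, or the actual
PSDs of the products; passing tests therefore demonstrate the
*machinery* — conservation, convergence to closed forms, statistical
identities, orderings — not clinical deposition values for real
patients.

## Numerical choices and problem sizes

Defaults: 100,000 particles per maneuver for headline numbers
(binomial SE ≈ 0.15 percentage points), 1,024-point time grids,
root-find tolerances 1e-12, LoA multiplier 1.96.  The test suite uses
800–20,000 particles for machinery checks and the full 100,000 for the
oracle, monotonicity and ordering checks; the synthetic recovery check
uses 10,000 Control subjects.

## Known limitations

* Absolute PD/ETD levels are preset-dependent (PSDs and throat
  coefficients are assumptions); only orderings and group contrasts
  are robust outputs.
* Per-generation deposition tallies are reported but unvalidated;
  central vs peripheral partitioning is out of scope.
* No pressure-drop/resistance modeling, no hygroscopic growth, no
  electrostatics, no mucociliary clearance, no device/mouthpiece
  retention.
* Exhalation is a mirrored trapezoid with assumed 25 % ramps; passive
  exhalation was not recorded.
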