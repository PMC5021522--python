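# Methods

## System and measurement model

A biomembrane force probe holds a ligand-coated bead on an aspirated red
blood cell that acts as a calibrated linear spring: force equals spring
constant × probe-bead deflection at every sample (default 0.3 pN/nm). A
receptor-bearing target (a platelet carrying GPIbα) is driven through
repeated approach → impinge → contact → retract cycles. Retraction at
constant speed (3.3 µm/s, nominal loading rate ≈ 1000 pN/s) loads any bond
formed during contact; in force-clamp mode a feedback loop then holds the
force at a preset level (10/25/40/60 pN) until the bond dissociates.

Two unfolding signatures are analysed:

* **ramped unfolding** — during loading, a domain unfolds and releases
  contour length, producing a transient force stagnation/drop (kink) and an
  extension jump on the force–extension curve;
* **clamped unfolding** — during the constant-force hold, an abrupt force
  drop that does not collapse to zero, of magnitude spring constant ×
  released extension, followed by feedback recovery.

## Synthetic-data generator

The simulator (`mechanobfp.simulate`) renders full traces from a mechanical
model: the molecular tether is a Marko–Siggia worm-like chain in series
with the probe spring; target displacement is partitioned between chain
extension and probe deflection by solving the series force balance on a
precomputed load curve. Unfolding increments the tether contour length by
the domain's contour length (25.99 nm MSD, 70.29 nm LRRD), so ramped kinks
and extension jumps are WLC-consistent by construction; the released
extension at force F is z(F)·ΔL_c, where z is the WLC extension fraction.

Stochastic structure, per cycle:

* bond formation is Bernoulli (default adhesion probability 0.15, matching
  the low-adhesion single-bond regime; at 20% adhesion the Poisson
  bond-number model gives >89% single bonds);
* ramped unfolding is threshold-force crossing with Gaussian thresholds
  truncated to the observable 5–20 pN kink range — LRRD N(15, 3) pN with
  per-cycle propensity 0.13, MSD N(12, 3) pN with propensity 0.10. The
  LRRD centre exceeds the MSD centre (a higher force is required to unfold
  the LRRD), and the implied released extensions (≈ 35–45 nm LRRD,
  ≈ 12–18 nm MSD) reproduce the reported length subpopulations;
* clamp-phase lifetimes are dual-exponential with parameters per
  (ligand, force, LRRD±); times-to-unfold are exponential with rate k_u;
  the event is rendered only if t_u < t_b. Cooperativity between the
  domains is therefore emergent: LRRD unfolding switches the lifetime
  distribution to the long-lived set, which raises the chance that t_u is
  reached;
* Gaussian force noise (1 pN s.d., a typical probe thermal noise) at 1 kHz
  sampling; feedback responds to a clamp drop after a 20 ms delay and
  restores the setpoint over 50 ms.

The per-force dual-exponential table (`mechanobfp.params.LIFETIME_TABLE`)
is a synthetic reconstruction: the 25 pN wild-type entries are solved so
that the closed-form clamped-unfolding probabilities equal the published
21.5% (LRRD−) and 46.2% (LRRD+) with k_u = 0.870 s⁻¹, with fractions and
rates in the physiological range of dual-exponential lifetime fits; the
other forces emulate the catch-slip (wild-type) and slip-only (R1450E)
patterns. They define the study conditions for all simulation-based tests
and are not fitted to any test outcome.

**Observability convention.** Ground-truth events carry an `observable`
flag set by physics, not by the detector: a clamped unfolding within one
feedback response (≈ 35 ms) of dissociation collapses with it and is
indistinguishable from plain dissociation; a ramped kink below ≈ 6.5 pN
releases too little extension (z < 0.4) to clear the tracking noise.
Detector completeness is quantified against observable events; precision is
quantified against all detections. Under the default 25 pN conditions
roughly 7% of clamped events and 2% of ramped events are censored this way.

**Calcium coupling.** Sessions of ~50–70 cycles span ≈ 200 s. An α-type
response (latency, fast rise over ~3 s, fast decay) is triggered by the
first clamped MSD unfolding in a cycle whose running longest lifetime
exceeds 2 s, provided the trigger falls early enough for the rise to be
recorded; sessions with lifetime events but no α trigger give a β-type
response (slow rise over ~30 s, low amplitude) with probability 0.6 and a
null trace otherwise. Amplitudes increase mildly with t_max (slope
0.08 /s for α, 0.03 /s for β, noise s.d. 0.06), which produces the
positive ΔI_max–t_max correlation. These shapes are phenomenological; the
generator does not emulate photobleaching, focus drift, or heterogeneous
platelet responsiveness, so passing tests validate the analysis chain, not
biological variability.

## Detection algorithms

Traces are smoothed with Savitzky–Golay filters (order 3; window 21
samples for segmentation, shorter windows where sharp features matter).
Cycle outcome: no-bond if the peak tensile force is below 5 pN; lifetime if
the clamp level is reached (within 2 pN, sustained ≥ 5 ms); rupture
otherwise. Dissociation is a sustained (≥ 5 ms) collapse below 2 pN; the
bond lifetime runs from clamp attainment to dissociation.

**Clamped unfolding** is found as a negative step of the smoothed force
inside the hold that (i) does not collapse below the dissociation level and
(ii) either recovers to the clamp level under feedback or holds a clear
post-drop plateau ≥ 12 ms before a subsequent dissociation. The released
length is (pre-drop − post-drop force)/spring constant; t_u is the drop
onset relative to the first approach to the clamp level.

**Ramped unfolding** uses a contour-length transform of the
force–extension curve (extension = target displacement − probe deflection,
zeroed at the tensile onset located on a heavily smoothed force channel):
each sample above 5 pN is mapped to L_c(t) = extension / z(force). Along an
unperturbed ramp L_c(t) is constant; unfolding is a step. Steps are called
where the difference of 12-sample block means (guard zones half a smoothing
window before, plus the feedback/reload transient after) exceeds 18 nm of
contour, with the threshold scaled up when edge effects shorten a window.
Candidates within ~10 ms merge into one event — two domains unfolding
within too short an interval are unresolvable and are reported as a single
event with the summed length. Event force is the pre-branch ramp
extrapolated to the step; event length is reported as released extension at
that force (z × contour step), the scale on which the unfolding-length
histograms and the force-vs-length WLC fits are built. Detected events
shorter than 10 nm are below the detection limit and dropped. A
slope-deficit criterion (slope below a fraction of the nominal loading
rate) was evaluated first but has poor sensitivity at ~1000 pN/s, where a
kink lasts only ~10 ms; the contour-transform step statistic detects the
same events with far better contrast and was adopted instead.

On labeled simulated ensembles at the default conditions the detector
achieves ≈ 97–99% recall on observable events, ≈ 97–100% precision, a
pooled median length error ≈ 1.6 nm, t_u resolution ≈ 3 ms, and < 1%
false calls per event-free trace.

`ramped_unfolding_length` offers two estimators on a force–extension
curve — the extension jump at the event and the difference of WLC contour
lengths fitted before/after — reported on a common scale (extension or
contour units, related by z(F)), on which the two agree to a few nm.

## Fitting choices

* **WLC fits** (Marko–Siggia, persistence length fixed at 0.5 nm by
  default, optionally free; k_BT = 4.28 pN nm at 310 K): nonlinear least
  squares with standard errors from the parameter covariance. Force (not
  length) is treated as the noisy response, matching how averaged
  force-vs-length points are built.
* **Exponential dwell fits**: reciprocal mean (the MLE, exact gamma
  confidence interval) or log-survival slope; both agree on exponential
  data and are cross-checked in tests.
* **Dual-exponential lifetimes**: direct maximum likelihood over
  (w₁, log k₁, log k₂) with 10 random restarts (Nelder–Mead); k₁ ≥ k₂
  identifiability convention; standard errors from the observed
  information; a likelihood-ratio statistic against the nested single
  exponential, with degenerate convergence (k₁ ≈ k₂ or a vanishing weight)
  flagged as a single-exponential collapse. The R1450E mutant is fitted
  pooled over LRRD status (too few post-LRRD events exist to segregate).
* **Bell model**: log-linear regression of rate on force; equal to the
  direct nonlinear fit for noiseless data. The measured 0.870 s⁻¹ at
  25 pN and the Bell pair (0.26 s⁻¹, 0.242 nm) are kept as separate
  anchors — they are not exactly mutually consistent at any single k_BT —
  and the simulator uses the measured value at 25 pN and the Bell
  extrapolation elsewhere.
* **χ² independence**: Pearson, no continuity correction (the uncorrected
  statistic reproduces the published worked value; Yates' correction would
  not), via `scipy.stats.chi2_contingency`.
* **Freedman–Diaconis width** 2·IQR·n^(−1/3): the quartile convention is
  an explicit argument (default type-7 linear interpolation) because the
  width depends on it; the hand-checked example uses midpoint quartiles.
* **Kernel density estimation**: Sheather–Jones solve-the-equation plug-in
  bandwidth (implemented here, cross-checked against R's `bw.SJ`), Gaussian
  or Epanechnikov kernel (canonical-bandwidth rescaling between them),
  peaks from local maxima with a 2.5%-of-mode prominence floor.
* **Calcium typing**: null below ΔI_max = 0.05; α requires a spike shape
  (rise time < 10 s and decay half-life < 30 s) and ΔI_max above 0.5;
  otherwise β. Onset = first run of 3 frames above baseline + 5 baseline
  noise s.d. Typing is scale-invariant by normalization.
* **ROC threshold**: predict α when t_max > t₀; the optimal t₀ minimizes
  false positives + false negatives, ties resolved toward the smaller
  (more sensitive) threshold; AUC by the trapezoid rule over the staircase.

## Problem sizes and numerical tolerances

Simulation-backed tests use 600 rendered cycles (detector metrics), 10⁴–
3×10⁴ outcome-only draws (distributional checks; the outcome sampler and
the trace renderer consume the same per-cycle draw routine, so they are
statistically identical), 40–50 sessions of 60 cycles (calcium linkage),
and 100-case parameter sweeps for the closed-form vs. quadrature identity
(tolerance 10⁻⁴). WLC inverse round-trips are checked to 10⁻⁹ relative;
the acceptance computations average 100–200 replicate fits so the reported
estimates are dominated by the estimator, not by a single noise draw.

## Known limitations

* The contour-length transform assumes the tether is a single WLC with the
  configured persistence length; heterogeneous linkers or instrument drift
  would bias the extension origin (the dominant residual error already at
  the few-nm level here).
* Events censored by dissociation (above) are invisible in principle;
  measured clamped-unfolding frequencies are accordingly a lower bound,
  which the closed-form model shares by construction (it conditions on the
  same t_u < t_b race).
* The calcium generator encodes the coupling rule being tested; sessions
  validate the linkage analysis (pre-onset statistics, correlation, ROC),
  not the biological claim itself.
* Real-platelet condition counts and group means cannot be reproduced at
  desk scale; simulation-based pattern checks cover them qualitatively
  only.
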