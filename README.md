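# mechanobfp

Analysis of biomembrane-force-probe (BFP) single-bond experiments on the
platelet mechanoreceptor GPIbα: detection and measurement of force-induced
domain unfolding in force–time traces, worm-like-chain (WLC) contour-length
fitting, dwell-time kinetics, a joint-probability model of cooperative
domain unfolding, and the linkage between bond mechanics and single-platelet
calcium signaling. A synthetic cycle/session generator with ground-truth
labels stands in for the instrument, so every stage of the pipeline is
testable end to end.

The package is written for single-molecule biophysicists analysing
force-clamp / force-ramp spectroscopy of receptors with force-unfoldable
domains — here GPIbα's leucine-rich-repeat domain (LRRD) and its
juxtamembrane mechanosensory domain (MSD), pulled via VWF-A1 or antibodies.

## The models at the core

**WLC elasticity (Marko–Siggia).** An unfolded domain behaves as a worm-like
chain: the force at extension *x* is

F(x) = (k_BT/p) · [ 1/(4(1 − x/L_c)²) − 1/4 + x/L_c ],

with contour length L_c and persistence length p (default 0.5 nm,
k_BT = 4.28 pN·nm at 310 K). Fitting mean unfolding force vs. length data
yields L_c ≈ 26 nm for the MSD and ≈ 70 nm for the LRRD, which is how
unfolding events are assigned to domains.

**Dwell-time kinetics.** Clamp-phase MSD times-to-unfold are exponential,
p(t_u) = k_u·e^(−k_u·t_u) (k_u = 0.870 s⁻¹ at 25 pN, estimated as the
reciprocal mean or the slope of log-survival). Bond lifetimes are
dual-exponential, p(t_b) = w₁k₁e^(−k₁t_b) + (1−w₁)k₂e^(−k₂t_b), with
separate parameter sets depending on whether the LRRD unfolded during the
ramp. The force dependence of k_u follows the Bell equation
k(f) = k⁰·exp(f·x‡/k_BT), with k⁰ = 0.26 s⁻¹ and x‡ = 0.242 nm.

**Joint-probability model.** If unfolding and dissociation are independent,
the chance of observing clamped MSD unfolding (t_u < t_b) is

P_u = w₁·k_u/(k_u + k₁) + (1 − w₁)·k_u/(k_u + k₂),

21.5% without and 46.2% with prior LRRD unfolding at 25 pN via wild-type
A1 — the mechanism by which LRRD unfolding, through prolonged lifetimes,
cooperatively promotes MSD unfolding. Cooperativity in per-cycle unfolding
tables is quantified by Pearson's χ² and ΔP/P = P(both)/(P(MSD)·P(LRRD)) − 1.

**Mechanics → signaling.** Platelet calcium traces are typed null/α/β by
amplitude and shape; the pre-calcium longest bond lifetime t_max correlates
with the calcium amplitude ΔI_max, and an ROC sweep of t_max thresholds
separates α from β responders (optimal threshold ≈ 2 s).

## Worked example

```python
import numpy as np
from mechanobfp import SimParams, simulate_cycle, analyze_cycle
from mechanobfp.coop import ContingencyTable2x2, chi_square_independence, single_bond_probability
from mechanobfp.kinetics import predict_unfold_probability
from mechanobfp.params import MSD_UNFOLD_RATE_25PN, lifetime_params

for lrrd in (False, True):
    pu = predict_unfold_probability(MSD_UNFOLD_RATE_25PN,
                                    lifetime_params("A1WT", 25.0, lrrd))
    print(f"P(unfold before dissociation | LRRD{'+' if lrrd else '-'}) = {100*pu:.1f}%")

chi2, df, p = chi_square_independence(ContingencyTable2x2(14, 11, 25, 95))
print(f"chi2 = {chi2:.2f} (df={df}, p = {p:.2e})")
print(f"single-bond fraction at 20% adhesion: {100*single_bond_probability(0.2):.1f}%")

params = SimParams(adhesion_probability=1.0)
trace, truth = simulate_cycle(params, np.random.default_rng(6))
result = analyze_cycle(trace)
print(f"cycle outcome: {result.outcome}, lifetime = {result.bond_lifetime:.2f} s")
for ev in result.events:
    print(f"  {ev.phase} unfolding: {ev.length:.1f} nm at {ev.force:.1f} pN, t_u = {ev.t_u:.2f} s")
```

prints

```
P(unfold before dissociation | LRRD-) = 21.5%
P(unfold before dissociation | LRRD+) = 46.2%
chi2 = 13.01 (df=1, p = 3.09e-04)
single-bond fraction at 20% adhesion: 89.3%
cycle outcome: lifetime, lifetime = 2.71 s
  clamped unfolding: 17.2 nm at 24.9 pN, t_u = 1.60 s
```

The first two lines are the closed-form clamped-unfolding probabilities at
a 25 pN clamp; the χ² rejects independence of LRRD and MSD unfolding
(cooperativity); the last lines show the detector recovering a clamped MSD
unfolding event (force drop / spring constant ≈ 17 nm released extension)
from a simulated noisy trace.

A full pipeline run (simulate → detect → classify → kinetics →
cooperativity → calcium) is driven by a YAML config:

```sh
mechanobfp run --config cfg.yaml     # writes summary.json per force level
mechanobfp simulate --mode clamp --clamp-force 25 --n-cycles 100 --seed 7 --out sess/
mechanobfp detect --in sess/ --out events.csv
```

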