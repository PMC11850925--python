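# Methods

This note documents the models behind `cifsim`, the defaults and why they
were chosen, and what the synthetic fixtures can and cannot say about real
blood.

## Element design

**Lamina model.** The flow fraction extracted through a gap equals the flux
carried by a wall-adjacent lamina of width *w*<sub>l</sub>. The default
velocity profile is the depth-averaged plane-Poiseuille parabola across the
channel width, whose cumulative flux fraction is F(x) = 3x² − 2x³ with
x = d/w. Channel depth (~150 µm) is comparable to or larger than both the
lamina (<10 µm) and the width scales, so a 2-D profile across the width is
the natural first model; the full rectangular-duct profile (depth-averaged
double-cosh series) is available behind `profile="duct"` and changes lamina
widths by a few percent, and `profile="uniform"` gives the plug-flow limit.
Inversion (fraction → width) is by bracketed root finding to 1e-12 relative.

**Design recurrence.** The cutoff is fixed at gap 0 by
(*f*\*, *w*<sub>r</sub>\*): *w*<sub>l</sub> = F⁻¹(*f*\*)·*w*<sub>r</sub>\*.
At every subsequent gap the fraction is recomputed from the current width so
the same lamina is extracted; the retentate flow then shrinks by
(1 − 2*f*<sub>gap</sub>(*i*)) (two symmetric side gaps). The default width
rule keeps the mean retentate velocity constant
(*w*<sub>r</sub>(*i*) ∝ *Q*<sub>r</sub>(*i*)), clamped at a minimum
manufacturable width (default 2 × gap width = 40 µm, so the gap posts stay
separable); after the clamp the fraction keeps growing in a fixed-width
channel. The alternative `width_rule="fixed"` never narrows the channel, so
the fraction is constant — the analytic reference mode in which the gap
count for a target flow ratio has the closed form
N = ⌈ln(1/(1+FR)) / ln(1 − 2f)⌉ (1521 gaps for f = 10⁻³, FR = 20).
A design is infeasible (structured error carrying the failing gap index)
when the required per-side fraction would reach 0.5, or — in strict mode —
when the velocity rule would push the width below the minimum.

**Defaults.** *w*<sub>r</sub>\* = 230 µm with *f*\* = 1.00 × 10⁻³ puts the
size cutoff 2*w*<sub>l</sub> ≈ 8.5 µm between typical lymphocyte (7.5 µm)
and monocyte (9.5 µm) diameters, which is what produces the observed
CE ordering (PLT < LYM < PMN < EOS/MON ≈ blasts). Gap width 20 µm, depth
150 µm, target FR = 20. The four study designs differ only in
*f*\* ∈ {0.72, 1.00, 1.28, 1.70} × 10⁻³, giving increasing cutoffs.
Units throughout: lengths µm, flows µL/min, concentrations cells/µL;
gap indices 0-based.

## Separation model

**Capture probability.** A cell of radius r at gap *i* is captured with
probability p = *f*<sub>gap</sub>(*i*) · F(*w*<sub>l</sub> − r)/F(*w*<sub>l</sub>)
(zero for r ≥ *w*<sub>l</sub>): the fraction of the lamina flux the cell's
center can actually sample. This is the simplest model consistent with the
steric-exclusion threshold; a hard cutoff and a soft power-law model
(`steric_model="hard"` / `"soft:q"`) are selectable. Between gaps cells are
assumed to re-mix across the flux-weighted cross-section (incremental
extraction perturbs the profile by ~10⁻³ per gap), so retention through the
element is the independent product ∏(1 − 2p(d, i)). Point particles recover
the fluid split exactly: retention → 1/(1 + FR).

**Transport paths.** The deterministic path integrates retention over each
population's log-normal diameter distribution by 64-node Gauss–Hermite
quadrature. The Monte-Carlo path simulates individual cells (one uniform
draw inverts the cumulative survival sequence, which is exactly the
sequential per-gap Bernoulli process) and serves as the stochastic oracle:
the two agree within binomial error by construction of the physics, and the
test suite asserts this at 3 standard errors with 10⁵ cells.

**Deliberate omissions.** Margination, deformability, hematocrit-dependent
cell–cell interactions and lift are ignored; the model is a dilute,
rigid-sphere, low-Reynolds approximation. The practical consequence: red
cells, modelled as rigid spheres of 5.5 µm effective diameter, are predicted
to be substantially retained, whereas real discocytes deform and follow the
fluid (measured losses are a few percent, near the 1/(1+FR) fluid share).
Predicted CE percentages for real blood are therefore *not* calibrated;
only orderings, limits and conservation laws are asserted. CE/CR are
reported to one decimal in formatted output; computation is never rounded.

## Hydraulics

Channels are lumped resistors. Rectangular-duct resistance uses the exact
series solution R = 12µL/(a³b·S), S = 1 − (192a/π⁵b)Σ tanh(nπb/2a)/n⁵ over
odd n ≤ 101 (truncation error ≪ 10⁻⁶; the tests cross-check against an
independent double-Fourier solution). Networks are solved by nodal analysis
with fixed-pressure boundaries and prescribed-flow edges (withdrawal pumps);
every connected component needs a pressure reference. Blood is Newtonian at
4 mPa·s by default — shear-thinning is out of scope for a lumped model.
Physiologic pressures are given in mmHg and converted internally to Pa, so
flows come out in µL/min.

## Multiplexing

Capture at a gap depends only on geometry at low Reynolds number, so CE is
flow-rate-agnostic and invariant under parallelization; the flow argument
exists for consistency checks (a mismatch between the array's per-element
flow and the element design flow warns rather than errors). Y-connector
tubing is modelled as resistance only (no cell loss). Device dead volume
defaults to 87 µL with 214 µL single-device tubing; array manifolds pass
their own measured tubing volume (an eight-device tree with 3.5 mL of
tubing gives the 4.2 mL total used in the clinical-scale arithmetic).

## Recirculation

One well-mixed compartment with volume V(t) and per-type cell counts
N(t): dN/dt = −Q<sub>proc</sub>·(CE/100)·N/V + influx, dV/dt =
−Q<sub>ret</sub>, where Q<sub>proc</sub> = Q<sub>fil</sub> + Q<sub>ret</sub>
and Q<sub>ret</sub> = 0.05·Q<sub>fil</sub> by default (FR ≈ 20). Tracking
counts rather than concentrations keeps the cell ledger exact under volume
change. Serial CBC draws are instantaneous whole-blood removals (default
0.3 mL every 15 min for the rat template — a realistic serial CBC+gas
draw), replaced 1:1 with crystalloid by default; this replacement is what
makes serial sampling dilute the red-cell count, the sham-arm signature.
Fluid boluses add volume without cells. The circuit's extracorporeal volume
(736 µL rat template, 4.2 mL pediatric array) is sequestered from the
circulating volume at connection. Integration is piecewise between events
(LSODA, rtol 1e-10) with the cumulative retentate and filtrate cell fluxes
co-integrated as state, so 30-min retentate aliquots and ledgers are
integrals of the same solution. With constant V and no events the solution
reduces to C(T) = C₀·exp(−(CE/100)·V<sub>proc</sub>/V), which the tests
verify to 1e-6 relative. The simulation aborts with a diagnostic if V(t)
would reach zero.

**Estimators.** The per-epoch concentration ratio divides the retentate
aliquot concentration by either the run-mean filtrate concentration (the
printed form, default) or the contemporaneous circulating concentration
(selectable; the only finite choice when CE = 100% empties the filtrate).
The whole-run CE estimator Σ(C<sub>ret,t</sub>·V<sub>ret,t</sub>) /
((C<sub>pre</sub>+C<sub>post</sub>)/2 · V<sub>proc</sub>) is exact when the
circulating concentration is linear in processed volume; under exponential
decline the pre/post arithmetic mean underestimates the true flow-weighted
exposure, biasing the estimate low — about 20% low at 3 eTBV processed with
CE = 60%, and <1% at 0.5 eTBV. Parameter-recovery tests therefore run at
modest processed volumes (~0.5 eTBV), where the estimator recovers the
injected CE within 5% relative; interpreting it on long runs requires this
caveat. The final-percent ratios (WBC%:RBC%, PLT%:RBC%) fall below 1
exactly when the numerator type's CE exceeds the RBC CE, because sampling
removes all types proportionally.

**Influx.** A configurable zero-order per-type influx models processes like
surgical-stress demargination (the sham-arm PMN rise); default 0. This is
the minimal kinetic structure the data support — no marginated or splenic
compartments.

## Fixtures

Synthetic samples are seeded and reproducible. Human defaults: RBC 5×10⁶,
PLT 2.5×10⁵, WBC 7×10³ /µL with a 60/30/7/3 PMN/LYM/MON/EOS differential;
rat defaults: RBC 7×10⁶, PLT 8×10⁵, WBC 8×10³ /µL, lymphocyte-dominant
(72/20/5/3), with PMN (9.5 µm) and EOS (10 µm) the two largest subtypes.
Diameters are log-normal with CV 0.10; donor-to-donor concentration noise
is log-normal with CV 0.10; WBC subtypes partition the drawn total exactly.
Spiked samples add a blast population (10.5 µm) at an exact, configurable
concentration (default 100 /µL after mixing, emulating dilution of a 10⁶
cells/mL culture stock); the hyperleukocytosis preset sets WBC above the
10⁵/µL definition with a blast-dominated differential. These are
literature-informed package defaults, not measurements. Because fixtures
share the rigid-sphere assumptions above, passing tests demonstrate model
self-consistency and correct bookkeeping on realistic magnitudes — not
predictive accuracy for measured CE of deformable cells.

**Protocol templates.** `rat_cif`: 375 g subject, 180 min, filtrate return
0.427 mL/min (total processed flow ≈ 0.448 mL/min with the 5% withdrawal),
q15-min 0.3 mL draws, 30-min retentate epochs, 736 µL circuit ECV.
`rat_sham`: 267 g subject, no withdrawal (retentate fraction 0), same
sampling, with a demargination-influx flag. `pediatric_multiplex`: 9 kg
subject on an eight-device array at 9.6 mL/min (576 mL/hr) with 4.2 mL ECV —
0.91 eTBV/hr and 0.7% of eTBV.

## Problem sizes and numerics

Default problem sizes were chosen so the full test suite runs in well under
a minute of CPU: reference designs have 157–384 gaps (the constant-fraction
mode, 1521 gaps, is used only for closed-form checks), Monte-Carlo checks
use 10⁴–10⁵ cells (binomial 3·SE bounds), and recirculation runs integrate
~200 time points. Monte-Carlo transport is chunked (2048 cells) to bound
memory. Tolerances: design lamina constancy <10⁻⁶ relative, flow
conservation <10⁻¹⁰, separation ledgers <10⁻⁹, recirculation ledgers <10⁻⁶,
network Kirchhoff residuals <10⁻⁹ relative.

## Known limitations

- No deformability, margination, or hematocrit effects: absolute CE for RBC
  (and to a lesser extent PLT) is intentionally unrealistic.
- No shear-thinning, pulsatility, compliance or clotting in the hydraulics.
- Single-compartment kinetics; no marginated/splenic pools beyond the
  zero-order influx term.
- The whole-run in-vivo CE estimator is biased at large processed volumes
  (see above); this is a property of the estimator, reproduced faithfully.
- Geometry export is tabular (CSV/JSON); no photomask/CAD output.
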