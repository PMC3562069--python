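# Methods

## Model form and units

Every biological event is an elementary reaction with mass-action
kinetics: zeroth-order synthesis, first-order conversion/degradation,
or second-order binding/catalysis, giving `dx/dt = S v(x)` with
`v_j = k_j ∏ x_i` over the reactants and catalytic modifiers of
reaction `j`. Amounts are molecules per cell and time is in hours.
Catalysts appear in the flux but carry zero net stoichiometry. The one
sanctioned departure from elementary kinetics is the saturating
inhibition multiplier `1/(1 + [I]/K)` used by the ROS–cFLIP model,
where "inhibition of production/degradation" has no elementary form
without extra machinery species; these are the only non-mass-action
laws in the package and are flagged as such in the reaction records.

Dose conversions are configurable constants: 60 ligand copies per
ng/ml TRAIL (20 ng/ml → 1200 copies against 200 receptors) and 40
input units per µM LY30 (25 µM → 1000 units). The experiments report
doses in ng/ml and µM without a published conversion, so these
constants set the operating point of the calibration; changing them
rescales the drug-dependent rate constants rather than the biology.

## The TRAIL network

The extrinsic cascade follows the Albeck architecture, condensed to
the core pathway species (~37 species, 47 reactions in the combination
model): TRAIL + receptor → DISC; cFLIP sequesters DISC;
DISC activates caspase-8; ARC buffers active caspase-8; caspase-8
activates caspase-3 and cleaves Bid; tBid activates Bax, which Bcl2
buffers; Bax dimers pair into pores; pores release cytochrome c and
Smac; cytochrome c builds the apoptosome, Smac neutralises XIAP;
caspase-3 cleaves PARP. The modifications relative to the base
architecture: caspase-3 catalyses caspase-9 activation; caspase-3
activates caspase-8 directly (caspase-6 removed); cFLIP starts at
1000 copies (an order of magnitude above the cycloheximide-era value,
which suppressed protein synthesis); and ARC replaces BAR as the
caspase-8 inhibitor.

Turnover is modelled for caspases only: pro- and active forms carry
first-order degradation (0.05/h and 1.0/h), bound caspase-8 is
degraded inside the ARC complex, and zeroth-order synthesis of the
pro-forms is set to `k_deg × initial amount` so the untreated model
rests exactly at its initial state. Two further reactions give the
survival/death switch a true threshold rather than a cumulative
integral: active Bax deactivates spontaneously (0.05/h), and the
Bax:Bcl2 complex decays back to inactive Bax and free Bcl2 (0.2/h),
making Bcl2 a recycling buffer with finite throughput instead of a
one-shot reservoir. Sub-threshold signals then settle at a safe steady
state; signals above the Bcl2 throughput overwhelm the buffer, and the
quartic pore nonlinearity (pairwise dimerisation, pairwise pore
assembly) makes the transition sharp.

## LY30 effects and the combination

LY30 is a non-depleting input species (no clearance is published for
the cell system; first-order decay is available as a parameter). It
catalyses: receptor → primed receptor conversion, with the primed form
binding ligand 10× faster (one knob, `priming_factor`, multiplies the
binding constant — a single-parameter choice keeps the model
identifiable); first-order cFLIP degradation (half-life ≈ 14 min at
25 µM — the constant-decay approximation of the more complex dynamics
below); and ROS production. ROS catalyses weak Bax activation in all
cells, and in a flagged subpopulation (probability 0.12 per cell,
drawn with the population seed) a direct ROS → PARP-cleavage channel
that kills without mitochondrial involvement. The subpopulation is a
binary per-cell flag because only the existence of a small
mitochondria-independent fraction is established, not its mechanism.

The combination schedule sets LY30 at 0 h and TRAIL at 1 h; single
treatments dose at 0 h. Events are implemented by stop-and-restart
integration at known times (no root-finding needed); a grid point
coinciding with an event reports the post-event state.

## Numerics

LSODA with relative tolerance 1e-6 and absolute tolerance 1e-3 copies
(copy numbers span six orders of magnitude). The state is clipped at
zero inside the rate function so transient solver undershoot cannot
generate negative fluxes; undershoot beyond 1e-6 of the largest
initial amount aborts with a diagnostic, smaller undershoot is clipped
on output. The derivative is evaluated vectorised (one indexed product
over an extended state vector per call), which keeps a 24 h single-cell
integration at ~20–30 ms and a 1000-cell population run at ~30–40 s.
Reaction order is capped at three (two reactants plus a modifier);
nothing in the models exceeds it.

## Population layer

Initial amounts of every species with a nonzero untreated level are
drawn independently per cell from a normal law with mean equal to the
network value and SD = 0.4 × mean. "Variance equal to 40 % of the
mean" is read as a coefficient of variation of 0.4: a literal variance
proportional to the mean is dimensionally inconsistent across species
spanning 200 to 10⁶ copies, and CV ≈ 0.4 is the standard
extrinsic-noise scale in this literature. Negative draws are resampled
rather than clipped (no point mass at zero); at CV 0.4 the truncation
bias is ≈ 0.1 % of the mean. Death is the first time cleaved PARP
reaches 50 % of the pool, linearly interpolated between grid points;
averaged trajectories include all cells, matching lysate assays.
Activity readouts mix caspase isoforms (the assay substrates are not
isoform-specific): the caspase-8-like signal is `C8a + 0.3·C3a` plus a
small positive background (200 copies-equivalent) that keeps the
untreated fold-change defined and exactly 1 at the baseline point.

## ROS–cFLIP model

Species: LY30, superoxide, H2O2, cFLIP mRNA, cFLIP, and a cumulative
degraded-cFLIP pool. Reactions: LY30-driven superoxide production;
superoxide → H2O2 conversion (1:1 mass flow by default; the 2:1
dismutation stoichiometry is a constructor flag); H2O2 degradation;
mRNA production (H2O2-inhibited), mRNA decay, translation; cFLIP
degradation into the degraded pool (superoxide-inhibited). Units are
arbitrary concentrations with the untreated cFLIP and mRNA steady
states equal to 1; LY30 is in µM.

Timescales are set so superoxide peaks well before 1 h and H2O2
accumulates over hours: conversion 4/h vs H2O2 clearance 0.4/h, cFLIP
turnover 1.5/h (fast enough for a visible 30 min rise and for
relaxation back to baseline under catalase by 6 h). LY30 carries
first-order decay (0.9/h) in this model: a transient drug input is
what gives superoxide a genuine early peak and lets the catalase
intervention restore the 6 h level; H2O2 is produced only via
superoxide conversion (the direct-production alternative is left to a
parameter override). Tiron pre-incubation is encoded as removal active
from −1 h with the simulation starting at −1 h; catalase is active
from 0 h of the pre-equilibrated state. With the default rates the
response is: fold-change 1.32 at 30 min, one interior maximum at
~1.2 h, crossing below baseline at ~2.5 h, 0.41 at 6 h.

A deliberate consequence of the two-arm structure: under strong
catalase the 6 h level converges not to exactly 1 but to a small
superoxide relic (+3–4 %), so the absolute deviation from baseline
decreases monotonically with removal rate only while H2O2 dominates
it; tests assert monotone convergence in that regime and an ε = 0.1
band at large rates.

Coupling to the apoptosis model replaces the constant-rate
LY30-catalysed cFLIP degradation with this submodel, merging LY30 and
cFLIP by name, rescaling translation to the copy-number steady state
and superoxide production to LY30's copy-number units, and keeping
the combination model's non-depleting drug input. The early cFLIP
rise then shields the DISC and delays caspase-8 activation; with
sustained drug input the coupled model settles at a partially
suppressed cFLIP level, so late-time killing is much weaker than in
the constant-decay model — the coupled model is a mechanism for the
delay, not a replacement calibration for 24 h viability.

## Calibration

Fitting is multi-start bounded least squares in log-parameter space:
Latin-hypercube starts, Nelder–Mead refinement (event discontinuities
degrade finite-difference gradients), residuals on the fold-change
scale (all readouts are relative, which removes unidentifiable scale
factors), weighted by replicate standard errors with a 0.05 floor so
zero-noise data cannot produce infinite weights. Profiles (loss
minimised over the remaining parameters along a grid) serve as the
identifiability diagnostic. Caspase-based objectives should use
reduced populations (~200 cells) during optimisation and the full
population only for the final report; the recovery tests here use the
deterministic cFLIP readouts, which carry the relevant parameters.

## Synthetic data

Activity and densitometry replicates carry multiplicative lognormal
noise with unit mean (positive support, matching assay/blot
behaviour); densitometry additionally simulates a per-lane scale
applied to both the cFLIP band and the loading control, whose ratio
cancels it exactly. Viability carries additive Gaussian noise
truncated to [0, 1] and is normalised to the untreated replicate mean.
Defaults: three replicates, 10 % CV (assay noise magnitudes are not
published; these are stated assumptions). Ground truth, noise model
and seed are embedded in each dataset's metadata. What passing
recovery tests show is that the estimation machinery works on data
with this statistical structure — they cannot certify performance on
real blots, whose noise is neither lognormal nor independent across
lanes and whose effective replicate count is small.

## Problem sizes in tests and the acceptance script

Population-level checks run at 1000 cells (CV 0.4, fixed seed), where
the Monte Carlo standard error of a 24 h death fraction is at most
~0.016 — small against every threshold tested; the test suite checks
that death fractions at different population sizes agree within three
standard errors, so results at the default size are representative of
the study-scale condition of 10 000 cells up to that error. Unit and
property tests use 15–60 cells, enough to exercise the machinery
without asserting population statistics.

## Known limitations

* Rate constants are calibration defaults in the Albeck style, chosen
  once to reproduce the study's quantitative claims; they are not
  transcriptions of a published parameter table, and absolute times
  (e.g. the 4.5 h caspase-8 peak) should be read as model properties,
  not measurements.
* Initial amounts are varied independently across proteins; correlated
  extrinsic noise and rate-constant variability are not modelled.
* The combination model treats the drug input as constant; no
  pharmacokinetics.
* The coupled ROS–cFLIP model explains the delayed onset of caspase-8
  activation but deliberately does not reproduce late (≥10 h)
  caspase-8 behaviour; no claim is made there.
* SBML I/O is a self-consistent Level 3 dialect (round-trip tested);
  it does not validate against the external schema and the importer
  only reads what the exporter writes.
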