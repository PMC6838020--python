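# Methods

## Model

The simulator describes a resting-cell (non-growing, washed) suspension
given a single pulse of glucose ¹³C-labeled at C1 or C2 at t = 0.  Carbon
routing is reduced to the fluxes around the fructose-6-phosphate node:

* `f_in` — glucose uptake (hexokinase + phosphoglucose isomerase; the
  carbon skeleton is untouched, so glucose Cᵢ → F6P Cᵢ);
* `f_fru` — dephosphorylation of F6P to free fructose (identity map);
* `f_ppp` — entry into the oxidative pentose phosphate pathway, in hexose
  equivalents.  The lump composes 6-phosphogluconate decarboxylation (C1 →
  CO₂ on each of three hexoses) with transketolase/transaldolase
  recombination (TK1, TA, TK2), with stoichiometry
  3 hexose-P → 2 F6P + 1 triose-P + 3 CO₂.  In source-hexose coordinates
  (A → X5P, B → R5P, C → X5P) the products are
  F6P#1 = (A2,A3,B2,A4,A5,A6), F6P#2 = (C2,C3,B3,B4,B5,B6) and
  GAP = (C4,C5,C6).  On pure [2-¹³C] input this yields exactly one
  [1-¹³C]- and one [1,3-¹³C]-F6P; on [1,3-¹³C] input (a second cycle) one
  [2-¹³C]- and one [2,3-¹³C]-F6P.
* `f_r` — back-flux from the triose-phosphate pool to F6P through aldolase
  and FBPase, in hexose equivalents (2 trioses consumed per hexose);
* sink drains from the triose pool (ethanol, glycerol, pyruvate, acetate,
  dihydroxyacetone, TCA), with decarboxylation of the pyruvate carboxyl on
  the ethanol and acetate routes.

Assumptions, in decreasing order of importance:

1. **Quasi-steady intracellular pools.**  F6P and the triose pool carry no
   holdup; their labeling compositions are flux-weighted mixtures of their
   inputs, computed as a fixed point.  This removes unidentifiable
   pool-size parameters.  Because the glucose pool's labeling never changes
   (a single tracer species), the fixed point is time-invariant until
   glucose exhaustion — the "composition steady state" the estimators
   assume holds exactly in the simulator from t = 0⁺.
2. **Zero-order fluxes.**  All fluxes are constant while glucose remains
   (matching the observed near-linear consumption) and stop at exhaustion;
   with the default configuration (50 mM pulse, 1.47 mM/min uptake) glucose
   runs out at ≈ 34 min, which is why the 30/45/60/120-min samples show a
   fructose plateau.
3. **Fully TPI-equilibrated single triose pool.**  DHAP and GAP are not
   distinguished; the pool is kept in GAP coordinates and the DHAP half of
   a cleaved hexose is re-indexed through the TPI map on entry.  Hexose C1
   and C6 therefore converge on GAP C3, and re-condensation assigns a
   labeled triose to the C1–C3 or C4–C6 half with probability ½ each —
   the factor underlying the (2 f_in + f_r)/f_r label-ratio formula.
4. **Well-mixed condensations.**  The two trioses of a condensation and
   the three hexoses of a PPP turn are drawn independently from the
   current pool distributions.  Returned PPP products re-enter the F6P
   pool, so second and later PPP cycles (the [2,3-¹³C] trace species)
   arise naturally.
5. **Binary positional labeling.**  Each carbon is ¹²C or ¹³C; natural
   abundance (1.1%) and mass-isotopomer effects are ignored.
6. **No fructose re-uptake.**  Excreted fructose is terminal during the
   assay.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| `f_in` | glucose uptake | mM/min | 1.47 (shipped fixture) |
| `f_fru` | F6P → fructose | mM/min | 0.68 |
| `f_ppp` | PPP entry (hexose eq.) | mM/min | 0.08 |
| `f_r` | triose → F6P back-flux (hexose eq.) | mM/min | 0.48/0.52 × (f_in − f_fru) ≈ 0.729 |
| `glucose_0` | tracer pulse | mM | 50 |
| grid | sampling times | min | 0, 15, 30, 45, 60, 120 |
| `sink_split` | fractions of net triose drain | – | ethanol 0.70, glycerol 0.10, pyruvate 0.06, acetate 0.05, DHA 0.04, TCA 0.05 |
| `relative_sd` / `absolute_sd` | measurement noise | – / mM | 0.05 / 0.05 |
| `detection_limit` | censoring threshold | mM | 0.1 |

The shipped fixture is the published point-estimate set; its back-flux is
fixed by requiring f_r/((f_in − f_fru) + f_r) = 48%, with the forward
glycolytic denominator defined as (f_in − f_fru) + f_r and the *net*
glycolytic denominator of the 86% diversion ratio as f_in − f_fru.  These
are the only denominator conventions that reproduce both percentages
simultaneously from the same flux set.  The sink split is a fixture
parameter only; it does not enter any estimator (sinks drain all labeling
classes proportionally).

The noise defaults are chosen as plausible quantitative-NMR errors (a few
percent integration error plus a ~0.05 mM baseline term, 0.1 mM limit of
quantification); they are tunable, not fitted to any dataset.

## What the generator emulates — and what it does not

The generator reproduces tidy supernatant tables (time × species ×
labeling pattern × mM) with independent Gaussian noise, zero-clamping and
detection-limit censoring.  It does **not** emulate raw NMR spectra,
peak-overlap artifacts, correlated errors from a shared internal standard,
natural-abundance background, or the small [3-¹³C]fructose signal of
unknown origin seen in real experiments (no mechanism is modeled, so the
simulator never produces it).  Passing tests therefore demonstrate
correctness of the flux→isotopomer forward map and of the estimators under
this idealized measurement model, not robustness to NMR artifacts.

## Inference

* **Rates.**  f_in and f_fru are OLS slopes over the pre-exhaustion window
  (grid points with glucose above the detection limit — 0/15/30 min at the
  fixture), averaged over the two tracer experiments.  The fructose slope
  is fit on the same window because fructose accumulation stops at glucose
  exhaustion; fitting the post-30-min plateau would measure ≈ 0.
* **Steady-state fractions.**  Positional mole fractions of fructose are
  concentration-weighted averages over t ≥ 30 min; the composition is
  frozen there, so the window size only matters under noise.
* **Back-flux.**  f_r = 2 f_in/(m₁/m₆ − 1) from the C1 experiment; under
  the C1 tracer the PPP burns the label (C1 → CO₂), so reversal is the
  only source of m₆.  The C2-based m₂/m₅ estimate is reported as a
  cross-check, not averaged in.
* **PPP.**  f_ppp = 1.5 m₁ f_in/(1.5 m₁ + m₂ + m₅) from the C2
  experiment, m₁ counting every C1-labeled pattern (including [1,3]).
* **Uncertainties.**  Seeded bootstrap, B = 200: residual resampling for
  the slopes, pairs resampling of the steady-window time points for the
  fraction-based quantities.  On noiseless data all SDs collapse to zero.

## Estimator accuracy (computed by the test suite)

The recovery grid (f_r/f_in ∈ {0, 0.25, 0.5} × f_ppp/f_in ∈ {0, 0.05,
0.15}, noiseless) shows:

* f_in and f_fru recover exactly (linear series, exact OLS);
* f_r recovers within 3.3% everywhere (and exactly when f_ppp = 0 — the
  ratio formula is algebraically exact in the no-PPP model);
* the m₁-based PPP estimator is **biased low once back-flux is active**:
  7.7% at (f_r = 0, f_ppp/f_in = 0.05) but 25–42% across the cells with
  f_r > 0, and 35% at the shipped fixture (0.052 vs 0.080 mM/min).

The bias has two mechanistic sources, both verifiable from the stationary
marginal balance a₁ = [(2/3) f_ppp a₂ + f_r (a₁+a₆)/2]/S: (i) the PPP
consumes the *mixed* hexose-P pool, whose C2-labeled fraction a₂ is ≈ 0.81
at the fixture rather than 1, so first-cycle C1-label yield is diluted;
(ii) aldolase cycling scrambles about half of the recycled PPP-derived C1
label to C6, which the formula does not count (and a small part is burned
in second PPP cycles).  The formula's first-cycle bookkeeping ignores both.
The package reports the formula's value unchanged — it is the field's
estimator — and surfaces the reversed-label cross-check and m₆ so users
can judge the regime; the grid test prints the approximation error per
cell.

A related, expected discrepancy: at the fixture fluxes the simulator
produces m₆ ≈ 0.16 of reversed-label fructose under the C1 tracer, while
experimental reports of ~10% coexist with a 48% back-flux claim; under
this model those two numbers cannot both be exact, and the inference
report prints m₆ so the tension stays visible rather than being
reconciled silently.

## Numerical choices

* Fixed point of the quasi-steady pools: damped-free Gauss–Seidel
  iteration from unlabeled pools, L1 tolerance 1e-14, pattern pruning at
  1e-13 mole fraction between iterations (the contraction factor is the
  back-flux share of F6P input, ≈ 0.33 at the fixture, so convergence
  takes ~30 iterations).  Solutions are cached per configuration.
* Distributions are sparse maps over ≤ 2⁶ binary patterns; renormalization
  drift up to 1e-9 is silently corrected, above 1e-6 it is an error.
* Time stepping: explicit, Δt = 0.1 min, with the final step before
  glucose exhaustion shortened to land on the exhaustion time exactly;
  sampling times are hit exactly by construction.
* Degenerate inputs: m₆ = 0 returns f_r = 0; m₁ ≤ m₆ raises a
  model-violation error (the ratio formula has no non-negative solution);
  an all-zero steady window or fewer than 3 fit points raise errors.
* Monte-Carlo cross-check (test suite): an independent molecule-tracking
  sampler with its own hand-derived carbon shuffles reproduces every
  fructose pattern fraction ≥ 1e-4 at the fixture within 3 binomial
  standard errors at N = 10⁵ samples, for both tracers.

## Problem sizes

Simulations use the 6-point experimental grid with Δt = 0.1 min; the
noisy-recovery study uses 20 generator seeds at default noise with
B = 200 bootstrap replicates; the stochastic cross-check uses 10⁵ sampled
molecules after a 3×10⁴-event burn-in with reservoirs of 2000 molecules.
These sizes make the full suite run in well under a minute while keeping
binomial/bootstrap resolution far below the tolerances being checked.

## Known limitations

* The estimators are steady-state, single-pulse; no kinetics, growth, or
  pH/temperature effects.
* No full isotopomer-balance least-squares fit: the package implements the
  closed-form estimators, not a general ¹³C-MFA optimizer.
* Sink splits are not inferable from the supernatant patterns modeled here
  and are treated as fixture parameters.
* Confidence measures are bootstrap SDs only; with 3-point fits the
  residual bootstrap is known to understate slope variability (observed
  ≈ 2× at default noise), so the SDs are indicative, not calibrated
  intervals.
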