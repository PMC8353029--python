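# Methods

## The system and the questions

*Paracoccus denitrificans* stores carbon as poly(3-hydroxybutyrate)
(PHB) granules. When starved, PHB-free cells are transferred to fresh
mineral medium with succinate as the sole carbon and energy source, the
culture passes through two physiological phases:

1. **Growth-arrested accumulation** (first ~30 min): biomass does not
   increase, while the PHB content per dry weight jumps from zero to
   roughly 7.8%.
2. **Exponential growth**: biomass grows at a constant specific rate
   with the PHB content steady near 7% of dry weight.

`phbflux` answers two questions about this experiment. First, what are
the physiological rates — specific growth rate, biomass yield on
succinate, specific succinate uptake and PHB production — implied by a
batch time series of dry weight, PHB content and residual succinate?
Second, what intracellular flux distribution is consistent with those
rates, as predicted by flux balance analysis (FBA) of a stoichiometric
model under each phase's constraints?

## Rate estimation (kinetics module)

All estimators are ordinary least squares (unweighted; per-point
standard deviations are carried but not used by default because the
replicate structure of the source data does not justify a particular
weighting):

- **Specific growth rate** `mu` [1/h]: slope of ln(dry weight) against
  time over the exponential window. The window defaults to the longest
  contiguous run of at least three points whose regression reaches
  R² ≥ 0.98 (ties broken by R²; if no window qualifies, the best-R²
  window is used). For the packaged fixture the analysis pins the
  window to the samples from 2 h through 16 h, the points after the
  accumulation burst.
- **Biomass yield** `Y_XS` [g-DW/mol]: slope of dry weight (g/L)
  against consumed succinate (mol/L) over all points.
- **Specific uptake** `q_s = 1000·mu/Y_XS` [mmol/g-DW/h] — an identity,
  not a fit.
- **Specific PHB production during growth**
  `q_PHB = mu · w_PHB` [mg/g-DW/h], where `w_PHB` is the constant
  fractional PHB content; molar rates divide by the effective monomer
  mass of 96 g/mol (the hydroxybutyrate unit as it sits in the polymer,
  i.e. minus the water lost on polymerisation).
- **Accumulation rate** [mmol/g-DW/h]: the content step over the first
  sampling interval divided by its duration and by 96. On the packaged
  fixture: (78.4 − 0 mg/g) / 0.5 h / 96 = 1.633.
- **Pirt maintenance**: the intercept of `q_s = mu/Y_max + m_s` fitted
  to (mu, q_s) pairs, in substrate units; conversion to ATP units is
  the caller's ATP-per-substrate factor. The shipped maintenance
  constant of 7.5 mmol ATP/g-DW/h is a literature-derived value whose
  chemostat inputs are not packaged, so the generic fitter does not
  re-derive it.

The thiolase sensitivity helper encodes a kinetic, not stoichiometric,
argument: beta-ketothiolase condenses two acetyl-CoA molecules, so far
below enzyme saturation its rate scales with the square of the
acetyl-CoA concentration — a 4-fold concentration drop maps to a
16-fold rate drop. This is the mechanism by which citrate synthase
outcompetes the PHB branch once growth resumes and TCA demand depletes
the acetyl-CoA pool.

## The core stoichiometric model

The built-in model (24 reactions, 26 metabolites) covers the fluxes
that matter for succinate-fed PHB synthesis: succinate exchange and
transport; the oxidative TCA reactions (succinate dehydrogenase,
fumarase, malate dehydrogenase, citrate synthase, aconitase,
NADP-isocitrate dehydrogenase, 2-oxoglutarate dehydrogenase,
succinyl-CoA synthetase); the anaplerotic exit malate → pyruvate →
acetyl-CoA through malic enzyme (ME) and pyruvate dehydrogenase (PDH);
the PHB branch phaA (2 acetyl-CoA → acetoacetyl-CoA), phaB
(NADPH-dependent reduction) and phaC (polymerisation, drained by a
monomer sink); lumped respiration; transhydrogenase; an ATP maintenance
drain; and a biomass pseudo-reaction.

Numerical and structural choices:

- **Respiration** is one lumped reaction,
  NADH + ½O₂ + P/O·(ADP+Pi) → NAD + P/O·ATP, with the P/O ratio a
  parameter (default 1.5 ATP/NADH — a mid-range value for aerobic
  bacteria; the analysis is insensitive to it as long as the
  growth-arrested phase can cover maintenance, which requires roughly
  2·(P/O)·(succinate flux) ≥ maintenance).
- **Succinate dehydrogenase** physiologically reduces the quinone pool;
  the core model folds the quinone pool into the NAD pool so a single
  respiration reaction suffices. This overstates ATP per succinate
  slightly and is irrelevant to carbon-limited optima.
- **Malic enzyme cofactor** defaults to NADPH (supplying phaB), with a
  reversible transhydrogenase included so the NADH choice is equally
  feasible.
- **Maintenance** is bounded below (default 7.5 mmol ATP/g-DW/h) and
  unbounded above, so surplus ATP can be spilled and minimal-uptake
  solutions are never blocked by an ATP excess.
- **Biomass composition** is a generic heterotroph calibration —
  acetyl-CoA 2.5, oxaloacetate 1.8, 2-oxoglutarate 1.1, pyruvate 2.8,
  NADPH 16 and ATP 40 mmol per g-DW — exposed as a parameter and
  clearly not organism-measured. Genome-scale questions (absolute
  exponential-phase uptake, organism-wide enzyme counts) belong to an
  externally supplied genome-scale SBML model, not to this core.
- **Sign convention**: exchange flux < 0 is uptake; reported uptake
  rates are magnitudes.
- **Mass balance** is checked for C, O, N, P and S; hydrogen is
  excluded because protons are not modelled. Exchanges, sinks, biomass
  and maintenance are exempt by construction.

## FBA, degeneracy and enzyme counts

`solve_fba` solves max/min cᵀv subject to S·v = 0 and bounds with
scipy's HiGHS simplex — deterministic and exact to ~1e-9 at this scale.
Phase constraints are equality pins implemented as collapsed bounds.
`pfba` re-solves at the fixed optimum (relative slack 1e-9) minimising
total |v| with every flux split into non-negative forward/reverse
parts. Reactions with |v| above 1e-6 mmol/g-DW/h (solver noise floor;
configurable) and a gene association count as "active enzymes".

FBA optima are degenerate: the optimal uptake and net acetyl-CoA rate
are unique, but which enzymes carry the flux is not. Active-enzyme
counts are therefore always reported next to a caveat and never treated
as model predictions with error bars. The package asserts only the
robust qualitative contrast: the growth-arrested active set is strictly
smaller than (on the core model, a strict subset of) the
exponential-phase set.

## The two phases

- **Accumulation**: growth pinned to 0, PHB monomer flux pinned to 1.63
  mmol/g-DW/h (the Table-derived value, kept over the 7.8%-rounded
  1.625), maintenance ≥ 7.5, uptake minimised. On the core model this
  forces succinate → malate → (ME) pyruvate → (PDH) acetyl-CoA at 3.26
  mmol/g-DW/h with two CO₂ released per monomer pair, zero citrate
  synthase flux, and maintenance covered by the NADH of that same
  route. Predicted uptake equals 3.26 (2 succinate per monomer).
- **Exponential**: growth pinned to the fitted mu (0.232/h on the
  packaged data), PHB pinned to the molar growth-phase rate (0.169
  mmol/g-DW/h = 16.2/96), maintenance ≥ 7.5. The TCA cycle engages to
  supply biomass precursors and ATP. On the core model the absolute
  uptake depends on the calibrated biomass coefficients and is reported,
  not asserted; matching the measured uptake quantitatively is the
  genome-scale model's job.

Infeasible phase constraint sets are diagnosed by relaxing one pin at a
time (growth, PHB, maintenance) and reporting which relaxation restores
feasibility.

## Synthetic data

`simulate_batch` draws noisy replicate measurements around a
deterministic truth: biomass constant at x₀ until a hard lag (default
4 h), then exponential at mu; succinate coupled linearly through the
yield and floored at exhaustion (growth stops there); PHB content zero
at inoculation, at the accumulation level (default 78 mg/g) from the
0.5 h sample onward and at the growth level (default 70 mg/g) once
growth starts. Defaults mirror the packaged experiment: x₀ = 0.04 g/L,
mu = 0.232/h, yield = 48.4 g/mol, s₀ = 25 mM, duplicate replicates.
Noise is Gaussian per replicate — dry weight 8% relative, PHB 6 mg/g,
succinate 0.4 mM, magnitudes read off the fixture's ± columns — and
fully seeded: identical (params, seed) give byte-identical CSV.

What the generator does **not** emulate: smooth lag-exit kinetics,
growth-rate dependence of PHB content, substrate-dependent (Monod)
growth, autocorrelated instrument drift, or single-cell granule
statistics. Recovery tests on this generator therefore demonstrate that
the estimators are unbiased and well-calibrated under the analysis's own
assumptions, not that those assumptions hold for any real culture.

`recovery_experiment` simulates many datasets, re-estimates mu and the
yield on each, and reports bias, RMSE and empirical 95% CI coverage,
with the CI built from the t-quantile at the regression's residual
degrees of freedom (with a 5-point window, using a normal quantile
would understate the interval and read as ~85% coverage even for a
perfectly calibrated estimator).

## Problem sizes and determinism

Everything is desk-scale by design: the core model's LPs solve in
milliseconds, the full test suite (including a 200-dataset recovery
study and 21 solver cross-checks against an independent constraint-based
implementation) runs in a few seconds, and the acceptance script's
computation is a single deterministic pFBA. The only randomness anywhere
is the synthetic generator's, always driven by an explicit seed.

## Known limitations

- The core model's biomass reaction is a calibration, so its
  exponential-phase uptake is indicative only.
- Enzyme counts inherit FBA degeneracy (see above).
- The quinone pool is lumped into NAD; FADH₂-level phosphorylation is
  not distinguished.
- SBML support targets flux-balance models (L3+FBC, or L2 with
  COBRA-style kinetic-law bounds); kinetic SBML is out of scope.
- No Monod/logistic fitting: the lag is a window-selection concern, not
  a modelled quantity.
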