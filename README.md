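# phbflux

Batch-culture kinetics and flux balance analysis of
poly(3-hydroxybutyrate) (PHB) synthesis in *Paracoccus denitrificans*
growing on succinate.

When starved, PHB-free *P. denitrificans* cells are transferred to
fresh mineral medium with succinate, they first fill their PHB stores
— the content per dry weight jumps from zero to ~7.8% within 30 minutes
while the biomass stays flat — and only then start growing
exponentially, holding the PHB content near 7%. `phbflux` is for
microbial physiologists and metabolic modellers who want to quantify
both phases from routine batch measurements and to ask what flux
distribution explains them.

The package provides:

- **Kinetics**: from a time series of dry weight X (g/L), PHB content
  w (mg/g-DW) and residual succinate S (mM), estimate the specific
  growth rate μ (slope of ln X vs t over the exponential window), the
  biomass yield Y_XS (slope of X vs consumed succinate, g-DW/mol) and
  the derived specific rates q_s = 1000·μ/Y_XS and q_PHB = μ·w, with
  molar PHB rates via the 96 g/mol effective monomer mass. A Pirt fit
  (q_s = μ/Y_max + m_s) and an OD660→biomass conversion are included.
- **A core stoichiometric model** of succinate metabolism (TCA cycle,
  malic enzyme + pyruvate dehydrogenase, phaA/phaB/phaC PHB branch,
  lumped respiration, maintenance, biomass), plus SBML (Level 3 + FBC)
  read/write for external genome-scale models.
- **FBA and parsimonious FBA** (max/min cᵀv s.t. S·v = 0, bounds)
  built on scipy's HiGHS solver, with equality pins for measured rates.
- **A two-phase pipeline**: pin (μ, q_PHB) for each phase, impose the
  maintenance ATP lower bound (7.5 mmol/g-DW/h), minimise succinate
  uptake, and compare the phases' predicted uptake, acetyl-CoA
  synthesis, TCA engagement and active-enzyme sets.
- **A synthetic batch generator** with the same experimental structure
  (lag, accumulation burst, yield coupling, seeded replicate noise) for
  testing and parameter-recovery studies.

## Worked example

The packaged fixture is a duplicate batch experiment: inoculation at
0.04 g/L on 25 mM succinate, sampled over 16 h.

```python
from phbflux import load_packaged_timeseries, run_full_analysis
from phbflux.kinetics import PACKAGED_EXP_WINDOW

series = load_packaged_timeseries()
report = run_full_analysis(series, window=PACKAGED_EXP_WINDOW, phb_content=70.0)
print(report["kinetics"])
```

prints (abridged):

```
mu_per_h                          0.2355   (se 0.024)
yield_gDW_per_mol                 47.86    (se 2.20)
q_s_mmol_per_gDW_h                4.92
q_phb_mg_per_gDW_h                16.48
accumulation_rate_mmol_per_gDW_h  1.633
```

So the culture grows at μ ≈ 0.235 h⁻¹, converts succinate to biomass at
≈ 48 g-DW/mol (hence takes up ≈ 4.9 mmol succinate/g-DW/h), and makes
PHB at ≈ 16.5 mg/g-DW/h during growth — but accumulated it ten times
faster (1.63 vs 0.17 mmol monomer/g-DW/h) in the initial zero-growth
burst.

The FBA blocks of the same report show what those rates imply:

```
phase_accumulation:  predicted_uptake 3.27, acetyl_coa_rate 3.27,
                     n_active_enzymes 10, tca_active False
phase_exponential:   predicted_uptake 3.67, acetyl_coa_rate 2.33,
                     n_active_enzymes 16, tca_active True
```

During the accumulation burst every consumed succinate is decarboxylated
twice (malic enzyme, pyruvate dehydrogenase) to one acetyl-CoA, two of
which condense per PHB monomer — uptake and acetyl-CoA synthesis both
equal 2 × 1.63 = 3.26 mmol/g-DW/h — and the citrate synthase flux is
zero: the NADH made en route already covers maintenance ATP, so the TCA
cycle stays silent. Once growth resumes, the TCA cycle engages (six
additional enzymes active) and competes for the same acetyl-CoA pool,
which is why the specific PHB rate collapses tenfold. Since the thiolase
condensation is bimolecular in acetyl-CoA, a 4-fold drop in its
concentration alone would slow PHB synthesis 16-fold
(`thiolase_sensitivity(4.0) == 16.0`).

Exponential-phase numbers on the core model depend on its calibrated
generic biomass composition; quantitative uptake predictions for growth
(e.g. against the measured 4.9) are the province of a genome-scale SBML
model passed via `read_sbml`/`--model`.

The same pipeline is scriptable from the shell:

```sh
phbflux rates series.csv --window 2 8
phbflux phase --growth 0 --phb 1.63 --maintenance 7.5
phbflux analyze series.csv --out report.json
phbflux build-model --out core.xml
phbflux simulate --seed 7 --out sim.csv
```

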