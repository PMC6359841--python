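# physioflux

Black-box quantitative physiology for bioreactor cultivations of
*Saccharomyces cerevisiae* (or any unicellular aerobe), built around the
kind of question acetyl-CoA pathway engineering raises: when a
heterologous phosphoketolase (Xfpk) diverts glycolytic carbon towards
acetate, where does the carbon go, what does it cost in ATP, and how do
the intracellular sugar phosphates respond?

The package is for metabolic engineers and quantitative physiologists
who have batch or chemostat time-series (biomass, extracellular
metabolites, off-gas) and replicate metabolite panels, and want the
standard strain characterization — specific rates, yields, C-mol
balances — plus the energetic bookkeeping of acetate overflow, as
tested, reusable code rather than spreadsheet arithmetic.

## What it computes

**Specific rates and yields** (statsmodels-style models). For a batch
series, `BatchPhysiologyModel(series).fit()` estimates the maximum
specific growth rate as the slope of ln *X* vs *t* over an automatically
selected exponential window, and each specific rate
*q*ᵢ (mmol gCDW⁻¹ h⁻¹, consumption negative) from the regression of
concentration on biomass: under balanced exponential growth
d*S*/d*X* = *q*·*M*/(1000·µ), so *q* = µ·slope·1000/*M*. Gas rates (CER,
OUR) come from the off-gas mole-fraction differences and the ideal-gas
inlet molar flow. For a chemostat, µ = *D* and the steady-state balances
apply directly: *q*_glc = −*D*(S_feed − S_res)·1000/(*M*·*X*),
Y(x/s) = *X*/(S_feed − S_res).

**C-mol flux accounting.** `normalize_fluxes(result)` expresses every
flux as a percentage of the glucose-uptake carbon flux
(100·|*q*ᵢ|·Cᵢ/(|*q*_glc|·6)), reports the carbon-balance closure
(Σ output C-mol / input C-mol), and partitions CO₂ into a fermentative
part (half the ethanol C-mol flux, released by pyruvate decarboxylase)
and a respiratory remainder.

**Energetics.** Henderson–Hasselbalch speciation of acetic acid
(fraction HA = 1/(1+10^(pH−pKa)), pKa 4.76); ATP ledgers per mole of
acetate assimilated (native overflow route: net 1 ATP; phosphoketolase +
acetyl-phosphate hydrolysis: net 2, because the ATP-generating half of
glycolysis is bypassed while Acs still spends 2 ATP equivalents); and a
two-substrate mixing model that decomposes an observed gas flux into
glucose- and acetate-limited reference fluxes.

**Metabolite panels.** `FoldChangeModel(test, control).fit()` gives
per-metabolite pool sizes as % of control with two-sided Welch t-tests
(tiers \* p<0.05, \*\* p<0.001), plus mass-action equilibrium
consistency checks (e.g. K = [DHAP][GAP]/[F-1,6-BP]: a twofold rise of
both trioses demands fourfold F-1,6-BP).

**Synthetic data.** `simulate_batch`, `simulate_chemostat` and
`simulate_panel` generate data with the statistical structure the
estimators assume (seeded, carbon-conserving in `closed` mode), so the
whole pipeline is testable end to end without instrument data.

## Worked example

```python
import physioflux as pf

series = pf.simulate_batch(pf.BatchScenario.xfpk(balance="as-printed"))
result = pf.BatchPhysiologyModel(series).fit()
print(result.summary())

fmap = pf.normalize_fluxes(result)
print(f"acetate share of glucose carbon: {fmap.normalized['acetate']:.2f}%")
print(f"carbon balance closure:          {fmap.balance_closure:.1f}%")
print(f"respiratory CO2 fraction:        {fmap.respiration_fraction:.1f}%")

sol = pf.solve_mixing(pf.MixingModel(2.8, 7.4, 3.35))
print(f"acetate-derived carbon fraction: {sol.fraction_acetate:.3f}")
print(f"net ATP per acetate, xfpk route: {pf.atp_cost('xfpk').net_cost:.0f}")
```

prints

```
Physiology results [batch, strain xfpk, n=1]
----------------------------------------------------
µ(max) (1/h)                       0.266
Y(x/s) (gCDW/gGlucose)             0.1211
q(Glucose) (mmol/gCDW/h)          -12.19
q(EtOH) (mmol/gCDW/h)              17.26
q(Acetate) (mmol/gCDW/h)           1.38
q(Glycerol) (mmol/gCDW/h)          0.62
q(Pyruvate) (mmol/gCDW/h)          0.15
q(Succinate) (mmol/gCDW/h)         0.01
q(CO2) (mmol/gCDW/h)               28.16
q(Biomass) (C-mmol/gCDW/h)         10.8
q(O2) (mmol/gCDW/h)               -7.63
window: 0.00–20.03 h

acetate share of glucose carbon: 3.77%
carbon balance closure:          107.5%
respiratory CO2 fraction:        14.9%
acetate-derived carbon fraction: 0.120
net ATP per acetate, xfpk route: 2
```

The fitted rates reproduce the generator's reference parameters exactly
(noise-free round trip); the acetate share of ~3.8% of glucose carbon —
roughly threefold the ~1.4% of a control strain — together with the
mixing-model estimate that ~12% of glucose carbon transits acetate under
glucose limitation, and a net cost of 2 ATP per acetate, summarize why a
seemingly small overflow flux carries a large respiratory burden.

## Command line

```bash
physioflux simulate --mode batch --strain xfpk --out xfpk.csv
physioflux rates xfpk.csv
physioflux balance xfpk.csv
physioflux energetics --ph 4 --mixing 2.8 7.4 3.35
physioflux report --seed 1 --out report_dir
```

Input CSV schemas (long form, units as a column) are documented in
`physioflux/io.py`; `report` runs the full pipeline from a YAML config
and writes tidy CSVs, a summary table, a flux edge list and a
machine-readable warnings file.

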