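# Methods

## Scope and model

physioflux does *black-box* physiology: the cell is a reaction
`glucose + O2 + NH3 → biomass + ethanol + acetate + glycerol + pyruvate
+ succinate + CO2 + H2O`, characterized entirely by extracellular
specific rates. No intracellular flux estimation (¹³C-MFA, FBA) is
attempted; the only intracellular stoichiometry carried is the
phosphoketolase-route reaction set used for carbon checks and ATP
ledgers.

### Stoichiometric basis

Atomic masses are fixed IUPAC 2021 constants (C 12.011, H 1.008,
O 15.999, N 14.007) so every derived mass is bit-stable. Biomass is a
pseudo-compound CH₁.₈O₀.₅N₀.₂ — the standard yeast elemental
composition — giving a C-mol mass of 24.63 g (computed from the
indices, never hard-coded). The C-mol mass is **ash-free**: no ash
fraction is modelled, and users with ash-corrected compositions can
supply their own indices. Degrees of reduction (electrons per C-mol,
NH₃-referenced) are carried for diagnostics only.

Phosphorylated intermediates (X5P, F6P, GAP, E4P, acetyl-phosphate) are
registered with their CHON content only; they participate in reaction
carbon checks, never in extracellular gram↔mole conversions, so the
omitted phosphate moiety is immaterial. Acetyl-CoA counts its acetyl
carbons only — the CoA thioester is treated as a carbon-free carrier,
like Pi.

### Rate estimation

*Batch.* µmax is the least-squares slope of ln X vs t. The automatic
exponential window is the longest contiguous stretch with ≥4 positive
biomass samples and R² ≥ 0.995; if none qualifies the full series is
used with a warning, and the user can always override the window.
Specific rates regress concentration against *biomass*, not time:
under balanced exponential growth S(X) is exactly linear with slope
qM/(1000µ), so q = µ·slope·1000/M. This avoids numerically
differentiating noisy concentration series and is exact for the
generator's growth law. The biomass yield follows as
Y(x/s) = µ·1000/(|q_glc|·M_glc).

*Gas rates.* The inlet molar flow is PV̇/RT at 1 atm and the broth
temperature (default 30 °C); inlet air is 20.95% O₂ / 0.04% CO₂
(overridable constants). CER and OUR per sample are
n_in·(y_out − y_in)·1000/(X·V), averaged over the window. Changes of
the total molar flow due to RQ ≠ 1 (a proper inert-gas balance) are
neglected; at 0.1 VVM aeration the off-gas deltas are a few percent and
the correction is second-order. Ethanol stripping is not corrected for.

*Chemostat.* µ = D by definition, independent of noise. Residual
glucose defaults to 0 g/L (glucose-limited operation) with a logged
warning when the channel is absent. Steady state requires the relative
drift (|trend slope|·span/mean) of both biomass and the off-gas CO₂
signal to stay below 5% over one residence time; both the span and the
threshold are configurable.

*Replicates.* Pooling is field-wise mean ± sample standard deviation
(n−1); mixing batch and chemostat fits is refused.

### Carbon accounting

Closure = 100 · Σ(C-mol output fluxes incl. biomass) / (6·|q_glc|),
with glucose as the sole carbon input (minimal medium). Printed rate
sets from real cultivations often close a few percent above 100%
(measurement bias); closure is reported as computed, uncorrected, with
a warning outside [90%, 110%]. The respiration partition attributes one
CO₂ per ethanol (pyruvate decarboxylase) to fermentation and the
remainder to respiration; CO₂ co-released on the small pyruvate →
acetate overflow route is deliberately not subtracted — the partition
reproduces the conventional definition, and the simplification is at
most a few tenths of a percent of glucose carbon. A flux below 0.1% of
glucose carbon is suppressed in rendered edge lists only, never in the
data.

### Energetics

Weak-acid speciation is Henderson–Hasselbalch for a monoprotic acid
(acetic acid pKa 4.76 by default). The ATP ledgers count ATP→ADP as 1
and ATP→AMP as 2 equivalents: the native overflow route earns 1 ATP in
lower glycolysis per acetate-equivalent and spends 2 on Acs activation
(net 1); the phosphoketolase route bypasses the glycolytic ATP and
still spends 2 (net 2); phosphotransacetylase reaches acetyl-CoA with
no activation cost (net 0).

The two-substrate mixing model treats an observed steady-state gas flux
as q_obs = q_glc·(1−y) + q_ace·y and solves for y; reference fluxes are
caller-supplied, and solutions outside [0,1] are flagged as
extrapolation rather than clipped. The classic reference pair
(2.8, 7.4 mmol gCDW⁻¹ h⁻¹) appears in tests as a worked fixture; the
literature reports nearly identical CO₂- and O₂-based pairs, so the
fixture does not commit to one gas.

`decoupling_atp_demand` is an explicit *model*, not a measurement: the
futile-cycle ATP burden is leak rate × undissociated fraction at the
extracellular pH × cost per cycle. The per-cycle export cost of one
acetate + proton is not settled (1 vs 2 ATP equivalents); the default
is 1 and the parameter is exposed.

### Metabolite panels

Fold-changes are ratios of arithmetic replicate means (matching how
panel bar charts report means ± sd), as % of control. Significance uses
the two-sided Welch t-test with Welch–Satterthwaite degrees of freedom
(scipy's unequal-variance t-test; an independent from-scratch
implementation of the statistic serves as the test-suite oracle).
Tiers: \* p<0.05, \*\* p<0.001. No multiple-testing correction is
applied by default — panels of ~12 metabolites are conventionally
reported with raw per-metabolite tests — but Benjamini–Hochberg
adjustment is one flag away. Internal-standard normalization is assumed
to have happened upstream (division by the IS response per sample);
the package starts from quantified pool sizes.

Equilibrium checks solve K-invariance (Π product fold-changes = Π
reactant fold-changes) for a single unmeasured species; the
triose-phosphate isomerase check compares the DHAP:GAP pool ratio to
the literature equilibrium value of 20 (configurable) on a log₂ scale.

## Synthetic data

The generator emulates a reference bioreactor characterization of a
control and a phosphoketolase-expressing yeast strain: exponential
batch growth on 20 g/L glucose (µ 0.353 vs 0.266 h⁻¹, with the full
signed rate sets of both strains as defaults), glucose-limited
chemostats at D ≈ 0.104 h⁻¹ with 7.5 g/L feed (steady-state biomass
from the strain yields 0.479 / 0.409 gCDW/g), and quadruplicate
sugar-phosphate panels whose fold-change map (X5P 0.26, F6P 0.74,
GAP 2.08, E4P 5.42, DHAP 2.0; Ru5P 0.6, S7P 0.7, 2PGA 0.8 as plausible
moderate decreases; others 1.0) is applied to order-of-magnitude
realistic base pools (µmol/gCDW). Batch sampling uses 16 points up to
97% of the glucose-exhaustion time, comfortably inside the exponential
phase.

Because printed rate sets need not conserve carbon (the batch reference
closes at ~107%), scenarios carry a `balance` switch: `closed` rescales
q(CO₂) before simulation so closure is exactly 100% (making
conservation a testable property of the generator/accountant pair);
`as-printed` uses the rates verbatim and reproduces their printed
closure. Tests use whichever mode the property under test calls for.

Noise is multiplicative Gaussian with a per-channel CV, independent
across channels and time points (replicate dispersions, not a validated
instrument noise model); for off-gas channels it is applied to the
inlet–outlet difference, the informative part of the signal. Replicate
panels use mean-preserving log-normal draws
(mean·exp(σZ − σ²/2), σ² = ln(1+CV²)) so expected fold-changes equal
the configured map; replicates are independent (no batch/run
correlation structure is modelled). All outputs are functions of
(scenario, seed): one root `SeedSequence` per scenario spawns one child
stream per channel in a fixed documented order, so adding a channel
never perturbs another channel's draws.

The optional second growth segment on accumulated ethanol
(`mu_ethanol`) is cosmetic — a fixed ethanol consumption rate and a
respiratory gas quotient — for exercising window selection on two-phase
profiles; it is not part of any quantitative contract.

What passing tests on synthetic data do **not** show: robustness to
instrument drift and calibration error, correlated replicate noise,
evaporation/stripping losses, non-exponential growth (lag, diauxie,
Crabtree switching), or CO₂ retention in the liquid phase at higher pH.
The generator validates the estimators' algebra and statistics, not the
measurement process.

## Numerical choices

* Regressions are ordinary least squares via `numpy.polyfit`; R² of a
  zero-variance signal is defined as 1 (a constant is a perfect fit),
  which makes µ = 0 for constant biomass well-defined.
* Reaction carbon checks use an absolute tolerance of 1e-9 on the
  signed carbon sum.
* Welch test of two zero-variance groups returns p = 1 when the means
  agree (no evidence of difference) and p = 0 otherwise.
* A negative respiratory CO₂ flux (ethanol-linked CO₂ exceeding total)
  is returned with a warning, not raised — it flags inconsistent inputs
  that the caller should see.
* Pipeline runs are deterministic per (config, seed); per-replicate
  seeds are derived as `seed·10⁴ + replicate index`.

## Design decisions that were genuinely open

* **Model/Results organisation.** Estimation is presented as model
  classes whose `fit()` returns a results object with `summary()`,
  mirroring the statsmodels idiom, with thin functional wrappers for
  one-off use. Pure-function pipelines were the alternative; the
  model objects keep window choices, registries and diagnostics
  attached to their results.
* **Concentration-vs-biomass regression** for batch specific rates
  (rather than point-wise differencing of time-series), as argued
  above.
* **q(biomass) convention**: reported in C-mmol gCDW⁻¹ h⁻¹ as
  µ·1000/cmol_mass — the reading consistent with reference tables where
  µ = 0.353 h⁻¹ accompanies q(biomass) ≈ 14.4.
* **Sign convention**: consumption negative, production positive, in
  data and reports alike; magnitudes are used inside yields and
  normalizations.
* **CLI**: a thin `click` layer (`simulate`, `rates`, `fluxmap`,
  `balance`, `energetics`, `metabolites`, `report`) over the library;
  every subcommand is plumbing around one library call.

## Limitations

* Batch mode assumes balanced exponential growth inside the fitted
  window; fed-batch and dynamic shifts are out of scope.
* The gas balance ignores inert-gas correction, pressure drift and
  liquid-phase CO₂ accumulation.
* Carbon closure above 100% is reported as-is; no reconciliation or
  error-in-variables correction is attempted (an optional first-order
  propagation of replicate dispersions is the only uncertainty
  treatment on the balance).
* The decoupling ATP model is intentionally minimal: it ignores
  intracellular pH dynamics, anion accumulation kinetics and transporter
  saturation.
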