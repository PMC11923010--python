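# Methods

This note documents the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic data do and do not emulate.

## System and boundary

The modelled system is a beef *finishing* enterprise on fertilised
permanent pasture in a mild, wet lowland climate: ~30 weaned
Charolais-cross calves enter each autumn at ~332 kg, are housed on
grass silage from 1 October to 30 April, grazed otherwise, and leave at
~555 kg (heifers) or ~620 kg (steers).  The boundary is partial
cradle-to-farmgate: upstream production and transport of purchased inputs
are included; the suckler (cow–calf) stage, land-use change, downstream
processing and electricity (below the cut-off except under anaerobic
digestion, where digester energy is folded into the digester-chain line)
are not.  The functional unit is 1 kg liveweight gain (LWG).  Analysis is
attributional; co-product handling is economic allocation throughout.

## Synthetic data generators

The generators stand in for farm-platform primary records and are
first-class, tested code.

* **Herd.**  Piecewise-linear liveweight trajectories between weighing
  events drawn every 14–28 days, with per-animal overall ADG ~ lognormal
  (mean 0.90 kg/d, CV 12 %) and per-period lognormal multipliers
  (σ = 0.30) rescaled to hit the sex-specific finishing target exactly.
  This is the simplest growth model consistent with period-resolution
  records; every generated animal's overall ADG falls in (0.3, 1.8) kg/d.
* **Forage.**  Monthly DE/CP/NDF climatology at the measured means
  (pasture 74.86 / 23.10 / 46; silage 69.40 / 15.46 / 52; NDF values are
  package defaults for these forages, used only as the litter-quality
  proxy), optionally with Gaussian noise.
* **Weather.**  Seasonal normals for a Devon lowland site (illustrative
  packaged constants) plus a linear warming ramp to the end of the
  century: +1.5 °C for the low pathway (`rcp26_like`), +4.0 °C for the
  high pathway (`rcp85_like`).  Rainfall and pan evaporation keep their
  normals, so pathway ordering is strictly a temperature effect — the
  property the soil projections rely on.  Real climate projections have
  variability, precipitation trends and spatial structure that these
  trajectories do not; passing tests therefore demonstrate internal
  consistency and correct ordering, not skill against observed climate.
* **Inventory.**  The baseline input table is packaged verbatim
  (21.61 ha; 3,354 kg fertiliser N; 11,867 kg DM/ha yield; straw, feed
  and transport lines; clay 36 %; initial SOC 53.78 Mg C/ha).

## Tier 2 livestock chain

Computed per animal per weighing interval, split by calendar month at the
housing boundary (silage diet and zero activity allowance housed; pasture
diet with activity allowance 0.17·NEm grazing).  Midpoint weight of the
whole interval is used for metabolic terms — sub-period weights are not
observable at the data's resolution.  Defaults: Cfi 0.322 MJ/d/kg^0.75,
growth-curve sex coefficient 1.0 (steers) / 0.8 (heifers), mature weight
650 kg, feed gross energy 18.45 MJ/kg DM, urinary energy 4 %, ash 8 %,
B₀ 0.18 m³ CH₄/kg VS, CH₄ density 0.67 kg/m³.  Ym defaults to 6.5 % of
GE with 7.0 % as a selectable alternative for high-forage diets; N
retention uses the growing-cattle equation from ADG and NEg; weight loss
floors NEg at zero (with a warning), and N retention is clamped so
excretion is never negative.

Manure systems and coefficients (cool temperate annual values, packaged
with citations, all config):

| system | MCF % | EF3 direct | FracGas | FracLeach |
|---|---|---|---|---|
| solid storage (midden) | 4.0 | 0.010 | 0.30 | 0.02 |
| pasture deposition | 0.47 | 0.006 | 0.21 | 0.24 |
| digester + sealed store | 0.1 | 0 | 0 | 0 |

The digester MCF represents fugitive leakage only: captured methane
leaves the boundary with the biogas co-product.

**Source boundary.**  "Manure management" in the ledger covers the housed
storage chain only; excreta deposited at grazing (its N₂O *and* its small
CH₄) are field emissions booked with the soil source, matching the
national-inventory grouping and the fact that digestion applies to housed
FYM only.

## RothC implementation

Standard five-pool monthly structure: decay constants 10 / 0.3 / 0.66 /
0.02 yr⁻¹ (DPM/RPM/BIO/HUM), clay-dependent CO₂:(BIO+HUM) ratio
x = 1.67(1.85 + 1.60e^(−0.0786·clay)), 46/54 BIO/HUM split of retained
carbon, temperature modifier a = 47.91/(1+e^(106.06/(T+18.27))), moisture
modifier from the accumulated topsoil moisture deficit (0.75 × open-pan
evaporation vs rainfall, 23 cm topsoil), soil-cover modifier fixed at 0.6
— permanent grassland is never bare.  FYM partitions 49/49/2 into
DPM/RPM/HUM; digestate uses the same partition with configurable C and N
post/pre-digestion ratios (defaults 0.55 and 0.95, placeholders for
digestion-model output).  Calendar is 12 equal months, no leap handling.

**Initialisation.**  Pedotransfer regressions give RPM, HUM and BIO from
total SOC and clay; IOM follows the 0.049·SOC^1.139 power law; DPM takes
the residual so pools sum exactly to the measured stock.  The regressions
only admit a non-negative residual in a mid-range stock window (roughly
25–150 Mg C/ha at 36 % clay); outside it the initialiser raises with a
diagnostic.

**Equilibrium inversion.**  Under a repeated baseline climate year the
active pools follow an affine annual map `x → Ax + I·b_plant + b_fym`.
`A`, `b_plant`, `b_fym` are extracted by propagating basis vectors
through 12 monthly steps, and the annual plant input consistent with a
steady state at the measured stock solves one linear system (verified to
1e-6 Mg C/ha; residuals are at solver precision, so no iterative polish
is needed).  The inversion always uses the *baseline* organic-amendment
schedule: the plant input is a property of the baseline field, which is
what keeps it fixed across the destocking and digestion scenarios by
construction.

**Plant input partitioning.**  Of aboveground biomass C (45 % of DM),
65 % is harvested or grazed and half of the remaining 35 % turns over
annually, so aboveground residue is 17.5 % of aboveground biomass C;
the belowground input is the equilibrium remainder, with net
rhizodeposition at half the belowground biomass.  Monthly inputs follow a
temperate grass growth profile; each month's DPM fraction is
1 − NDF/100.  FYM carbon (0.5 × organic matter of excreted VS plus straw
bedding at 85 % OM) is applied in March–April after winter storage.

**Projections and the SOC flux.**  100-year-horizon runs (2016–2100)
start from the pedotransfer pools.  The annual SOC change rate is
(final − initial)/window with the window defaulting to the 100-year
impact horizon; it is a reporting convention only and is configurable
because reported tables for this system are not consistent with any
single window.  The rate enters the ledger as −rate·area·44/12 t CO₂/yr.
With equilibrium-derived inputs and a warming pathway the synthetic
baseline soil is close to neutral (slightly losing); the sensitivity
analysis (±20 % plant C) brackets this.

## Footprint assembly

AR6 GWP100 factors: fossil CH₄ 29.8, biogenic CH₄ 27.2, N₂O 273.  All
on-farm CH₄ (enteric, manure) is biogenic; fossil CH₄ can arise only in
upstream entries.  Upstream lines priced directly in CO₂-eq use a
pass-through factor of 1.  Land-based sources (soil N₂O, lime, fertiliser
chain incl. DCD and seed, SOC flux) are scaled by the cattle share
(default 0.74) before normalisation; the share is a fixture — the
co-grazing sheep enterprise's economic values are not derivable from the
packaged data, so allocation shares are inputs, not outputs.  Hotspot
shares are percentages of gross (sink-exclusive) emissions with the sink
reported separately as an offset; the SOC entry is applied
post-allocation (it is land-based).

## Upstream emission factors

The packaged EF table (`data/ef_table.yaml`) replaces proprietary LCI
databases with literature-style constants (fertiliser N 5.5 kg CO₂e/kg N;
road transport 0.11 kg CO₂e/t·km; straw 0.10, rapeseed meal 0.55, seed
1.6, DCD 5.0 kg CO₂e/kg; digester chain 900 kg CO₂e/yr amortised).  Every
entry carries units, gas, an uncertainty spec and a citation note
flagging it as a database stand-in; all are overridable via
`--ef-table PATH` or `EFTable.with_overrides`.

## Scenarios

Implemented as deep-copy transforms with per-override provenance notes
(tested: the baseline bundle is bit-identical after any transform).
Choices worth recording:

* **LD** is a 0.5 multiplier on animal-derived physical quantities rather
  than a sub-herd selection — the destocking assumption is strict
  proportionality, and a multiplier makes "emissions halve, LWG halves"
  exact rather than sample-dependent.  Upstream input lines are kept at
  baseline (exported silage leaves burden-free, no substitution credit,
  consistent with attributional practice), while the manure-derived soil
  C input halves with the herd.
* **AD**'s 76/24 economic allocation applies to the digester chain
  (infrastructure, energy, fugitive CH₄, digestate storage); on-field
  digestate emissions remain fully with the beef system because the
  digestate substitutes FYM on-farm.  Biogas is excluded by allocation,
  not credited.
* **WC** adds no explicit fixation-N₂O term (changed residue and diet
  characteristics only) — a documented limitation.  Clover-mix CP/NDF
  values are package fixtures.

## Uncertainty

Monte Carlo re-prices the once-computed physical state (GE, VS, N flows,
input masses) under sampled emission factors; the SOC flux is held
deterministic and handled by the separate ±20 % C-input sensitivity.
Distribution defaults: mean-preserving lognormals for multiplicative
factors with CVs from the EF table (0.2–0.7) and pedigree-style CVs for
qualitatively scored parameters (Ym 0.10, B₀ 0.15, midden MCF 0.30,
storage EF3 0.50).  Sample SD uses the n−1 denominator; the 95 % interval
is the empirical 2.5/97.5 percentiles; a constant sample reports SD
exactly 0; non-finite draws are rejected (error above 1 % rejections).
Default 5,000 draws; the acceptance script uses 1,000, which stabilises
the mean and CV to well under a percent of themselves.

## What passing tests show — and don't

All quantitative behaviour is demonstrated on synthetic data with
packaged stand-in emission factors.  Desk-level checks against the
embedded reference summary tables (CV recomputation, scenario deltas from
reported means, sensitivity ratios) validate the summary arithmetic, not
the simulation.  The simulated baseline lands in the plausible
12–18 kg CO₂-eq/kg LWG range with the expected hotspot ordering, but
scenario deltas and SOC trajectories differ quantitatively from any real
farm: upstream factors are stand-ins, the climate is stylised, and herd
heterogeneity is generated, not measured.

## Known limitations

No rumen mechanistic model, dairy equations or feed optimisation; no
nitrogen cycle inside the soil model; no spatial structure; no
correlated Monte Carlo draws or variance decomposition; no costs.  The
digestate transformation ratios and the grass-clover fixtures are
placeholders pending measured values.
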