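# grazefoot

Farm-gate carbon footprinting of a grass-based beef **finishing** system:
a tailored RothC soil-organic-carbon simulator coupled with per-animal
IPCC Tier 2 livestock emission accounting inside an attributional
life-cycle assessment (LCA), with four mitigation scenarios, Monte Carlo
uncertainty propagation, and a ±20 % plant-carbon-input sensitivity
analysis.  All primary data are synthetic, generated to emulate a lowland
permanent-pasture finishing enterprise in south-west England (North Wyke
Farm Platform style): ~30 weaned calves entering each autumn at ~332 kg,
housed October–April on silage, grazed otherwise, finished at ~555 kg
(heifers) / ~620 kg (steers).

## Who this is for

Researchers in livestock systems modelling and agricultural LCA who want a
transparent, fully scripted re-implementation of the ensemble
(soil model + Tier 2 inventory + LCA) approach — every emission factor,
assumption and intermediate quantity is inspectable and overridable, and
nothing depends on proprietary LCI databases.

## The model in brief

**Functional unit.** 1 kg of liveweight gain (LWG) at the farmgate;
the footprint is kg CO₂-eq (AR6 GWP100: fossil CH₄ 29.8, biogenic CH₄
27.2, N₂O 273) per kg LWG, partial cradle-to-finishing-farmgate (the
suckler stage is outside the boundary).

**Livestock (Tier 2).** For each animal and each interval between two
weighing events: NEm = Cfi·W^0.75, NEg = 22.02·(W/(C·MW))^0.75·ADG^1.097,
REM/REG as polynomials of diet digestible energy (DE), GE = ((NEm+NEa)/REM
+ NEg/REG)/(DE/100).  Enteric CH₄ = GE·Ym/55.65; volatile solids and
excreted N follow the energy and protein balance; manure CH₄ =
VS·B₀·0.67·MCF and manure N₂O (direct + indirect) use per-system emission
factors.  Excreta splits between the midden (housed months) and pasture
deposition (grazing) by calendar.

**Soil (RothC).** Five pools (DPM, RPM, BIO, HUM + inert IOM), monthly
first-order decay modulated by temperature, topsoil moisture deficit and
cover (c = 0.6 for permanent grassland); clay-dependent CO₂/(BIO+HUM)
split.  Pools are initialised by pedotransfer functions of measured SOC
and clay with IOM = 0.049·SOC^1.139; the annual plant C input is recovered
by running the model to equilibrium at the measured stock (an exact affine
inversion under a repeated baseline climate year).  Litter quality
(DPM:RPM) is proxied by forage NDF; 100-year projections run under
stylised low- and high-emission warming pathways, and the SOC change
enters the ledger as a CO₂ flux.

**Scenarios** (pure parameter overrides of the baseline): nitrification
inhibitor (`NI`, fertiliser EF₁ → 0.54 %, DCD at 10 kg/ha), 50 %
destocking (`LD`, 1.04 → 0.52 LU/ha), white clover (`WC`, fertiliser
removed, grass-clover diet DE 72.8 %, clover-field initial SOC
38.88 Mg C/ha), anaerobic digestion (`AD`, housed FYM to a gas-tight
digester, digestate replaces FYM, 76/24 biogas/digestate allocation).

**Allocation.** Land-based burdens (soil N₂O, lime, fertiliser chain, SOC
flux) are shared 74/26 between the cattle and the co-grazing sheep
enterprise; animal-specific burdens are not.

## Worked example

```bash
$ grazefoot run --scenario BAU --rcp rcp26 --seed 1
BAU / rcp26
  intensity : 13.23 kg CO2-eq/kg LWG
  LWG       : 7762 kg
  SOC offset: -0.0 % of gross
  enteric                        42.5 %
  soil_N2O                       25.8 %
  upstream_fert_n                13.3 %
  manure_management               8.4 %
  ...
```

The 30-head synthetic herd gains 7,762 kg liveweight over the finishing
season; the allocated, characterised ledger comes to 13.23 kg CO₂-eq per
kg of that gain.  Enteric fermentation is the dominant source (42.5 % of
gross emissions), followed by soil N₂O (25.8 %) and manure management
(8.4 %); under the equilibrium-derived plant C inputs and a warming
pathway the soil is approximately carbon-neutral, so the SOC flux offsets
essentially nothing here.  Python equivalent:

```python
from grazefoot import build_baseline_bundle, run_footprint, apply_scenario

bundle = build_baseline_bundle(seed=1)
base = run_footprint(bundle, "rcp26")
ad = run_footprint(apply_scenario(bundle, "AD"), "rcp26")
print(base.result.intensity, ad.result.intensity)   # 13.23  12.68
```

Monte Carlo uncertainty and the C-input sensitivity:

```bash
grazefoot mc   --scenario BAU --rcp rcp26 --n 5000 --seed 42
grazefoot sens --scenario BAU --rcp rcp85 --delta 0.2 --seed 1
```

## Layout

- `src/grazefoot/synthetic_farm.py` — seed-reproducible herd, weather,
  forage and inventory generators
- `src/grazefoot/herd_emissions.py` — Tier 2 per-animal, per-period chain
- `src/grazefoot/rothc_soil.py` — the five-pool monthly SOC model
- `src/grazefoot/field_and_upstream.py` — soil N₂O, liming CO₂, packaged
  upstream EF table (`data/ef_table.yaml`)
- `src/grazefoot/scenario_engine.py` — the four mitigation transforms
- `src/grazefoot/footprint_assembly.py` — ledger, GWP100, allocation,
  intensity and hotspots
- `src/grazefoot/uncertainty.py` — Monte Carlo + sensitivity
- `docs/methods.md` — model description, defaults and their rationale,
  limitations
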