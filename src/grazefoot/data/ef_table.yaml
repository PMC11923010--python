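# Packaged emission-factor table.
# Every entry: value, units, gas ('N2O-N', 'CO2_fossil', 'CO2e', ...),
# dist (uncertainty spec for Monte Carlo), cite (provenance note).
# Upstream values are package defaults standing in for proprietary LCI
# databases; all are overridable from user config (`--ef-table PATH`).

ef1_synthetic:
  value: 0.016
  units: kg N2O-N / kg N
  gas: N2O
  dist: {family: lognormal, cv: 0.6}
  cite: "IPCC 2019 Refinement, disaggregated EF1 for synthetic N, wet climate"

ef1_synthetic_dcd:
  value: 0.0054
  units: kg N2O-N / kg N
  gas: N2O
  dist: {family: lognormal, cv: 0.6}
  cite: "UK/Irish field trials of ammonium nitrate with DCD (20-yr flux dataset)"

ef1_organic:
  value: 0.006
  units: kg N2O-N / kg N
  gas: N2O
  dist: {family: lognormal, cv: 0.6}
  cite: "IPCC 2019 Refinement, EF1 for organic amendments, wet climate"

ef4_deposition:
  value: 0.010
  units: kg N2O-N / kg (NH3-N + NOx-N)
  gas: N2O
  dist: {family: lognormal, cv: 0.5}
  cite: "IPCC 2019 Refinement, EF4 aggregated"

ef5_leaching:
  value: 0.011
  units: kg N2O-N / kg N leached
  gas: N2O
  dist: {family: lognormal, cv: 0.7}
  cite: "IPCC 2019 Refinement, EF5"

frac_gasf:
  value: 0.11
  units: kg NH3-N+NOx-N / kg N applied
  gas: none
  dist: {family: point}
  cite: "IPCC 2019 Refinement, FracGASF for ammonium-nitrate-type fertiliser"

frac_gasm:
  value: 0.21
  units: kg NH3-N+NOx-N / kg N applied
  gas: none
  dist: {family: point}
  cite: "IPCC 2019 Refinement, FracGASM organic amendments and excreta"

frac_leach:
  value: 0.24
  units: kg N / kg N applied or deposited
  gas: none
  dist: {family: point}
  cite: "IPCC 2019 Refinement, FracLEACH-(H) wet climate"

lime_c_fraction:
  value: 0.12
  units: kg C / kg limestone
  gas: CO2_fossil
  dist: {family: point}
  cite: "IPCC 2006 Vol.4 Ch.11 default carbonate C fraction of limestone"

upstream_fert_n:
  value: 5.5
  units: kg CO2e / kg N
  gas: CO2e
  dist: {family: lognormal, cv: 0.25}
  cite: "European ammonium nitrate manufacture, literature average; stands in for a commercial LCI database entry"

upstream_fert_p:
  value: 1.8
  units: kg CO2e / kg P
  gas: CO2e
  dist: {family: lognormal, cv: 0.3}
  cite: "Triple superphosphate manufacture, literature average; database stand-in"

upstream_fert_k:
  value: 1.0
  units: kg CO2e / kg K
  gas: CO2e
  dist: {family: lognormal, cv: 0.3}
  cite: "Potassium chloride manufacture, literature average; database stand-in"

upstream_lime:
  value: 0.08
  units: kg CO2e / kg
  gas: CO2e
  dist: {family: lognormal, cv: 0.3}
  cite: "Quarrying and grinding of agricultural limestone; database stand-in"

upstream_rapeseed_meal:
  value: 0.55
  units: kg CO2e / kg
  gas: CO2e
  dist: {family: lognormal, cv: 0.3}
  cite: "Rapeseed expeller meal at mill, economic allocation; database stand-in"

upstream_straw:
  value: 0.10
  units: kg CO2e / kg
  gas: CO2e
  dist: {family: lognormal, cv: 0.3}
  cite: "Barley straw at farm, economic allocation; database stand-in"

upstream_transport_road:
  value: 0.11
  units: kg CO2e / t.km
  gas: CO2e
  dist: {family: lognormal, cv: 0.2}
  cite: "Lorry 16-32 t, EURO6, average load; database stand-in"

upstream_seed:
  value: 1.6
  units: kg CO2e / kg
  gas: CO2e
  dist: {family: lognormal, cv: 0.4}
  cite: "Grass/clover seed production; database stand-in"

upstream_dcd:
  value: 5.0
  units: kg CO2e / kg
  gas: CO2e
  dist: {family: lognormal, cv: 0.4}
  cite: "Dicyandiamide synthesis from calcium cyanamide, incl. transport; pedigree-scored stand-in"

upstream_ad_chain:
  value: 900.0
  units: kg CO2e / yr
  gas: CO2e
  dist: {family: lognormal, cv: 0.5}
  cite: "Small on-farm digester: amortised infrastructure plus parasitic energy, rescaled from public AD process data; pedigree-scored stand-in"
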