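# aquarisk

Groundwater quality screening and health-risk assessment for per-well
physicochemical + trace-metal monitoring tables:

- **hydrochem** — charge-balance QA (CBE), chloro-alkaline indices,
  Piper-style facies, Gibbs mechanism zones, Sulin origin classes, ionic
  ratio panels, and lab QA stats (LOD/LOQ/%RSD)
- **wqi** — integrated-weight drinking-water quality index (entropy weights ×
  CRITIC weights, product or convex integration) with WHO-standard quality
  ratings and class labels
- **pollution_indices** — heavy-metal pollution index (HPI) and the
  Hakanson-style ecological risk index (RI)
- **health_risk** — deterministic USEPA-style non-carcinogenic chain: oral
  and dermal chronic daily intake, hazard quotients, hazard indices, for
  adult and child cohorts
- **monte_carlo** — seeded probabilistic hazard quotients (truncated
  lognormal concentrations, normal exposure variables, point masses),
  percentile summaries, exceedance fractions and calibration checks
- **synthetic_data** — charge-balanced synthetic cohorts moment-matched to
  published summary statistics, with a Gaussian-copula salinity block, for
  end-to-end testing when raw per-sample data are unavailable

## CLI

All randomness requires an explicit `--seed`. Every command writes CSV plus a
JSON metadata sidecar.

```sh
aquarisk simulate --n 69 --seed 1 --out cohort.csv
aquarisk hydrochem cohort.csv --out panel.csv
aquarisk wqi cohort.csv --out wqi.csv --weights recompute --integration product
aquarisk pollution cohort.csv --toxicity tox.yaml --out pollution.csv
aquarisk risk cohort.csv --out risk.csv --summary-out risk_summary.csv
aquarisk mc cohort.csv --n-iter 10000 --seed 1 --out mc.csv
aquarisk report cohort.csv --out-dir report/ --seed 1
```

Configuration is YAML; omitted fields fall back to package defaults
(WHO standards, published integrated weights, toxicity constants, exposure
profiles). Ecological-risk backgrounds have **no default** and must be
configured:

```yaml
toxicity:
  Fe: {background: 0.30}
  Mn: {background: 0.10}
cai_numerator: schoeller   # or as_printed
```

## Input format

Comma-separated UTF-8 with one header row; one row per sample with columns
`sample_id, easting, northing, ph, ec, tds, th, Ca, Mg, Na, K, Cl, SO4,
HCO3, CO3, NO3, Fe, Mn, Cu, Zn`. Units are fixed (mg/L except EC in µS/cm
and unitless pH) — no automatic unit conversion. Arbitrary headers can be
mapped via `load_samples(path, column_map=...)`.
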