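# isodil

Isotope-dilution analysis of phosphorus nutrition experiments: partition
plant P uptake into fertilizer-, soil-, and seed-derived sources from
radiotracer specific activities, quantify fertilizer recovery and
relative agronomic efficiency, characterize soil P availability through
isotopic exchange kinetics (m, n, E1min), resin-extractable P and
microbial P, and generate fully synthetic datasets with embedded ground
truth for end-to-end testing.

## Layout

| module | purpose |
|---|---|
| `isodil.tracer` | decay correction to a reference date, specific activity |
| `isodil.partition` | direct/indirect source partitioning, seed-P calibration, recovery, RAE, OLS |
| `isodil.kinetics` | exchange-kinetics model, nonlinear (m, n) fitting, 1-minute E value |
| `isodil.pools` | resin P, fertilizer-derived resin fraction, fumigation microbial P |
| `isodil.synthetic` | seeded generators for the pot, seed, kinetics and incubation experiments |
| `isodil.io` / `isodil.cli` | CSV schemas and validation, config, pipeline orchestration, regression report |
| `isodil.datasets` | bundled published treatment-level means used as worked-example inputs |

## CLI

Generate a synthetic dataset and run every stage on it:

```sh
isodil simulate --seed 1 --out-dir demo_in
isodil run-all --input-dir demo_in --out-dir demo_out
```

Stages can be run individually (`partition`, `kinetics`, `pools`,
`report`) and configured with a YAML file (`--config`), e.g.

```yaml
half_life_days: 25.383
soil_total_p: 1024
soil_organic_p: 456
exclude_flagged: true
e_value_source: fitted
```

Input CSVs (`plants.csv`, `fertilizers.csv`, `kinetics.csv`,
`extractions.csv`) are validated against schemas before any
computation; an optional second `#units` row lets activity columns be
declared in kBq/MBq and converted at ingest. Outputs are
`partition_results.csv`, `partition_summary.csv`, `kinetics_fits.csv`,
`pool_summary.csv`, `regression_report.csv`, plus a `run_log.json`
recording input checksums, the effective configuration and all quality
flags raised.

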