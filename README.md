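# unicub

Analysis pipeline for **uniparental incubation in biparentally incubating
shorebirds**, going from raw nest-monitoring streams to behavioural phases
and statistical summaries:

1. **data model & IO** (`unicub.data_model`, `unicub.io`) — per-nest
   temperature/RFID traces, nest metadata and species references, read and
   written as plain CSV with ISO-8601 UTC timestamps.
2. **synthetic data** (`unicub.synthetic`) — a generator emulating the field
   recording setup (biparental bout alternation, diel ambient cycle,
   exponential cooling after departures, desertions, circadian uniparental
   rhythms) with a ground-truth ledger for every reading.
3. **extraction** (`unicub.extraction`) — local solar time, per-reading
   incubation classification from nest-vs-surface temperature (margin rule
   plus steep-slope onset/offset refinement), RFID-labelled bout
   segmentation, population median bouts and incubation-start estimation.
4. **phase detection** (`unicub.phases`) — qualified uniparental phases: a
   solo span minus the remaining parent's first regular bout qualifies when
   the remainder spans at least twice the population median bout; ends are
   trimmed 6 h before hatching / 24 h before chicks were found; causes
   (natural, post-capture, experimental removal, temporal) are attributed
   from nest events and later bouts.
5. **attendance** (`unicub.attendance`) — hourly/daily nest attendance in
   local solar time with the 75% type-purity filter, day-in-period and
   sine/cosine circadian covariates.
6. **inference** (`unicub.inference`) — the preset mixed models (daily,
   hourly, sex-specific variants; Gaussian ML with crossed variance
   components) and the binomial-logit nest-success model (adaptive
   Gauss-Hermite quadrature), summarized by 5,000-draw posterior simulation
   around the ML fit and variance-component shares.
7. **reporting & CLI** (`unicub.reporting`, `unicub.fixtures`, `unicub.cli`)
   — species/population summary tables, case-level descriptive statistics,
   actogram rendering, and the bundled published-count tables used by the
   acceptance targets.

## CLI

```bash
unicub simulate  --config cfg.yaml --seed 1 --out data/
unicub extract   --in data/ --out out/
unicub phases    --in data/ --out out/
unicub attendance --in data/ --out out/
unicub fit       --model daily --records out/daily_attendance.csv --out out/
unicub report    --in data/ --out out/ --actograms
unicub run-all   --config cfg.yaml --seed 1 --out run/
```

The YAML config groups parameters per stage (`simulate`, `extract`,
`phases`, `attendance`); any omitted key falls back to the documented
default of the corresponding dataclass
(`SimConfig`, `ExtractionParams`, `PhaseParams`, `AttendanceParams`).

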