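# infantwear

Analysis pipeline for multi-day infant wearable recordings: wear-state
detection from joint ECG/accelerometry evidence, validity-gated heart rate
and heart-rate variability, respiration-quality gating with ultradian
sleep-cycle extraction, per-child reliability statistics, paired device
comparison, and diary–physiology timelines. A seeded synthetic-cohort
generator stands in for raw recordings, so the whole pipeline is testable
offline.

## What it computes

| Module | Purpose |
| --- | --- |
| `infantwear.synthetic` | Seeded generators: R–R streams with artefacts/detach gaps, accelerometry straddling the 13 mg movement threshold, respiration nights with an embedded 30–120-min cycle, cohorts with requested usable-unit counts |
| `infantwear.io` | Canonical CSV round-trip for R–R, accelerometry, respiration-night and diary streams, with strict line-numbered validation |
| `infantwear.wear` | Per-10-min-window classification {worn_attached, worn_detached, not_worn} and wear summaries (periods, accidental detachments, artefact error rate) |
| `infantwear.cardiac` | Physiological-range filtering, per-minute HR (≥ 25-interval gate), per-10-min SDRRI (≥ 100-interval gate, mean of 2-min sub-segment SDs), coverage/quality report, within-child z-scoring |
| `infantwear.respiration` | Autocorrelation quality mask (> 0.35), nightly summaries, band-pass + peak-detection ultradian period estimation |
| `infantwear.reliability` | Usable-unit counts, mean/95% CI/CV tables, Wilcoxon signed-rank device comparison (exact p, both tie-ranking modes), proportion-precision helper, threshold sensitivity sweeps |
| `infantwear.timeline` | Diary–physiology merge and z-scored nap-response analysis |

All thresholds live in `AnalysisConfig` (movement SD 13 mg, 10-min windows,
150 non-physiological intervals per window, 25/50/100 interval gates,
autocorrelation 0.35, 30–120-min ultradian band) and every one can be swept
via `threshold_sensitivity`. The physiological R–R range default of
[250, 1000] ms is a config value — revisit it for other populations.

## CLI

```bash
# generate a synthetic recording set from a scenario file
infantwear simulate --config scenario.yaml --out sim/ [--seed 7]

# process one recording
infantwear wear    --rr sim/rr.csv --accel sim/accel.csv --out wear.json
infantwear cardiac --rr sim/rr.csv --out cardiac/
infantwear nappa   --nappa sim/respiration.csv --out night.json

# paired device comparison from a per-child usable-units table
infantwear compare --units units.csv --tie-method ordinal

# diary integration
infantwear timeline --rr rr.csv --accel accel.csv --diary diary.csv --out timeline.csv
infantwear nap      --rr rr.csv --diary diary.csv --out naps.json
```

A scenario file lists profile fields per stream, e.g.

```yaml
rr:
  duration_s: 3600
  baseline_hr_bpm: 130
  hr_jitter_ms: 20
  movement_schedule: [[0.0, 3600.0, "still"]]
  seed: 7
respiration:
  duration_s: 28800
  ultradian_period_min: 65
  ultradian_amplitude_bpm: 2
  noise_sd_bpm: 1
  seed: 7
```

## File formats

Plain UTF-8 CSV with `# key=value` metadata lines before the header
(`start_time` anchor, accelerometer `sample_rate_hz`). Times are float
seconds since the recording start; round-trips are lossless to 1 ms (R–R)
and 0.1 mg (accelerometry). Unknown columns and unknown position/category
labels warn instead of failing; invariant violations fail naming the first
offending line. An optional `read_rr_edf` adapter ingests EDF Holter
exports when `pyedflib` is installed.

## Conventions worth knowing

- An interval belongs to the half-open segment containing its beat's end
  time; windows are 0-based seconds since recording start.
- Sample SD (n−1) everywhere in cardiac/reliability statistics; population
  SD for the accelerometer vector-magnitude movement index.
- Detachment gaps appear in R–R streams as one long spanning interval, so
  beat times stay exact cumulative sums and the gap is discarded by the
  physiological-range filter.
- Undefined values are NaN; gated-out segments stay undefined rather than
  being interpolated.
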