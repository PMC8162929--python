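# dreamlink

A desk-scale, fully synthetic pipeline for two-way communication with lucid
dreamers: experimenter queries are encoded as timed stimulus trains
(Morse-coded math problems, spoken problems, word blocks), a simulator renders
multichannel polysomnography with ground-truth embedded volitional answer
signals (eye movements, facial-muscle contractions), an automated detector
recovers and decodes those signals, a consensus layer classifies trials under
multi-rater rules with REM gating, and a statistics layer reproduces the
aggregate outcome tables and chance-level control analyses.

## Layout

| module | role |
|---|---|
| `dreamlink.codec` | Morse/gaze/LR-count/muscle answer codes, pulse-train timing |
| `dreamlink.protocol` | problem generation and per-team session scheduling, incl. the full-night intensity-ramping state machine |
| `dreamlink.psg_sim` | synthetic PSG records, hypnograms with imperfect scorers, simulated rater judgments |
| `dreamlink.detect` | eye-movement and EMG-burst detection and answer decoding |
| `dreamlink.consensus` | 4-rater trial classification, 2-of-3 REM gating, lucidity-signal verification |
| `dreamlink.stats` | outcome summaries, Fleiss' kappa, Fisher exact chance analyses |
| `dreamlink.io` / `dreamlink.edf` / `dreamlink.cli` | CSV/JSON/EDF/YAML interchange and the CLI |

Published summary tables used as fixtures ship as CSVs under
`src/dreamlink/data/`.

## CLI

```bash
dreamlink simulate --design usa_tlr --seed 7 --out out/session   # schedule + hypnogram + EDF + truth log
dreamlink detect --edf out/session/record.edf --schedule out/session/schedule.json --out out/detections.json
dreamlink classify --trials trials.csv --out outcomes.csv
dreamlink report --trials trials.csv --controls controls.csv --out report.json
dreamlink replicate-tables --out out/tables
```

Designs: `usa_tlr`, `nl_tlr`, `french_blocks`, `german_night`. All commands
are deterministic given `--seed`; each run writes a `run_log.json` with the
config hash, seed, and package version.

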