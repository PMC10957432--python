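# ctgproc

Processing pipeline for cardiotocography (CTG) — the electronic fetal
monitoring (EFM) records of fetal heart rate (FHR) and uterine activity
(UA) collected during labor.  The package is aimed at researchers who
need to turn raw per-sample monitor exports into analysis-ready signals,
clinically meaningful pattern events, per-epoch feature vectors, and an
objectively phenotyped birth cohort for studies of hypoxic-ischemic
encephalopathy (HIE) and related adverse outcomes.

## What it does

Monitor exports are tall CSV files: one row per sample, at 4 Hz, keyed by
a tracing identifier, a timestamp in milliseconds before birth, and a
signal identity (measurement × sensor × monitor).  The pipeline:

1. **Ingestion** (`tracing_io`) — parses tall CSVs into *segmented
   signals* (gappy 4 Hz series stored as contiguous segments plus onset
   pointers), resolving duplicate timestamps (the highest row wins, as a
   resent packet's correction), normalizing 7/8/12-digit maternal record
   numbers to a canonical 12-digit form, and discarding samples more than
   72 h before birth.
2. **Assembly** (`assemble`) — merges per-sensor channels into one FHR,
   UA and MHR signal each, giving the more accurate sensor precedence
   (fetal scalp ECG over external ultrasound; intrauterine catheter over
   tocodynamometer) while keeping per-segment sensor provenance; detects
   duplicate and overlapping ("special") tracing files.
3. **Repair** (`repair`) — converts zero-valued FHR dropouts into gaps,
   bridges gaps strictly shorter than 15 s by linear interpolation, and
   flags uninterpretable (NOI) spans: maternal-heart-rate capture,
   recurrent impulse noise, out-of-physiologic-range values.
4. **Patterns** (`patterns`) — rule-based detection of baseline (BAS),
   accelerations/decelerations (ACC/DEC, >15 bpm for >15 s against a
   running trimmed-mean baseline), uterine contractions (CON), and the
   deceleration subtypes variable / early / late / prolonged.
5. **Features** (`features`) — non-overlapping 20-minute epochs (kept
   when ≥ 3840 of 4800 samples remain interpretable) with a sequential
   marked-point-process block (dwell times, transition counts,
   contraction rate per 10 min, deceleration subtype frequencies) and a
   variability battery per event type and frequency component:
   PRSA acceleration/deceleration capacity (T = 2.5 s, L = 25 s),
   Lomb-Scargle LF/MF/HF band powers, ApEn/SampEn (m = 2,
   r ∈ {0.1, 0.2, 0.3}·SD), Hurst exponent (bias-corrected rescaled
   range), Lyapunov exponent, correlation dimension, and the classical
   STV / LTI / Delta / interval-index battery on the 2.5 s grid.
6. **Outcome** (`outcome`) — objective eight-way study groups from blood
   gases and neonatal course: acidosis is cord pH < 7.0 or base deficit
   ≥ 10 mmol/L (or BD ≥ 10 on the first infant gas before 2 h); HIE is
   acidosis + an abnormal Sarnat exam + a confirmatory criterion.
7. **Synthesis** (`synthetic`) and **catalog** (`catalog`) — a
   deterministic ground-truth generator for tracings and cohorts (the
   real data cannot leave the originating health system), and a SQLite /
   CSV store with coverage statistics.

## Worked example

```python
import ctgproc as c

cfg = c.standard_config(seed=7, duration_h=2.0)     # stated world: 2 h of labor
c.simulate_tracing(cfg, out_path="example.csv")

raw, report = c.parse_tracing_csv("example.csv")
combined    = c.combine_sensors(raw)
repaired, noi = c.repair_record(combined)
events      = c.detect_patterns(repaired, noi)
features    = c.extract_features(repaired, events, noi)
```

This prints (seed 7):

```
signals: ['HR2/FECG/Coro250', 'HR2/external/Coro250', 'MHR/ECG/Coro250',
          'UP/Internal/Coro250', 'UP/TOCO/Coro250']
event counts: {'BAS': 183, 'RIN': 175, 'ACC': 3, 'CON': 19, 'DEC': 2}
retained epochs: 6
dwell_BAS = 1070            # s spent at baseline in the last epoch
mean__BAS__low = 139.3      # slow-trend baseline level, bpm
sd__BAS__high = 3.511       # high-frequency variability, bpm
stv__BAS__high = 3.628      # short-term variability on the 2.5 s grid
prsa_ac__BAS__high = 1.172  # acceleration capacity (PRSA)
prsa_dc__BAS__high = -1.163 # deceleration capacity (PRSA)
sampen_0.2__BAS__high = 1.36
hurst__BAS__high = 0.5261
```

The five raw signal identities reflect the mid-labor sensor switch; the
pipeline found the planted accelerations, decelerations and contractions
(3/2/19 over two hours), retained all six 20-minute epochs, and the
feature cells read as expected for AR(1) noise of ~3.5 bpm around a
139-140 bpm baseline (near-symmetric PRSA capacities, Hurst near 0.5).

A CLI wraps the same steps:

```sh
ctgproc simulate --seed 7 --duration-h 2 --out example.csv
ctgproc pipeline example.csv --db ctg.sqlite --features-out features.csv
ctgproc classify --n 800 --seed 0 --out cohort.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch —
simulating a four-hour tracing and an 800-infant cohort from the given
seed, then ingesting, combining, repairing, detecting patterns,
extracting features and classifying outcomes — and writes its JSON
report to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the models, the detector rules and their
parameters, the synthetic stated world, numerical choices, and known
limitations.
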