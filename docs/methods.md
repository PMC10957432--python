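# Methods

This note documents the models and procedures implemented in `ctgproc`,
the parameters that matter, the synthetic stated world the tests rely
on, and the numerical and design choices made where the problem was
genuinely open.

## Signal model and time convention

An EFM signal is a 4 Hz series (`delta` = 0.25 s) with gaps: a sequence
of contiguous *segments* separated by spans with no stored samples.
`SegmentedSignal` stores the concatenated values once, with per-segment
start times, lengths and sensor/monitor provenance; 1-based
`onset_pointers` (and 0-based `onset_offsets`) locate each segment in
the data array.  The canonical time axis is signed seconds relative to
birth (birth = 0, before birth negative); ingestion converts the
"milliseconds before birth" magnitudes of the tall CSV format to this
axis.  Floating-point time comparisons use an absolute tolerance of
`delta/100`.

One deliberate relaxation: two segments may *abut* (no missing sample
between them) when their sensor/monitor provenance differs.  This is
required so a combined signal can record a mid-labor sensor switch
(external ultrasound → scalp ECG) on a sample-by-sample basis without
inventing a gap.  Same-provenance segments must still be separated by at
least one missing sample, and `find_gaps` reports only positive-duration
gaps.

## Ingestion rules

* **Duplicate timestamps** (resent packets): keep the valid reading; if
  several valid readings differ, keep the one with the greatest row
  index — the later write is assumed to be a correction.
* **Validity** is non-empty, numeric and physically plausible: 0–300 bpm
  for heart rates, 0–100 for the uncalibrated uterine channel.  An FHR
  of exactly 0 bpm is *valid* at this stage — it is the monitor's
  dropout marker and is handled by repair, not ingestion.
* **MRN normalization**: 7-digit identifiers are zero-padded to 8, then
  8-digit identifiers receive the "1100" prefix; 12-digit identifiers
  pass through.  Non-numeric input and any other length (including the
  undefined 9–11-digit forms) are rejected with a reason code.
* **Birth window**: samples earlier than 72 h before birth are removed;
  a tracing with nothing left is excluded as `outside_window_prior`.

## Sensor combination

Where channels overlap in time, precedence is resolved pointwise:
FECG > external ultrasound for FHR (and HR2 over HR1 among equal
sensors, HR2 being the usual receptacle); internal pressure catheter >
TOCO for uterine activity.  The merge is implemented on a common sample
grid with lower-precedence channels written first, so the
higher-precedence sensor's sample wins at any shared timestamp,
including the switch boundary.  Combination never invents samples and is
idempotent.  Among exact-duplicate files one is retained (lowest GUID —
a convention; the source material does not specify the choice);
non-identical files overlapping in time are set aside as "special"; more
than one distinct non-overlapping file for the same infant excludes them
all.

## Repair

Only the FHR is repaired; uterine activity passes through.

* Runs of dropout samples (0 bpm) become gaps.
* Gaps strictly shorter than 15 s are bridged by linear interpolation
  between the flanking samples; a gap of duration `g` contains exactly
  `g/delta` missing slots and receives that many points on the line.
  Original samples are never modified; gaps at a signal boundary are
  never interpolated.  Dropout-created and transmission gaps are treated
  identically (the distinction is not recoverable downstream).
* Uninterpretable (NOI) spans are *flagged, not deleted*, so feature
  code can exclude them while the samples remain auditable:
  - `mhr_capture`: |FHR − MHR| < 5 bpm continuously for ≥ 60 s;
  - `impulse_noise`: ≥ 3 sample-to-sample jumps > 25 bpm within 10 s;
  - `out_of_range`: values outside 50–240 bpm.
  All three heuristics and their thresholds are this package's own
  documented choices (`RepairConfig`); the upstream system's repair
  internals are proprietary and only its <15 s interpolation bound is
  public.

## Pattern detection

The detectors are deterministic rules standing in for a proprietary
neural detector; every numeric parameter lives in `PatternConfig`.

* **Baseline**: a running 10-minute trimmed mean (25 % per tail),
  evaluated on a 2.5 s stride and interpolated, iterated to a fixpoint
  (≤ 5 iterations) while excluding excursion candidates — samples more
  than ±10 bpm from the current estimate.  This keeps isolated
  accelerations/decelerations from dragging the baseline (on a flat
  140 bpm signal with a planted 40 bpm deceleration the baseline stays
  within 1 bpm of 140).  Interpretable chunks shorter than 2 minutes get
  no baseline and are labeled RIN.
* **ACC/DEC**: an excursion starts when the signal leaves the ±10 bpm
  baseline band and ends once it is back in band for ≥ 5 s ("returned to
  baseline").  It becomes an event iff its peak deviation exceeds
  15 bpm and its duration exceeds 15 s — both strictly; a +15.0 bpm
  plateau or an exactly 15.0 s dip is not an event.  Height is the peak
  |deviation|; area is Σ|deviation|·delta/60 in beats.
* **Subtypes**: duration ≥ 120 s → prolonged; onset-to-nadir < 30 s
  (the standard clinical abrupt/gradual boundary) → variable; otherwise
  the deceleration is paired with the nearest overlapping contraction
  and its nadir is timed against the contraction peak with a 15 s
  coincidence tolerance: within it → early, later → late; unpaired
  gradual decelerations → variable.  The 30 s and 15 s values are
  conventions, exposed in the config.
* **Contractions**: resting tone is a running 10-minute 10th percentile;
  a contraction is a span where the 30 s-smoothed activity rises ≥ 15
  units above tone for ≥ 30 s.  Height and area are measured on the
  unsmoothed signal.  Each above-threshold span is one event (no
  multi-peak splitting).
* **RIN** is defined as interpretable FHR time covered by none of
  BAS/ACC/DEC; with NOI, these labels partition the FHR timeline by
  construction.  (The source material names RIN but never defines it;
  this definition is a convention.)

## Epochs and features

Epochs tile backwards from birth in 1200 s blocks.  NOI samples are
removed first; an epoch is retained iff ≥ 3840 samples (80 %) remain.

The FHR of each retained epoch is split by FFT into a low (≤ 30 mHz)
and a high (> 30 mHz, up to the 2 Hz Nyquist) component — the two sum
to the original signal to numerical precision — and each component is
masked by event type.  Features are computed only for the cells of a
configurable feature × event × band mask whose default covers: mean/SD
everywhere; slope on the low BAS cell; height/area on the low ACC/DEC
cells (referenced to the epoch's mean low-frequency baseline level);
and PRSA, Lomb-Scargle band powers, entropies, complexity and the
classical indices on the high-frequency cells.

* **Gap handling per feature**: samples removed inside an epoch are
  concatenated for time-domain features but keep true timestamps for the
  Lomb-Scargle periodogram, whose point is robustness to gaps.  The FFT
  decomposition operates on the concatenated series — a documented
  limitation, as the removal instants are not re-aligned.
* **PRSA** (T = 2.5 s, L = 25 s): anchors are samples where the mean of
  the T-window after minus before is positive (acceleration capacity,
  AC) or negative (deceleration capacity, DC); windows of ±L are
  aligned and averaged and the capacity is the quarter-sum of the two
  central post-anchor T-means minus the two pre-anchor T-means.
  Deceleration reserve DR = DC − AC (the fetal-PRSA convention; no
  printed formula exists for it).
* **Band powers**: Lomb-Scargle on actual sample times, integrated over
  LF 30–150 mHz, MF 150–500 mHz, HF 0.5–1 Hz and normalized by the
  signal variance; the LF/(MF+HF) ratio is also reported.
* **Entropies**: standard ApEn (self-matches counted) and SampEn
  (excluded), m = 2, r ∈ {0.1, 0.2, 0.3} of the analyzed segment's SD.
  A zero-variance segment is defined as perfectly regular (entropy 0,
  flagged degenerate); tolerance thresholds are applied in float32 for
  memory reasons, which the oracle tests mirror.
* **Hurst exponent**: rescaled-range over dyadic window sizes (16 up to
  n/2) with the Anis–Lloyd small-sample correction — the regression is
  run on log(R/S) minus its white-noise expectation and 0.5 is added
  back.  Without the correction the raw R/S slope of white noise at
  n = 4096 averages ≈ 0.54; with it, 0.50 ± 0.02 over 50 seeds.
* **Lyapunov / correlation dimension**: Rosenstein's method and
  Grassberger–Procaccia with embedding dimension 2, delay 1; inputs
  longer than 1200 points are decimated deterministically to bound the
  O(n²) cost.
* **Classical indices** on the 2.5 s grid: STV = mean |Δx| of grid
  samples; Delta = mean one-minute peak-to-peak range; interval index =
  STV / SD of the grid samples; LTI = interquartile range of the
  modulus √(s_j² + s_{j+1}²) of consecutive grid samples (the de Haan
  convention — LTI has no printed formula).
* **Sequential block**: dwell per event type and cumulative dwell since
  monitoring start; transitions counted between consecutive FHR events
  unless separated by ≥ 30 s of unclassified time; contraction rate =
  count/2 per 10 min; deceleration subtype frequencies grouped as
  {late, abrupt (=variable), others (=early+prolonged)}.

## Outcome classification

Acidosis: lowest-pH cord gas (any source) with pH < 7.0 (strict) or
base deficit ≥ 10 mmol/L (inclusive), or BD ≥ 10 on the first infant
gas drawn before 2 h of age.  Study groups are evaluated in fixed
precedence: death under 6 h → perinatal HIE (acidosis + ≥ 1 abnormal
Sarnat item + ≥ 1 of hypothermia / abnormal exam ≥ 6 h / seizures in the
first 24 h) → distant HIE (characteristic imaging without perinatal
HIE) → acidosis without HIE (acidosis, zero exam items, none of the
three) → healthy vs neonatal-intervention splits by blood-gas
availability.  The precedence order is inferred from the flow of the
published group definitions; it is logged per record.  Acidotic infants
with an abnormal exam but no confirmatory criterion match no published
definition and are reported UNCLASSIFIED rather than silently binned.
HIE severity: moderate/severe with ≥ 3 abnormal exam items or seizures,
else mild.

## The synthetic stated world

`standard_config` fixes the default conditions: 4 h of monitoring at
4 Hz; baseline 140 bpm; AR(1) variability (φ = 0.95) with 5 bpm SD;
contractions of height 40 every 3 minutes through the first half of the
record (i.e. the half nearer birth); accelerations (+20 bpm, 30 s) and
early decelerations (−25 bpm, 60 s, 10 s onset-to-nadir) on a fixed
schedule; two transmission gaps (120 s and 30 s); 1 % dropout samples in
geometric runs; 0.1 % duplicated rows with corrupted earlier copies; a
sensor switch (external→FECG, TOCO→internal) 30 min before birth; and a
maternal signal at 80 bpm.  These values are what a clinician would
recognize as an unremarkable labor tracing; they were chosen once and
are not tuned.  Planted accelerations use trapezoidal ramps so true
heights and durations are exact, which the planted-recovery tests rely
on.

What the generator does **not** emulate: physiologic coupling between
contractions and decelerations beyond fixed schedules, baseline
responses to events, autonomic spectral structure, or any HIE-specific
signal morphology.  A green planted-recovery or round-trip test
establishes that the pipeline's rules behave as specified on signals
with known truth — not that the detectors would match clinical
annotation on real tracings.

## Numerical choices

* Strict thresholds ("more than 15 bpm/s") are applied with a 1e-9
  guard so exactly-at-threshold synthetic plateaus never qualify.
* The baseline trimmed mean falls back to carrying the last estimate
  forward when a window retains fewer than 8 included samples, and to
  the chunk median when nothing is included.
* Event durations are `n_samples * delta`; event extents are half-open
  `[start, end)` intervals.
* Entropy distance matrices are float32 (≈ 90 MB for a full epoch);
  matrices for m and m+1 share the m-level computation.
* `detect_duplicate_tracings` compares full content, not just min/max
  timestamps, so value-level discrepancies are caught.

## Known limitations

* The pattern detectors are rule-based stand-ins; their agreement with
  the proprietary detector they replace cannot be measured from here.
* The FFT low/high split assumes a contiguous epoch; NOI-removal inside
  an epoch shifts later samples (see gap handling above).
* The published feature-table check-marks for the sequential block are
  typographically corrupted in the source; cumulative dwell is computed
  for all five event types and the reported subset is configurable.
* Legacy wide-format ingestion exists only as the synthetic module's
  writer/converter for exercising the parser; there is no live
  monitor-server retrieval.
* Clinical linkage is modeled abstractly (birth times supplied by the
  cohort fixture); real record-number crosswalks are out of scope.
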