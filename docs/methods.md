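# Methods

## Audio canonicalisation

All analysis runs on mono float audio in [−1, 1] at 44,100 Hz — twice the
22,050 Hz edge of human hearing, so the canonical rate preserves the full
audible band. Multichannel input is downmixed by channel mean (a
`mode="first"` flag drops to channel 0 instead; the mean preserves energy
balance when channels carry correlated content). Resampling is polyphase
band-limited interpolation (`scipy.signal.resample_poly`), deterministic
and exact for the rational rate ratios integer sample rates always give.
Files are 16-bit PCM RIFF WAV; amplitudes are scaled by 32768 on write
(clamped to the int16 range), so a write/read round trip is accurate to one
quantisation step. Clips from the generators are peak-normalised to 0.9,
standing in for recording gain the pipeline does not otherwise model.

## Fingerprinting

The landmark pipeline has four stages, each exposed separately:

1. **Spectrogram** — frames of 4,096 samples (~93 ms) hopped by 2,048 (50%
   overlap), periodic Hann taper, magnitude of the real FFT. Frame k covers
   samples [k·hop, k·hop + window), 0-based, timestamped at the window's
   left edge. The default log scale stores `log1p(|X|)`: non-negative,
   monotone, and compresses dynamic range so a percentile floor behaves
   consistently across loud and quiet clips. ~93 ms windows give ~10.8 Hz
   bins — fine enough to separate harmonics of a 200 Hz snore fundamental,
   short enough to localise burst onsets.
2. **Peaks** — a cell is a peak iff strictly greater than every other cell
   within ±15 frames × ±15 bins and at least the per-frame 60th-percentile
   magnitude floor. Strict inequality means plateaus yield no peak: the
   constellation is a deterministic function of the magnitudes, with no
   tie-break order to document. Implementation uses a separable maximum
   filter for candidates and verifies uniqueness per candidate; the test
   suite holds it equal to an exhaustive neighbourhood scan.
3. **Pairs** — each peak anchors up to 5 targets in (frame, bin) order from
   the zone Δt ∈ [1, 60] frames, |Δf| ≤ 120 bins. The zone is symmetric in
   frequency by default (`targets_above_only` restricts it) since snore
   harmonics above and below an anchor are equally informative.
4. **Hashes** — SHA-1 over the string `"f_anchor|f_target|Δt"`, truncated
   to 20 hex chars (80 bits; collision probability negligible at the
   hundreds-of-tracks scale this targets). The token carries no absolute
   time, so a hop-aligned time shift changes only the anchor timestamps —
   the covariance the matcher exploits.

## Matching and detection

The database is an inverted index token → (track, anchor frame). A query
is scored per track by the highest column of the offset histogram
`t_db − t_query`, counting each query hash at most once per offset; ties
between tracks break lexicographically on track id, ties between offsets
take the smallest. The store is a single versioned JSON file, which doubles
as the debug export.

`classify_clip` declares a snore when the best snore-labelled score is at
least the threshold (default 5 aligned hits) *and* not beaten by any
other-labelled template; a flag relaxes the second condition for
snore-template-only databases. `detect_stream` slides a 3.4 s window (the
modelled end-to-end decision latency of the wearable) in 1 s hops and
coalesces directly consecutive positive windows into one event whose onset
is the first positive window's start and whose reported decision is the
highest-scoring window of the run.

## Stimulus controller

The schedule is three 3 s bursts with 1 s gaps: on-intervals [t, t+3),
[t+4, t+7), [t+8, t+11) for trigger t — 11 s span, 9 s on-time. The state
machine evaluates at each `step(t, snore_active)` call: an idle controller
triggers when snoring appears; clearing snoring aborts immediately at that
very call rather than waiting for a burst boundary; a completed schedule
re-triggers at the first call after its span elapses if snoring persists
(no refractory period is imposed — a deliberate choice, since the device
model re-activates "when snoring attacks occur again" and any hold-off
would be an invented constant). Time must be non-decreasing; regression is
an error, not a clamp.

The heart-rate alarm fires strictly outside [40, 120] bpm: the bracketed
bounds are read as part of the normal range, so 40 and 120 themselves do
not alert. While out of range the actuator follows a 0.5 s on / 0.5 s off
pulse train; the pattern is configurable because only "frequent
vibrations" is specified by the device concept, not a duty cycle.

## PSG scoring

Traces are uniform-step time series (≥ 1 Hz). The flow baseline is a
rolling median over 120 s — long against any single event (≤ ~25 s), so
the events themselves barely move it, short enough to track slow drift.

* **Apnea**: maximal runs with |flow| ≤ 10% of baseline lasting ≥ 10 s. The
  10% cut operationalises "airflow cessation"; it is the common scoring
  convention and config-exposed.
* **Hypopnea**: maximal runs with |flow| ≤ 50% of baseline *but above the
  apnea cut* (so cessations score once, as apneas) lasting ≥ 10 s, plus
  either an SpO2 drop ≥ 3% — measured from the median of the 30 s before
  the event to the minimum within the event and 30 s after it, allowing
  for circulatory desaturation lag — or an arousal inside the event.
* **Indices**: AHI = events/hour; supine and REM AHI divide events tagged
  by the position/stage annotation at their start time by hours spent in
  the stratum. Severity: AHI < 5 Normal, < 16 Mild, ≤ 30 Moderate, else
  Severe. The grade table is integer-gapped between Mild (5–15) and
  Moderate (16–30); fractional values in (15, 16) grade Mild here, while
  the separate clinical-importance flag fires at AHI ≥ 15 regardless of
  grade. Event durations count run length × sample step with half-open
  [start, start + duration) intervals.

## Synthetic data

**Snore clips** model one sleeper's stereotyped snore: bursts at breathing
pace (default 0.35 /s) of a harmonic stack (default 8 partials, amplitude
1/k) on a fundamental in the 200–1000 Hz band (default 220 Hz — palatal
snoring; tongue-base snores sit near 1 kHz). Each burst has a sharp 40 ms
inspiratory attack with exponential decay (time constant 0.35 s), and each
partial's envelope lags the previous by a fixed 60 ms "flutter". Both
choices matter for fingerprinting and reflect real snore acoustics: the
sharp attack pins each partial's energy maximum to a well-defined
spectrogram frame (a smooth symmetric envelope leaves the peak frame at
the mercy of noise), and the stagger spreads a burst's landmarks over
several frames so anchor-target pairs exist within the Δt ≥ 1 zone. The
seed drives only breath noise (−20 dB), per-burst loudness (±10%) and
partial phases — the signature itself is a function of the parameters, so
independently seeded clips from one signature match in the fingerprint
domain, which is exactly the premise of template-based snore detection.
Burst-spacing jitter defaults to 0 for the same reason and is available
for robustness experiments.

**Non-snore distractors**: white noise, a 100→4,000 Hz linear chirp, an
inharmonic tone cluster above the snore band, and a speech-like source —
a 120 Hz pulse train through two formant resonators that re-draw their
centre frequencies every 80 ms, giving constellation statistics unlike the
stationary harmonic stacks of snores.

**Degradations**: additive Gaussian noise scaled to an exact target SNR in
dB, amplitude clipping at a ceiling, and a resample round trip through a
lower rate.

**Synthetic nights** plant `round(target_ahi × hours)` events, alternating
apnea/hypopnea, in evenly spaced slots with ≥ 60 s clearance (placement
jittered within slots; infeasible combinations raise). Apneas zero the
flow; hypopneas set it to 40% of baseline — inside the scoring window of
(10%, 50%]. Each apnea, and ~70% of hypopneas, gets a desaturation of
3.5–6% ramping to a nadir 5 s after the event and recovering by +20 s; the
remaining hypopneas get a mid-event arousal instead, exercising the "or"
criterion. Heart rate dips 15 bpm during events and rebounds +20 bpm for
10 s after — magnitudes invented for test realism, not physiological
claims. Position is a supine block covering `supine_fraction` of the night
from its 30% mark; REM is a terminal block of `rem_fraction` (REM clusters
late in real nights). Snore episodes precede events with the configured
coupling probability. Default trace noise (flow SD 0.02, SpO2 SD 0.1%,
HR SD 2 bpm, `noise_scale` to scale or disable) is small against every
scoring margin, so recovery is exact at zero noise by construction and
typically exact at defaults.

**What passing synthetic tests does not show**: the generators contain no
room acoustics, bed-partner sounds, position-dependent spectral change,
central-vs-obstructive event morphology, or between-sleeper variation
beyond the fundamental frequency; benchmark numbers therefore measure the
pipeline's self-consistency and noise robustness under these stated
conditions, not clinical accuracy on recorded patients.

## Benchmark protocol

20 snore signatures with fundamentals evenly spaced over 210–990 Hz (seeds
100–119) and 8 labelled distractors (two per kind, distinct durations so
structurally seed-invariant kinds do not duplicate) form the template
database. Queries are 100 freshly seeded 3.4 s snore clips drawn from the
same signature population and 100 fresh distractors, every query degraded
with additive noise at 10 dB SNR, classified at the default 5-hit
threshold. All clip seeds derive from the single benchmark seed. Problem
sizes (20 templates, 200 queries, 3.4 s clips) keep a full run under ten
seconds while leaving each class ~100 decisions wide.

## Numerical and degenerate-input choices

* Silence fingerprints to an empty hash list (no strict maxima exist) and
  classifies as non-snore with score 0; matching against an empty database
  is an error, as is a stream shorter than one analysis window.
* Bisection-based boundary checks (acceptance script) report the *scored*
  quantity at the behavioural boundary — e.g. the duration of the shortest
  detected apnea — so sampling-grid quantisation does not smear the rule's
  constant.
* Frame/bin indices are 0-based throughout; intervals half-open.
* Config files are YAML mirrors of the dataclass defaults; unknown keys
  are rejected loudly.

## Known limitations

Fingerprint matching requires enrolled templates of the target snore
signature; it does not generalise to unseen snorers by design. The PSG
layer scores only apneas and hypopneas (no RERA, no central/obstructive
typing, no EEG staging). The stimulus controller models timing, not
actuation hardware or perceived intensity; `intensity_level` is carried as
metadata only.
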