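# snorefp

Snore-sound detection by audio fingerprinting, closed-loop tactile alerting,
and apnea/hypopnea scoring — a software model of a wearable anti-snoring
device, exercisable end to end on synthetic audio and synthetic
polysomnography (PSG) traces.

## Who this is for

Researchers and engineers prototyping acoustic sleep-monitoring pipelines:
the package provides a complete, deterministic, dependency-light testbed —
signal in, decision out, stimulus schedule out, AHI report out — without any
patient data. All inputs are generated by the built-in simulators.

## What it computes

**Snore detection (Shazam-style landmark fingerprinting).** A clip is
reduced to a constellation of spectrogram peaks: cells of the short-time
Fourier magnitude |X(t, f)| that strictly exceed every neighbour in a
±15 frame × ±15 bin region. Each peak (the *anchor*) is paired with up to 5
later peaks in a bounded target zone (Δt ∈ [1, 60] frames, |Δf| ≤ 120 bins),
and each pair is hashed with SHA-1 over `(f_anchor, f_target, Δt)`,
truncated to 80 bits. Matching scores a candidate track by the mode of the
offset histogram `t_db − t_query` over token hits — a genuine match piles
hits on one offset, chance collisions scatter. A clip is declared a snore
when its best snore-template score clears a hit threshold (default 5) and
beats every non-snore template. Audio is canonicalised to mono 44,100 Hz
(the full-audio-band Nyquist rate) before analysis.

**Closed-loop alerting.** A detection triggers the tactile stimulus
schedule: three 3 s vibration bursts with 1 s gaps — 11 s end to end, 9 s
actuator-on. The schedule aborts the moment snoring stops and re-arms when
it recurs. Independently, a heart-rate reading outside the normal
[40, 120] bpm band raises a rapid-pulse alarm (the bounds themselves do not
alert).

**PSG scoring.** From airflow/SpO2/arousal traces: an *apnea* is a ≥ 10 s
airflow cut (flow ≤ 10% of a rolling-median baseline); a *hypopnea* is a
≥ 10 s reduction of ≥ 50% backed by a ≥ 3% SpO2 desaturation or an arousal.
AHI = (apneas + hypopneas) / hours of sleep, stratified by supine position
and REM stage; severity grades Normal (< 5), Mild (5–15), Moderate (16–30),
Severe (> 30), with AHI ≥ 15 flagged clinically important.

**Synthetic data.** `snorefp.synthetic_data` generates snore clips
(harmonic burst trains with fundamentals in the 200–1000 Hz snore band),
four kinds of non-snore distractors, controlled degradations (target-SNR
noise, clipping, resample round trips), and whole synthetic nights with
planted respiratory events, coupled desaturations, heart-rate dips and
rebounds, position/stage annotations and snore-episode schedules.

## Worked example

```python
from snorefp.synthetic_data import SnoreClipParams, gen_snore_clip, \
    gen_nonsnore_clip, degrade
from snorefp.fingerprint import fingerprint_signal
from snorefp.matcher import FingerprintDB, index_track
from snorefp.detector import classify_clip
from snorefp.alert_controller import build_schedule

db = FingerprintDB()
for i in range(5):                       # enrol 5 snore templates
    template = gen_snore_clip(SnoreClipParams(seed=100 + i))
    index_track(db, f"snore_{i}", "snore", fingerprint_signal(template))

clip = gen_snore_clip(SnoreClipParams(seed=1, duration=3.4))
noisy = degrade(clip, "additive_noise", level=10.0, seed=7)   # 10 dB SNR
print(classify_clip(db, noisy))
print(classify_clip(db, gen_nonsnore_clip("white_noise", 3.4, seed=7)))
print(build_schedule(trigger_time=0.0))
```

prints

```
SnoreDecision(is_snore=True, score=35, matched_track='snore_0')
SnoreDecision(is_snore=False, score=0, matched_track=None)
[(0.0, 3.0), (4.0, 7.0), (8.0, 11.0)]
```

The freshly seeded snore clip, even under 10 dB additive noise, lands 35
offset-aligned hash hits on a template of the same snore signature — far
above the 5-hit threshold — while white noise lands none. The triggered
stimulus runs bursts over [0, 3), [4, 7) and [8, 11) seconds.

The same flows are available from the shell:

```sh
snorefp simulate clip --kind snore --seed 1 --out clip.wav
snorefp index --db db.json --label snore clip.wav
snorefp detect --db db.json stream.wav --out events.jsonl
snorefp alert-sim --events events.jsonl --hr hr.csv --out actuation.csv
snorefp simulate night --seed 11 --outdir night/
snorefp score --airflow night/airflow.csv --spo2 night/spo2.csv \
    --arousals night/arousals.csv --hours 6 --out report.json
snorefp benchmark --n 100 --seed 42 --out bench.json
```

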