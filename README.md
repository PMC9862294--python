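# slowave

Detection and cohort analysis of **paroxysmal slow-wave events (PSWEs)** in
resting-state EEG, plus a synthetic-EEG generator with planted ground truth so
the whole pipeline is testable without patient data.

The analysis chain:

1. **preprocess** — 1–95 Hz FIR band-pass and 45–55 Hz band-stop
   (Hamming-windowed, zero-phase forward–backward), input-driven bad-channel
   exclusion, average re-referencing over the EEG channels, EOG removal.
2. **regions** — spatial averaging of 10-10 channels into 9 scalp areas
   (right/left/central × frontal/tempo-parietal/occipital). The default
   60-channel montage ships as an editable TSV (`slowave/data/montage_1010_60.tsv`)
   and can be overridden.
3. **spectral** — sliding-window FFT spectra (2 s window, 1 s step), the
   **median power frequency** (MPF: half-power crossing over 1–45 Hz with
   linear interpolation), and relative δ/θ/α/β band powers (1–5, 5–8, 8–12,
   12–20 Hz over a 1–45 Hz total band).
4. **events** — a PSWE is a maximal run of windows with MPF **< 6 Hz**
   spanning **≥ 5 s** (m consecutive overlapping windows span m+1 s).
   Metrics: events/minute, percent time in a PSWE state, and a 2–8 Hz
   threshold sweep.
5. **stats** — per-subject pipeline driver, Spearman correlations (e.g.
   event count vs. a disease-duration covariate), and per-area
   Kruskal–Wallis group comparisons with unadjusted pairwise rank-sum
   follow-ups.
6. **synth** — 1/f-background + alpha-rhythm EEG with tapered sinusoidal
   slow bursts planted per channel, and Poisson-process cohorts whose event
   rate can depend on a covariate. Every planted event is logged, so
   detector sensitivity/specificity are measurable exactly.

EDF/EDF+ I/O is provided by a small built-in codec (`slowave.edfio`).

A note on average referencing: it mixes a spatially confined slow event into
every other channel (sign-inverted), and MPF is scale-invariant, so localized
synthetic events surface in all areas downstream of re-referencing. When
validating against planted per-region truth, disable that stage
(`PipelineConfig(rereference=False)`).

## CLI

```sh
# simulate a synthetic cohort (EDFs + subjects.csv + truth_events.csv)
slowave simulate config.yaml outdir/

# filter / re-reference / drop EOG for one recording
slowave preprocess in.edf clean.edf --bandpass 1 95 --bandstop 45 55

# detect PSWEs in one recording (add --sweep for the 2-8 Hz threshold sweep)
slowave detect clean.edf results/ --threshold 6 --min-duration 5 --sweep

# full cohort analysis: metrics, events, group tests, manifest
slowave analyze edf_dir/ metadata.csv results/ --config pipeline.yaml
```

`simulate` reads a YAML file with `synth:` (channels, duration, sampling
rate, spectral exponent, alpha) and `cohort:` (groups, sizes, event rate,
covariate slope, event duration/frequency ranges, seed) sections. `analyze`
accepts a `pipeline:` section overriding any stage parameter; defaults match
the published protocol (250 Hz, 240 s, 1–95 Hz, 45–55 Hz, 2 s/1 s windows,
6 Hz threshold, 5 s minimum, 2–8 Hz sweep).

## Library example

```python
import slowave as sw

rec = sw.generate_background(sw.SynthSpec(seed=1))
montage = sw.default_montage()
rec = sw.plant_slow_event(rec, sw.PlantedEvent(
    rec.subject_id, tuple(montage.labels_in(5)),
    start_s=100, duration_s=10, dominant_freq=3, amplitude_ratio=5))

metrics = sw.run_subject_pipeline(rec, sw.PipelineConfig(rereference=False))
print(metrics.per_area)
```

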