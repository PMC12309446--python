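# eegqc

Automated quality control for field-acquired resting-state EEG.

Large-scale EEG programs run by nonspecialist field teams — portable
16-channel gear, recordings in offices, schools and open air — live or
die by daily, automated data-quality feedback. `eegqc` implements the
two detector families such programs use to quantify signal quality,
plus everything around them:

* **FASTER-style detection** — per-channel statistics (mean pairwise
  correlation, variance, Hurst exponent, 48–62 Hz powerline band
  power) and per-epoch statistics (amplitude range, variance,
  deviation parameter) are standardized into Z-scores across channels
  or epochs; entries with |Z| > 3 are flagged.
* **PREP-style detection** — robust statistics: the robust SD is
  IQR × 0.7413 (the factor that makes an interquartile range agree
  with the SD under Gaussianity), the robust Z is
  (value − median)/robust SD, threshold 5. Channel criteria: flat/NaN
  signals (< 1×10⁻¹⁵ µV), robust amplitude, windowed correlation
  (best |r| < 0.4 in > 1 % of 2 s windows), high/low-frequency
  noisiness after a 50 Hz FIR split. An epoch-level extension
  standardizes each channel's per-epoch median and robust SD across
  epochs and flags epochs whose max |robust Z| over channels exceeds 5.
* **Spectral features** — Welch PSD (Hann, 2 s window, 50 % overlap)
  and the peak alpha frequency: the argmax bin within 7–12 Hz of the
  eyes-closed spectrum.
* **Cohort statistics** — percentage of bad channels/epochs per
  recording, mean ± SEM per group, empirical CDFs, Welch t tests
  between subgroups, and an averaged-p bootstrap for comparing a large
  field cohort against a small benchmark (subsample to the benchmark
  size, t-test, repeat, average the p values).
* **Daily dashboard** — the report a field supervisor reads each
  morning: recordings, nonstandard/missing electrodes and quality
  percentages, on-date and year-to-date, overall / per condition /
  per team / per device.
* **Synthetic EEG generator** — seeded, ground-truth-labelled
  3-minute 16-channel recordings (1/f background mixed from shared
  pink-noise sources, posterior-weighted alpha, optional mains
  contamination, injectable flat/noisy/uncorrelated channels, burst
  epochs and eyeblinks), so the whole pipeline is testable without
  field data.

Recordings are handled as channels × samples matrices in microvolts
(16 channels of the 10–20 system at 256 Hz in the default protocol),
read from EDF or plain CSV with a JSON session sidecar. All detection
runs on 0.5 Hz high-passed data cut into 2 s epochs.

## Worked example

```python
from eegqc import (highpass, epoch, prep_bad_channels, faster_bad_epochs,
                   percent_bad, peak_alpha_frequency)
from eegqc.simulate import SyntheticSpec, ArtifactSpec, generate_recording

spec = SyntheticSpec(duration_s=60.0, seed=8,
                     artifacts=(ArtifactSpec("flat_channel", channel=3),))
rec, truth = generate_recording(spec)

filtered = highpass(rec, 0.5)
channels = prep_bad_channels(filtered)
epochs = faster_bad_epochs(epoch(filtered, 2.0))

print(percent_bad(channels))              # 6.25  (1 of 16 channels)
print(percent_bad(epochs))                # 0.0   (no epoch artifacts injected)
print(peak_alpha_frequency(rec).mean_paf) # 10.0  (the generator's alpha peak, Hz)
```

`percent_bad` returns 100 × flagged/total, so a single bad electrode on
a 16-channel montage reads 6.25 % (on a 64-channel lab montage the same
fault would read 1.6 %). The `examples/` directory has one narrative
script per capability (detection, peak alpha, dashboard, group
comparison); each prints its numbers with a note on what they mean.

A thin CLI covers the field workflow:

```bash
eegqc simulate --seed 3 --n 12 --out recordings/
eegqc run --in recordings/ --method both --out summaries/
eegqc dashboard --in summaries/ --date 2024-02-15 --method faster
```

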