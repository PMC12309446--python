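"""Extract the peak alpha frequency (PAF) from an eyes-closed recording.

The PAF is the frequency of maximal Welch power inside 7-12 Hz
(2 s window, 50% overlap, so a 0.5 Hz grid).  Here the generator
injects a 9.5 Hz posterior alpha rhythm and the pipeline recovers it.
"""

from dataclasses import replace

from eegqc import peak_alpha_frequency
from eegqc.simulate import SyntheticSpec, generate_recording

spec = SyntheticSpec(duration_s=180.0, seed=21)
spec = replace(spec, alpha=replace(spec.alpha, peak_hz=9.5))
rec, truth = generate_recording(spec)

pk = peak_alpha_frequency(rec)
print(f"injected alpha peak: {truth.true_paf} Hz")
print(f"per-channel peaks:   {pk.per_channel}")
print(f"mean PAF:            {pk.mean_paf} Hz")
print(f"peak of mean PSD:    {pk.peak_of_mean_spectrum} Hz")

# Per-channel peaks are picked first and then averaged (mean_paf); the
# peak of the channel-averaged spectrum is reported separately.  Both
# conventions land on the injected 9.5 Hz here because the alpha
# oscillation sits exactly on the 0.5 Hz analysis grid.
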