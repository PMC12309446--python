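"""Flag bad channels and bad epochs in one recording with FASTER and PREP.

Builds a synthetic 60 s, 16-channel recording with two injected
problems — a flat electrode and a burst of movement artifact — then
runs both detector families and prints what each criterion flagged.
"""

import numpy as np

from eegqc import (
    epoch,
    faster_bad_channels,
    faster_bad_epochs,
    highpass,
    percent_bad,
    prep_bad_channels,
    prep_bad_epochs,
)
from eegqc.simulate import ArtifactSpec, SyntheticSpec, generate_recording

spec = SyntheticSpec(
    duration_s=60.0,
    seed=8,
    artifacts=(
        ArtifactSpec("flat_channel", channel=3),
        ArtifactSpec("burst_epoch", channel=10, epochs=(12,)),
    ),
)
rec, truth = generate_recording(spec)
print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print(f"injected:  bad channels {truth.bad_channels}, bad epochs {truth.bad_epochs}\n")

filtered = highpass(rec, 0.5)           # 0.5 Hz high-pass before any detection
epochs = epoch(filtered, 2.0)           # 2 s non-overlapping epochs

for name, ch_res, ep_res in [
    ("FASTER", faster_bad_channels(filtered), faster_bad_epochs(epochs)),
    ("PREP", prep_bad_channels(filtered), prep_bad_epochs(epochs)),
]:
    print(f"{name}: {percent_bad(ch_res):.2f}% bad channels, "
          f"{percent_bad(ep_res):.2f}% bad epochs")
    for crit, flags in ch_res.per_criterion.items():
        if flags.any():
            print(f"  channel criterion {crit!r} flagged {list(np.flatnonzero(flags))}")
    for crit, flags in ep_res.per_criterion.items():
        if flags.any():
            print(f"  epoch criterion {crit!r} flagged {list(np.flatnonzero(flags))}")

# The flat electrode is caught by PREP's absolute flatness test and by
# FASTER's correlation and powerline Z-scores; the burst epoch is caught
# by the FASTER variance Z and by both PREP robust-Z components.  The
# burst is also large enough to make its host channel an outlier in
# whole-channel variance/correlation, so both methods flag it too:
# 2 of 16 channels = 12.5%.  One flagged channel of 16 would be 6.25%.
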