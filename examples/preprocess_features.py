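"""Preprocess a synthetic recording into per-movement RMS feature vectors.

The chain is calibrate -> DC removal -> 20-450 Hz band-pass -> 60 Hz notch ->
cue-aligned windowing -> per-channel RMS. One 8-value feature vector per
movement execution is the classifier input.
"""

import pandas as pd

from myoanfis import featurize, generate_session

recording, schedule = generate_session(seed=42)
features = featurize(recording, schedule)

table = pd.DataFrame(
    [dict(zip(fv.channel_ids, fv.rms.round(4)), movement=fv.label) for fv in features]
)
print(table.head(7).to_string(index=False))
print(f"\n{len(features)} feature vectors, {len(features[0].rms)} channels each")
# Each row should peak on the movement's primary channel (e.g. C0/biceps for
# forearm flexion); shared-muscle channels of the forearm flexion/rotation
# pair show intermediate crosstalk amplitudes.
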