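"""Generate one synthetic sEMG acquisition session and inspect its layout.

A session is 5 repetitions of each of 7 arm/hand movements in random order,
each an 8.3 s cue animation followed by a 3 s rest, recorded on 8 channels
at 1 kHz.
"""

import collections

from myoanfis import Protocol, generate_session

recording, schedule = generate_session(seed=42)
protocol = Protocol()

print(f"channels:       {recording.channel_ids}")
print(f"sample rate:    {recording.sample_rate:g} Hz")
print(f"duration:       {recording.duration:.1f} s "
      f"(closed form {protocol.session_duration():.1f} s)")
print(f"movement cues:  {len(schedule)}")
print("repetitions per movement:")
for movement, count in sorted(collections.Counter(schedule['movement_label']).items()):
    print(f"  {movement:<18} {count}")
print("\nfirst three cues (onset seconds -> movement):")
print(schedule.head(3).to_string(index=False))
# Each onset marks the start of an animation; the muscle activity it elicits
# peaks on that movement's primary channel during the 1.3 s hold phase.
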