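"""Build the three kinds of figure-ground stimulus and render one to WAV.

Constructs a detection pair (figure-present / figure-absent), a 2I-2AFC
discrimination pair with a figure gap and a ground gap, and prints their
geometry.  The rendered WAV lands in a temporary directory.
"""

import tempfile
from pathlib import Path

import numpy as np

from figground import (
    assemble_detection_pair,
    assemble_discrimination_pair,
    load_fixture_track,
    render_waveform,
    write_sidecar,
    write_wav,
)

rng = np.random.default_rng(0)

present, absent = assemble_detection_pair(rng)
print("detection stimulus:")
print(f"  {present.n_chords} chords x {present.chord_ms:.0f} ms = {present.duration_ms:.0f} ms")
print(f"  figure: {present.figure_n_chords} chords starting at chord "
      f"{present.figure_onset_chord + 1} (1-based)")
print(f"  tone-chord count present={present.tone_chord_count()} "
      f"absent={absent.tone_chord_count()}  (matched pairs conserve energy)")

track = load_fixture_track("synthetic_sentence_42bins.csv")
first, second = assemble_discrimination_pair(
    "coherent_roving", tmr_db=6.0, gap_interval=1, rng=rng, track=track
)
print("\ncoherent-roving discrimination pair (TMR = +6 dB):")
for i, s in enumerate((first, second), start=1):
    print(f"  interval {i}: {s.duration_ms:.0f} ms background, "
          f"{s.figure_n_chords}-chord figure, gap in {s.gap.location} "
          f"at chord {s.gap.onset_chord + 1}")

audio = render_waveform(present)
out = Path(tempfile.mkdtemp())
write_wav(audio, out / "detection_present.wav")
write_sidecar(present, out / "detection_present.json")
print(f"\nrendered {audio.samples.size} samples at {audio.sample_rate} Hz "
      f"({audio.duration_ms:.0f} ms) -> {out / 'detection_present.wav'}")
print("the JSON sidecar regenerates the audio bit-exactly")
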