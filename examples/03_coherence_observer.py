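"""Let the temporal-coherence observer 'listen' to figure-ground stimuli.

The observer maps tones into frequency channels, correlates channel
time-courses in a sliding window, and accumulates significantly positive
correlations as figure evidence.  Its discrimination accuracy rises with
the figure's level (TMR) and is well above chance when the figure is loud.
"""

import numpy as np

from figground import CoherenceObserver, assemble_detection_pair

observer = CoherenceObserver(decision_noise=1.0)
rng = np.random.default_rng(2)

print("figure evidence (peak of the coherence trace), 20 detection pairs:")
present_scores, absent_scores = [], []
for _ in range(20):
    present, absent = assemble_detection_pair(rng)
    present_scores.append(observer.coherence_score(present).max())
    absent_scores.append(observer.coherence_score(absent).max())
print(f"  figure present: {np.mean(present_scores):.2f}   "
      f"figure absent: {np.mean(absent_scores):.2f}")
print("  coherent figures light up the correlator; random decoys do not\n")

n = 40
print(f"2I-2AFC gap discrimination accuracy ({n} trials per TMR):")
for task in ("same_frequency", "coherent_roving", "complex_roving"):
    fn = observer.discrimination_trial_fn(task)
    accs = {tmr: np.mean([fn(tmr, rng) for _ in range(n)]) for tmr in (-10, 0, 20)}
    row = "  ".join(f"{tmr:+3d} dB: {acc:.2f}" for tmr, acc in accs.items())
    print(f"  {task:16s} {row}")
print("accuracy is ~0.5 (chance) when the figure is faint and rises with TMR")
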