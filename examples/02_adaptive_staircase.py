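"""Run the 1-up/1-down adaptive procedure with a psychometric observer.

Two interleaved runs start at +6 dB TMR, step 2 dB (0.5 dB after the 3rd
reversal) and stop after 10 reversals; the session threshold is the mean of
the two runs' medians of their last 6 reversals.  With a simulated observer
whose 50%-correct point is 0 dB, the session threshold lands near 0 dB.
"""

import numpy as np

from figground import PsychometricObserver, run_adaptive_session

observer = PsychometricObserver(mu=0.0, slope=1.0)  # 50% correct at 0 dB TMR
rng = np.random.default_rng(1)

session = run_adaptive_session(observer.trial_fn(), rng, task="same_frequency")
for name, run in (("run 1", session.run1), ("run 2", session.run2)):
    revs = ", ".join(f"{r:+.1f}" for r in run.reversal_tmrs)
    print(f"{name}: {len(run.trial_log)} trials, reversals at [{revs}] dB")
    print(f"        threshold (median of last 6 reversals) = {run.threshold:+.2f} dB")
print(f"session threshold = {session.threshold:+.2f} dB "
      f"(observer's true 50% point: {observer.mu:+.2f} dB)")

thresholds = [run_adaptive_session(observer.trial_fn(), rng).threshold
              for _ in range(100)]
print(f"mean over 100 sessions: {np.mean(thresholds):+.2f} dB "
      f"(s.d. {np.std(thresholds):.2f}) — the staircase recovers the 50% point")
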