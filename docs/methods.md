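# Methods

This note documents the models, parameters and design choices behind
`figground`: what each component computes, which settings matter, what the
synthetic data emulate, and where the package's own judgement had to fill
gaps left open by the task descriptions it implements.

## Stimuli

A stimulus is a grid of 50-ms chords with zero inter-chord interval; every
tone is a 50-ms sinusoid (longer tones are sequences of per-chord tones)
gated by 10-ms raised-cosine ramps.  The ground draws, independently for
each chord, a uniform 5–15 tones without replacement from a geometric
frequency grid `f = 179 · 2^(k/24) Hz, k = 0…128` (129 members, top member
7216.8 Hz ≤ 7246 Hz).  Detection stimuli are 40 chords (2000 ms) with a
6-chord (300-ms) figure starting on chord 15–20 (1-based; internally
0-based onsets 14–19).  Discrimination stimuli are 70 chords (3500 ms);
the same-frequency figure is exactly 42 chords, roving figures inherit the
formant track's 34–50 bins.

**ERB separation.**  Same-frequency figure components are rejection-sampled
from the grid until all pairwise ERB-number differences exceed 1 cam, with
the Glasberg–Moore scale `E(f) = 21.4·log10(4.37 f/1000 + 1)`.  The scale
choice is ours: the separation rule names ERBs without a formula, and
Glasberg–Moore is the field default.

**Roving construction.**  The coherent-roving components are F1 scaled by
the sentence-average F2/F1 and F3/F2 relationships.  We implement "average
difference" between formants as the mean of bin-wise frequency *ratios*:
multiplying F1 by a mean ratio is dimensionally coherent and keeps the
three components at constant ratios (equal log-frequency motion), which is
what "changing at the same rate" means on a musical axis.  A
`linear_offset` variant (mean Hz difference, added) is available for
comparison.  Complex-roving components are the F1/F2/F3 trajectories
verbatim.  Roving frequencies are not snapped to the 1/24-octave grid;
same-frequency components are grid members.

**Gaps.**  The figure gap removes all 3 figure components for 6 consecutive
chords, with onset uniform over positions leaving at least one figure chord
on each side (an edge gap would merely shorten the figure).  The ground gap
removes 3 randomly chosen ground tones at each of 6 consecutive chords,
with the window constrained to overlap the figure's span so that both
intervals contain a perturbation while the figure is audible.  Both
constraints are our choices on points the task description leaves open, as
is the uniform placement of the discrimination figure within the 70-chord
background.  In the detection task, figure-absent stimuli carry 3 decoy
components with the figure's onset and duration whose frequencies are
redrawn independently at every chord — held constant they would *be* a
figure — so matched present/absent stimuli have identical tone counts and,
at equal amplitudes, identical energy.

**Levels.**  TMR is defined per tone: a figure (or decoy) tone's amplitude
is `10^(TMR/20)` times a ground tone's.  The reference convention is ours;
the detection task runs at TMR = 0 dB (fixed stimulus parameters).
Rendered audio is peak-normalised to −1 dBFS; absolute presentation level
is out of scope.

## Formant tracks

Tracks are inputs (CSV: `bin,f1_hz,f2_hz,f3_hz`, 50-ms bins); extraction
from recordings is out of scope.  The bundled fixtures and the runtime
generator are *synthetic*: bounded smooth log-frequency walks (F1 300–900,
F2 900–2300, F3 2300–3200 Hz, smoothed over ~5 bins) with 34–50 bins.
They emulate the slow, ordered motion of vowel formants but none of the
phonetic structure of real sentences — consonantal discontinuities,
formant mergers, pitch-correlated amplitude.  Results obtained with them
demonstrate that the machinery behaves correctly, not that any particular
threshold matches human data.

## Adaptive procedure

1-up/1-down on TMR: start +6 dB, step 2 dB, step 0.5 dB once 3 reversals
have occurred, stop at exactly 10 reversals.  A reversal is recorded at the
TMR of the trial on which the direction changed (the track's extremum), and
every direction change counts, including the first — standard practice on
points the rule statement leaves open.  The run threshold is the median of
the last 6 reversals; a session interleaves two runs (strict alternation by
default, randomised optionally) and averages their thresholds.  A guard
aborts runs that exceed 200 trials without finishing, which only
pathological simulated observers (e.g. "always correct") can trigger — such
observers never change direction and so never finish by reversal count.
Note that a 1-up/1-down rule targets the 50%-correct point, which for a
2AFC task is chance; the procedure is implemented exactly as specified for
the battery, and the simulated-observer validation therefore checks
convergence to the 50% point of the observer's psychometric function, not
to a particular human threshold.

The detection session is 50 trials, exactly half figure-present, shuffled;
sensitivity is d′ = z(H) − z(F) with rates clipped to
[1/(2N), 1 − 1/(2N)] per side so perfect scores stay finite (25/25 hits
with 0/25 false alarms gives d′ ≈ 4.11).

## Simulated observers

Neither observer is fit to human data; they exist to exercise and validate
the task machinery.

**Psychometric observer.**  p(correct) = guess + (1 − guess − lapse) ·
logistic(slope · (TMR − mu)).  Used to verify that the staircase recovers
mu: over 200 sessions the mean session threshold lies within ±1 dB of mu
for mu ∈ {−10, 0, +6} dB.

**Temporal-coherence observer.**  Operates on the symbolic chord grid, not
rendered audio — it demonstrates the grouping mechanism, not the auditory
periphery.  Tones are mapped to their nearest channel of the stimulus
frequency grid; within each sliding 10-chord window the observer takes the
12 most active channels (by mean activation) whose time-courses vary,
Pearson-correlates them pairwise, and sums the correlations exceeding a
one-sided p < 0.05 threshold.  The trace peaks where coherent events drive
several channels together: figure onset and offset, and the edges of a
figure gap.  The salience bottleneck (top-12 channels) is what confers TMR
sensitivity — Pearson correlation is amplitude-invariant, but a faint
figure never reaches the correlator because denser ground channels
out-compete it.  The 2AFC decision compares the total evidence mass of the
two intervals (plus Gaussian internal noise): the figure-gap interval
carries two extra coherent transitions (all figure channels switching off
and on together), whereas the ground gap removes tones from unrelated
channels and adds no coherent structure.  We also explored a decision based
on a transient *dip* in the evidence trace; with a correlation-based trace
the gap manifests as extra transition coherence rather than a dip (the
within-figure trace is flat because constant channels have no variance to
correlate), so the evidence-mass rule is the faithful decision statistic
for this trace and is the one implemented.  The observer's accuracy is
validated directionally only: chance at low TMR, monotone non-decreasing in
TMR up to Monte-Carlo noise, and well above chance at +20 dB for all three
figure classes.

## Statistics

Pearson correlations with two-tailed t-test p-values and 95% Fisher-z
confidence intervals, `tanh(atanh r ± 1.96/√(n−3))`; these reproduce the
battery's printed intervals for (r = 0.39, n = 97) → (0.21, 0.55) and
(r = 0.32, n = 97) → (0.13, 0.49) exactly at two decimals.  Variance
explained is reported as the rounded integer percentage of r².  The noise
ceiling is the test–retest correlation between the two speech blocks with
its CI band and the implied explainable-variance bound r².  Hierarchical
regression adds predictor blocks to an OLS fit and tests each r² change
with the partial F on (q, n − p − 1) degrees of freedom; exactly collinear
additions yield a zero change with a warning rather than an error.
Forward-stepwise selection enters, at each round, the candidate with the
smallest change-p below 0.05 (threshold configurable; no removal step —
pure forward selection, the simplest reading of a "stepwise" hierarchical
procedure).  Partial correlations residualise both variables on the
covariates (df = n − k − 2; CI at effective n − k); a numerically zero
residual returns r = 0 with a warning flag instead of NaN.  Independent
correlations are compared with the Fisher-z statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, which reproduces the
printed z = 1.05, p = 0.29 for 0.39 (n = 97) vs 0.25 (n = 89); when the
analysis applies it to a subsample-vs-full comparison the samples overlap,
so the test is approximate there — a caveat inherited from the analysis it
mirrors.  Audiogram screening excludes a participant whose six-frequency
(0.25–8 kHz) average reaches 20 dB HL in either ear and computes the
high-frequency average over the four 4/8-kHz thresholds.  P-values are
two-tailed and uncorrected throughout.

## Synthetic cohorts

The generator draws task-level scores from a multivariate normal whose
correlation matrix defaults to the battery's reported values (speech ×
audiogram 0.39, × same-frequency 0.32, × coherent roving 0.28, × complex
roving 0.08, × detection d′ −0.19, × age 0.43; audiogram × age 0.78;
figure-ground × age 0.23).  Unreported cells are filled by a
single-common-factor product rule through the speech score,
`r(i,j) = r(i,speech)·r(j,speech)`, and the matrix is repaired to the
nearest positive semi-definite correlation matrix by eigenvalue clipping —
an explicit modelling assumption, not an empirical claim.  Run pairs are
built *antithetically* around the task score A: `r1 = A + d, r2 = A − d`
with Var(d) chosen so that corr(r1, r2) equals the requested run
reliability.  This makes the run average equal A exactly, so the task-level
correlation matrix of a large cohort converges to the generating matrix
(maximum deviation ≤ 0.05 at n = 5000) *and* the run pairs hit their
reliability targets simultaneously — including a reliability of 0 for the
complex-roving task, whose near-zero between-run correlation is the
reported motivation for treating it as unreliable.  (A conventional
latent-plus-independent-noise construction cannot satisfy both properties
at once: averaging noisy runs attenuates the between-task correlations.)
Speech blocks use the reported test–retest value 0.69 as their
reliability; same-frequency (0.60) and coherent-roving (0.55) reliabilities
are artifact choices in the plausible range for adaptive thresholds.
Means and SDs are artifact choices too (speech −6 ± 1.75 dB TMR, spanning
the reported ≈7-dB range; same-frequency −2 ± 3 dB; roving tasks ≈ +18 ±
4 dB, reflecting the ~20-dB deficit for roving figures; age 32 ± 11 years,
a normal approximation that ignores the skew of real recruitment).
Per-ear audiograms are synthesised around the high-frequency average, with
the four 4/8-kHz values constrained to average to it exactly.

## Problem sizes and numerics

The test suite validates the staircase against a literal step-by-step
reference over all 2¹² response sequences, observer recovery over 200
sessions, coherence accuracy at 60 trials per TMR level, cohort recovery
at n = 5000, and the stimulus invariants (tone-count conservation, ERB
separation, grid membership) over 1000 seeds each; these sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the default run to a few minutes.  All randomness flows
through `numpy.random.Generator` seeds; identical seeds give bit-identical
stimuli, trial logs and rendered audio.  Degenerate inputs (zero-variance
columns, constant difference scores, non-finite values) raise explicit
errors rather than propagating NaNs.

## Known limitations

- The coherence observer has no peripheral model (no filter bandwidths,
  compression or adaptation); its thresholds are not comparable to human
  ones in absolute terms, and its same-frequency advantage over roving
  figures is qualitative only.
- Synthetic formant tracks are statistical stand-ins for sentence formants.
- The cohort generator models scores, not trial-level behaviour; it cannot
  exhibit learning, fatigue or run-order effects.
- The product-rule completion of unreported correlations is a guess; users
  exploring predictor intercorrelations should supply their own matrix.
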