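# Methods

This note documents the models and procedures implemented in `semgrip`, the
parameters that matter, and the design choices made where the design was
genuinely open.  Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is quoted from elsewhere.

## The recognition problem

Twenty-five classes: eight grip families (hammer, tip pinch, 3-jaw chuck,
key, scissors, door knob, jar lid, ball), each with a base grip and one to
three follow-on movements (raise/lower, supination/pronation turns, squeeze,
open/close), plus neutral/rest (NR).  Data come as eight-channel sEMG at
2 kHz from forearm/biceps muscles and six hand-accelerometer channels at
148.1 Hz, collected in eight two-minute runs of twelve scripted ten-second
repetitions (repetitions start at seconds 5, 15, …, 115; the first five
seconds of every run are rest).  Two script slots per repetition are
*hybrid* (activity or rest, performed inconsistently); they are represented
explicitly and resolved to the first-named activity by default.

## Pipeline

### MAV features

`g_j(kT) = 1/(2N) Σ_{i=−N+1..N} |f_j(kT + iT1)|` with `T = 50 ms`,
`T1 = 0.5 ms`, `N = 100`.  Window indices run `k = 1..⌊duration/T⌋`;
boundary windows are truncated to the available samples and averaged over
the actual count, so a 120 s run yields exactly 2400 instances.  The
implementation is a cumulative-sum; tests pin it to a per-window brute-force
oracle at 1e−12.  A zero-phase Butterworth 20–450 Hz band-pass is available
for raw hardware input and disabled by default (simulated and
hardware-exported signals are already band-limited).

### Channel statistics

Instance-level baselines z-score each channel with *training* mean and
standard deviation (population convention, divide-by-n; a fixed documented
choice).  Constant channels raise an error rather than dividing by zero.
SAX codebooks are fitted on unnormalised MAVs — per-channel quantiles make
z-scoring redundant.

### ACC summary and labelling

The six hand-ACC channels are decimated to every 7th sample
(7/148.1 ≈ 47 ms, ≈ 21.1 steps/s — the decimation step is a reconstruction;
the exact windowing behind that rate is not derivable) and reduced to the
summed absolute successive difference; each value is stamped with the later
sample's time and matched to the nearest MAV instant (ties to the earlier;
the mismatch never exceeds 30 ms on the stated grids).  A step is *active*
when the statistic strictly exceeds twice its run median; active steps
within 150 ms merge into one event (the script gives no gap rule; 150 ms is
three decimated steps).  Movements start at the event nearest their
scheduled second; grips start at the *end* of the nearest event (the reach
toward the object ends when the grip is established).  Adjustments are
clamped to ±500 ms; with no event in range the scheduled time is used and a
warning logged.  A grip is sustained for up to three seconds or until the
next movement onset; movements last until the next onset (back-to-back
slots) or their scheduled end.  Everything else is NR.

NR retention: the run-start window [1 s, 4 s).  The 3 s window at 20
instances/s keeps 60 NR instances per run and 480 across the eight runs,
restoring class balance (unretained NR occupies gaps where the subject's
posture is unverifiable).  Segmentation cuts maximal same-label consecutive
runs, truncated to 40 instances; the repetition index is taken at the
segment midpoint so grips whose adjusted onset precedes the scheduled
second still count to their repetition.

### SAX symbolisation

Per-channel breakpoints are type-1 empirical quantiles at k/n (inverse
ECDF), k = 1..n−1; values equal to a breakpoint fall to the lower interval.
On training data every symbol is equally probable up to ties (tested within
binomial tolerance).  Alphabets of 2–26 render as letters A..; internally
words are integer rank vectors.  Distances: lexical
`d_l = Σ|Δrank|` (symmetric metric-like, used for nearest-word search) and
modified `D = Σ max(|Δrank|−1, 0)` (adjacent symbols cost nothing — two
values either side of a quantile cut may be arbitrarily close; `D` is
symmetric and non-negative but *not* a metric: distinct words can be at
distance zero).

### Affinity classifier

`A` counts words per class; `Ā` divides by class totals (every class must
occur in training, else its row cannot be normalised nor predicted — an
error); `Â` scales columns to unit vectors.  "Unit" is Euclidean by
default; the normalisation (here and for imputed rows) is switchable to L1.
Out-of-vocabulary words receive the normalised sum of the `Â` columns of
*all* vocabulary words at minimal `d_l`; imputed rows are cached for the
session and never written back into the trained model.  The windowed sum
uses `w + 1` rows (current plus `w` predecessors; early positions use the
truncated sum); argmax ties break to the lowest class index in catalogue
order.

In evaluation each activity segment is classified as its own stream: the
summation window does not cross segment boundaries.  Activity segments are
the unit the dataset is processed into, the window sweep extends to 40
(the maximum segment length), and a window that crossed boundaries would
accumulate a transition lag that *grows* with `w`, inverting the observed
benefit of context.  Word-level accuracy is reported.

### DTW classifier

Standard three-move DP (match/insert/delete, unweighted — no step
weighting is specified, so the simplest symmetric pattern is used) with
local cost `D` and a Sakoe–Chiba band `|i−j| ≤ r`, default `r = 5`.
Prefix evaluation compares the test prefix of length `p` with each training
segment's prefix of length `min(p, |train|)` — equal lengths, so the band
always admits the diagonal.  Because a DP cell depends only on the
subsequences before it, a single banded pass per training segment yields
every prefix distance on its diagonal; the engine vectorises this across
training segments and is pinned to an unbanded recursive oracle in tests.
1-NN with distance ties to the earliest training segment; K > 1 (majority,
ties to the nearest) and length-normalised or full-training-segment
comparison are available behind the config.

Segment-level reports score each segment at `min(15, length)` words: the
accuracy-by-wordcount curves of the default synthetic subjects flatten
near 15 words, and that flattening point is where one would operate the
classifier.  The full curve is always reported.  Note two properties of the
curve itself: at word counts above ~20 only long (grip) segments remain in
the average, and the `min(p, |train|)` rule lets short training segments'
distances stop accumulating, which can undercut long same-class matches at
large `p` — both visible as a dip beyond the flattening point.

### Evaluation schemes

*Leave-one-repetition-out*: fold k holds repetition k's segments from all
eight runs.  The 480 retained NR instances are split into twelve
consecutive 5-word chunks per run, one chunk per fold, keeping folds
disjoint while giving every fold rest data (≈ 5 % of each fold).  On the
DTW training side, a run's surviving NR chunks are re-merged into one rest
sequence (rest is quasi-stationary); without this, 5-word stubs saturate
the prefix-truncated distance and undercut every long segment.  Codebooks,
affinity matrices and channel statistics are rebuilt per fold from training
data only.

*Instance baselines*: decision tree, 1-NN (normalised Euclidean), random
forest (25 trees) and SVM (C = 5, RBF kernel) on z-scored instances under
stratified 10-fold cross-validation, via scikit-learn.  These are context
classifiers' foils, not contributions; their library internals are not
re-implemented.

Reports carry the pooled accuracy (trace of the summed confusion matrix
over the total — exactly recomputable from the matrix), per-fold accuracies
and their mean, and per-class recall.  Sweep tables aggregate multiple
synthetic subjects as [low, high] ranges per parameter cell.

## The synthetic subjects

The simulator emulates the statistical structure the classifiers rely on,
not motor-unit physiology.  Per subject:

* **Activations**: a (25 × 8) class-by-channel amplitude matrix.  Grips
  activate extensor digitorum / flexor digitorum superficialis / flexor
  carpi ulnaris (0.4–0.9 mV); movements add deltas on semantically chosen
  channels (raises load biceps + brachioradialis, pronation the pronator
  quadratus, …).  Raise/lower pairs share one delta draw — the same muscles
  act concentrically vs eccentrically — and differ only in envelope
  direction (ramps 0.6→1.3 vs 1.3→0.6 of the plateau).  NR sits at
  0.02–0.06 mV.
* **Carrier**: envelope × alternating ±1 at the sample rate, so |signal|
  equals the envelope and the MAV of a plateau recovers the activation in
  closed form (the oracle used in tests).  White sensor noise (0.03 mV) is
  added on top.
* **Reach transient**: the first 100 ms of every activity blends a
  class-agnostic "reach/settling" vector (80 % of the mean activation) into
  the class envelope — all motions start alike, which is why one-word
  prefixes are ambiguous for every method.
* **Amplitude scatter**: log-normal mean-one AR(1) processes at the MAV
  window scale (τ = 50 ms): a common-drive factor shared by all channels
  (σ ≈ 0.20–0.24) and per-channel factors (σ ≈ 0.20–0.25) — the
  window-to-window MAV estimator variability of real recordings.  A
  per-repetition log-normal gain (σ = 0.05–0.06) adds between-repetition
  variability.
* **Artifacts**: isolated per-channel contact spikes (3 % of
  instance-channels) and short common-mode adjustment bursts (8 % of
  instances), both large multiplicative factors confined to single 50 ms
  blocks.
* **ACC**: 300 ms raised-cosine transients on all six channels at movement
  onsets (1 g); grips get a half-amplitude transient ending at the onset;
  white noise 0.02 g.
* **Timing**: activity onsets jittered uniformly within ±250–300 ms
  (within a few hundred milliseconds of the script); the ground-truth track
  records jittered times and tiles [0, 120] s exactly.

Three default subjects differ in scatter and noise levels.  A
*well-separated* profile (larger movement deltas, minimal scatter/jitter,
no artifacts) supports parameter-recovery tests; a *quiet* profile (no
noise, no jitter) supports closed-form checks.

**What passing tests do and do not show.**  The generator produces the
structure under which context is informative: instance-ambiguous onsets,
voting-correctable scatter, order-separable raise/lower pairs.  On these
subjects the ordering DTW > affinity > instance baseline and the
rising-accuracy trends in the summation window and word count hold across
seeds, with magnitudes (≈ 95/90/87 %) in the range reported for comparable
real recordings.  Passing does not show that the methods reach any
particular accuracy on real sEMG: real recordings add nonstationarity
(fatigue, electrode drift), crosstalk, deep-muscle invisibility and
between-session variation that the simulator does not model.

## Numerical choices and degenerate inputs

* Quantile ties: boundary values to the lower interval; a constant channel
  yields equal breakpoints and encodes to rank 0.
* Argmax and nearest-neighbour ties break deterministically (lowest class
  index; earliest training segment).
* All randomness flows from integer seeds through `numpy` generators;
  per-run seeds derive as master + group index.
* Empty streams, missing channels, absent classes, too-short signals and
  degenerate channels raise errors naming the offending entity rather than
  propagating NaNs.

## Known limitations

* The affinity model cannot separate classes with identical word
  distributions (raise vs lower); its recall on those classes is low by
  construction — the motivation for the segment-shape classifier.
* The `min(p, |train|)` prefix rule makes distances across training
  segments of different lengths incomparable at large `p`; the curve dip
  beyond the flattening point is inherent to the rule.
* The simulator's ACC model is a stylised transient; onset detection
  robustness to realistic ACC clutter is untested.
* Hybrid script slots are generated as the first-named activity by default;
  the alternative (rest) is a profile switch, and labelling handles either
  through the sustain rules.
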