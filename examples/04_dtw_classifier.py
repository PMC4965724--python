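"""Classify whole activity segments with banded DTW 1-NN.

Each labelled activity (a word sequence of up to 40 instances) is compared
with every training segment under dynamic time warping with a Sakoe-Chiba
band of +-5 and the modified lexical distance as local cost.  The comparison
is repeated at growing prefix lengths, showing how quickly an activity can
be recognised as its words stream in.
"""

import semgrip as sg
from semgrip import evaluation as ev

data = ev.build_subject_data(sg.default_profiles()[0], seed=0)
folds = ev.make_repetition_folds(data.segments, data.nr_segments)

report, curve = ev.evaluate_dtw(folds, n=15)
print(f"leave-one-repetition-out DTW 1-NN: {report.fold_mean_accuracy:.1f} % "
      f"(segments scored at up to {ev.DEFAULT_SCORE_PREFIX} words)")
print("accuracy by word count (prefix length):")
for p in (1, 3, 5, 10, 15, 20):
    print(f"  {p:>2} words: {curve[p]:5.1f} %")
print("accuracy flattens out around 15 words (~0.75 s); early prefixes are "
      "ambiguous because every activity starts with a similar reach motion. "
      "Beyond 20 words only the long grip segments remain in the average.")
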