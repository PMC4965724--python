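"""Symbolise MAV instances as equal-probability SAX words.

Fits per-channel breakpoints so each of the n symbols is equally probable on
the training data, encodes every 8-channel instance as an 8-letter word, and
shows the two word distances: the plain lexical distance d_l (used for
nearest-word imputation) and the modified lexical distance D (the DTW local
cost), under which adjacent symbols cost nothing.
"""

import numpy as np

import semgrip as sg
from semgrip import sax

profile = sg.default_profiles()[0]
run = sg.generate_run(sg.make_schedule("key"), profile, seed=1)
mav = sg.compute_mav(run.as_bundle())

codebook = sax.fit_codebook(mav.values, n=5)
words = sax.encode(mav.values, codebook)
strings = sax.words_to_strings(words)
print("alphabet size 5; sample words around the first repetition:")
print("  rest   :", strings[40], strings[60])
print("  key grip:", strings[105], strings[115])

freq = np.bincount(words[:, 0], minlength=5) / len(words)
print("channel-1 symbol frequencies (should be ~0.2 each):",
      np.round(freq, 3).tolist())

a, b = sax.strings_to_words(["AAAAAAAA", "AACCBBEE"])
print("lexical distance d_l(AAAAAAAA, AACCBBEE)  =", sax.lexical_distance(a, b))
print("modified distance D(AAAAAAAA, AACCBBEE)   =", sax.modified_lexical_distance(a, b),
      " (per letter: 0 if equal, |rank diff| - 1)")
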