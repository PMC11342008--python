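"""Count lexicon categories in raw posts and normalise by post length.

Builds a few posts by hand, runs them through the shipped toy lexicon
(LIWC-dic dialect: exact words and prefix wildcards, with a category
hierarchy), and prints the per-period normalized frequencies.
"""

import datetime as dt

import trajlens as tl
from trajlens.features import build_feature_matrix, normalized_frequency
from trajlens.periods import PostRecord, default_grid

lex = tl.toy_lexicon()
posts = [
    PostRecord("u1", dt.date(2021, 4, 2), "I hate everything and I am angry"),
    PostRecord("u1", dt.date(2021, 5, 9), "nobody will miss me when I die"),
    PostRecord("u2", dt.date(2021, 4, 20), "today was a good day with friends"),
]
matrix = build_feature_matrix(posts, default_grid(), lex)
freq, missing = normalized_frequency(matrix)

t5 = matrix.period_labels.index("T5")
for u, uid in enumerate(matrix.user_ids):
    print(f"{uid} (T5, {matrix.total_words[u, t5]} words):")
    for c, cat in enumerate(matrix.categories):
        if matrix.hits[u, t5, c]:
            print(f"  {cat:12s} hits={matrix.hits[u, t5, c]} "
                  f"freq={freq[u, t5, c]:.3f}")
# 'hate' counts for anger and propagates to negemo and affect; 'die'
# counts for death (and its parent, personal concerns).  Frequencies are
# hits divided by the period's word total; periods without posts are
# flagged missing rather than zero.
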