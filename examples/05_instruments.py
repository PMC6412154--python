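"""Score workload/mood instruments and classify scenario difficulty.

Covers the study-design computations: NASA-TLX and PANAS scoring, the
two-way random-effects ICC for three instructors' difficulty ratings,
and Jenks natural-breaks classification into low/medium/high.
"""

import numpy as np

from dyadnirs import RatingRecord, icc, jenks_classify, score_instruments

record = RatingRecord(
    "participant-1",
    borg=13,
    tlx_dims=(55, 30, 70, 40, 65, 35),
    panas_items=(4, 2, 4, 1, 3, 2, 1, 2, 4, 3, 1, 4, 2, 1, 2, 3, 4, 1, 3, 2),
)
scores = score_instruments(record)
print("instrument scores:", scores)

# three instructors rate ten scenarios on a 1-5 difficulty scale
rng = np.random.default_rng(0)
target = np.clip(3 + 1.0 * rng.standard_normal(10), 1, 5)
ratings = np.clip(target[:, None] + 0.3 * rng.standard_normal((10, 3)), 1, 5)
result = icc(ratings)
print(f"inter-rater ICC (two-way random, average measures): {result.icc:.2f}")

means = ratings.mean(axis=1)
classes = jenks_classify(means, k=3)
print(f"Jenks breaks at {classes.breaks[0]:.2f} and {classes.breaks[1]:.2f} "
      f"(goodness of fit {classes.goodness:.2f})")
for i, (m, c) in enumerate(zip(means, classes.classes)):
    print(f"  scenario {i}: mean rating {m:.2f} -> {c}")

# TLX overall is the unweighted sum of six 0-100 dimensions (0-600);
# PANAS positive/negative are 10-item sums (10-50).  The ICC here is
# high because rater disagreement (SD 0.3) is small next to scenario
# spread (SD 1.0); Jenks then cuts the averaged ratings into three
# contiguous classes minimizing within-class squared deviation.
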