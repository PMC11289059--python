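"""Benchmark behavioural profile of a large online PRT cohort.

Mean accuracy rates (percent correct among valid trials) per feedback group,
stimulus type, and block.  These are used as correctness probabilities when
simulating design-level sessions (e.g. expected reward counts under the
skewed schedule); they are inputs to simulations, not fitted quantities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ACCURACY_PCT", "mean_accuracy", "GROUP_ORDER"]

GROUP_ORDER = ("star", "verbal", "face", "thumbs")

#: accuracy (%) -> [stimulus][block] = (star, verbal, face, thumbs)
ACCURACY_PCT = {
    "rich": {
        1: (74.13, 75.99, 76.44, 76.22),
        2: (75.42, 76.94, 78.63, 78.94),
        3: (78.22, 77.69, 79.46, 77.87),
    },
    "lean": {
        1: (68.94, 69.33, 71.08, 69.17),
        2: (67.20, 69.34, 70.85, 70.02),
        3: (66.63, 69.73, 71.07, 69.42),
    },
}


def mean_accuracy(stimulus: str, block: int) -> float:
    """Across-group mean accuracy (as a probability) for one stimulus-by-block
    cell of the benchmark profile."""
    return float(np.mean(ACCURACY_PCT[stimulus][block])) / 100.0
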