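"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann–Whitney U statistic with midrank tie handling.

    ``labels`` is boolean (True = positive); larger ``scores`` are treated as
    more positive.  Equivalent to exhaustive pair counting with ties worth
    one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
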