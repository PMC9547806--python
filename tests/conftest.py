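import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def detection_scores(records, truth_labels):
    """Match detected clusters to planted objects by centroid containment.

    Returns (recall, precision): a detection whose centroid falls inside a
    planted label is a true positive (each planted object counts once).
    """
    truth_ids = set(np.unique(truth_labels)) - {0}
    matched = set()
    fp = 0
    for rec in records:
        x, y = rec.centroid_xy
        lab = int(truth_labels[int(round(y)), int(round(x))])
        if lab > 0:
            matched.add(lab)
        else:
            fp += 1
    tp = len(matched)
    recall = tp / len(truth_ids) if truth_ids else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    return recall, precision
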