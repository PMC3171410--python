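import numpy as np
import pandas as pd
import pytest

from gazeframe import DisplayGeometry, FixationDataset


@pytest.fixture
def paper_geom():
    """The 1280x960 px / 28.4x21.3 deg display used in the docs."""
    return DisplayGeometry(1280, 960, 28.4, 21.3)


@pytest.fixture
def make_fixations():
    """Factory: build a FixationDataset from raw (x, y) positions."""

    def _make(xy, geometry, subject="s1", image="i1", category="naturals",
              **kwargs):
        xy = np.atleast_2d(np.asarray(xy, float))
        df = pd.DataFrame({
            "subject": subject, "image": image, "category": category,
            "trial_index": np.arange(1, len(xy) + 1),
            "x": xy[:, 0], "y": xy[:, 1],
        })
        kwargs.setdefault("max_fixations", len(xy))
        return FixationDataset(df, geometry, **kwargs)

    return _make


def pairwise_auc(positives, negatives):
    """O(n^2) Mann-Whitney oracle: (wins + half ties) / (n_pos * n_neg)."""
    pos = np.asarray(positives, float)[:, None]
    neg = np.asarray(negatives, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum())
                 / (pos.size * neg.size))
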