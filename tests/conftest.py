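import numpy as np
import pandas as pd
import pytest

from dbnpsy import GroundTruthDBN, default_catalog, join_waves, sample_cohort
from dbnpsy.bn_core import temporal_constraints_for


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_gt(items, arcs, marginals=None, targets=None):
    """Small ground-truth network over generic items for search tests."""
    items = tuple(items)
    marginals = marginals or {i: 0.3 for i in items}
    targets = targets or dict(marginals)
    return GroundTruthDBN(
        w1_items=items,
        w2_items=items,
        static_items=(),
        w1_marginals=dict(marginals),
        arcs=tuple(arcs),
        w2_targets=dict(targets),
    )


@pytest.fixture
def single_arc_gt():
    """One planted arc a@W1 -> a@W2 at odds ratio 8 among two items."""
    return make_gt(
        ("a", "b"),
        arcs=((f"a@W1", f"a@W2", float(np.log(8))),),
        marginals={"a": 0.4, "b": 0.3},
    )


def joint_frame(gt, n, seed):
    p1, p2 = sample_cohort(gt, n, seed)
    return join_waves(p1, p2)


@pytest.fixture
def constraints_of():
    def _make(joint):
        return temporal_constraints_for(list(joint.columns))

    return _make
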