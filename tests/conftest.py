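import numpy as np
import pytest

import chloroconv as cc
from chloroconv.fixtures import (
    study_forced_splits,
    study_replacements,
    study_tree,
)


@pytest.fixture(scope="session")
def study():
    """The packaged synthetic study fixture, fully classified."""
    tree = study_tree()
    branches = cc.find_reference_branches(tree, forced_splits=study_forced_splits())
    pairs = cc.enumerate_pairs(branches)
    replacements = study_replacements()
    events = cc.compare_all_pairs(replacements, pairs)
    summary = cc.summarize(events, pairs)
    return {
        "tree": tree,
        "branches": branches,
        "branch_types": {b.branch_id: b.type for b in branches},
        "pairs": pairs,
        "replacements": replacements,
        "events": events,
        "summary": summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_binary_tree(tip_names, rng, with_lengths=True):
    """Random topology by successive joins; plain newick string."""
    parts = [
        (name + (f":{rng.uniform(0.05, 0.5):.4f}" if with_lengths else ""))
        for name in tip_names
    ]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        merged = f"({a},{b})"
        if with_lengths:
            merged += f":{rng.uniform(0.05, 0.5):.4f}"
        parts.append(merged)
    return parts[0].rsplit(":", 1)[0] + ";"
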