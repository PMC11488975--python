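"""Shared test utilities (independent oracles live in the test modules)."""

import numpy as np

from annosom import AnnotationTree, ThresholdTable, add_node


def make_thresholds(mapping) -> ThresholdTable:
    return ThresholdTable.from_mapping(mapping)


def random_tree(rng: np.random.Generator, markers) -> AnnotationTree:
    """Random small hierarchy with consistent (non-contradictory) branches."""
    markers = list(markers)
    tree = AnnotationTree(markers=markers)
    for i in range(int(rng.integers(1, 4))):
        pos = list(rng.choice(markers, size=int(rng.integers(1, 3)), replace=False))
        rest = [m for m in markers if m not in pos]
        neg = list(rng.choice(rest, size=int(rng.integers(0, 2)), replace=False))
        nid = add_node(tree, tree.root_id, f"P{i}", pos, neg)
        if rng.random() < 0.6:
            used = set(pos) | set(neg)
            avail = [m for m in markers if m not in used]
            if avail:
                cpos = [str(rng.choice(avail))]
                add_node(tree, nid, f"P{i}.0", cpos, [])
    return tree
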