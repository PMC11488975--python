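"""Hierarchical phenotype annotation tree.

Annotation proceeds top-down: every cluster starts at the root ("unassigned")
and is filtered into child nodes whose positive/negative marker definitions
it satisfies against the current thresholds, recursively.  A node's full
phenotype is the cumulative union of marker constraints along its branch, so
e.g. a central-memory CD8 T-cell leaf can be reached through
CD66b- -> CD3+CD19- -> CD56-TCRgd- -> CD8+CD4- -> CCR7+CD45RA-.

Whenever any threshold changes the whole assignment is recomputed from
scratch; the assignment is therefore a pure function of
(tree structure, thresholds, expression matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContradictionError,
    MissingThresholdError,
    NameClashError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROOT_NAME = "unassigned"
REMAINING_SUFFIX = "_remaining"


@dataclass
class PhenotypeNode:
    """One phenotype: a named set of positive/negative marker constraints."""

    node_id: str
    name: str
    parent_id: str | None
    positive_markers: tuple[str, ...] = ()
    negative_markers: tuple[str, ...] = ()
    children: list[str] = field(default_factory=list)


@dataclass
class NodeStatus:
    """Per-node occupancy summary."""

    node_id: str
    name: str
    n_clusters: int  # clusters anywhere in the subtree
    n_direct: int  # clusters resting at this node itself
    pct_cells: float  # % of all cells in the subtree (needs frequencies)
    fully_defined: bool  # has children and no direct clusters


class AnnotationTree:
    """Ordered hierarchy of phenotype nodes plus the current assignment.

    ``markers`` optionally pins the marker universe; node definitions are
    then validated against it.  ``assignment`` maps each cluster to the
    deepest node containing it and is maintained by :func:`recompute`.
    """

    def __init__(self, markers: Iterable[str] | None = None) -> None:
        self.root_id = "n0"
        self.nodes: dict[str, PhenotypeNode] = {
            self.root_id: PhenotypeNode(self.root_id, ROOT_NAME, None)
        }
        self.markers: set[str] | None = set(markers) if markers is not None else None
        self.assignment: dict[str, str] = {}
        self.overlaps: list[tuple[str, list[str]]] = []
        self._counter = 0

    # -- structure ---------------------------------------------------------

    def _next_id(self) -> str:
        self._counter += 1
        return f"n{self._counter}"

    def children_of(self, node_id: str) -> list[PhenotypeNode]:
        return [self.nodes[c] for c in self.nodes[node_id].children]

    def descendants(self, node_id: str) -> list[str]:
        """node_id plus all nodes below it, in depth-first order."""
        out = [node_id]
        for child in self.nodes[node_id].children:
            out.extend(self.descendants(child))
        return out

    def used_markers(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out.update(node.positive_markers)
            out.update(node.negative_markers)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTree):
            return NotImplemented
        return self.root_id == other.root_id and self.nodes == other.nodes


def add_node(
    tree: AnnotationTree,
    parent_id: str,
    name: str,
    positive_markers: Sequence[str] = (),
    negative_markers: Sequence[str] = (),
    node_id: str | None = None,
) -> str:
    """Append a phenotype node under ``parent_id``; returns the new node id.

    Sibling order is insertion order and matters: when a cluster satisfies
    two siblings it lands in the earlier one.  Assignments become stale and
    must be refreshed with :func:`recompute`.
    """
    if parent_id not in tree.nodes:
        raise ValidationError(f"unknown parent node {parent_id!r}")
    parent = tree.nodes[parent_id]
    siblings = {tree.nodes[c].name for c in parent.children}
    if name in siblings:
        raise NameClashError(f"sibling named {name!r} already exists")
    pos = tuple(dict.fromkeys(positive_markers))
    neg = tuple(dict.fromkeys(negative_markers))
    both = set(pos) & set(neg)
    if both:
        raise ValidationError(f"markers both positive and negative: {sorted(both)}")
    if tree.markers is not None:
        unknown = (set(pos) | set(neg)) - tree.markers
        if unknown:
            raise ValidationError(f"unknown markers: {sorted(unknown)}")
    nid = node_id or tree._next_id()
    if nid in tree.nodes:
        raise ValidationError(f"duplicate node id {nid!r}")
    tree.nodes[nid] = PhenotypeNode(nid, name, parent_id, pos, neg)
    parent.children.append(nid)
    return nid


def delete_node(tree: AnnotationTree, node_id: str) -> None:
    """Remove a node and its whole subtree; its clusters fall back to the
    parent on the next :func:`recompute`."""
    if node_id == tree.root_id:
        raise ValidationError("cannot delete the root node")
    node = tree.nodes[node_id]
    for nid in tree.descendants(node_id):
        del tree.nodes[nid]
    tree.nodes[node.parent_id].children.remove(node_id)


def matches(cluster_id: str, node: PhenotypeNode, thresholds, expression) -> bool:
    """Does a cluster satisfy a node's own (non-cumulative) definition?

    A marker counts as positive when its normalised expression is strictly
    above the threshold; a value exactly at the threshold is negative.
    """
    row = expression.normalized.loc[cluster_id]
    for m in node.positive_markers:
        if m not in thresholds:
            raise MissingThresholdError(m)
        if not row[m] > thresholds[m].threshold:
            return False
    for m in node.negative_markers:
        if m not in thresholds:
            raise MissingThresholdError(m)
        if not row[m] <= thresholds[m].threshold:
            return False
    return True


def _node_mask(node: PhenotypeNode, norm: pd.DataFrame, thr: dict[str, float]) -> np.ndarray:
    mask = np.ones(len(norm), dtype=bool)
    for m in node.positive_markers:
        mask &= norm[m].to_numpy() > thr[m]
    for m in node.negative_markers:
        mask &= norm[m].to_numpy() <= thr[m]
    return mask


def recompute(tree: AnnotationTree, thresholds, expression) -> AnnotationTree:
    """Rebuild the cluster -> node assignment from scratch.

    Top-down: the root receives every cluster; at each node the direct
    clusters are tested against the children in insertion order and move
    into the first child they match.  Clusters matching two or more siblings
    are recorded in ``tree.overlaps`` (cluster id, matching child names).
    """
    for m in tree.used_markers():
        if m not in thresholds:
            raise MissingThresholdError(m)
    norm = expression.normalized
    thr = {m: thresholds[m].threshold for m in thresholds}
    clusters = np.asarray(expression.cluster_ids, dtype=object)
    masks = {nid: _node_mask(node, norm, thr) for nid, node in tree.nodes.items()}

    assignment: dict[str, str] = {}
    overlaps: list[tuple[str, list[str]]] = []

    def assign(node_id: str, idx: np.ndarray) -> None:
        node = tree.nodes[node_id]
        if node.children:
            n_hits = np.zeros(idx.size, dtype=int)
            taken = np.zeros(idx.size, dtype=bool)
            child_idx: dict[str, np.ndarray] = {}
            for cid in node.children:
                hit = masks[cid][idx]
                n_hits += hit
                child_idx[cid] = idx[hit & ~taken]
                taken |= hit
            for i in idx[n_hits >= 2]:
                names = [
                    tree.nodes[cid].name
                    for cid in node.children
                    if masks[cid][i]
                ]
                overlaps.append((str(clusters[i]), names))
            for cid in node.children:
                assign(cid, child_idx[cid])
            idx = idx[~taken]
        for i in idx:
            assignment[str(clusters[i])] = node_id

    assign(tree.root_id, np.arange(clusters.size))
    # restore expression row order for a stable, readable assignment
    tree.assignment = {c: assignment[c] for c in expression.cluster_ids}
    tree.overlaps = overlaps
    if overlaps:
        logger.warning(
            "%d clusters match more than one sibling definition; "
            "first-match rule applied",
            len(overlaps),
        )
    logger.info(
        "assigned %d clusters across %d nodes", len(assignment), len(tree.nodes)
    )
    return tree


def cumulative_definition(
    tree: AnnotationTree, node_id: str
) -> tuple[set[str], set[str]]:
    """Union of positive/negative markers along the root -> node path."""
    pos: set[str] = set()
    neg: set[str] = set()
    nid: str | None = node_id
    while nid is not None:
        node = tree.nodes[nid]
        pos.update(node.positive_markers)
        neg.update(node.negative_markers)
        nid = node.parent_id
    both = pos & neg
    if both:
        raise ContradictionError(
            f"markers required both + and - on the branch to "
            f"{tree.nodes[node_id].name!r}: {sorted(both)}"
        )
    return pos, neg


def node_status(
    tree: AnnotationTree, frequency: pd.Series | None = None
) -> list[NodeStatus]:
    """Occupancy summary of every node, in depth-first order.

    ``frequency`` maps cluster id -> fraction of all cells; when given,
    ``pct_cells`` reports the percentage of cells in each subtree.
    A node is *fully defined* when it has children and no cluster rests at
    the node itself (every cluster fell through to a child).
    """
    direct: dict[str, list[str]] = {nid: [] for nid in tree.nodes}
    for cluster, nid in tree.assignment.items():
        direct[nid].append(cluster)

    statuses: dict[str, NodeStatus] = {}

    def visit(node_id: str) -> tuple[int, float]:
        node = tree.nodes[node_id]
        n = len(direct[node_id])
        pct = (
            100.0 * sum(frequency[c] for c in direct[node_id])
            if frequency is not None
            else float("nan")
        )
        for child in node.children:
            cn, cp = visit(child)
            n += cn
            pct = pct + cp if frequency is not None else pct
        statuses[node_id] = NodeStatus(
            node_id=node_id,
            name=node.name,
            n_clusters=n,
            n_direct=len(direct[node_id]),
            pct_cells=pct,
            fully_defined=bool(node.children) and not direct[node_id],
        )
        return n, pct

    visit(tree.root_id)
    return [statuses[nid] for nid in tree.descendants(tree.root_id)]


def terminal_labels(tree: AnnotationTree) -> pd.Series:
    """Final phenotype label of every cluster.

    Clusters at a leaf get the leaf's name; clusters resting at an internal
    node with children are that node's leftover population and get
    ``"<name>_remaining"``; clusters still at the root stay "unassigned".
    """
    labels: dict[str, str] = {}
    for cluster, nid in tree.assignment.items():
        node = tree.nodes[nid]
        if nid == tree.root_id or not node.children:
            labels[cluster] = node.name
        else:
            labels[cluster] = node.name + REMAINING_SUFFIX
    return pd.Series(labels, name="label", dtype=object)
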