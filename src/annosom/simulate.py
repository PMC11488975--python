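"""Ground-truth-labelled synthetic projects.

Emulates the cluster-level output of an over-clustered SOM-style cytometry
pipeline: a few hundred clusters whose per-marker medians sit in a low
(negative) or high (positive) mode according to a generating phenotype tree,
plus per-sample cluster counts drawn Dirichlet-multinomial around
condition-specific phenotype proportions with a configurable fold-change
spiked into one phenotype.

The generator emits exactly the four CSV inputs the analysis consumes
(expression, frequency, metadata, counts) together with the generating tree
and a :class:`GroundTruth` record, so thresholding, annotation and
differential abundance can be validated end-to-end against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ContradictionError, ValidationError
from .io import (
    write_counts,
    write_expression,
    write_frequency,
    write_metadata,
    write_annotation,
)
from .io import ClusterExpressionMatrix
from .tree import AnnotationTree, add_node, cumulative_definition

DEFAULT_MARKERS = (
    "CD3",
    "CD19",
    "CD56",
    "CD4",
    "CD8",
    "CD45RA",
    "CCR7",
    "CD27",
    "CD38",
    "HLA-DR",
)


def default_phenotype_tree(markers=DEFAULT_MARKERS) -> AnnotationTree:
    """A small immune hierarchy: T / B / NK at the top, CD4/CD8 below T.

    T cells deliberately have a leftover population (clusters that are
    neither CD4 nor CD8 single-positive) so the ``*_remaining`` path is
    exercised, and some clusters match no top-level node and stay
    unassigned.
    """
    tree = AnnotationTree(markers=markers)
    t = add_node(tree, tree.root_id, "T cells", ["CD3"], ["CD19"])
    add_node(tree, tree.root_id, "B cells", ["CD19"], ["CD3"])
    add_node(tree, tree.root_id, "NK cells", ["CD56"], ["CD3", "CD19"])
    add_node(tree, t, "CD4 T cells", ["CD4"], ["CD8"])
    add_node(tree, t, "CD8 T cells", ["CD8"], ["CD4"])
    return tree


@dataclass
class SimulationConfig:
    """Study design of one synthetic project.

    Defaults model a typical two-arm cytometry comparison: 200 SOM clusters
    over a 10-marker panel, expression modes at 0.2/0.8 with SD 0.05
    (cleanly separated, as expected after arcsinh + normalisation for a
    well-behaved marker), 8 samples per condition with 100 000 cells each,
    Dirichlet concentration 100 (inter-sample proportion SD of a few
    percentage points, typical biological variability), and a two-fold
    abundance increase of B cells in the second condition.
    """

    n_clusters: int = 200
    markers: tuple[str, ...] = DEFAULT_MARKERS
    phenotype_tree: AnnotationTree | None = None
    low_mode: float = 0.2
    high_mode: float = 0.8
    mode_sd: float = 0.05
    n_samples_per_condition: int = 8
    conditions: tuple[str, ...] = ("control", "case")
    total_cells_per_sample: int = 100_000
    effect: tuple[str, str, float] = ("B cells", "case", 2.0)
    dirichlet_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        self.conditions = tuple(self.conditions)
        self.effect = tuple(self.effect)
        if not self.low_mode < self.high_mode:
            raise ValidationError("low_mode must be below high_mode")
        if self.effect[2] <= 0:
            raise ValidationError("fold_change must be positive")
        if self.mode_sd < 0:
            raise ValidationError("mode_sd must be non-negative")

    def tree(self) -> AnnotationTree:
        return self.phenotype_tree or default_phenotype_tree(self.markers)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis should recover."""

    phenotype: pd.Series  # cluster -> generating terminal label
    true_thresholds: pd.Series  # marker -> (low+high)/2
    true_proportions: pd.DataFrame  # condition x label expected proportions
    modes: pd.DataFrame = field(repr=False)  # cluster x marker in {low,high}


@dataclass
class SimulatedProject:
    expression: pd.DataFrame  # clusters x markers raw values
    frequency: pd.Series
    metadata: pd.DataFrame
    counts: pd.DataFrame
    tree: AnnotationTree
    truth: GroundTruth

    def expression_matrix(self) -> ClusterExpressionMatrix:
        return ClusterExpressionMatrix.from_values(self.expression)

    def write(self, outdir) -> dict[str, Path]:
        """Write the four input CSVs plus the generating tree and truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.csv",
            "frequency": outdir / "frequency.csv",
            "metadata": outdir / "metadata.csv",
            "counts": outdir / "counts.csv",
            "annotation": outdir / "annotation.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        write_expression(self.expression_matrix(), paths["expression"])
        write_frequency(self.frequency, paths["frequency"])
        write_metadata(self.metadata, paths["metadata"])
        write_counts(self.counts, paths["counts"])
        write_annotation(self.tree, paths["annotation"])
        truth_df = self.truth.phenotype.rename("phenotype").to_frame()
        truth_df.to_csv(paths["ground_truth"], index_label="cluster_id")
        return paths


def _terminal_label_constraints(tree: AnnotationTree) -> dict[str, tuple[set, set]]:
    """Marker constraints realising each terminal label of a tree.

    Leaves use their cumulative definition.  For an internal node (and the
    root) a leftover label is emitted whose constraints extend the node's
    cumulative definition by forcing every child's own positive markers
    negative, which guarantees the cluster matches no child.  Children
    defined purely by negative markers admit no such construction and are
    skipped.
    """
    out: dict[str, tuple[set, set]] = {}
    from .tree import REMAINING_SUFFIX, ROOT_NAME

    for nid in tree.descendants(tree.root_id):
        node = tree.nodes[nid]
        pos, neg = cumulative_definition(tree, nid)
        if not node.children:
            out[node.name] = (set(pos), set(neg))
            continue
        extra_neg: set[str] = set()
        constructible = True
        for cid in node.children:
            child_pos = set(tree.nodes[cid].positive_markers)
            if not child_pos - pos:
                constructible = False  # cannot force this child off
                break
            extra_neg.update(child_pos - pos)
        if not constructible:
            continue
        label = ROOT_NAME if nid == tree.root_id else node.name + REMAINING_SUFFIX
        out[label] = (set(pos), set(neg) | extra_neg)
    return out


def _draw_mode(rng, mean, sd, size) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_project(config: SimulationConfig | None = None) -> SimulatedProject:
    """Generate a complete synthetic project, reproducible from the seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    constraints = _terminal_label_constraints(tree)
    labels = list(constraints)
    if config.n_clusters < len(labels):
        raise ValidationError(
            f"need at least {len(labels)} clusters for {len(labels)} phenotypes"
        )
    for name, (pos, neg) in constraints.items():
        if pos & neg:
            raise ContradictionError(f"phenotype {name!r} demands {pos & neg} both ways")

    width = len(str(config.n_clusters))
    cluster_ids = [f"c{i + 1:0{width}d}" for i in range(config.n_clusters)]
    phenotype = pd.Series(
        [labels[i % len(labels)] for i in range(config.n_clusters)],
        index=cluster_ids,
        name="phenotype",
    )

    # per-cluster per-marker mode: constrained by the phenotype, else coin flip
    modes = pd.DataFrame(index=cluster_ids, columns=list(config.markers), dtype=object)
    coin = rng.random((config.n_clusters, len(config.markers))) < 0.5
    for j, m in enumerate(config.markers):
        col = np.where(coin[:, j], "high", "low")
        modes[m] = col
    for cid in cluster_ids:
        pos, neg = constraints[phenotype[cid]]
        for m in pos:
            modes.loc[cid, m] = "high"
        for m in neg:
            modes.loc[cid, m] = "low"

    expression = pd.DataFrame(index=cluster_ids, columns=list(config.markers), dtype=float)
    expression.index.name = "cluster_id"
    for m in config.markers:
        is_high = (modes[m] == "high").to_numpy()
        vals = np.empty(config.n_clusters)
        vals[is_high] = _draw_mode(rng, config.high_mode, config.mode_sd, int(is_high.sum()))
        vals[~is_high] = _draw_mode(rng, config.low_mode, config.mode_sd, int((~is_high).sum()))
        expression[m] = vals

    # condition-specific expected phenotype proportions: uniform baseline,
    # the effect phenotype scaled by the fold change and the rest shrunk to
    # keep the simplex, so the effect phenotype's proportion ratio between
    # conditions equals the fold change exactly
    n_labels = len(labels)
    base = np.full(n_labels, 1.0 / n_labels)
    eff_label, eff_cond, fold = config.effect
    if eff_label not in labels:
        raise ValidationError(f"effect phenotype {eff_label!r} not generated by the tree")
    if eff_cond not in config.conditions:
        raise ValidationError(f"effect condition {eff_cond!r} not in conditions")
    props = {}
    for cond in config.conditions:
        p = base.copy()
        if cond == eff_cond and fold != 1.0:
            i = labels.index(eff_label)
            new_eff = fold * p[i]
            if new_eff >= 1.0:
                raise ValidationError("fold change pushes the effect phenotype past 100%")
            others = 1.0 - p[i]
            p *= (1.0 - new_eff) / others
            p[i] = new_eff
        props[cond] = p
    true_proportions = pd.DataFrame(props, index=labels).T

    sample_ids, sample_conditions = [], []
    for cond in config.conditions:
        for i in range(config.n_samples_per_condition):
            sample_ids.append(f"{cond}_{i + 1:02d}")
            sample_conditions.append(cond)
    metadata = pd.DataFrame({"condition": sample_conditions}, index=sample_ids)
    metadata.index.name = "sample_id"

    members = {lab: [c for c in cluster_ids if phenotype[c] == lab] for lab in labels}
    counts = pd.DataFrame(0, index=cluster_ids, columns=sample_ids, dtype=np.int64)
    counts.index.name = "cluster_id"
    for sid, cond in zip(sample_ids, sample_conditions):
        alpha = config.dirichlet_concentration * true_proportions.loc[cond].to_numpy()
        q = rng.dirichlet(alpha)
        pheno_counts = rng.multinomial(config.total_cells_per_sample, q)
        for lab, n_lab in zip(labels, pheno_counts):
            mem = members[lab]
            share = rng.multinomial(n_lab, np.full(len(mem), 1.0 / len(mem)))
            counts.loc[mem, sid] += share

    grand_total = counts.to_numpy().sum()
    frequency = counts.sum(axis=1) / grand_total
    frequency.name = "frequency"

    truth = GroundTruth(
        phenotype=phenotype,
        true_thresholds=pd.Series(
            0.5 * (config.low_mode + config.high_mode),
            index=list(config.markers),
            name="threshold",
        ),
        true_proportions=true_proportions,
        modes=modes,
    )
    return SimulatedProject(
        expression=expression,
        frequency=frequency,
        metadata=metadata,
        counts=counts,
        tree=tree,
        truth=truth,
    )
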