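"""CSV readers/writers and project assembly.

All project artifacts are plain UTF-8 CSV with a mandatory header row,
comma separator and '.' decimal mark:

* ``expression.csv``  — ``cluster_id,<marker1>,...`` median expression per
  cluster (assumed already variance-stabilised, e.g. arcsinh, upstream);
* ``frequency.csv``   — ``cluster_id,frequency`` global cell fractions;
* ``metadata.csv``    — ``sample_id,condition[,...]``;
* ``counts.csv``      — ``cluster_id,<sample1>,...`` integer cell counts;
* ``thresholds.csv``  — one row per marker with threshold + diagnostics;
* ``annotation.csv``  — one row per tree node, parents before children.

The threshold and annotation files exist so an analysis can be saved,
reloaded and rerun bit-for-bit, and shared between analysts.  Writers are
atomic (temp file + rename) so a crash never leaves a half-written table.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    ParseError,
    ValidationError,
)
from .thresholds import MarkerThreshold, ThresholdTable
from .tree import ROOT_NAME, AnnotationTree, add_node

logger = logging.getLogger(__name__)

FREQUENCY_TOL = 1e-6


def _atomic_to_csv(df: pd.DataFrame, path, **kwargs) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent if str(path.parent) else ".", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    if df.empty and df.shape[1] == 0:
        raise EmptyInputError(f"{path}: no columns")
    return df


# -- expression -------------------------------------------------------------


@dataclass
class ClusterExpressionMatrix:
    """Clusters x markers median-expression table.

    ``values`` holds the data as supplied; ``normalized`` is the per-marker
    min–max rescaling to [0, 1] on which thresholds and annotation operate
    (monotone, hence order- and partition-preserving, and invertible for
    reporting on the original scale).  Markers constant across clusters
    cannot be rescaled; they are mapped to all zeros and listed in
    ``constant_markers``.
    """

    values: pd.DataFrame
    normalized: pd.DataFrame = field(repr=False)
    constant_markers: tuple[str, ...] = ()

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "ClusterExpressionMatrix":
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate cluster ids: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate marker names: {dupes}")
        if values.isna().any().any():
            raise ParseError("expression matrix contains missing values")
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = hi - lo
        constant = tuple(span.index[span == 0])
        safe_span = span.replace(0, 1.0)
        normalized = (values - lo) / safe_span
        for m in constant:
            normalized[m] = 0.0
        if constant:
            logger.warning("constant markers (no low/high split): %s", list(constant))
        return cls(values=values, normalized=normalized, constant_markers=constant)


def read_expression(path) -> ClusterExpressionMatrix:
    """Load ``expression.csv``; first column is the cluster id."""
    df = _read_csv(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a cluster id column plus >=1 marker")
    df = df.set_index(df.columns[0])
    df.index.name = "cluster_id"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} "
            f"(cluster {df.index[r]!r}, marker {df.columns[c]!r})"
        )
    return ClusterExpressionMatrix.from_values(numeric.astype(float))


def write_expression(expr: ClusterExpressionMatrix, path) -> None:
    _atomic_to_csv(expr.values, path, index_label="cluster_id")


# -- frequency / metadata / counts ------------------------------------------


def read_frequency(path) -> pd.Series:
    """Load ``frequency.csv``: per-cluster fractions of all cells."""
    df = _read_csv(path)
    if {"cluster_id", "frequency"} - set(df.columns):
        raise ParseError(f"{path}: expected columns cluster_id,frequency")
    if df["cluster_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate cluster ids")
    freq = pd.to_numeric(df["frequency"], errors="coerce")
    if freq.isna().any():
        raise ParseError(f"{path}: non-numeric frequency")
    if (freq < 0).any():
        raise ValidationError(f"{path}: negative frequency")
    total = float(freq.sum())
    if abs(total - 1.0) > FREQUENCY_TOL:
        raise ValidationError(
            f"{path}: frequencies sum to {total:.6g}, expected 1"
        )
    out = pd.Series(freq.to_numpy(), index=df["cluster_id"].to_numpy(), name="frequency")
    out.index.name = "cluster_id"
    return out


def write_frequency(freq: pd.Series, path) -> None:
    _atomic_to_csv(freq.rename("frequency").to_frame(), path, index_label="cluster_id")


def read_metadata(path) -> pd.DataFrame:
    """Load ``metadata.csv``: sample -> condition (extra columns kept)."""
    df = _read_csv(path)
    if {"sample_id", "condition"} - set(df.columns):
        raise ParseError(f"{path}: expected columns sample_id,condition")
    if df["sample_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    df["condition"] = df["condition"].astype(str)
    if df["condition"].nunique() < 1 or df.shape[0] == 0:
        raise ValidationError(f"{path}: need at least one sample")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    _atomic_to_csv(metadata, path, index_label="sample_id")


def read_counts(path) -> pd.DataFrame:
    """Load ``counts.csv``: clusters x samples non-negative integer counts."""
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a cluster id column plus >=1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "cluster_id"
    if df.index.duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate cluster ids")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if (numeric.isna() & ~df.isna()).any().any() or numeric.isna().any().any():
        raise ParseError(f"{path}: non-numeric count")
    vals = numeric.to_numpy()
    if (vals < 0).any():
        raise ParseError(f"{path}: negative count")
    if np.any(vals != np.floor(vals)):
        raise ParseError(f"{path}: fractional count")
    return numeric.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    _atomic_to_csv(counts, path, index_label="cluster_id")


# -- thresholds --------------------------------------------------------------

THRESHOLD_COLUMNS = [
    "marker",
    "threshold",
    "method",
    "silhouette_kmeans",
    "silhouette_gmm",
    "bimodality_coefficient",
    "is_bimodal",
    "manual",
]


def write_thresholds(table: ThresholdTable, path) -> None:
    rows = [
        {
            "marker": e.marker,
            "threshold": e.threshold,
            "method": e.method,
            "silhouette_kmeans": e.silhouette_kmeans,
            "silhouette_gmm": e.silhouette_gmm,
            "bimodality_coefficient": e.bimodality_coefficient,
            "is_bimodal": e.is_bimodal,
            "manual": e.manual,
        }
        for e in table.values()
    ]
    df = pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)
    _atomic_to_csv(df, path, index=False)


def read_thresholds(path, expression: ClusterExpressionMatrix | None = None) -> ThresholdTable:
    """Reload a saved threshold table; optionally validate markers against a
    loaded expression matrix."""
    df = _read_csv(path)
    missing = set(THRESHOLD_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["marker"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate marker rows")
    table = ThresholdTable()
    for _, row in df.iterrows():
        table.add(
            MarkerThreshold(
                marker=str(row["marker"]),
                threshold=float(row["threshold"]),
                method=str(row["method"]),
                silhouette_kmeans=float(row["silhouette_kmeans"]),
                silhouette_gmm=float(row["silhouette_gmm"]),
                bimodality_coefficient=float(row["bimodality_coefficient"]),
                is_bimodal=_parse_bool(row["is_bimodal"]),
                manual=_parse_bool(row["manual"]),
            )
        )
    if expression is not None:
        unknown = set(table.markers) - set(expression.marker_names)
        if unknown:
            raise ValidationError(
                f"{path}: thresholds for unknown markers {sorted(unknown)}"
            )
    return table


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ParseError(f"cannot parse boolean {v!r}")


# -- annotation tree ---------------------------------------------------------

ANNOTATION_COLUMNS = [
    "node_id",
    "parent_id",
    "name",
    "positive_markers",
    "negative_markers",
]


def write_annotation(tree: AnnotationTree, path) -> None:
    """Save the tree, one row per node, parents before children (DFS)."""
    rows = []
    for nid in tree.descendants(tree.root_id):
        node = tree.nodes[nid]
        rows.append(
            {
                "node_id": node.node_id,
                "parent_id": node.parent_id or "",
                "name": node.name,
                "positive_markers": ";".join(node.positive_markers),
                "negative_markers": ";".join(node.negative_markers),
            }
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    _atomic_to_csv(df, path, index=False)


def read_annotation(path, expression: ClusterExpressionMatrix | None = None) -> AnnotationTree:
    """Reload a saved tree; sibling order follows row order."""
    df = _read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df.fillna("")
    if df["node_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate node ids")
    roots = df[df["parent_id"].astype(str) == ""]
    if len(roots) != 1:
        raise ValidationError(f"{path}: expected exactly one root row, got {len(roots)}")
    root_row = roots.iloc[0]
    if root_row["positive_markers"] or root_row["negative_markers"]:
        raise ValidationError(f"{path}: the root node must have no marker constraints")

    markers = set(expression.marker_names) if expression is not None else None
    tree = AnnotationTree(markers=markers)
    tree.nodes.clear()
    root_id = str(root_row["node_id"])
    tree.root_id = root_id
    from .tree import PhenotypeNode  # local to avoid polluting module surface

    tree.nodes[root_id] = PhenotypeNode(
        root_id, str(root_row["name"]) or ROOT_NAME, None
    )
    known = {root_id}
    pending = df[df["parent_id"].astype(str) != ""]
    for _, row in pending.iterrows():
        parent = str(row["parent_id"])
        if parent not in set(df["node_id"].astype(str)):
            raise ValidationError(f"{path}: orphan node {row['node_id']!r} (parent {parent!r})")
    # insert rows in file order; a parent appearing after its child is a
    # cycle or forward reference and is rejected
    for _, row in pending.iterrows():
        parent = str(row["parent_id"])
        if parent not in known:
            raise ValidationError(
                f"{path}: node {row['node_id']!r} appears before its parent "
                f"{parent!r} (cycle or misordered file)"
            )
        pos = tuple(m for m in str(row["positive_markers"]).split(";") if m)
        neg = tuple(m for m in str(row["negative_markers"]).split(";") if m)
        add_node(
            tree,
            parent,
            str(row["name"]),
            positive_markers=pos,
            negative_markers=neg,
            node_id=str(row["node_id"]),
        )
        known.add(str(row["node_id"]))
    return tree


def write_labels(labels: pd.Series, path) -> None:
    _atomic_to_csv(labels.rename("label").to_frame(), path, index_label="cluster_id")


def read_labels(path) -> pd.Series:
    df = _read_csv(path)
    if {"cluster_id", "label"} - set(df.columns):
        raise ParseError(f"{path}: expected columns cluster_id,label")
    if df["cluster_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate cluster ids")
    out = pd.Series(
        df["label"].astype(str).to_numpy(),
        index=df["cluster_id"].to_numpy(),
        name="label",
    )
    out.index.name = "cluster_id"
    return out


# -- project assembly ---------------------------------------------------------


@dataclass
class ProjectState:
    """All loaded artifacts of one analysis, cross-validated."""

    expression: ClusterExpressionMatrix
    frequency: pd.Series | None = None
    metadata: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    thresholds: ThresholdTable | None = None
    tree: AnnotationTree | None = None


def assemble_project(
    expression: ClusterExpressionMatrix,
    frequency: pd.Series | None = None,
    metadata: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
    thresholds: ThresholdTable | None = None,
    tree: AnnotationTree | None = None,
) -> ProjectState:
    """Bundle the loaded tables after checking that every cross-reference
    (cluster ids, sample ids, marker names) resolves."""
    clusters = set(expression.cluster_ids)
    markers = set(expression.marker_names)
    if frequency is not None:
        extra = set(frequency.index) - clusters
        missing = clusters - set(frequency.index)
        if extra or missing:
            raise ValidationError(
                f"frequency/expression cluster mismatch: "
                f"unknown={sorted(extra)[:5]} missing={sorted(missing)[:5]}"
            )
    if counts is not None:
        extra = set(counts.index) - clusters
        if extra:
            raise ValidationError(f"counts reference unknown clusters: {sorted(extra)[:5]}")
        if metadata is not None:
            unknown = set(counts.columns) - set(metadata.index)
            if unknown:
                raise ValidationError(
                    f"counts reference unknown samples: {sorted(unknown)[:5]}"
                )
    if thresholds is not None:
        unknown = set(thresholds.markers) - markers
        if unknown:
            raise ValidationError(f"thresholds for unknown markers: {sorted(unknown)}")
        uncovered = markers - set(thresholds.markers) - set(expression.constant_markers)
        if uncovered:
            raise ValidationError(f"markers without thresholds: {sorted(uncovered)}")
    if tree is not None:
        unknown = tree.used_markers() - markers
        if unknown:
            raise ValidationError(f"tree references unknown markers: {sorted(unknown)}")
    return ProjectState(
        expression=expression,
        frequency=frequency,
        metadata=metadata,
        counts=counts,
        thresholds=thresholds,
        tree=tree,
    )
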