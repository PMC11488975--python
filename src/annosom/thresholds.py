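"""Per-marker positive/negative threshold estimation.

Cluster medians of a cytometry marker are typically bimodal: a low mode of
marker-negative clusters and a high mode of marker-positive ones.  For each
marker this module estimates the value separating the two modes with two
deterministic methods —

* an *exact* 1D two-means split (all n-1 contiguous splits of the sorted
  vector are scored; no Lloyd iterations, no random initialisation), and
* a two-component univariate Gaussian mixture fitted by EM, initialised from
  the exact two-means partition, whose threshold is the density crossing
  between the component means (the posterior-0.5 decision boundary);

scores each candidate partition with the mean silhouette width, and keeps the
method with the better silhouette.  Sarle's bimodality coefficient is
reported alongside so that markers without a usable low/high split can be
flagged.  All quantities are computed on the min–max normalised [0,1] scale
supplied by :mod:`annosom.io`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import (
    DegenerateMarkerError,
    RangeError,
    UndefinedSilhouetteError,
)

logger = logging.getLogger(__name__)

#: Sarle's bimodality coefficient of the uniform distribution; the
#: conventional cutoff above which a sample is considered bimodal.
BIMODALITY_CUTOFF = 5.0 / 9.0

_EM_TOL = 1e-6
_EM_MAX_ITER = 500
_VARIANCE_FLOOR = 1e-8


@dataclass
class ThresholdConfig:
    """Tunable knobs of threshold estimation.

    bimodality_cutoff:
        Bimodality-coefficient cutoff; defaults to 5/9 (the uniform
        distribution's asymptotic value, often printed as 0.555).
    bimodality_direction:
        ``"gt"`` flags a marker bimodal when BC > cutoff (the convention of
        the coefficient's literature); ``"lt"`` inverts the comparison.
    """

    bimodality_cutoff: float = BIMODALITY_CUTOFF
    bimodality_direction: str = "gt"

    def __post_init__(self) -> None:
        if self.bimodality_direction not in ("gt", "lt"):
            raise RangeError(
                f"bimodality_direction must be 'gt' or 'lt', "
                f"got {self.bimodality_direction!r}"
            )


@dataclass
class MarkerThreshold:
    """Estimated threshold and diagnostics for a single marker."""

    marker: str
    threshold: float
    method: str  # "kmeans" | "gmm" | "manual"
    silhouette_kmeans: float
    silhouette_gmm: float
    bimodality_coefficient: float
    is_bimodal: bool
    manual: bool = False


class ThresholdTable:
    """Mapping marker -> :class:`MarkerThreshold` for one marker panel."""

    def __init__(self, entries: Iterable[MarkerThreshold] = ()) -> None:
        self._entries: dict[str, MarkerThreshold] = {}
        for e in entries:
            self._entries[e.marker] = e

    def __getitem__(self, marker: str) -> MarkerThreshold:
        return self._entries[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ThresholdTable):
            return NotImplemented
        return self._entries == other._entries

    @property
    def markers(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ThresholdTable":
        """Build a table of bare manual thresholds (no diagnostics)."""
        return cls(
            MarkerThreshold(
                marker=m,
                threshold=float(v),
                method="manual",
                silhouette_kmeans=math.nan,
                silhouette_gmm=math.nan,
                bimodality_coefficient=math.nan,
                is_bimodal=False,
                manual=True,
            )
            for m, v in mapping.items()
        )

    def add(self, entry: MarkerThreshold) -> None:
        self._entries[entry.marker] = entry

    def values(self) -> Iterable[MarkerThreshold]:
        return self._entries.values()


def kmeans1d_exact(x) -> tuple[float, np.ndarray, tuple[float, float]]:
    """Globally optimal two-means partition of a 1D vector.

    The sorted vector is scanned over all ``n - 1`` contiguous split points
    and the split minimising the total within-cluster sum of squares is
    selected (for k=2 in one dimension the optimal clusters are contiguous
    in sorted order, so this scan is exact).  Ties are broken toward the
    leftmost split, making the result fully deterministic.

    Returns ``(split_value, labels, (mean_low, mean_high))`` where
    ``split_value`` is the midpoint of the two cluster means (the 2-means
    decision boundary) and ``labels[i]`` is 0 for the low cluster.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateMarkerError("need at least two values")
    if np.unique(x).size < 2:
        raise DegenerateMarkerError("all values identical")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs * xs)
    total, total2 = csum[-1], csum2[-1]

    k = np.arange(1, n)  # size of the left cluster
    left_sum = csum[:-1]
    left_sum2 = csum2[:-1]
    sse_left = left_sum2 - left_sum**2 / k
    right_sum = total - left_sum
    sse_right = (total2 - left_sum2) - right_sum**2 / (n - k)
    sse = sse_left + sse_right

    best = int(np.argmin(sse))  # first minimum on ties
    k_best = best + 1
    mean_low = csum[best] / k_best
    mean_high = (total - csum[best]) / (n - k_best)
    split_value = 0.5 * (mean_low + mean_high)

    labels_sorted = np.ones(n, dtype=int)
    labels_sorted[:k_best] = 0
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return float(split_value), labels, (float(mean_low), float(mean_high))


@dataclass
class GaussianMixture1D:
    """Two-component univariate Gaussian mixture fitted by EM.

    Components are ordered so that ``means[0] <= means[1]``.  ``trace`` holds
    the log-likelihood after every EM iteration (non-decreasing).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iter: int
    trace: list[float] = field(default_factory=list, repr=False)


def gmm2_fit(x) -> GaussianMixture1D:
    """Fit a 2-component univariate Gaussian mixture by EM.

    Initialisation comes from :func:`kmeans1d_exact`, so the fit is fully
    deterministic for a given input vector.  EM stops when the
    log-likelihood improves by less than 1e-6 or after 500 iterations; the
    component variances are floored at 1e-8 to keep point masses finite.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 4:
        raise DegenerateMarkerError("need at least 4 distinct values for GMM")

    _, labels, (m_low, m_high) = kmeans1d_exact(x)
    n = x.size
    mask = labels == 0
    w = np.array([mask.mean(), 1.0 - mask.mean()])
    mu = np.array([m_low, m_high])
    var = np.array(
        [
            max(np.var(x[mask]), _VARIANCE_FLOOR),
            max(np.var(x[~mask]), _VARIANCE_FLOOR),
        ]
    )

    trace: list[float] = []
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, _EM_MAX_ITER + 1):
        # E step in log space for numerical safety with floored variances
        log_comp = np.log(w)[:, None] + stats.norm.logpdf(
            x[None, :], loc=mu[:, None], scale=np.sqrt(var)[:, None]
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        if ll - prev_ll < _EM_TOL:
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm[None, :])
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x * x)) / nk - mu**2
        var = np.maximum(var, _VARIANCE_FLOOR)

    if mu[0] > mu[1]:  # relabel so component 0 is the low mode
        w, mu, var = w[::-1], mu[::-1], var[::-1]
    return GaussianMixture1D(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(math.sqrt(var[0])), float(math.sqrt(var[1]))),
        log_likelihood=trace[-1],
        n_iter=n_iter,
        trace=trace,
    )


def threshold_from_gmm(g: GaussianMixture1D) -> float:
    """Decision boundary of a fitted two-component mixture.

    Solves ``w1 N(x; mu1, sd1) = w2 N(x; mu2, sd2)`` (a quadratic in x after
    taking logs) and returns the root strictly between the two means; when no
    real root lies in that open interval the midpoint of the means is used.
    """
    (w1, w2), (mu1, mu2), (s1, s2) = g.weights, g.means, g.sds
    if mu1 >= mu2:
        raise DegenerateMarkerError("mixture means are not separated")
    midpoint = 0.5 * (mu1 + mu2)

    v1, v2 = s1 * s1, s2 * s2
    a = 0.5 / v2 - 0.5 / v1
    b = mu1 / v1 - mu2 / v2
    c = 0.5 * mu2 * mu2 / v2 - 0.5 * mu1 * mu1 / v1 + math.log(
        (w1 * s2) / (w2 * s1)
    )

    roots: list[float] = []
    if abs(a) < 1e-300:
        if b != 0.0:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    return float(inside[0]) if inside else float(midpoint)


def silhouette_binary(x, labels) -> float:
    """Mean silhouette width of a binary partition of a 1D vector.

    Uses the usual per-point width ``s = (b - a) / max(a, b)`` with
    Euclidean (absolute-difference) distances; points in a singleton group
    get ``s = 0``, as do points with ``a = b = 0``.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.shape != labels.shape:
        raise ValueError("x and labels must have the same shape")
    groups = np.unique(labels)
    if groups.size != 2:
        raise UndefinedSilhouetteError(
            f"expected exactly 2 non-empty groups, got {groups.size}"
        )
    in_g1 = labels == groups[1]
    n0 = int((~in_g1).sum())
    n1 = int(in_g1.sum())

    dist = np.abs(x[:, None] - x[None, :])
    sum0 = dist[:, ~in_g1].sum(axis=1)
    sum1 = dist[:, in_g1].sum(axis=1)

    s = np.zeros(x.size)
    for own_mask, n_own, sum_own, sum_other, n_other in (
        (~in_g1, n0, sum0, sum1, n1),
        (in_g1, n1, sum1, sum0, n0),
    ):
        if n_own == 1:
            continue  # singleton convention: s stays 0
        a = sum_own[own_mask] / (n_own - 1)
        b = sum_other[own_mask] / n_other
        denom = np.maximum(a, b)
        nonzero = denom > 0
        s_own = np.zeros(n_own)
        s_own[nonzero] = (b[nonzero] - a[nonzero]) / denom[nonzero]
        s[own_mask] = s_own
    return float(s.mean())


def bimodality_coefficient(x) -> float:
    """Sarle's sample-adjusted bimodality coefficient.

    ``BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))`` with ``g1`` the
    bias-corrected sample skewness and ``g2`` the bias-corrected excess
    kurtosis.  Uniform samples give about 5/9 (the usual cutoff), normal
    samples about 1/3, a balanced two-point mass approaches 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise DegenerateMarkerError("bimodality coefficient needs n >= 4")
    if np.unique(x).size < 2:
        raise DegenerateMarkerError("constant vector")
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, fisher=True, bias=False))
    correction = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return (g1 * g1 + 1.0) / (g2 + correction)


def _flag_bimodal(bc: float, config: ThresholdConfig) -> bool:
    if math.isnan(bc):
        return False
    if config.bimodality_direction == "gt":
        return bc > config.bimodality_cutoff
    return bc < config.bimodality_cutoff


def estimate_threshold(
    x, marker: str = "", config: ThresholdConfig | None = None
) -> MarkerThreshold:
    """Estimate the low/high threshold of one marker vector.

    Both candidate thresholds (exact two-means boundary and GMM density
    crossing) are computed, each induces the binary partition
    ``x <= t`` / ``x > t``, and the method whose partition has the strictly
    higher mean silhouette wins; ties go to k-means.  The bimodality
    coefficient and flag are attached as diagnostics.
    """
    config = config or ThresholdConfig()
    x = np.asarray(x, dtype=float)

    split_km, _, _ = kmeans1d_exact(x)  # raises on constant input
    candidates: dict[str, float] = {"kmeans": split_km}
    try:
        candidates["gmm"] = threshold_from_gmm(gmm2_fit(x))
    except DegenerateMarkerError:
        logger.debug("marker %s: GMM degenerate, k-means only", marker)

    silhouettes: dict[str, float] = {}
    for method, t in candidates.items():
        part = (x > t).astype(int)
        try:
            silhouettes[method] = silhouette_binary(x, part)
        except UndefinedSilhouetteError:
            logger.debug("marker %s: %s partition one-sided", marker, method)

    sil_km = silhouettes.get("kmeans", math.nan)
    sil_gmm = silhouettes.get("gmm", math.nan)
    if not silhouettes:
        warnings.warn(
            f"marker {marker!r}: no candidate threshold induces a valid "
            "binary partition; falling back to the k-means split",
            stacklevel=2,
        )
        method = "kmeans"
    elif "gmm" in silhouettes and (
        "kmeans" not in silhouettes or sil_gmm > sil_km
    ):
        method = "gmm"
    else:
        method = "kmeans"

    try:
        bc = bimodality_coefficient(x)
    except DegenerateMarkerError:
        bc = math.nan
    return MarkerThreshold(
        marker=marker,
        threshold=candidates[method],
        method=method,
        silhouette_kmeans=sil_km,
        silhouette_gmm=sil_gmm,
        bimodality_coefficient=bc,
        is_bimodal=_flag_bimodal(bc, config),
    )


def estimate_thresholds(
    expression,
    config: ThresholdConfig | None = None,
    existing: ThresholdTable | None = None,
    overwrite_manual: bool = False,
) -> ThresholdTable:
    """Estimate thresholds for every non-constant marker of a panel.

    ``expression`` is a :class:`annosom.io.ClusterExpressionMatrix`; the
    normalised values are used.  Constant markers are skipped with a
    warning.  When ``existing`` is given and ``overwrite_manual`` is False,
    markers carrying a manual override keep their manual value.
    """
    table = ThresholdTable()
    skipped = list(expression.constant_markers)
    if skipped:
        warnings.warn(
            f"constant markers excluded from threshold estimation: {skipped}",
            stacklevel=2,
        )
    for marker in expression.marker_names:
        if marker in skipped:
            continue
        if (
            existing is not None
            and not overwrite_manual
            and marker in existing
            and existing[marker].manual
        ):
            table.add(replace(existing[marker]))
            continue
        x = expression.normalized[marker].to_numpy()
        table.add(estimate_threshold(x, marker=marker, config=config))
    logger.info("estimated thresholds for %d markers", len(table))
    return table


def set_manual_threshold(
    table: ThresholdTable, marker: str, value: float
) -> ThresholdTable:
    """Override one marker's threshold with a user-chosen value.

    The entry keeps its estimation diagnostics but switches
    ``method='manual'`` and sets the ``manual`` flag, which protects it from
    re-estimation unless explicitly overwritten.
    """
    if not 0.0 <= value <= 1.0:
        raise RangeError(f"threshold {value} outside [0, 1]")
    old = table[marker]  # KeyError on unknown marker
    table.add(replace(old, threshold=float(value), method="manual", manual=True))
    return table


def thresholds_as_mapping(table: ThresholdTable) -> Mapping[str, float]:
    """Plain marker -> threshold value view of a table."""
    return {m: table[m].threshold for m in table}
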