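"""Betti-0 curves of the Rips filtration and their scalar features.

Sweeping the filtration value eps from 0 upward, an edge (i, j) exists once
d[i, j] <= eps; the zeroth Betti number B0(eps) is the number of connected
components of that threshold graph.  B0 starts at the node count n, is
non-increasing and right-continuous, and reaches 1 once the graph is
connected.  The n - 1 filtration values at which two components merge
determine the whole curve; they equal the sorted edge weights of a minimum
spanning tree (single-linkage dendrogram heights).

Each curve is summarised by three scalars:

* ``auc`` — the exact integral of the step function over the fixed domain
  [0, 2] (the full range of d = 1 - r).  Smaller area means the network
  collapses into one component at lower thresholds, i.e. less segregation.
* ``slope`` — the least-squares rate of change of B0 against eps, sampled at
  eps = 0 and at every merge value.  Always negative for n >= 2.
* ``kurtosis`` — excess kurtosis (m4/m2^2 - 3) of the merge-value
  distribution; higher values mean the merges concentrate around their mean,
  a sharper transition to a single component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectivityMatrix, DistanceMatrix, to_distance

#: Fixed integration domain for the AUC: the full range of d = 1 - r.
AUC_DOMAIN = (0.0, 2.0)


class DegenerateCurveError(ValueError):
    """Raised when a curve feature is undefined (too few or tied merges)."""


@dataclass(frozen=True)
class B0Curve:
    """A Betti-0 curve in merge-value form.

    ``merge_values`` holds the n - 1 filtration values at which two
    components join, sorted non-decreasing, each in [0, 2].  The step
    function is B0(eps) = n - #{m in merge_values : m <= eps}.
    """

    n: int
    merge_values: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.merge_values, dtype=float).ravel()
        if self.n < 1:
            raise ValueError("node count must be >= 1")
        if m.size != self.n - 1:
            raise ValueError(f"expected {self.n - 1} merge values, got {m.size}")
        if m.size and (np.any(np.diff(m) < 0) or m[0] < 0 or m[-1] > 2):
            raise ValueError("merge values must be sorted and within [0, 2]")
        m.flags.writeable = False
        object.__setattr__(self, "merge_values", m)


@dataclass(frozen=True)
class CurveFeatures:
    """The (AUC, slope, kurtosis) summary of one Betti-0 curve."""

    auc: float
    slope: float
    kurtosis: float


class _UnionFind:
    """Disjoint sets with path compression and union by rank."""

    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.rank[ri] < self.rank[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        if self.rank[ri] == self.rank[rj]:
            self.rank[ri] += 1
        return True


def b0_curve(dm: DistanceMatrix) -> B0Curve:
    """Component-merge values of the Rips filtration on a distance matrix.

    Kruskal's scan: edges in ascending weight (ties broken by (i, j) index,
    which cannot change B0, only which edge is recorded as the merger); each
    component-joining edge contributes its weight as a merge value.
    """
    d = dm.d
    n = dm.n
    if n == 1:
        return B0Curve(1, np.empty(0))
    iu, ju = np.triu_indices(n, k=1)
    w = d[iu, ju]
    order = np.lexsort((ju, iu, w))  # weight first, then (i, j) for stable ties
    uf = _UnionFind(n)
    merges = np.empty(n - 1)
    got = 0
    for e in order:
        if uf.union(int(iu[e]), int(ju[e])):
            merges[got] = w[e]
            got += 1
            if got == n - 1:
                break
    return B0Curve(n, merges)


def b0_at(curve: B0Curve, eps: float) -> int:
    """Number of components at filtration value eps (edge rule d <= eps)."""
    if eps < 0:
        raise ValueError("filtration value must be non-negative")
    return int(curve.n - np.searchsorted(curve.merge_values, eps, side="right"))


def curve_breakpoints(curve: B0Curve, domain=AUC_DOMAIN) -> pd.DataFrame:
    """Step-function representation: one row per breakpoint (epsilon, b0)."""
    lo, hi = domain
    eps = np.concatenate(([lo], curve.merge_values, [hi]))
    b0 = [b0_at(curve, float(e)) for e in eps]
    return pd.DataFrame({"epsilon": eps, "b0": b0})


def auc(curve: B0Curve, domain=AUC_DOMAIN) -> float:
    """Exact integral of the B0 step function over the fixed domain.

    The right-continuous step function is summed piecewise:
    sum_k (t_{k+1} - t_k) * B0(t_k) over merge-value breakpoints augmented
    with the domain endpoints.  Using one fixed domain for every subject and
    node subset keeps areas comparable across subjects: the flat tail after
    the final merge adds the same constant to everyone.
    """
    lo, hi = domain
    m = curve.merge_values
    t = np.concatenate(([lo], np.clip(m, lo, hi), [hi]))
    # B0 on [t_k, t_{k+1}) equals n - (number of merges <= t_k)
    b0 = curve.n - np.searchsorted(m, t[:-1], side="right")
    return float(np.sum(np.diff(t) * b0))


def slope(curve: B0Curve) -> float:
    """Ordinary least-squares slope of B0 against eps over the staircase.

    The curve is sampled at eps = 0 and at each merge value (inclusive of
    ties, so repeated merge values weight the fit); the OLS slope of those
    n points is the curve's rate of change, negative whenever the merges
    are not all at zero.
    """
    if curve.n < 2:
        raise DegenerateCurveError("slope needs at least 2 nodes")
    x = np.concatenate(([0.0], curve.merge_values))
    y = curve.n - np.searchsorted(curve.merge_values, x, side="right").astype(float)
    if np.ptp(x) == 0:
        raise DegenerateCurveError("all merges at eps = 0; slope undefined")
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def kurtosis_feature(curve: B0Curve) -> float:
    """Excess kurtosis (Fisher, bias-uncorrected m4/m2^2 - 3) of the merges."""
    m = curve.merge_values
    if m.size < 4:
        raise DegenerateCurveError("kurtosis needs at least 4 merge values")
    if np.ptp(m) == 0:
        raise DegenerateCurveError("merge values have zero variance")
    return float(stats.kurtosis(m, fisher=True, bias=True))


def features(dm: DistanceMatrix | ConnectivityMatrix) -> CurveFeatures:
    """AUC, slope and kurtosis of the Betti-0 curve of one connectome."""
    if isinstance(dm, ConnectivityMatrix):
        dm = to_distance(dm)
    curve = b0_curve(dm)
    return CurveFeatures(auc(curve), slope(curve), kurtosis_feature(curve))


FEATURE_NAMES = ("auc", "slope", "kurtosis")


class BettiVectorizer:
    """Transformer mapping connectomes to (AUC, slope, kurtosis) vectors.

    scikit-learn compatible: ``fit`` is stateless validation, ``transform``
    accepts a list of ``ConnectivityMatrix``/``DistanceMatrix`` objects or a
    stacked (n_subjects, n, n) array of correlations and returns an
    (n_subjects, 3) array in FEATURE_NAMES order.

    Parameters
    ----------
    domain : (float, float)
        Integration domain of the AUC; default the full d = 1 - r range.
    """

    def __init__(self, domain=AUC_DOMAIN):
        self.domain = domain

    def get_params(self, deep=True):
        return {"domain": self.domain}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        dms = [self._coerce(x) for x in X]
        out = np.empty((len(dms), 3))
        for i, dm in enumerate(dms):
            curve = b0_curve(dm)
            out[i] = (
                auc(curve, self.domain),
                slope(curve),
                kurtosis_feature(curve),
            )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    @staticmethod
    def _coerce(x) -> DistanceMatrix:
        if isinstance(x, DistanceMatrix):
            return x
        if isinstance(x, ConnectivityMatrix):
            return to_distance(x)
        return to_distance(ConnectivityMatrix(None, np.asarray(x, dtype=float)))


def features_table(connectomes, subject_ids=None, domain=AUC_DOMAIN) -> pd.DataFrame:
    """Per-subject feature table with columns subject_id, auc, slope, kurtosis."""
    arr = BettiVectorizer(domain=domain).fit_transform(connectomes)
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, columns=list(FEATURE_NAMES))
    df.insert(0, "subject_id", [str(s) for s in subject_ids])
    return df
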