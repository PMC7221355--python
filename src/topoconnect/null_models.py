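"""Weighted rewiring null models for Betti-0 curve features.

A rewired surrogate keeps every observed correlation value but relocates it
to a random edge, destroying the community topology while conserving the
weight multiset exactly (hence all moments of the weight distribution).
Comparing observed curve features with the rewired ensemble asks whether a
feature reflects the network's topology or merely its weight histogram.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .betti import FEATURE_NAMES, BettiVectorizer
from .connectome import ConnectivityMatrix

#: Number of random transpositions per edge in a single rewiring pass.
SWAPS_PER_EDGE = 10


def _upper(n: int):
    return np.triu_indices(n, k=1)


def rewire(
    cm: ConnectivityMatrix, seed=None, mode: str = "transpositions"
) -> ConnectivityMatrix:
    """One rewired surrogate of a connectome.

    Off-diagonal weights are permuted over the edge positions of the
    complete graph; symmetry and the unit diagonal are preserved, and the
    sorted weight multiset is exactly conserved.

    ``mode='transpositions'`` applies a seeded sequence of 10 * E random
    pairwise swaps of upper-triangle entries (E = n(n-1)/2), each mirrored
    to the lower triangle — the weighted-rewiring analogue of edge-swap
    randomisation, which on a complete weighted graph amounts to shuffling
    weights over edges.  ``mode='shuffle'`` draws one uniform permutation
    directly; the two are statistically equivalent and 'shuffle' is faster.
    """
    if cm.n < 3:
        raise ValueError("rewiring needs at least 3 nodes")
    rng = np.random.default_rng(seed)
    iu, ju = _upper(cm.n)
    w = cm.r[iu, ju]
    e = w.size
    if mode == "shuffle":
        perm = rng.permutation(e)
    elif mode == "transpositions":
        perm = np.arange(e)
        pairs = rng.integers(0, e, size=(SWAPS_PER_EDGE * e, 2))
        for a, b in pairs:
            perm[a], perm[b] = perm[b], perm[a]
    else:
        raise ValueError(f"unknown rewiring mode {mode!r}")
    out = np.eye(cm.n)
    out[iu, ju] = w[perm]
    out[ju, iu] = w[perm]
    return ConnectivityMatrix(list(cm.node_ids), out)


class RewiringNull:
    """Ensemble of curve features from rewired surrogates of one connectome.

    Estimator-style interface: construct with the ensemble parameters, call
    ``fit(cm)``, then read ``features_`` (an n_perm x 3 DataFrame in
    permutation order).  Per-permutation seeds are spawned from the master
    seed by counter, so the ensemble is reproducible bit-for-bit and
    permutations could be evaluated in any order or in parallel.

    Parameters
    ----------
    n_perm : int
        Ensemble size; 1000 by default, matching common practice of one
        thousand rewirings per subject.
    random_state : int or None
        Master seed for the surrogate sequence.
    mode : str
        Rewiring scheme passed to :func:`rewire`.
    """

    def __init__(self, n_perm: int = 1000, random_state=None, mode: str = "transpositions"):
        self.n_perm = n_perm
        self.random_state = random_state
        self.mode = mode

    def get_params(self, deep=True):
        return {
            "n_perm": self.n_perm,
            "random_state": self.random_state,
            "mode": self.mode,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, cm: ConnectivityMatrix, y=None):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if isinstance(self.random_state, np.random.SeedSequence):
            master = self.random_state
        else:
            master = np.random.SeedSequence(self.random_state)
        vec = BettiVectorizer()
        rows = np.empty((self.n_perm, 3))
        for i in range(self.n_perm):
            # counter-based sub-seed: permutation i is order-independent
            sub = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(*master.spawn_key, i)
            )
            surrogate = rewire(cm, seed=sub, mode=self.mode)
            rows[i] = vec.transform([surrogate])[0]
        self.features_ = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
        return self


def null_features(
    cm: ConnectivityMatrix, n_perm: int, seed=None, mode: str = "transpositions"
) -> pd.DataFrame:
    """Feature table of ``n_perm`` independent rewirings (see RewiringNull)."""
    return RewiringNull(n_perm=n_perm, random_state=seed, mode=mode).fit(cm).features_


def empirical_p(
    observed: float,
    ensemble,
    feature: str | None = None,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value of an observed feature against a null ensemble.

    Uses the add-one rule p = (1 + #{null at least as extreme}) / (1 + n),
    so p never falls below 1/(1 + n_perm).  ``ensemble`` may be a
    RewiringNull, its ``features_`` DataFrame, or a plain array of null
    values; ``feature`` selects the column when a table is given.
    'two-sided' doubles the smaller one-sided p (capped at 1).
    """
    if isinstance(ensemble, RewiringNull):
        ensemble = ensemble.features_
    if isinstance(ensemble, pd.DataFrame):
        if feature is None:
            raise ValueError("feature name required with a feature table")
        if feature not in ensemble.columns:
            raise ValueError(
                f"unknown feature {feature!r}; expected one of {list(ensemble.columns)}"
            )
        null = ensemble[feature].to_numpy()
    else:
        null = np.asarray(ensemble, dtype=float).ravel()
    if null.size == 0:
        raise ValueError("empty null ensemble")
    n = null.size
    p_greater = (1 + np.sum(null >= observed)) / (1 + n)
    p_less = (1 + np.sum(null <= observed)) / (1 + n)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative {alternative!r}")
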