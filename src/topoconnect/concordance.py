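"""Kendall's coefficient of concordance (W) across parcellations.

When the same subjects are measured under several parcellations, each
parcellation acts as a "rater" ranking the subjects by a curve feature;
Kendall's W in [0, 1] quantifies how well the rankings agree.  Under the
null of independent rankings, m(n-1)W is approximately chi-square with
n - 1 degrees of freedom, which also yields the smallest W significant at a
given level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class KCCResult:
    """Kendall's W with its chi-square test."""

    w: float
    m: int  # raters (parcellations)
    n: int  # subjects
    chi2: float
    df: int
    p: float


def kendalls_w(ratings) -> KCCResult:
    """Kendall's W of an m-raters x n-subjects table, with tie correction.

    Ranks are computed within each rater with mid-ranks for ties;
    W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i), where S is the sum of squared
    deviations of the subject rank sums and T_i = sum over tie groups of
    (t^3 - t) for rater i.  The chi-square statistic is m (n - 1) W on
    n - 1 degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D m x n table")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 raters")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing values")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise ValueError("all ratings tied within every rater; W undefined")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    return KCCResult(w=float(w), m=m, n=n, chi2=float(chi2), df=df, p=float(stats.chi2.sf(chi2, df)))


def kendalls_w_permutation_p(ratings, n_perm: int = 999, seed=None) -> float:
    """Permutation p-value for W (each rater's ranking permuted independently).

    An exact-style alternative to the chi-square approximation for small n,
    using the add-one rule.
    """
    x = np.asarray(ratings, dtype=float)
    obs = kendalls_w(x).w
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.vstack([rng.permutation(row) for row in x])
        if kendalls_w(perm).w >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def kcc_critical(m: int, n: int, alpha: float = 0.05) -> float:
    """Smallest W significant at ``alpha`` under the chi-square approximation.

    W* = chi2_{1-alpha, n-1} / (m (n - 1)).
    """
    if m < 2:
        raise ValueError("need at least 2 raters")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.chi2.ppf(1 - alpha, n - 1) / (m * (n - 1)))


def pairwise_kcc(feature_tables: dict[str, pd.DataFrame], features=None) -> pd.DataFrame:
    """Two-rater W for every unordered pair of parcellations and feature.

    ``feature_tables`` maps parcellation name to a per-subject feature table
    (columns subject_id, auc, slope, kurtosis).  All tables must cover the
    same subjects; rows are aligned by subject_id.  Returns a long-form
    table (feature, parcellation_a, parcellation_b, w, chi2, df, p).
    """
    if len(feature_tables) < 2:
        raise ValueError("need at least 2 parcellations")
    names = sorted(feature_tables)
    base = feature_tables[names[0]].set_index("subject_id").sort_index()
    aligned = {names[0]: base}
    for name in names[1:]:
        t = feature_tables[name].set_index("subject_id").sort_index()
        if list(t.index) != list(base.index):
            raise ValueError(f"subject mismatch between {names[0]!r} and {name!r}")
        aligned[name] = t
    if features is None:
        features = [c for c in ("auc", "slope", "kurtosis") if c in base.columns]
    rows = []
    for feat in features:
        for a, b in combinations(names, 2):
            res = kendalls_w(
                np.vstack([aligned[a][feat].to_numpy(), aligned[b][feat].to_numpy()])
            )
            rows.append(
                dict(
                    feature=feat,
                    parcellation_a=a,
                    parcellation_b=b,
                    w=res.w,
                    chi2=res.chi2,
                    df=res.df,
                    p=res.p,
                )
            )
    return pd.DataFrame(rows)
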