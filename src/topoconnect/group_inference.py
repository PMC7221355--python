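"""Diagnostic-group inference on Betti-0 curve features.

The whole-brain model is a logistic regression of diagnostic group on the
three curve features plus nuisance covariates,

    group ~ auc + kurtosis + slope + sex + age + motion

with dimensional terms standardised to z scores over the analysis sample, so
each odds ratio is per standard deviation.  The same model is re-fitted on
every intranetwork and internetwork node subset of a partition; clusters of
significant subsets on the network-of-networks graph are assigned
family-wise-error-corrected p-values by permuting diagnostic labels
(network-based-statistic style).  Edge-level contrasts compare, per edge,
the proportion of subjects in whom the edge is present at a filtration
threshold.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .betti import AUC_DOMAIN, BettiVectorizer, FEATURE_NAMES
from .connectome import (
    ConnectivityMatrix,
    DistanceMatrix,
    Partition,
    enumerate_subnetworks,
    subset,
    to_distance,
)

MODEL_TERMS = ("auc", "kurtosis", "slope", "sex", "age", "motion")
DIMENSIONAL_TERMS = ("auc", "kurtosis", "slope", "age", "motion")
DEFAULT_EPS_LIST = (0.35, 0.5, 0.75, 1.0)


def zscore_features(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardise dimensional columns to mean 0, sample SD 1.

    Binary columns (and any column not listed) are left untouched.  The
    standardisation uses the full analysis sample, once, so subnetwork
    models share the covariate scaling.
    """
    if columns is None:
        columns = [c for c in DIMENSIONAL_TERMS if c in table.columns]
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


class GroupLogisticRegression:
    """Maximum-likelihood logistic regression with per-term odds ratios.

    A thin estimator around the standard ML logistic fit exposing, per model
    term, the log-odds ``params_``, odds ratios ``odds_ratios_``, Wald 95%
    confidence bounds ``conf_int_`` (odds-ratio scale) and two-sided Wald
    p-values ``pvalues_``.  Separation or non-convergence is flagged on
    ``converged_`` rather than raised, with NaN inference results.

    Parameters
    ----------
    alpha : float
        Size of the Wald confidence interval (default 0.05 -> 95% CI).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.isna().any().any():
            bad = X.columns[X.isna().any()][0]
            raise ValueError(f"missing values in covariate {bad!r}")
        if len(np.unique(y)) != 2:
            raise ValueError("outcome must be binary with both groups present")
        self.terms_ = list(X.columns)
        self.n_cases_ = int(y.sum())
        self.n_controls_ = int(len(y) - y.sum())
        design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        names = ["const"] + self.terms_
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = None
            converged = False
        if res is not None and np.isfinite(res.bse).all():
            self.params_ = pd.Series(res.params, index=names)
            self.bse_ = pd.Series(res.bse, index=names)
            self.pvalues_ = pd.Series(res.pvalues, index=names)
            ci = res.conf_int(alpha=self.alpha)
            with np.errstate(over="ignore"):
                self.conf_int_ = pd.DataFrame(
                    np.exp(ci), index=names, columns=["ci_low", "ci_high"]
                )
            self.result_ = res
        else:
            nan = pd.Series(np.nan, index=names)
            self.params_, self.bse_, self.pvalues_ = nan, nan.copy(), nan.copy()
            self.conf_int_ = pd.DataFrame(
                np.nan, index=names, columns=["ci_low", "ci_high"]
            )
            self.result_ = res
            converged = False
        with np.errstate(over="ignore"):
            self.odds_ratios_ = np.exp(self.params_)
        self.converged_ = converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        design = sm.add_constant(
            pd.DataFrame(X).to_numpy(dtype=float), has_constant="add"
        )
        eta = design @ self.params_.to_numpy()
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def summary_frame(self) -> pd.DataFrame:
        """One row per term: beta, OR, Wald CI bounds, p."""
        return pd.DataFrame(
            {
                "term": self.params_.index,
                "beta": self.params_.to_numpy(),
                "or": self.odds_ratios_.to_numpy(),
                "ci_low": self.conf_int_["ci_low"].to_numpy(),
                "ci_high": self.conf_int_["ci_high"].to_numpy(),
                "p": self.pvalues_.to_numpy(),
            }
        ).reset_index(drop=True)


def fit_group_model(
    features: pd.DataFrame, phenotypes: pd.DataFrame
) -> GroupLogisticRegression:
    """Fit group ~ auc + kurtosis + slope + sex + age + motion.

    ``features`` has columns subject_id, auc, slope, kurtosis; it is merged
    with the phenotype table by subject_id.  Dimensional terms are z-scored
    over the full sample; sex stays a raw binary indicator.
    """
    missing = [c for c in ("sex", "age", "motion", "group") if c not in phenotypes]
    if missing:
        raise ValueError(f"phenotypes missing column(s): {', '.join(missing)}")
    merged = features.merge(phenotypes, on="subject_id", how="inner", validate="1:1")
    if len(merged) < len(features) or len(merged) < len(phenotypes):
        raise ValueError("subject_id mismatch between features and phenotypes")
    if len(merged) < 20:
        raise ValueError(f"need at least 20 subjects, got {len(merged)}")
    merged = zscore_features(merged)
    X = merged[list(MODEL_TERMS)]
    return GroupLogisticRegression().fit(X, merged["group"])


# ---------------------------------------------------------------------------
# Subnetwork scan with cluster-level permutation FWE
# ---------------------------------------------------------------------------


def _cell_name(labels: tuple[str, ...]) -> str:
    return labels[0] if len(labels) == 1 else f"{labels[0]}-{labels[1]}"


def _clusters_of(sig_labels: list[tuple[str, ...]]) -> list[list[tuple[str, ...]]]:
    """Connected clusters of significant cells on the network-of-networks graph.

    Networks are vertices; a significant internetwork cell is an edge, a
    significant intranetwork cell a self-loop (contributing its vertex).
    Clusters are the connected components; each significant cell belongs to
    the unique component containing its network(s).
    """
    g = nx.Graph()
    for labs in sig_labels:
        if len(labs) == 1:
            g.add_node(labs[0])
        else:
            g.add_edge(labs[0], labs[1])
    clusters = []
    for comp in nx.connected_components(g):
        cells = [labs for labs in sig_labels if set(labs) <= comp]
        clusters.append(sorted(cells))
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


class SubnetworkScanner:
    """Re-fit the group model on every intra-/internetwork node subset.

    For a partition with k networks there are k(k+1)/2 subsets (k single
    networks plus all unordered pairs, each pair taken as the union of both
    networks' nodes).  Curve features are recomputed on each subset's
    principal submatrix and entered into the same logistic model; the
    AUC-term odds ratio and Wald p are recorded per cell.  With
    ``n_perm > 0``, cells significant at ``alpha_cell`` are clustered on the
    network graph and the maximal cluster size under diagnostic-label
    permutation (covariates stay attached to their subjects) yields
    family-wise-error-corrected cluster p-values.

    Fitted attributes: ``cells_`` (per-cell table), ``clusters_`` (list of
    cell-label lists), ``p_fwe_`` (per-cluster p), ``null_max_`` (the
    permutation distribution of the maximal cluster size).
    """

    def __init__(
        self,
        alpha_cell: float = 0.05,
        n_perm: int = 0,
        random_state=None,
        min_nodes: int = 5,
        domain=AUC_DOMAIN,
    ):
        self.alpha_cell = alpha_cell
        self.n_perm = n_perm
        self.random_state = random_state
        self.min_nodes = min_nodes
        self.domain = domain

    def get_params(self, deep=True):
        return {
            "alpha_cell": self.alpha_cell,
            "n_perm": self.n_perm,
            "random_state": self.random_state,
            "min_nodes": self.min_nodes,
            "domain": self.domain,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, connectomes, y, partition: Partition, covariates: pd.DataFrame):
        """Scan all subsets.

        ``connectomes``: sequence of ConnectivityMatrix sharing node order;
        ``y``: binary group per subject; ``covariates``: DataFrame with
        sex, age, motion per subject (same order as connectomes).
        """
        y = np.asarray(y, dtype=float).ravel()
        cov = covariates.reset_index(drop=True)[["sex", "age", "motion"]]
        cov = zscore_features(cov, columns=["age", "motion"])
        subsets = enumerate_subnetworks(partition)
        vec = BettiVectorizer(domain=self.domain)

        cell_feats: dict[tuple[str, ...], pd.DataFrame | None] = {}
        rows = []
        for labels, nodes in subsets:
            if len(nodes) < self.min_nodes:
                cell_feats[labels] = None
                rows.append(
                    dict(cell=_cell_name(labels), n_nodes=len(nodes), evaluable=False)
                )
                continue
            try:
                feats = vec.transform([subset(c, nodes) for c in connectomes])
                fdf = zscore_features(
                    pd.DataFrame(feats, columns=list(FEATURE_NAMES)),
                    columns=list(FEATURE_NAMES),
                )
            except ValueError:
                cell_feats[labels] = None
                rows.append(
                    dict(cell=_cell_name(labels), n_nodes=len(nodes), evaluable=False)
                )
                continue
            cell_feats[labels] = fdf
            or_auc, p_auc = self._fit_cell(fdf, cov, y)
            rows.append(
                dict(
                    cell=_cell_name(labels),
                    n_nodes=len(nodes),
                    evaluable=True,
                    or_auc=or_auc,
                    p_auc=p_auc,
                )
            )
        cells = pd.DataFrame(rows)
        if "p_auc" in cells:
            cells["significant"] = cells["p_auc"].lt(self.alpha_cell).fillna(False)
        else:
            cells["or_auc"] = np.nan
            cells["p_auc"] = np.nan
            cells["significant"] = False
        self._subset_labels = [labels for labels, _ in subsets]
        self._cell_feats = cell_feats
        sig = [
            labels
            for labels, row in zip(self._subset_labels, cells.itertuples())
            if row.significant
        ]
        self.clusters_ = _clusters_of(sig)
        self.cells_ = cells
        self.p_fwe_ = []
        self.null_max_ = None
        if self.n_perm > 0:
            self._permute_fwe(y, cov)
        self._attach_clusters()
        return self

    def _fit_cell(self, fdf: pd.DataFrame, cov: pd.DataFrame, y) -> tuple[float, float]:
        X = pd.concat([fdf.reset_index(drop=True), cov], axis=1)[list(MODEL_TERMS)]
        model = GroupLogisticRegression().fit(X, y)
        if not model.converged_:
            return np.nan, np.nan
        return float(model.odds_ratios_["auc"]), float(model.pvalues_["auc"])

    def _permute_fwe(self, y, cov):
        if 1.0 / (1 + self.n_perm) > self.alpha_cell:
            warnings.warn(
                f"n_perm={self.n_perm} cannot resolve alpha={self.alpha_cell}",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        null_max = np.zeros(self.n_perm, dtype=int)
        for b in range(self.n_perm):
            yb = rng.permutation(y)
            sig = []
            for labels in self._subset_labels:
                fdf = self._cell_feats[labels]
                if fdf is None:
                    continue
                _, p = self._fit_cell(fdf, cov, yb)
                if np.isfinite(p) and p < self.alpha_cell:
                    sig.append(labels)
            clusters = _clusters_of(sig)
            null_max[b] = max((len(c) for c in clusters), default=0)
        self.null_max_ = null_max
        self.p_fwe_ = [
            float((1 + np.sum(null_max >= len(c))) / (1 + self.n_perm))
            for c in self.clusters_
        ]

    def _attach_clusters(self):
        cells = self.cells_
        cells["cluster"] = pd.array([pd.NA] * len(cells), dtype="Int64")
        cells["p_fwe"] = np.nan
        name_to_pos = {c: i for i, c in enumerate(cells["cell"])}
        for ci, cluster in enumerate(self.clusters_):
            for labs in cluster:
                pos = name_to_pos[_cell_name(labs)]
                cells.loc[pos, "cluster"] = ci
                if self.p_fwe_:
                    cells.loc[pos, "p_fwe"] = self.p_fwe_[ci]


def subnetwork_scan(
    connectomes,
    partition: Partition,
    phenotypes: pd.DataFrame,
    alpha_cell: float = 0.05,
    n_perm: int = 0,
    seed=None,
) -> SubnetworkScanner:
    """Run the subnetwork scan from a phenotype table (see SubnetworkScanner)."""
    return SubnetworkScanner(
        alpha_cell=alpha_cell, n_perm=n_perm, random_state=seed
    ).fit(
        connectomes,
        phenotypes["group"].to_numpy(),
        partition,
        phenotypes[["sex", "age", "motion"]],
    )


def fwe_correct(
    scan: SubnetworkScanner, phenotypes: pd.DataFrame, n_perm: int, seed=None
) -> SubnetworkScanner:
    """Add cluster-level permutation FWE p-values to a completed scan.

    ``phenotypes`` must carry group, sex, age and motion in the subject
    order the scan was fitted with.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null distribution")
    scan.n_perm = n_perm
    scan.random_state = seed
    cov = phenotypes.reset_index(drop=True)[["sex", "age", "motion"]]
    cov = zscore_features(cov, columns=["age", "motion"])
    scan._permute_fwe(phenotypes["group"].to_numpy(dtype=float), cov)
    scan._attach_clusters()
    return scan


# ---------------------------------------------------------------------------
# Edge-level proportion contrasts
# ---------------------------------------------------------------------------


def edge_proportion_test(
    distances, groups, eps: float, alpha_edge: float = 0.01, node_ids=None
) -> pd.DataFrame:
    """Between-group contrast of edge presence at one filtration threshold.

    An edge is present for a subject when d <= eps.  Per edge, the two
    group proportions are compared with the pooled two-proportion z-test
    (two-sided); edges with zero pooled variance (present in everyone or in
    no one) report p = 1.  Returns a long-form table with one row per edge:
    node_i, node_j, eps, prop_case, prop_control, diff, p, mask.
    """
    if not 0 <= eps <= 2:
        raise ValueError("eps must lie in [0, 2]")
    mats = [m.d if isinstance(m, DistanceMatrix) else np.asarray(m) for m in distances]
    d = np.stack(mats)
    y = np.asarray(groups).astype(int).ravel()
    if d.shape[0] != y.size:
        raise ValueError("one group label per subject required")
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both groups must be non-empty")
    n = d.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    present = d[:, iu, ju] <= eps
    x_case = present[y == 1].sum(axis=0)
    x_ctrl = present[y == 0].sum(axis=0)
    p_case = x_case / n_case
    p_ctrl = x_ctrl / n_ctrl
    pooled = (x_case + x_ctrl) / (n_case + n_ctrl)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_case + 1 / n_ctrl))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p_case - p_ctrl) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "node_i": [node_ids[i] for i in iu],
            "node_j": [node_ids[j] for j in ju],
            "eps": eps,
            "prop_case": p_case,
            "prop_control": p_ctrl,
            "diff": p_case - p_ctrl,
            "p": p,
            "mask": p < alpha_edge,
        }
    )


def edge_proportion_scan(
    connectomes, groups, eps_list=DEFAULT_EPS_LIST, alpha_edge: float = 0.01
) -> pd.DataFrame:
    """Edge contrasts at several thresholds, stacked long-form."""
    dms = [
        to_distance(c) if isinstance(c, ConnectivityMatrix) else c
        for c in connectomes
    ]
    node_ids = list(dms[0].node_ids) if isinstance(dms[0], DistanceMatrix) else None
    return pd.concat(
        [
            edge_proportion_test(dms, groups, e, alpha_edge, node_ids=node_ids)
            for e in eps_list
        ],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Descriptive effect sizes (phenotype-table style)
# ---------------------------------------------------------------------------


def cohens_d_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d from group summaries, with the pooled standard deviation."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float((mean1 - mean2) / s_pooled)


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """Cross-product odds ratio (a*d)/(b*c) of a 2x2 table.

    When any cell is zero the Haldane-Anscombe +0.5 correction is applied
    to every cell; a zero row or column (two zero cells in line) leaves the
    odds ratio undefined and raises.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (
        b == 0 and d == 0
    ):
        raise ValueError("a zero row or column makes the odds ratio undefined")
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    return float((a * d) / (b * c))
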