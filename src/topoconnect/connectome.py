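"""Subject-level functional connectomes, phenotypes, and node partitions.

A functional connectome is the node-by-node matrix of Pearson correlations
between regional time series.  Downstream topological analysis builds a Rips
filtration on the dissimilarity d = 1 - r, so the containers here guarantee
the invariants that filtration relies on: symmetry, unit diagonal, and
off-diagonal entries in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Largest |r[i,j] - r[j,i]| tolerated in input files; pairs within the
#: tolerance are averaged, larger asymmetry is treated as file corruption.
SYMMETRY_TOL = 1e-6

PHENOTYPE_COLUMNS = ("subject_id", "group", "sex", "age", "motion")
OPTIONAL_PHENOTYPE_COLUMNS = ("adhd_index", "iq")


def _as_labels(node_ids, n: int) -> list[str]:
    if node_ids is None:
        width = len(str(max(n - 1, 1)))
        return [f"n{idx:0{width}d}" for idx in range(n)]
    labels = [str(x) for x in node_ids]
    if len(labels) != n:
        raise ValueError(f"{len(labels)} node labels for a {n}x{n} matrix")
    if len(set(labels)) != n:
        raise ValueError("node labels must be unique")
    return labels


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson-correlation matrix for one subject.

    Parameters
    ----------
    node_ids : list of str
        Ordered node labels (regions of interest).
    r : (n, n) ndarray
        Pearson correlations; symmetric, unit diagonal, entries in [-1, 1].
    """

    node_ids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {r.shape}")
        n = r.shape[0]
        object.__setattr__(self, "node_ids", _as_labels(self.node_ids, n))
        if not np.isfinite(r).all():
            raise ValueError("correlation matrix contains non-finite entries")
        asym = np.abs(r - r.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        off = r[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
            raise ValueError(
                "off-diagonal correlations outside [-1, 1]: "
                f"range [{off.min():.6g}, {off.max():.6g}]"
            )
        r.flags.writeable = False
        object.__setattr__(self, "r", r)

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Dissimilarity matrix d = 1 - r; entries in [0, 2], zero diagonal."""

    node_ids: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got {d.shape}")
        n = d.shape[0]
        object.__setattr__(self, "node_ids", _as_labels(self.node_ids, n))
        if not np.isfinite(d).all():
            raise ValueError("distance matrix contains non-finite entries")
        if np.abs(d - d.T).max() > SYMMETRY_TOL if n else False:
            raise ValueError("distance matrix is not symmetric")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        if d.size and (d.min() < -1e-12 or d.max() > 2.0 + 1e-12):
            raise ValueError("distances must lie in [0, 2]")
        d.flags.writeable = False
        object.__setattr__(self, "d", np.clip(d, 0.0, 2.0))

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one network (or lobe) label."""

    node_ids: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.node_ids) != len(self.labels):
            raise ValueError("node_ids and labels must have equal length")
        if len(self.node_ids) == 0:
            raise ValueError("partition is empty")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in partition")
        object.__setattr__(self, "node_ids", [str(x) for x in self.node_ids])
        object.__setattr__(self, "labels", [str(x) for x in self.labels])

    @property
    def k(self) -> int:
        return len(set(self.labels))

    @property
    def networks(self) -> list[str]:
        """Distinct labels in sorted order."""
        return sorted(set(self.labels))

    def members(self, label: str) -> list[int]:
        """Node indices belonging to one network."""
        return [i for i, lab in enumerate(self.labels) if lab == label]


def pearson_connectome(
    timeseries: np.ndarray, node_ids=None, *, rows_are_time: bool = True
) -> ConnectivityMatrix:
    """Pearson cross-correlation between all pairs of regional signals.

    ``timeseries`` is T x n (rows = time points, columns = nodes) unless
    ``rows_are_time`` is False, in which case it is transposed first.
    """
    x = np.asarray(timeseries, dtype=float)
    if not rows_are_time:
        x = x.T
    if x.ndim != 2:
        raise ValueError("timeseries must be a 2-D array")
    if np.isnan(x).any():
        raise ValueError("timeseries contains NaN values")
    t, n = x.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    labels = _as_labels(node_ids, n)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValueError(f"constant time series for node {bad!r}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(labels, r)


def to_distance(cm: ConnectivityMatrix) -> DistanceMatrix:
    """Filtration dissimilarity d = 1 - r."""
    d = 1.0 - cm.r
    return DistanceMatrix(list(cm.node_ids), d)


def subset(cm: ConnectivityMatrix, nodes) -> ConnectivityMatrix:
    """Principal submatrix on the given node indices, in the given order."""
    idx = np.asarray(list(nodes), dtype=int)
    if idx.size < 2:
        raise ValueError("a subnetwork needs at least 2 nodes")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicate node indices")
    if idx.min() < 0 or idx.max() >= cm.n:
        raise ValueError(f"node index out of range for a {cm.n}-node connectome")
    labels = [cm.node_ids[i] for i in idx]
    return ConnectivityMatrix(labels, cm.r[np.ix_(idx, idx)])


def enumerate_subnetworks(p: Partition) -> list[tuple[tuple[str, ...], list[int]]]:
    """All intranetwork and internetwork node subsets of a partition.

    Returns the k singleton subsets and the k(k-1)/2 unordered pairs, each
    paired with the union of member-node indices, in sorted label order.
    The internetwork subset of networks A and B is the union of both
    networks' nodes, so intra-network edges of both members take part in
    the filtration.
    """
    nets = p.networks
    out: list[tuple[tuple[str, ...], list[int]]] = []
    for i, a in enumerate(nets):
        out.append(((a,), p.members(a)))
        for b in nets[i + 1 :]:
            out.append(((a, b), sorted(p.members(a) + p.members(b))))
    # sorted primarily by label tuple for a deterministic, readable order
    out.sort(key=lambda t: t[0])
    return out


# ---------------------------------------------------------------------------
# CSV plumbing.  All files identify nodes and subjects by label, never by
# position, so reordered files remain valid.
# ---------------------------------------------------------------------------


def read_matrix(path) -> ConnectivityMatrix:
    """Read a square correlation CSV (optional header row of node labels)."""
    df = pd.read_csv(path, header=None)
    header = None
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        header = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:]
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError(
            f"{path}: matrix is {vals.shape[0]}x{vals.shape[1]}, expected square"
        )
    return ConnectivityMatrix(_as_labels(header, vals.shape[0]), vals)


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(cm.r, columns=cm.node_ids).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype table.

    Required columns: subject_id, group, sex, age, motion.  ``group`` and
    ``sex`` must be binary; ``group`` is recoded so that 1 marks the case
    (diagnosed) level and 0 the control/reference level.
    """
    df = pd.read_csv(path)
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    for col in ("group", "sex"):
        levels = sorted(pd.unique(df[col]))
        if len(levels) != 2:
            raise ValueError(f"column {col!r} must have exactly 2 levels, got {levels}")
        df[col] = (df[col] == levels[1]).astype(int)
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if (df["motion"] < 0).any():
        raise ValueError("motion must be non-negative")
    return df


def read_partition(path) -> Partition:
    """Read a node_id,network CSV into a Partition."""
    df = pd.read_csv(path)
    for col in ("node_id", "network"):
        if col not in df.columns:
            raise ValueError(f"partition file missing column {col!r}")
    return Partition(list(df["node_id"].astype(str)), list(df["network"].astype(str)))


def write_partition(p: Partition, path) -> None:
    pd.DataFrame({"node_id": p.node_ids, "network": p.labels}).to_csv(path, index=False)


def align_partition(p: Partition, cm: ConnectivityMatrix) -> Partition:
    """Reorder a partition to a connectome's node order, by node label."""
    lookup = dict(zip(p.node_ids, p.labels))
    missing = [nid for nid in cm.node_ids if nid not in lookup]
    if missing:
        raise ValueError(f"partition lacks node(s): {', '.join(missing[:5])}")
    return Partition(list(cm.node_ids), [lookup[nid] for nid in cm.node_ids])
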