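"""Group-level inference on band spectra.

Cell-wise t statistics over subjects x channels x carrier-band x AM-band
arrays, corrected for multiple comparisons with a two-tailed cluster-based
non-parametric permutation test: cells passing a parametric forming
threshold (p < alpha, two-tailed) are grown into connected components over
a 3-D adjacency — sensors within 75 mm, adjacent carrier bands, adjacent AM
bands (one axis at a time) — and each cluster's t-mass is referred to the
permutation null of the maximum cluster mass.  Also: Pearson correlation
maps against clinical scores with the same cluster correction, and the
demographic-table statistics (effect sizes, sex χ²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sst
from scipy.sparse.csgraph import connected_components

from holospect.montage import ChannelMontage


@dataclass
class SpectralDataset:
    """Subjects x channels x carrier bands x AM bands, with metadata."""

    data: np.ndarray
    metadata: pd.DataFrame  # one row per subject: group, scores, ...
    montage: ChannelMontage
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be subjects x channels x carrier x AM")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must equal subject count")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")

    @property
    def cell_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.metadata["group"] == group).to_numpy()


@dataclass(frozen=True)
class AdjacencySpec:
    """Cluster connectivity: 75-mm sensor neighbours, ±1 frequency band."""

    neighbor_distance_mm: float = 75.0
    connect_carrier: bool = True
    connect_am: bool = True

    def build(
        self, montage: ChannelMontage, n_carrier: int, n_am: int
    ) -> sparse.csr_matrix:
        """Sparse symmetric adjacency over flattened (ch, carrier, am) cells.

        The AM axis is trend-first; the trend row counts as adjacent to the
        lowest AM band.  Neighbourhood is one axis at a time (6-connectivity
        plus the sensor graph).
        """
        n_ch = montage.n_channels
        n_cells = n_ch * n_carrier * n_am
        idx = np.arange(n_cells).reshape(n_ch, n_carrier, n_am)
        rows, cols = [], []

        ch_adj = montage.adjacency(self.neighbor_distance_mm)
        ch_i, ch_j = np.nonzero(ch_adj)
        for a, b in zip(ch_i, ch_j):
            rows.append(idx[a].ravel())
            cols.append(idx[b].ravel())
        if self.connect_carrier and n_carrier > 1:
            rows.append(idx[:, :-1, :].ravel())
            cols.append(idx[:, 1:, :].ravel())
        if self.connect_am and n_am > 1:
            rows.append(idx[:, :, :-1].ravel())
            cols.append(idx[:, :, 1:].ravel())
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        mat = sparse.coo_matrix(
            (np.ones(len(r), dtype=bool), (r, c)), shape=(n_cells, n_cells)
        ).tocsr()
        return (mat + mat.T).astype(bool)


@dataclass
class Cluster:
    cells: np.ndarray  # flat cell indices
    mass: float  # sum of t over member cells
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray  # (channels, carrier, am); NaN where masked
    threshold: float
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


# ------------------------------------------------------------- t statistics


def _independent_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t along axis 0; NaN where variance is 0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[sp2 == 0] = np.nan
    return t


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t of difference maps along axis 0; NaN where variance is 0."""
    n = d.shape[0]
    m = d.mean(axis=0)
    v = d.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(v / n)
    t[v == 0] = np.nan
    return t


def cell_ttest(
    ds: SpectralDataset,
    design: str,
    groups: tuple[str, str] | None = None,
    paired_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, int]:
    """Per-cell t map and degrees of freedom.

    ``design`` is "independent" (between ``groups``, e.g. ("PD", "HC") via
    group labels in the metadata) or "paired" (within-subject difference of
    the two arrays in ``paired_data``, e.g. EC and EO spectra).
    """
    if design == "independent":
        if groups is None:
            raise ValueError("independent design needs a pair of group labels")
        m1 = ds.group_mask(groups[0])
        m2 = ds.group_mask(groups[1])
        if m1.sum() < 2 or m2.sum() < 2:
            raise ValueError("need at least 2 subjects per group")
        return _independent_t(ds.data[m1], ds.data[m2]), int(m1.sum() + m2.sum() - 2)
    if design == "paired":
        if paired_data is None:
            raise ValueError("paired design needs the two condition arrays")
        a, b = paired_data
        if a.shape != b.shape:
            raise ValueError("paired arrays must have identical shapes")
        if a.shape[0] < 2:
            raise ValueError("need at least 2 paired observations")
        return _paired_t(a - b), a.shape[0] - 1
    raise ValueError(f"unknown design {design!r}")


# -------------------------------------------------- clustering machinery


def _cluster_masses(
    t_flat: np.ndarray, threshold: float, adjacency: sparse.csr_matrix
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components of suprathreshold cells, per sign.

    Returns (list of member-index arrays, masses).  Positive and negative
    clusters are formed separately.
    """
    members: list[np.ndarray] = []
    masses: list[float] = []
    for sign in (1.0, -1.0):
        mask = np.nan_to_num(sign * t_flat) > threshold
        cells = np.flatnonzero(mask)
        if len(cells) == 0:
            continue
        sub = adjacency[cells][:, cells]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            cc = cells[labels == comp]
            members.append(cc)
            masses.append(float(t_flat[cc].sum()))
    return members, np.asarray(masses)


def _max_cluster_mass(
    t_flat: np.ndarray, threshold: float, adjacency: sparse.csr_matrix
) -> float:
    _, masses = _cluster_masses(t_flat, threshold, adjacency)
    return float(np.max(np.abs(masses))) if len(masses) else 0.0


def cluster_permutation(
    ds: SpectralDataset,
    design: str,
    groups: tuple[str, str] | None = None,
    paired_data: tuple[np.ndarray, np.ndarray] | None = None,
    adjacency: AdjacencySpec | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Two-tailed cluster-based non-parametric permutation test.

    Cluster-forming threshold: parametric |t| at p < ``alpha`` two-tailed
    with the design's df.  Null distribution: maximum |cluster mass| under
    group-label permutations (independent) or random sign flips of the
    subject difference maps (paired).  Cluster p = (1 + #{null >= obs}) /
    (1 + n_perm); deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    adjacency = adjacency or AdjacencySpec()
    t_map, df = cell_ttest(ds, design, groups=groups, paired_data=paired_data)
    threshold = float(sst.t.isf(alpha / 2.0, df))
    n_ch, n_cb, n_ab = t_map.shape
    adj = adjacency.build(ds.montage, n_cb, n_ab)
    t_flat = t_map.ravel()

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if design == "independent":
        m1 = ds.group_mask(groups[0])
        m2 = ds.group_mask(groups[1])
        n1 = int(m1.sum())
        x = np.concatenate([ds.data[m1], ds.data[m2]])
        x = x.reshape(x.shape[0], -1)
        for i in range(n_perm):
            perm = rng.permutation(x.shape[0])
            tp = _independent_t(x[perm[:n1]], x[perm[n1:]])
            null[i] = _max_cluster_mass(tp, threshold, adj)
    elif design == "paired":
        a, b = paired_data
        d = (a - b).reshape(a.shape[0], -1)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=d.shape[0])
            tp = _paired_t(d * signs[:, None])
            null[i] = _max_cluster_mass(tp, threshold, adj)
    else:
        raise ValueError(f"unknown design {design!r}")

    members, masses = _cluster_masses(t_flat, threshold, adj)
    clusters = [
        Cluster(
            cells=cc,
            mass=m,
            p_value=float((1 + np.sum(null >= abs(m))) / (1 + n_perm)),
        )
        for cc, m in zip(members, masses)
    ]
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters, t_map=t_map, threshold=threshold, n_permutations=n_perm
    )


def correlation_map(
    ds: SpectralDataset,
    score: np.ndarray | str,
    adjacency: AdjacencySpec | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, ClusterResult]:
    """Per-cell Pearson r against a subject score, with cluster inference.

    The r map is converted to t = r sqrt((n-2)/(1-r²)); the null shuffles
    the score vector across subjects.
    """
    if isinstance(score, str):
        score = ds.metadata[score].to_numpy(dtype=float)
    score = np.asarray(score, dtype=float)
    n = ds.data.shape[0]
    if score.shape != (n,):
        raise ValueError("score must be one value per subject")
    if not np.isfinite(score).all():
        raise ValueError("score contains non-finite values")
    if n < 4:
        raise ValueError("need at least 4 subjects for correlation inference")
    if np.std(score) == 0:
        raise ValueError("score is constant; correlation undefined")

    adjacency = adjacency or AdjacencySpec()
    x = ds.data.reshape(n, -1)

    def r_of(s: np.ndarray) -> np.ndarray:
        sc = (s - s.mean()) / s.std()
        xc = x - x.mean(axis=0)
        sd = x.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sc @ xc) / (n * sd)
        r[sd == 0] = np.nan
        return np.clip(r, -1.0, 1.0)

    def t_of(r: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-15))

    df = n - 2
    threshold = float(sst.t.isf(alpha / 2.0, df))
    n_ch, n_cb, n_ab = ds.cell_shape
    adj = adjacency.build(ds.montage, n_cb, n_ab)

    r_obs = r_of(score)
    t_obs = t_of(r_obs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _max_cluster_mass(
            t_of(r_of(score[rng.permutation(n)])), threshold, adj
        )
    members, masses = _cluster_masses(t_obs, threshold, adj)
    clusters = [
        Cluster(
            cells=cc,
            mass=m,
            p_value=float((1 + np.sum(null >= abs(m))) / (1 + n_perm)),
        )
        for cc, m in zip(members, masses)
    ]
    clusters.sort(key=lambda c: c.p_value)
    result = ClusterResult(
        clusters=clusters,
        t_map=t_obs.reshape(ds.cell_shape),
        threshold=threshold,
        n_permutations=n_perm,
    )
    return r_obs.reshape(ds.cell_shape), result


# ------------------------------------------------------------ demographics


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Effect size |m1 - m2| / sqrt((s1² + s2²)/2) (RMS-SD denominator)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson χ² (no continuity correction, df = 1) for a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    chi2, p, dof, _ = sst.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(p)
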