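"""Dissimilarity matrices, principal-coordinates ordination, and
Monte-Carlo contrasts between groups of pairwise distances.

Community dissimilarity uses Bray-Curtis on (rarefied) counts; the
transcriptome analog is Jaccard on presence/absence.  Group contrasts
follow the permutational two-sample t procedure: distances selected by two
pair-selectors are compared with a Monte-Carlo null, Bonferroni-corrected
across the declared comparisons.  By default the null permutes *sample*
identities on the distance matrix, which preserves the correlation between
pairs sharing a sample and keeps the test calibrated; pooling the distances
themselves as exchangeable units (``permute="pairs"``) reproduces the
classical nonparametric distance t-test but is anti-conservative for
within-group pair sets (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables_io import ExpressionMatrix, FeatureTable, SampleMetadata

DEFAULT_N_PERM = 1000


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("id count does not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-10).any():
            raise ValueError("negative distances")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id) -> int:
        return self.ids.index(sample_id)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v) on counts."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad[:5]}")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def jaccard_presence(matrix, detect_threshold: float = 0.0) -> DistanceMatrix:
    """Jaccard distance on presence/absence at ``value > detect_threshold``.

    Two samples with empty presence sets are at distance 0.
    """
    if isinstance(matrix, (FeatureTable, ExpressionMatrix)):
        ids = matrix.sample_ids
        values = matrix.data.to_numpy(dtype=float)
    else:
        ids = list(matrix.index)
        values = matrix.to_numpy(dtype=float)
    presence = values > detect_threshold
    d = squareform(pdist(presence, metric="jaccard"))
    return DistanceMatrix(ids, d)


@dataclass
class Ordination:
    """Principal-coordinates embedding.

    coordinates: samples x axes (axis t scaled by sqrt(eigenvalue_t));
    eigenvalues sorted non-increasing, all retained ones positive;
    proportion_explained is relative to the positive-eigenvalue mass;
    negative_eigenvalue_mass reports the magnitude sum of dropped
    negative eigenvalues.
    """

    ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _gower(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    a = -0.5 * values ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, k: int | None = None) -> Ordination:
    """Classical metric multidimensional scaling (principal coordinates).

    Double-centers -1/2 D^2 (Gower centering), eigendecomposes, and keeps
    the top ``k`` positive eigenvalues (all of them when ``k`` is None);
    negative eigenvalues (non-Euclidean metric) are dropped and their mass
    reported.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    g = _gower(dm.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    n_pos = int(positive.sum())
    if k is None:
        k = n_pos
    if n_pos < k:
        raise ValueError(f"only {n_pos} positive eigenvalues; k={k} requested")
    neg_mass = float(-eigval[eigval < -tol].sum())
    vals = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(vals)
    pos_sum = eigval[positive].sum()
    return Ordination(
        ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=vals / pos_sum,
        negative_eigenvalue_mass=neg_mass,
    )


@dataclass
class PairSelector:
    """Selects a set of pairwise distances from a labeled matrix.

    stratum: metadata filter (column -> required value) applied to both
    members of a pair.  mode "within": both members share ``level`` of
    ``factor``; mode "between": the two members have different levels of
    ``factor`` (optionally restricted to ``levels``).
    """

    factor: str
    mode: str = "within"
    level: str | None = None
    levels: tuple | None = None
    stratum: dict = field(default_factory=dict)

    def pair_indices(self, dm: DistanceMatrix, meta: SampleMetadata) -> np.ndarray:
        """(m, 2) array of index pairs (i < j) selected from the matrix."""
        md = meta.data.loc[dm.ids]
        mask = np.ones(len(md), dtype=bool)
        for col, val in self.stratum.items():
            mask &= (md[col] == val).to_numpy()
        labels = md[self.factor].to_numpy()
        pairs = []
        idx = np.flatnonzero(mask)
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1:]:
                if self.mode == "within":
                    if labels[i] == labels[j] and (self.level is None or labels[i] == self.level):
                        pairs.append((i, j))
                elif self.mode == "between":
                    if labels[i] != labels[j] and (
                        self.levels is None or {labels[i], labels[j]} == set(self.levels)
                    ):
                        pairs.append((i, j))
                else:
                    raise ValueError(f"unknown mode: {self.mode!r}")
        return np.asarray(pairs, dtype=int).reshape(-1, 2)

    def select(self, dm: DistanceMatrix, meta: SampleMetadata) -> np.ndarray:
        pairs = self.pair_indices(dm, meta)
        return dm.values[pairs[:, 0], pairs[:, 1]]


@dataclass
class DistanceContrast:
    group_a: np.ndarray
    group_b: np.ndarray
    t: float
    p: float
    corrected_p: float
    n_perm: int


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def distance_contrast(dm: DistanceMatrix, meta: SampleMetadata,
                      sel_a: PairSelector, sel_b: PairSelector,
                      n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                      n_comparisons: int = 1,
                      permute: str = "samples") -> DistanceContrast:
    """Monte-Carlo two-sample t contrast between two sets of distances.

    p = (1 + #{|t*| >= |t|}) / (1 + n_perm); corrected p is Bonferroni over
    ``n_comparisons``.

    permute="samples" (default) relabels sample identities on the distance
    matrix and re-extracts both pair sets, preserving the dependence of
    pairs that share a sample — this null is calibrated.  permute="pairs"
    pools the two distance sets and reassigns them, the classical
    nonparametric distance t-test; it overstates significance when pairs
    within a set share samples.
    """
    pairs_a = sel_a.pair_indices(dm, meta)
    pairs_b = sel_b.pair_indices(dm, meta)
    a = dm.values[pairs_a[:, 0], pairs_a[:, 1]]
    b = dm.values[pairs_b[:, 0], pairs_b[:, 1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each selection must yield at least 2 distances")
    t_obs = _t_stat(a, b)
    rng = np.random.default_rng(seed)
    exceed = 0
    if permute == "pairs":
        pooled = np.concatenate([a, b])
        na = len(a)
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(_t_stat(perm[:na], perm[na:])) >= abs(t_obs) - 1e-12:
                exceed += 1
    elif permute == "samples":
        n = dm.n
        for _ in range(n_perm):
            perm = rng.permutation(n)
            a_p = dm.values[perm[pairs_a[:, 0]], perm[pairs_a[:, 1]]]
            b_p = dm.values[perm[pairs_b[:, 0]], perm[pairs_b[:, 1]]]
            if abs(_t_stat(a_p, b_p)) >= abs(t_obs) - 1e-12:
                exceed += 1
    else:
        raise ValueError(f"unknown permute mode: {permute!r}")
    p = (1 + exceed) / (1 + n_perm)
    return DistanceContrast(
        group_a=a, group_b=b, t=t_obs, p=p,
        corrected_p=min(1.0, p * n_comparisons), n_perm=n_perm,
    )
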