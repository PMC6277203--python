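"""Host-microbiome linkage: ordination scores, canonical correlation,
a total-variance-explained statistic and its permutation null, plus the
transcriptome fold-change contrast.

The linkage statistic is the Stewart-Love redundancy of the microbiome
score matrix A given the expression score matrix B on the covariance
scale: variance_explained = tr(A_c' P_B A_c) / tr(A_c' A_c), which equals
sum_t rho_t^2 * f_t, where rho_t are the canonical correlations and f_t is
the fraction of A's total variance carried by its t-th canonical variate.
It is 1 exactly when B spans A and reduces to the squared Pearson
correlation for k = 1.  The permutation null shuffles the row order of B
(the sample correspondence), leaving each matrix internally intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import distances as _distances
from .tables_io import ExpressionMatrix, FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_N_PERM = 1000


def component_scores(data, method: str = "pca", k: int = DEFAULT_K) -> pd.DataFrame:
    """Top-k ordination scores of a data matrix.

    method "pca": column-centered SVD scores (U S), ordered by explained
    variance.  method "pcoa_braycurtis": principal coordinates of the
    Bray-Curtis distance matrix.  The returned frame carries the explained
    variance fractions in ``attrs["proportion_explained"]``.
    """
    if method == "pcoa_braycurtis":
        if not isinstance(data, FeatureTable):
            raise ValueError("pcoa_braycurtis requires a FeatureTable")
        ordn = _distances.pcoa(_distances.bray_curtis(data), k)
        frame = ordn.to_frame()
        frame.attrs["proportion_explained"] = ordn.proportion_explained[:k]
        return frame
    if method != "pca":
        raise ValueError(f"unknown method: {method!r}")
    if isinstance(data, (FeatureTable, ExpressionMatrix)):
        df = data.data.astype(float)
    else:
        df = pd.DataFrame(data).astype(float)
    x = df.to_numpy() - df.to_numpy().mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    scores = u[:, :k] * s[:k]
    frame = pd.DataFrame(scores, index=df.index,
                         columns=[f"PC{i + 1}" for i in range(k)])
    frame.attrs["proportion_explained"] = (s[:k] ** 2) / (s ** 2).sum()
    return frame


def _centered(m) -> np.ndarray:
    x = np.asarray(pd.DataFrame(m).to_numpy(), dtype=float)
    return x - x.mean(axis=0)


def _orthobasis(x: np.ndarray):
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > (s[0] if s.size else 0) * 1e-10).sum())
    return u[:, :rank], rank


def cca_redundancy(a, b):
    """Canonical correlations and the redundancy of A given B.

    Returns (rho, variance_explained): rho are the canonical correlations
    (non-increasing, clipped to [0, 1]); variance_explained is the fraction
    of A's total (centered) variance explained by projection onto B's
    column space.  Rank deficiency reduces the number of canonical pairs,
    with a log notice.
    """
    ac, bc = _centered(a), _centered(b)
    if ac.shape[0] != bc.shape[0]:
        raise ValueError("A and B must have the same samples")
    if ac.shape[0] <= max(ac.shape[1], bc.shape[1]):
        raise ValueError("need more samples than score dimensions")
    qa, ra = _orthobasis(ac)
    qb, rb = _orthobasis(bc)
    if ra < ac.shape[1] or rb < bc.shape[1]:
        logger.info("cca_redundancy: rank reduced to (%d, %d)", ra, rb)
    rho = np.linalg.svd(qa.T @ qb, compute_uv=False)
    rho = np.clip(rho, 0.0, 1.0)
    total = float((ac ** 2).sum())
    if total == 0:
        raise ValueError("A has zero variance")
    explained = float(((qb.T @ ac) ** 2).sum()) / total
    return rho, min(explained, 1.0)


@dataclass
class CcaResult:
    k: int
    canonical_correlations: np.ndarray
    variance_explained: float
    permuted_values: np.ndarray
    p: float
    n_perm: int

    @property
    def permuted_mean(self) -> float:
        return float(np.mean(self.permuted_values)) if len(self.permuted_values) else np.nan


def cca_permutation_test(a, b, n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> CcaResult:
    """Permutation test of the variance-explained statistic.

    Null draws shuffle the row order of B only; p = (1 + #{stat* >= stat})
    / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a_df, b_df = pd.DataFrame(a), pd.DataFrame(b)
    if list(a_df.index) != list(b_df.index):
        common = [i for i in a_df.index if i in set(b_df.index)]
        if len(common) < len(a_df):
            raise ValueError("A and B rows are not aligned")
        b_df = b_df.loc[a_df.index]
    n = len(a_df)
    if n < 8:
        raise ValueError("need at least 8 samples")
    rho, stat = cca_redundancy(a_df, b_df)
    rng = np.random.default_rng(seed)
    bmat = b_df.to_numpy()
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        _, permuted[i] = cca_redundancy(a_df.to_numpy(), bmat[rng.permutation(n)])
    p = (1 + int((permuted >= stat - 1e-12).sum())) / (1 + n_perm)
    return CcaResult(
        k=min(pd.DataFrame(a).shape[1], b_df.shape[1]),
        canonical_correlations=rho,
        variance_explained=stat,
        permuted_values=permuted,
        p=p,
        n_perm=n_perm,
    )


@dataclass
class FoldChangeContrast:
    fold_change: pd.DataFrame        # gene x group FC (cold/warm)
    log2_fc: pd.DataFrame
    statistic: float
    p: float
    median_abs_log2_fc: dict


def expression_fold_change(expr: ExpressionMatrix, meta,
                           n_perm: int | None = None, seed: int = 0) -> FoldChangeContrast:
    """Per-gene cold/warm fold change per tolerance group and the
    between-group rank-sum contrast on |log2 FC|.

    ``meta`` rows must cover the expression samples and carry ``tolerance``
    and ``temperature`` columns (fish-level metadata when expression is one
    row per fish).  Zero warm means get a pseudo-value of half the smallest
    nonzero mean.
    """
    md = meta.data if isinstance(meta, SampleMetadata) else pd.DataFrame(meta)
    md = md.loc[expr.sample_ids]
    groups = sorted(md["tolerance"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly 2 tolerance groups")
    values = expr.data
    means = {}
    for g in groups:
        for temp in ("warm24", "cold12"):
            sel = (md["tolerance"] == g) & (md["temperature"] == temp)
            if not sel.any():
                raise ValueError(f"group {g!r} lacks temperature arm {temp!r}")
            means[(g, temp)] = values.loc[sel.to_numpy()].mean(axis=0)
    nonzero = np.concatenate([m[m > 0].to_numpy() for m in means.values()])
    pseudo = nonzero.min() / 2.0 if nonzero.size else np.nan
    fc = {}
    for g in groups:
        warm = means[(g, "warm24")].mask(means[(g, "warm24")] == 0, pseudo)
        cold = means[(g, "cold12")].mask(means[(g, "cold12")] == 0, pseudo)
        fc[g] = cold / warm
    fc = pd.DataFrame(fc)
    log2fc = np.log2(fc)
    a = log2fc[groups[0]].abs().to_numpy()
    b = log2fc[groups[1]].abs().to_numpy()
    stat, p_asym = scipy.stats.ranksums(a, b)
    if n_perm:
        pooled = np.concatenate([a, b])
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s, _ = scipy.stats.ranksums(perm[: len(a)], perm[len(a):])
            if abs(s) >= abs(stat) - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    else:
        p = float(p_asym)
    return FoldChangeContrast(
        fold_change=fc,
        log2_fc=log2fc,
        statistic=float(stat),
        p=p,
        median_abs_log2_fc={g: float(np.median(np.abs(log2fc[g]))) for g in groups},
    )
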