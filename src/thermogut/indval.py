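"""Dufrene-Legendre indicator-value analysis with a permutation null.

For feature i and group j:
  specificity_ij = mean abundance of i in j / sum over groups of the means
  fidelity_ij    = fraction of samples in j where i is present
  IndVal_ij      = specificity_ij * fidelity_ij * 100
The test statistic per feature is max_j IndVal_ij, and its p-value counts
group-label permutations whose statistic is at least the observed one.
Applies unchanged to count tables and to normalized expression matrices
(presence then means value > detect_threshold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .tables_io import ExpressionMatrix, FeatureTable

DEFAULT_N_PERM = 1000


def _as_matrix(matrix):
    if isinstance(matrix, (FeatureTable, ExpressionMatrix)):
        return matrix.data.to_numpy(dtype=float), list(matrix.data.columns), list(matrix.sample_ids)
    df = pd.DataFrame(matrix)
    return df.to_numpy(dtype=float), list(df.columns), list(df.index)


def _indval_components(x: np.ndarray, onehot: np.ndarray, group_sizes: np.ndarray,
                       detect_threshold: float):
    """Per-group specificity, fidelity, indval for every feature (vectorized)."""
    means = (onehot.T @ x) / group_sizes[:, None]          # groups x features
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(denom > 0, means / denom, 0.0)
    fid = (onehot.T @ (x > detect_threshold)) / group_sizes[:, None]
    return spec, fid, spec * fid * 100.0


def indval(matrix, groups, n_perm: int = DEFAULT_N_PERM, seed: int = 0,
           detect_threshold: float = 0.0) -> pd.DataFrame:
    """Indicator values per feature with permutation p for max_j IndVal.

    Parameters
    ----------
    groups : sequence of labels
        One label per sample (pandas Series indexed by sample id, or array
        in the matrix's sample order).

    Returns
    -------
    pandas.DataFrame indexed by feature with per-group ``specificity_*``,
    ``fidelity_*`` and ``indval_*`` columns, the best group, the statistic
    (max IndVal) and its permutation ``p``.  Features absent everywhere get
    IndVal 0 and p = 1.
    """
    x, features, sample_ids = _as_matrix(matrix)
    if isinstance(groups, pd.Series):
        groups = groups.reindex(sample_ids)
        if groups.isna().any():
            raise ValueError("group label missing for some samples")
        labels = groups.to_numpy()
    else:
        labels = np.asarray(groups)
        if len(labels) != len(sample_ids):
            raise ValueError("group labels do not match sample count")
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    onehot = np.column_stack([(labels == lv) for lv in levels]).astype(float)
    sizes = onehot.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("empty group")

    spec, fid, iv = _indval_components(x, onehot, sizes, detect_threshold)
    stat = iv.max(axis=0)
    best = np.asarray(levels)[iv.argmax(axis=0)]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(features))
    for _ in range(n_perm):
        perm_onehot = onehot[rng.permutation(len(labels))]
        _, _, iv_p = _indval_components(x, perm_onehot, sizes, detect_threshold)
        exceed += iv_p.max(axis=0) >= stat - 1e-12
    p = (1 + exceed) / (1 + n_perm)

    absent = x.sum(axis=0) == 0
    stat = np.where(absent, 0.0, stat)
    p = np.where(absent, 1.0, p)

    out = {"best_group": best, "indval": stat, "p": p}
    for gi, lv in enumerate(levels):
        out[f"specificity_{lv}"] = spec[gi]
        out[f"fidelity_{lv}"] = fid[gi]
        out[f"indval_{lv}"] = iv[gi]
    df = pd.DataFrame(out, index=pd.Index(features, name="feature"))
    df.attrs["n_perm"] = n_perm
    return df


def filter_indicators(records: pd.DataFrame, alpha: float = 0.05,
                      min_indval: float = 0.0) -> pd.DataFrame:
    """Significant indicators (raw p <= alpha, IndVal >= min_indval).

    A Holm-adjusted p across features is attached as ``p_holm``; filtering
    uses the raw permutation p (the primary statistic for this analysis).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    records = records.copy()
    if len(records):
        records["p_holm"] = multipletests(records["p"].to_numpy(), method="holm")[1]
    else:
        records["p_holm"] = pd.Series(dtype=float)
    keep = (records["p"] <= alpha) & (records["indval"] >= min_indval)
    return records.loc[keep]
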