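"""Prevalence filtering, rarefaction, alpha-diversity and the mixed-model stage.

The pipeline's defaults follow the amplicon-analysis conventions used for
the study design this package targets: features seen in fewer than two
samples are discarded, samples are rarefied to a common depth of 6000
reads, and Shannon diversity is computed in log base 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .tables_io import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 6000
DEFAULT_LOG_BASE = 2.0


def filter_doubletons(table: FeatureTable, min_prevalence: int = 2) -> FeatureTable:
    """Remove features observed in fewer than ``min_prevalence`` samples."""
    presence = (table.counts > 0).sum(axis=0)
    keep = presence >= min_prevalence
    return FeatureTable(table.data.loc[:, keep].copy(), kind=table.kind)


def rarefy(table: FeatureTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> FeatureTable:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (and logged).
    Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [sid for sid, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:10])
    rng = np.random.default_rng(seed)
    counts = table.counts[keep]
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    ids = [sid for sid, k in zip(table.sample_ids, keep) if k]
    return FeatureTable(pd.DataFrame(out, index=ids, columns=table.feature_ids),
                        kind=table.kind)


def alpha_diversity(table: FeatureTable, log_base: float = DEFAULT_LOG_BASE) -> pd.DataFrame:
    """Per-sample richness and Shannon entropy.

    Shannon H' = -sum p_i log(p_i) / log(log_base) over features with
    p_i > 0, where p_i is the relative abundance within the sample.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {bad[:5]}")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / np.log(log_base)
    shannon = np.maximum(shannon, 0.0)  # clamp -0.0 from single-feature rows
    richness = (counts > 0).sum(axis=1)
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.sample_ids)


def rarefaction_curve(table: FeatureTable, depths, reps: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean richness per sample after repeated subsampling at each depth.

    Depths exceeding a sample's total are reported as NaN for that sample.
    """
    depths = list(depths)
    if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    out = np.full((len(table.sample_ids), len(depths)), np.nan)
    for i in range(counts.shape[0]):
        for j, d in enumerate(depths):
            if d > totals[i]:
                continue
            rich = [
                int((rng.multivariate_hypergeometric(counts[i], d) > 0).sum())
                for _ in range(reps)
            ]
            out[i, j] = float(np.mean(rich))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def _gls_fixed_cov(X: np.ndarray, groups: np.ndarray, var_group: float,
                   var_resid: float) -> np.ndarray:
    """(X' V^-1 X)^-1 for V = var_resid*I + var_group*ZZ' (random intercept).

    Uses the per-group Woodbury identity, so the zero-variance boundary
    reduces exactly to the OLS covariance.
    """
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        xg = X[groups == g]
        ng = xg.shape[0]
        shrink = var_group / (var_resid + ng * var_group) if var_group > 0 else 0.0
        colsum = xg.sum(axis=0, keepdims=True)
        xtvx += (xg.T @ xg - shrink * (colsum.T @ colsum)) / var_resid
    return np.linalg.pinv(xtvx)


@dataclass
class LmmResult:
    """REML random-intercept fit for a diversity response.

    fixed_effects: one row per fixed factor with the joint Wald F over its
    coefficients, the denominator df used, and the F-test p-value.
    """

    fixed_effects: pd.DataFrame
    group_variance: float
    residual_variance: float
    loglike: float
    ddf_method: str
    converged: bool


def fit_diversity_lmm(values, meta: SampleMetadata, fixed=("temperature", "tolerance"),
                      random_intercept: str = "family",
                      ddf_method: str = "residual") -> LmmResult:
    """Random-intercept linear mixed model fitted by REML.

    ``values`` is a per-sample response (pandas Series indexed by sample id,
    or array aligned with ``meta``).  Fixed factors are treatment-coded;
    each factor gets a joint Wald F test on its coefficients.

    ddf_method controls the denominator df of the F tests:
    ``"residual"`` uses n_obs - rank(X); ``"between_within"`` subtracts the
    between-group df as well (n_obs - rank(X) - (n_groups - 1)).
    """
    df = meta.data.copy()
    if isinstance(values, pd.Series):
        values = values.reindex(df.index)
        if values.isna().any():
            raise ValueError("response missing for some metadata samples")
        df["_y"] = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if len(arr) != len(df):
            raise ValueError("response length does not match metadata")
        df["_y"] = arr

    for f in fixed:
        if df[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has fewer than 2 levels")
    if df[random_intercept].nunique() < 2:
        raise ValueError(f"random factor {random_intercept!r} has fewer than 2 groups")

    X_parts, term_slices = [], {}
    col = 1  # intercept occupies column 0
    for f in fixed:
        dummies = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True)
        X_parts.append(dummies.to_numpy(dtype=float))
        term_slices[f] = slice(col, col + dummies.shape[1])
        col += dummies.shape[1]
    X = np.column_stack([np.ones(len(df))] + X_parts)

    groups_arr = df[random_intercept].to_numpy()
    model = sm.MixedLM(df["_y"].to_numpy(), X, groups=groups_arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits are expected and handled
        fit = model.fit(reml=True)

    n = len(df)
    rank_x = np.linalg.matrix_rank(X)
    n_groups = df[random_intercept].nunique()
    if ddf_method == "residual":
        ddf = n - rank_x
    elif ddf_method == "between_within":
        ddf = n - rank_x - (n_groups - 1)
    else:
        raise ValueError(f"unknown ddf_method: {ddf_method!r}")

    beta = np.asarray(fit.fe_params)
    # GLS covariance of the fixed effects from the estimated variance
    # components; statsmodels' observed-information covariance is unstable
    # when the group variance sits on the zero boundary.
    cov = _gls_fixed_cov(X, groups_arr,
                         float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale))
    rows = []
    for f in fixed:
        sl = term_slices[f]
        b = beta[sl.start:sl.stop]
        V = cov[sl, sl]
        q = len(b)
        F = float(b @ np.linalg.solve(V, b)) / q
        p = float(scipy.stats.f.sf(F, q, ddf))
        est = float(b[0]) if q == 1 else np.nan
        rows.append({"term": f, "estimate": est, "num_df": q, "den_df": ddf,
                     "F": F, "p": p})
    return LmmResult(
        fixed_effects=pd.DataFrame(rows).set_index("term"),
        group_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        loglike=float(fit.llf),
        ddf_method=ddf_method,
        converged=bool(fit.converged),
    )
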