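"""Permutational multivariate ANOVA (Adonis-style) on a distance matrix.

Sequential (Type I) sums of squares are extracted from the Gower-centered
matrix G = C(-1/2 D∘D)C via hat matrices of cumulative treatment-coded
design matrices: SS_k = tr((H_k - H_{k-1}) G), SS_res = tr((I - H_m) G),
pseudo-F_k = (SS_k/df_k)/(SS_res/df_res).  Term p-values come from joint
row/column permutation of the distance matrix (free permutation of
observations by default; within-strata permutation optional).  This is the
McArdle-Anderson construction: for Euclidean distances on coordinates it
reproduces coordinate-space multivariate ANOVA exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .tables_io import SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 999


@dataclass
class ModelFormula:
    """Ordered term list; a term is a factor name or 'a:b' interaction."""

    terms: list

    @classmethod
    def parse(cls, formula: str) -> "ModelFormula":
        terms = [t.strip() for t in formula.split("+") if t.strip()]
        if len(terms) != len(set(terms)):
            raise ValueError("duplicate terms in formula")
        return cls(terms)

    def factors(self) -> list:
        out = []
        for t in self.terms:
            for f in t.split(":"):
                if f not in out:
                    out.append(f)
        return out


def gower_center(dm: DistanceMatrix) -> np.ndarray:
    """G = C(-1/2 D∘D)C with C = I - 11'/n; trace(G) is the total SS."""
    if dm.n < 2:
        raise ValueError("need at least 2 samples")
    d2 = -0.5 * dm.values ** 2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    return d2 - row - col + d2.mean()


def _dummy_columns(series: pd.Series, numeric: bool = False) -> np.ndarray:
    levels = sorted(series.unique())
    if len(levels) < 2:
        raise ValueError(f"factor has a single level: {levels}")
    if numeric:
        codes = series.map({lv: i for i, lv in enumerate(levels)})
        return codes.to_numpy(dtype=float)[:, None]
    # treatment coding, first level as reference
    return np.column_stack(
        [(series == lv).to_numpy(dtype=float) for lv in levels[1:]]
    )


def build_design(meta: SampleMetadata, formula: ModelFormula,
                 sample_ids, numeric_factors=()) -> dict:
    """Treatment-coded columns per term; interactions are column products."""
    md = meta.data.loc[list(sample_ids)]
    main_cols = {}
    for f in formula.factors():
        if f not in md.columns:
            raise ValueError(f"factor {f!r} not in metadata")
        main_cols[f] = _dummy_columns(md[f].astype(str), numeric=f in numeric_factors)
    term_cols = {}
    for term in formula.terms:
        parts = term.split(":")
        cols = main_cols[parts[0]]
        for extra in parts[1:]:
            other = main_cols[extra]
            cols = np.concatenate(
                [cols[:, [i]] * other for i in range(cols.shape[1])], axis=1
            )
        term_cols[term] = cols
    return term_cols


def _orthobasis(x: np.ndarray, tol_factor: float = 1e-9):
    """Orthonormal basis of the column space of x, with its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0:
        return u[:, :0], 0
    rank = int((s > s[0] * tol_factor).sum())
    return u[:, :rank], rank


def adonis(dm: DistanceMatrix, meta: SampleMetadata, formula,
           n_perm: int = DEFAULT_N_PERM, seed: int = 0,
           strata: str | None = None, numeric_factors=()) -> pd.DataFrame:
    """Sequential PERMANOVA table for ``formula`` on ``dm``.

    Parameters
    ----------
    formula : str or ModelFormula
        e.g. ``"tolerance + temperature + family + part + tolerance:temperature"``.
    strata : str, optional
        Metadata column restricting permutations to within-stratum swaps.
    numeric_factors : iterable of str
        Factors to code as a single numeric column (df=1) instead of
        treatment dummies.

    Returns
    -------
    pandas.DataFrame
        Rows: one per term, plus ``Residuals`` and ``Total``; columns
        ``df``, ``SS``, ``MS``, ``pseudo_F``, ``R2``, ``p``.
    """
    if isinstance(formula, str):
        formula = ModelFormula.parse(formula)
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    g = gower_center(dm)
    n = dm.n
    ss_total = float(np.trace(g))
    term_cols = build_design(meta, formula, dm.ids, numeric_factors=numeric_factors)

    # cumulative orthonormal bases; hat-difference matrices per term
    ones = np.ones((n, 1)) / np.sqrt(n)
    q_prev, rank_prev = ones, 1
    h_diffs, dfs = [], []
    for term in formula.terms:
        x_cum = np.concatenate([q_prev, term_cols[term]], axis=1)
        q_cum, rank_cum = _orthobasis(x_cum)
        df_term = rank_cum - rank_prev
        if df_term == 0:
            logger.warning("adonis: term %r adds no rank (aliased); SS = 0", term)
        h_diffs.append(q_cum @ q_cum.T - q_prev @ q_prev.T)
        dfs.append(df_term)
        q_prev, rank_prev = q_cum, rank_cum
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def decompose(gmat):
        ss = np.array([float((h * gmat).sum()) for h in h_diffs])
        ss_res = float(np.trace(gmat)) - ss.sum()
        return ss, ss_res

    ss_terms, ss_res = decompose(g)
    if ss_res <= 0:
        raise ValueError("non-positive residual sum of squares")
    f_obs = np.array([
        (ss_terms[k] / dfs[k]) / (ss_res / df_res) if dfs[k] > 0 else np.nan
        for k in range(len(dfs))
    ])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    if strata is not None:
        strata_labels = meta.data.loc[dm.ids, strata].to_numpy()
        groups = [np.flatnonzero(strata_labels == lv) for lv in np.unique(strata_labels)]
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = decompose(gp)
        if ss_res_p <= 0:
            continue
        f_p = np.array([
            (ss_p[k] / dfs[k]) / (ss_res_p / df_res) if dfs[k] > 0 else np.nan
            for k in range(len(dfs))
        ])
        exceed += (f_p >= f_obs - 1e-12)  # ties counted as >= (conservative)
    p_vals = (1 + exceed) / (1 + n_perm) if n_perm > 0 else np.full(len(dfs), np.nan)

    rows = []
    for k, term in enumerate(formula.terms):
        ms, f, r2 = assemble_permanova_row(ss_terms[k], dfs[k], ss_res, df_res, ss_total)
        rows.append({"term": term, "df": dfs[k], "SS": ss_terms[k], "MS": ms,
                     "pseudo_F": f, "R2": r2, "p": float(p_vals[k])})
    rows.append({"term": "Residuals", "df": df_res, "SS": ss_res,
                 "MS": ss_res / df_res, "pseudo_F": np.nan,
                 "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "MS": np.nan,
                 "pseudo_F": np.nan, "R2": 1.0, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


def assemble_permanova_row(ss_term: float, df_term: int, ss_res: float,
                           df_res: int, ss_total: float):
    """(MS, pseudo-F, R²) from a term's SS/df and the residual SS/df."""
    if df_res <= 0:
        raise ValueError("df_res must be positive")
    if ss_total <= 0:
        raise ValueError("SS_total must be positive")
    if df_term <= 0:
        return np.nan, np.nan, ss_term / ss_total
    ms = ss_term / df_term
    pseudo_f = ms / (ss_res / df_res)
    return ms, pseudo_f, ss_term / ss_total
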