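"""End-to-end orchestration: ingest/generate -> filter -> rarefy ->
diversity -> distances -> PERMANOVA -> indicator values -> core resilience
-> CCA linkage, from a single configuration with per-stage seeds.

Every stage default mirrors the analysis settings of the study design this
package targets: rarefaction to 6000 reads, 999 PERMANOVA permutations,
1000 permutations for indicator values, distance contrasts and the CCA
test, core prevalence threshold 0.5, and four ordination components per
side of the CCA.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_resilience as core_mod
from . import distances as dist_mod
from . import diversity as div_mod
from . import omics_link as omics_mod
from . import permanova as perm_mod
from .indval import filter_indicators as _filter_indicators
from .indval import indval as _indval
from .synthetic import SyntheticConfig, generate_expression, generate_microbiome
from .tables_io import (ExpressionMatrix, FeatureTable, SampleMetadata,
                        align_tables, write_expression, write_feature_table,
                        write_metadata)

logger = logging.getLogger(__name__)

DEFAULT_FORMULA = "tolerance + temperature + family + part + tolerance:temperature"


@dataclass
class PipelineConfig:
    """Stage settings; defaults are the pipeline's canonical analysis."""

    seed: int = 0
    rarefaction_depth: int = 6000
    shannon_log_base: float = 2.0
    permanova_n_perm: int = 999
    indval_n_perm: int = 1000
    cca_n_perm: int = 1000
    distance_contrast_n_perm: int = 1000
    core_prevalence_threshold: float = 0.5
    core_mode: str = "either"
    cca_k: int = 4
    formula: str = DEFAULT_FORMULA
    indval_group: str = "tolerance"
    indval_alpha: float = 0.05
    lmm_ddf_method: str = "residual"
    synthetic: SyntheticConfig | None = None

    def stage_seed(self, stage: str) -> int:
        """Named per-stage substream of the global seed (below 2**31)."""
        idx = _STAGE_IDS[stage]
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


_STAGE_IDS = {
    "rarefy": 10,
    "distance_contrast": 11,
    "permanova": 12,
    "indval": 13,
    "cca": 14,
    "resilience": 15,
}


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _to_jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _to_jsonable(obj.to_dict())
    return obj


def run_pipeline(config: PipelineConfig, table: FeatureTable | None = None,
                 meta: SampleMetadata | None = None,
                 expr: ExpressionMatrix | None = None,
                 out_dir=None) -> dict:
    """Execute the full analysis and return a machine-readable report.

    If ``table`` is None the synthetic generator (``config.synthetic``, or
    its defaults) supplies the inputs, including the expression matrix.
    Any stage failure raises with the stage name in the message.
    """
    report = {"config": {k: (asdict(v) if isinstance(v, SyntheticConfig) else v)
                         for k, v in asdict(config).items()},
              "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(payload):
            payload["elapsed_s"] = round(time.time() - t0, 3)
            report["stages"][name] = payload
            logger.info("stage %s done in %.2fs", name, payload["elapsed_s"])

        return done

    try:
        done = stage("input")
        if table is None:
            syn = config.synthetic or SyntheticConfig(seed=config.seed)
            table, meta, truth = generate_microbiome(syn)
            if expr is None:
                expr = generate_expression(syn, truth)
            done({"source": "synthetic", "n_samples": table.n_samples,
                  "n_features": table.n_features})
        else:
            if meta is None:
                raise ValueError("metadata required with an input table")
            done({"source": "files", "n_samples": table.n_samples,
                  "n_features": table.n_features})
        table, meta = align_tables(table, meta)

        done = stage("filter")
        table = div_mod.filter_doubletons(table)
        done({"n_features_after": table.n_features})

        done = stage("rarefy")
        table = div_mod.rarefy(table, depth=config.rarefaction_depth,
                               seed=config.stage_seed("rarefy"))
        meta = meta.select_samples(table.sample_ids)
        done({"depth": config.rarefaction_depth, "n_samples_after": table.n_samples,
              "seed": config.stage_seed("rarefy")})

        done = stage("alpha_diversity")
        alpha = div_mod.alpha_diversity(table, log_base=config.shannon_log_base)
        md = meta.data
        lmm_out = {}
        for response in ("shannon", "richness"):
            fit = div_mod.fit_diversity_lmm(alpha[response], meta,
                                            ddf_method=config.lmm_ddf_method)
            lmm_out[response] = {
                "fixed_effects": fit.fixed_effects,
                "family_variance": fit.group_variance,
                "residual_variance": fit.residual_variance,
            }
        done({
            "mean_shannon": {
                temp: float(alpha.loc[(md["temperature"] == temp).to_numpy(), "shannon"].mean())
                for temp in ("warm24", "cold12")},
            "mean_richness": {
                temp: float(alpha.loc[(md["temperature"] == temp).to_numpy(), "richness"].mean())
                for temp in ("warm24", "cold12")},
            "lmm": lmm_out,
        })

        done = stage("beta_diversity")
        dm = dist_mod.bray_curtis(table)
        shift_sel = {
            g: dist_mod.PairSelector(factor="temperature", mode="between",
                                     stratum={"tolerance": g})
            for g in ("resistant", "sensitive")}
        shift_contrast = dist_mod.distance_contrast(
            dm, meta, shift_sel["resistant"], shift_sel["sensitive"],
            n_perm=config.distance_contrast_n_perm,
            seed=config.stage_seed("distance_contrast"), n_comparisons=2)
        warm_sel = {
            g: dist_mod.PairSelector(factor="tolerance", mode="within", level=g,
                                     stratum={"temperature": "warm24"})
            for g in ("resistant", "sensitive")}
        warm_contrast = dist_mod.distance_contrast(
            dm, meta, warm_sel["resistant"], warm_sel["sensitive"],
            n_perm=config.distance_contrast_n_perm,
            seed=config.stage_seed("distance_contrast") + 1, n_comparisons=2)
        done({
            "mean_warm_cold_distance": {
                "resistant": float(shift_contrast.group_a.mean()),
                "sensitive": float(shift_contrast.group_b.mean())},
            "temperature_shift_contrast": {
                "t": shift_contrast.t, "p": shift_contrast.p,
                "corrected_p": shift_contrast.corrected_p},
            "warm_within_group_contrast": {
                "mean_within": {"resistant": float(warm_contrast.group_a.mean()),
                                "sensitive": float(warm_contrast.group_b.mean())},
                "t": warm_contrast.t, "p": warm_contrast.p,
                "corrected_p": warm_contrast.corrected_p},
        })

        done = stage("permanova")
        ptable = perm_mod.adonis(dm, meta, config.formula,
                                 n_perm=config.permanova_n_perm,
                                 seed=config.stage_seed("permanova"))
        done({"table": ptable,
              "interaction_p": float(ptable.loc["tolerance:temperature", "p"])
              if "tolerance:temperature" in ptable.index else None})

        done = stage("indval")
        iv = _indval(table, meta[config.indval_group],
                     n_perm=config.indval_n_perm,
                     seed=config.stage_seed("indval"))
        sig = _filter_indicators(iv, alpha=config.indval_alpha)
        done({"n_features": len(iv), "n_significant": len(sig),
              "top": sig.sort_values("indval", ascending=False).head(10)[
                  ["best_group", "indval", "p"]]})

        done = stage("core_resilience")
        core = core_mod.find_core(table, meta,
                                  prevalence_threshold=config.core_prevalence_threshold,
                                  mode=config.core_mode)
        profile = core_mod.renormalize_core(table, core)
        meta_core = meta.select_samples(profile.percent.index)
        res = core_mod.resilience_contrast(profile, meta_core,
                                           seed=config.stage_seed("resilience"))
        done({"core_size": len(core), "core": core,
              "median_abs_log2_fc": res.median_abs_log2_fc,
              "ranksum_statistic": res.statistic, "p": res.p})

        done = stage("cca")
        if expr is None:
            logger.warning("no expression matrix: CCA stage skipped")
            done({"skipped": True})
        else:
            cca_out = cca_linkage(table, meta, expr, k=config.cca_k,
                                  n_perm=config.cca_n_perm,
                                  seed=config.stage_seed("cca"))
            done(cca_out)

        done = stage("expression_fold_change")
        if expr is None:
            done({"skipped": True})
        else:
            fish_md = fish_metadata(meta).loc[expr.sample_ids]
            fcc = omics_mod.expression_fold_change(expr, fish_md)
            done({"median_abs_log2_fc": fcc.median_abs_log2_fc,
                  "ranksum_statistic": fcc.statistic, "p": fcc.p})
    except Exception as exc:
        failed = [s for s in report["stages"]]
        raise RuntimeError(
            f"pipeline failed after stages {failed}: {exc}") from exc

    report = _to_jsonable(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        write_feature_table(table, out / "feature_table.rarefied.tsv")
        write_metadata(meta, out / "metadata.tsv")
        if expr is not None:
            write_expression(expr, out / "expression.tsv")
    return report


def fish_metadata(meta: SampleMetadata) -> pd.DataFrame:
    """Collapse sample-level metadata to one row per fish."""
    md = meta.data
    return (md.groupby("fish")[["tolerance", "temperature", "family"]]
            .first())


def cca_linkage(table: FeatureTable, meta: SampleMetadata,
                expr: ExpressionMatrix, k: int = 4,
                n_perm: int = 1000, seed: int = 0) -> dict:
    """Posterior-gut microbiome vs liver expression CCA linkage.

    Microbiome scores are principal coordinates of Bray-Curtis on the
    posterior-gut samples (one per fish); expression scores are PCA scores.
    Rows are matched by fish id before the permutation test.
    """
    md = meta.data
    post_ids = [s for s in table.sample_ids if md.loc[s, "part"] == "posterior"]
    if not post_ids:
        post_ids = table.sample_ids  # single-part designs
    sub = table.select_samples(post_ids)
    fish_of = md.loc[sub.sample_ids, "fish"]
    if fish_of.duplicated().any():
        raise ValueError("multiple posterior samples per fish")
    micro_scores = omics_mod.component_scores(sub, method="pcoa_braycurtis", k=k)
    micro_scores.index = fish_of.to_numpy()

    common = [f for f in micro_scores.index if f in set(expr.sample_ids)]
    if len(common) < 8:
        raise ValueError("fewer than 8 fish shared between microbiome and expression")
    expr_scores = omics_mod.component_scores(expr.select_samples(common),
                                             method="pca", k=k)
    result = omics_mod.cca_permutation_test(
        micro_scores.loc[common], expr_scores.loc[common],
        n_perm=n_perm, seed=seed)
    return {
        "k": k,
        "n_fish": len(common),
        "canonical_correlations": result.canonical_correlations,
        "variance_explained": result.variance_explained,
        "permuted_mean": result.permuted_mean,
        "p": result.p,
        "n_perm": n_perm,
    }
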