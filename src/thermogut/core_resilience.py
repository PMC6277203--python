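"""Core-microbiome identification and warm-to-cold fold-change resilience.

The core is the set of taxa present in more than a prevalence threshold
(default 50%) of *individuals* — a fish counts as positive if the feature
occurs in either gut part — within a temperature arm.  Core abundances are
renormalized to percentages within the core community; per tolerance group,
each core taxon's fold change FC = mean percent at cold / mean percent at
warm.  Resilience is contrasted between tolerance groups by a two-sided
Wilcoxon rank-sum test on the |log2 FC| distributions: a buffered
(resilient) microbiome shows smaller absolute log fold-changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .tables_io import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_PREVALENCE_THRESHOLD = 0.5


def _individual_presence(table: FeatureTable, meta: SampleMetadata) -> pd.DataFrame:
    """Fish x feature presence: positive if any of the fish's samples has the feature."""
    md = meta.data.loc[table.sample_ids]
    present = pd.DataFrame(table.counts > 0, index=table.sample_ids,
                           columns=table.feature_ids)
    return present.groupby(md["fish"]).any()


def find_core(table: FeatureTable, meta: SampleMetadata,
              prevalence_threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
              mode: str = "either") -> list:
    """Features whose individual-level prevalence strictly exceeds the
    threshold within the warm arm, the cold arm ("either", default) or
    both arms ("both")."""
    if not 0 < prevalence_threshold < 1:
        raise ValueError("prevalence_threshold must be in (0, 1)")
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    md = meta.data.loc[table.sample_ids]
    fish_presence = _individual_presence(table, meta)
    fish_temp = md.groupby("fish")["temperature"].first()
    prevalences = []
    for temp in ("warm24", "cold12"):
        fish_in_arm = fish_temp.index[fish_temp == temp]
        if len(fish_in_arm) == 0:
            raise ValueError(f"no individuals in temperature arm {temp!r}")
        prevalences.append(fish_presence.loc[fish_in_arm].mean(axis=0))
    prev_warm, prev_cold = prevalences
    if mode == "either":
        in_core = (prev_warm > prevalence_threshold) | (prev_cold > prevalence_threshold)
    else:
        in_core = (prev_warm > prevalence_threshold) & (prev_cold > prevalence_threshold)
    return [f for f, ok in in_core.items() if ok]


@dataclass
class CoreProfile:
    """Renormalized core community: per-sample percentages summing to 100."""

    core: list
    percent: pd.DataFrame
    dropped_samples: list = field(default_factory=list)


def renormalize_core(table: FeatureTable, core) -> CoreProfile:
    """Scale each sample's core counts to percentages summing to 100.

    Samples with no core reads are dropped (and logged).
    """
    core = list(core)
    if not core:
        raise ValueError("core feature set is empty")
    sub = table.data.loc[:, core].astype(float)
    totals = sub.sum(axis=1)
    dropped = list(sub.index[totals == 0])
    if dropped:
        logger.info("renormalize_core: dropping %d samples with no core reads", len(dropped))
        sub = sub.loc[totals > 0]
        totals = totals[totals > 0]
    percent = sub.div(totals, axis=0) * 100.0
    return CoreProfile(core=core, percent=percent, dropped_samples=dropped)


@dataclass
class ResilienceContrast:
    fold_change: pd.DataFrame         # feature x group FC
    log2_fc: pd.DataFrame             # feature x group log2 FC
    pseudo_flagged: dict              # group -> features needing a pseudo warm mean
    statistic: float                  # rank-sum statistic on |log2 FC|
    p: float
    median_abs_log2_fc: dict          # group -> median |log2 FC|


def resilience_contrast(profile: CoreProfile, meta: SampleMetadata,
                        n_perm: int | None = None, seed: int = 0) -> ResilienceContrast:
    """Per-group core fold changes and the between-group rank-sum contrast.

    FC per feature per tolerance group = mean renormalized percent at cold
    / mean at warm (group-level means: warm and cold fish are different
    individuals, so no pairing exists).  Zero warm means are replaced by
    half the smallest nonzero renormalized value and flagged.  The p-value
    is the asymptotic two-sided Wilcoxon rank-sum p, or a Monte-Carlo
    label-permutation p when ``n_perm`` is given.
    """
    md = meta.data.loc[profile.percent.index]
    groups = sorted(md["tolerance"].unique())
    if len(groups) != 2:
        raise ValueError("resilience contrast requires exactly 2 tolerance groups")
    pseudo = profile.percent.to_numpy()
    pseudo = pseudo[pseudo > 0].min() / 2.0 if (pseudo > 0).any() else np.nan

    fc, flagged = {}, {}
    for g in groups:
        rows_g = md["tolerance"] == g
        for temp in ("warm24", "cold12"):
            if not ((md["temperature"] == temp) & rows_g).any():
                raise ValueError(f"group {g!r} lacks temperature arm {temp!r}")
        warm = profile.percent.loc[rows_g & (md["temperature"] == "warm24")].mean(axis=0)
        cold = profile.percent.loc[rows_g & (md["temperature"] == "cold12")].mean(axis=0)
        zero_warm = warm == 0
        flagged[g] = list(warm.index[zero_warm])
        warm = warm.mask(zero_warm, pseudo)
        cold = cold.mask(cold == 0, pseudo)
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
    return ResilienceContrast(
        fold_change=fc,
        log2_fc=log2fc,
        pseudo_flagged=flagged,
        statistic=float(stat),
        p=p,
        median_abs_log2_fc={g: float(np.median(np.abs(log2fc[g]))) for g in groups},
    )
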