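"""Synthetic study-design generator with known ground truth.

Emulates a two-temperature challenge experiment on fish families selected
for cold tolerance: 2 tolerance groups x 3 families x 7 fish per family per
temperature x 2 temperatures x 2 gut parts (168 gut samples from 84 fish).
Counts are Dirichlet-multinomial around a group x temperature composition;
the cold composition is the warm composition perturbed by log-normal
fold-changes whose scale differs between tolerance groups (the sensitive
group shifts more), a fraction of non-core taxa is absent at cold (lower
cold richness), and the Dirichlet concentration is lower at cold (more
overdispersion under stress).  A per-fish latent factor perturbs both the
microbiome composition and a liver-expression matrix, so a canonical
correlation between the two data sets has recoverable signal of tunable
strength.

One global seed drives an independent named stream per artifact
(structure / counts / expression) so that, e.g., regenerating expression
does not disturb the count draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables_io import ExpressionMatrix, FeatureTable, SampleMetadata

_STREAMS = {"structure": 1, "counts": 2, "expression": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the experimental design scale: 2 tolerance groups,
    3 families per group, 7 fish per family in each temperature arm, both
    gut parts sampled, ~20k reads per sample rarefiable to 6000.
    ``shift_resistant`` (delta_R) and ``shift_sensitive`` (delta_S) scale
    the per-taxon warm-to-cold log fold-changes of each group; delta_R <=
    delta_S encodes the buffered microbiome response of resistant hosts.
    """

    seed: int = 0
    n_families_per_group: int = 3
    fish_per_family: int = 7
    parts: int = 2
    n_taxa: int = 150
    n_core_taxa: int = 11
    depth_mean: int = 20000
    dm_concentration_warm: float = 200.0
    dm_concentration_cold: float = 100.0
    shift_resistant: float = 0.3
    shift_sensitive: float = 1.0
    diversity_drop_cold: float = 0.3
    n_transcripts: int = 400
    latent_dim: int = 4
    latent_loading: float = 0.9
    noise_sd: float = 1.0
    # secondary effect scales (log-composition units)
    baseline_sd: float = 2.0
    core_boost: float = 3.5
    tolerance_sd: float = 0.4
    family_sd: float = 0.15
    part_sd: float = 0.8
    microbiome_latent_scale: float = 0.4
    expression_shift_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.shift_resistant > self.shift_sensitive:
            raise ValueError("shift_resistant (delta_R) must be <= shift_sensitive (delta_S)")
        if self.shift_resistant < 0:
            raise ValueError("shift scales must be non-negative")
        if self.dm_concentration_warm <= 0 or self.dm_concentration_cold <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if not 0 <= self.diversity_drop_cold < 1:
            raise ValueError("diversity_drop_cold must be in [0, 1)")
        if self.n_core_taxa > self.n_taxa:
            raise ValueError("n_core_taxa exceeds n_taxa")
        for name in ("n_families_per_group", "fish_per_family", "parts", "n_taxa",
                     "depth_mean", "n_transcripts", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth the generator committed to.

    baseline_composition: group -> warm composition vector (sums to 1).
    cold_lfc: group -> per-taxon log fold-change applied at cold.
    dropped_at_cold: indices of taxa zeroed in the cold arm.
    core_taxa: feature ids constructed to exceed 50% prevalence.
    latent_scores: per-fish latent factor scores (fish x latent_dim).
    """

    baseline_composition: dict
    cold_lfc: dict
    dropped_at_cold: np.ndarray
    core_taxa: list
    latent_scores: pd.DataFrame
    config: SyntheticConfig = field(repr=False, default=None)


PARTS = ("anterior", "posterior")
GROUPS = ("resistant", "sensitive")
TEMPS = ("warm24", "cold12")


def _design(config: SyntheticConfig) -> pd.DataFrame:
    """Enumerate the sample sheet implied by the factorial design."""
    rows = []
    for gi, group in enumerate(GROUPS):
        for fam in range(config.n_families_per_group):
            family = f"{group[0].upper()}{fam + 1}"
            for temp in TEMPS:
                for k in range(config.fish_per_family):
                    fish = f"{family}_{temp}_{k + 1:02d}"
                    for part in PARTS[: config.parts]:
                        rows.append({
                            "sample_id": f"{fish}_{part}",
                            "tolerance": group,
                            "temperature": temp,
                            "family": family,
                            "part": part,
                            "fish": fish,
                        })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_microbiome(config: SyntheticConfig):
    """Draw the count table, metadata and ground truth.

    Returns
    -------
    (FeatureTable, SampleMetadata, SyntheticTruth)
        Counts are Dirichlet-multinomial; each sample's total equals its
        Poisson(depth_mean) library size.  Fully reproducible from
        ``config.seed``.
    """
    rng = _rng(config.seed, "structure")
    p = config.n_taxa
    taxa = [f"taxon_{i + 1:04d}" for i in range(p)]

    base_log = rng.normal(0.0, config.baseline_sd, size=p)
    core_idx = rng.choice(p, size=config.n_core_taxa, replace=False)
    # core taxa sit in a narrow high-abundance band so their prevalence
    # exceeds 50% in both temperature arms by construction
    base_log[core_idx] = rng.normal(config.core_boost, 0.5, size=config.n_core_taxa)

    tol_off = {g: rng.normal(0.0, config.tolerance_sd, size=p) for g in GROUPS}
    shifts = {"resistant": config.shift_resistant, "sensitive": config.shift_sensitive}
    # one shared cold-response direction, attenuated in the resistant group:
    # both groups face the same stressor, the buffered host damps its effect
    cold_response = rng.normal(0.0, 1.0, size=p)
    cold_lfc = {g: shifts[g] * cold_response for g in GROUPS}

    non_core = np.setdiff1d(np.arange(p), core_idx)
    n_drop = int(round(config.diversity_drop_cold * p))
    n_drop = min(n_drop, len(non_core))
    dropped = rng.choice(non_core, size=n_drop, replace=False) if n_drop else np.array([], int)

    part_off = {pt: rng.normal(0.0, config.part_sd, size=p) for pt in PARTS[: config.parts]}

    meta_df = _design(config)
    families = sorted(meta_df["family"].unique())
    fam_off = {f: rng.normal(0.0, config.family_sd, size=p) for f in families}

    fish_ids = sorted(meta_df["fish"].unique())
    eta = rng.normal(0.0, 1.0, size=(len(fish_ids), config.latent_dim))
    latent_scores = pd.DataFrame(
        eta, index=fish_ids, columns=[f"factor_{t + 1}" for t in range(config.latent_dim)]
    )
    w_micro = rng.normal(0.0, config.microbiome_latent_scale, size=(config.latent_dim, p))

    def softmax(logc):
        e = np.exp(logc - logc.max())
        return e / e.sum()

    baseline_composition = {g: softmax(base_log + tol_off[g]) for g in GROUPS}

    crng = _rng(config.seed, "counts")
    meta_df = meta_df.sort_index()
    counts = np.zeros((len(meta_df), p), dtype=np.int64)
    conc = {"warm24": config.dm_concentration_warm, "cold12": config.dm_concentration_cold}
    for si, (sid, row) in enumerate(meta_df.iterrows()):
        logc = (
            base_log
            + tol_off[row["tolerance"]]
            + fam_off[row["family"]]
            + part_off[row["part"]]
            + latent_scores.loc[row["fish"]].to_numpy() @ w_micro
        )
        if row["temperature"] == "cold12":
            logc = logc + cold_lfc[row["tolerance"]]
        comp = softmax(logc)
        if row["temperature"] == "cold12" and len(dropped):
            comp[dropped] = 0.0
            comp /= comp.sum()
        depth = crng.poisson(config.depth_mean)
        present = comp > 0
        alpha = conc[row["temperature"]] * comp[present]
        probs = crng.dirichlet(alpha)
        counts[si, present] = crng.multinomial(depth, probs)

    table = FeatureTable(pd.DataFrame(counts, index=meta_df.index, columns=taxa), kind="taxa")
    meta = SampleMetadata(meta_df)
    truth = SyntheticTruth(
        baseline_composition=baseline_composition,
        cold_lfc=cold_lfc,
        dropped_at_cold=np.sort(dropped),
        core_taxa=[taxa[i] for i in np.sort(core_idx)],
        latent_scores=latent_scores,
        config=config,
    )
    return table, meta, truth


def generate_expression(config: SyntheticConfig, truth: SyntheticTruth) -> ExpressionMatrix:
    """Liver-expression matrix sharing latent structure with the microbiome.

    One row per fish (expression is an organ-level measurement).  Log
    expression = latent_loading * (latent scores x transcript loadings)
    + a per-group cold shift scaled by delta_group + Gaussian noise, then
    exponentiated to a non-negative scale.
    """
    if truth.latent_scores is None or len(truth.latent_scores) == 0:
        raise ValueError("truth carries no latent scores")
    if truth.config is not None and truth.config.seed != config.seed:
        raise ValueError("config/truth seed mismatch")
    rng = _rng(config.seed, "expression")
    fish_ids = list(truth.latent_scores.index)
    n, m = len(fish_ids), config.n_transcripts
    w_expr = rng.normal(0.0, 1.0, size=(config.latent_dim, m)) / np.sqrt(config.latent_dim)
    shifts = {"resistant": config.shift_resistant, "sensitive": config.shift_sensitive}
    # shared transcriptional cold response, attenuated in resistant hosts
    cold_response = rng.normal(0.0, 1.0, size=m)
    cold_shift = {
        g: config.expression_shift_scale * shifts[g] * cold_response
        for g in GROUPS
    }
    eta = truth.latent_scores.to_numpy()
    log_expr = config.latent_loading * (eta @ w_expr)
    log_expr += rng.normal(0.0, config.noise_sd, size=(n, m))
    for i, fish in enumerate(fish_ids):
        family = fish.split("_")[0]
        group = "resistant" if family.startswith("R") else "sensitive"
        if "_cold12_" in fish:
            log_expr[i] += cold_shift[group]
    values = np.exp(log_expr)
    transcripts = [f"transcript_{j + 1:05d}" for j in range(m)]
    return ExpressionMatrix(pd.DataFrame(values, index=fish_ids, columns=transcripts))
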