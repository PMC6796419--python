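"""Seeded synthetic data emulating the study design.

Generates negative-binomial count matrices over seven sample groups (two
brain regions x {symptomatic disease, asymptomatic gene-positive, control,
reference population}), with per-gene disease, region, disease x region
interaction, age and sex effects on the log2 scale, plus per-sample
sequencing-depth factors.  The true effect sizes, dispersions and membership
flags are returned so downstream recovery can be scored against ground truth.

The count model matches the analysis model: counts for gene g in sample j are
NB with mean ``depth_j * q_g * 2**(x_j' beta_g)`` and dispersion ``alpha_g``
(variance = mu + alpha * mu**2), where ``x_j`` holds the disease, region,
interaction, standardized-age and sex covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts_io import validate_counts, validate_metadata
from .gene_sets import write_gmt

__all__ = ["SimConfig", "SimTruth", "generate_dataset", "generate_gene_sets",
           "STUDY_GROUP_SIZES"]

#: Sample sizes of the study design: 26 symptomatic (HD) and 56 control BA9,
#: 3 asymptomatic gene-positive (HD+) BA9, 2 HD+ and 2 control caudate, and
#: the 90 BA9 / 102 CAU reference-population (GTEx) samples.
STUDY_GROUP_SIZES: dict[str, int] = {
    "HD_BA9": 26,
    "C_BA9": 56,
    "HD+_BA9": 3,
    "HD+_CAU": 2,
    "C_CAU": 2,
    "GTEx_BA9": 90,
    "GTEx_CAU": 102,
}

_DISEASED_GROUPS = {"HD", "HD+"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Fractions are independent: a gene may carry both a disease and an
    interaction effect.  Effect magnitudes are |L2FC| draws; signs are
    Rademacher.  ``dispersion_lognorm`` is (mean, sd) of log(alpha), chosen
    so typical dispersions span roughly 0.01-1.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    n_genes: int = 2000
    frac_de: float = 0.10
    frac_region: float = 0.10
    frac_interaction: float = 0.05
    l2fc_loc: float = 2.0          # |L2FC| of disease / region effects
    l2fc_scale: float = 0.5
    interaction_l2fc_loc: float = 4.0   # scale of the caudate-specific disease effect
    interaction_l2fc_scale: float = 0.5
    dispersion_lognorm: tuple[float, float] = (np.log(0.1), 1.0)
    age_effect_scale: float = 0.01      # log2 per year, on genes with covariate effects
    sex_effect_scale: float = 0.2       # log2, M vs F
    frac_covariate: float = 0.2
    baseline_mean_log_range: tuple[float, float] = (np.log(20.0), np.log(2000.0))
    library_size_range: tuple[float, float] = (0.5, 2.0)
    age_range: tuple[float, float] = (40.0, 90.0)
    seed: int = 0

    def __post_init__(self):
        for label, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {label!r} has size {n}; all sizes must be >= 1")
        for name in ("frac_de", "frac_region", "frac_interaction", "frac_covariate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class SimTruth:
    """Ground truth per gene: effects, dispersions and membership flags."""

    table: pd.DataFrame  # index gene_id; columns l2fc_disease, l2fc_region,
    #                      l2fc_interaction, alpha, baseline_mean, is_de,
    #                      is_region, is_interaction

    @property
    def de_genes(self) -> list[str]:
        return self.table.index[self.table["is_de"]].tolist()

    @property
    def region_genes(self) -> list[str]:
        return self.table.index[self.table["is_region"]].tolist()

    @property
    def interaction_genes(self) -> list[str]:
        return self.table.index[self.table["is_interaction"]].tolist()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _signed_effects(rng, n, flags, loc, scale):
    effects = np.zeros(n)
    k = int(flags.sum())
    if k:
        magnitude = np.abs(rng.normal(loc, scale, size=k))
        sign = rng.choice([-1.0, 1.0], size=k)
        effects[flags] = sign * magnitude
    return effects


def generate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw (counts, metadata, truth) for the configured design.

    Identical config (including seed) gives bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"GSYN{i:05d}" for i in range(n)]

    # -- samples ----------------------------------------------------------
    rows = []
    for label, size in config.group_sizes.items():
        group, _, region = label.rpartition("_")
        if region not in ("BA9", "CAU"):
            raise ValueError(f"group label {label!r} must end in '_BA9' or '_CAU'")
        for k in range(size):
            rows.append((f"{label}_{k:03d}", group, region))
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "region"]).set_index("sample_id")
    n_samples = len(meta)
    meta["age_at_death"] = np.round(rng.uniform(*config.age_range, size=n_samples), 1)
    meta["sex"] = np.where(rng.random(n_samples) < 0.5, "M", "F")

    disease = meta["group"].isin(_DISEASED_GROUPS).to_numpy(float)
    region = (meta["region"] == "CAU").to_numpy(float)
    interaction = disease * region
    age_z = (meta["age_at_death"].to_numpy() - np.mean(config.age_range)) / 15.0
    sex = (meta["sex"] == "M").to_numpy(float)

    # -- per-gene truth ----------------------------------------------------
    is_de = rng.random(n) < config.frac_de
    is_region = rng.random(n) < config.frac_region
    is_interaction = rng.random(n) < config.frac_interaction
    l2fc_disease = _signed_effects(rng, n, is_de, config.l2fc_loc, config.l2fc_scale)
    l2fc_region = _signed_effects(rng, n, is_region, config.l2fc_loc, config.l2fc_scale)
    l2fc_interaction = _signed_effects(
        rng, n, is_interaction, config.interaction_l2fc_loc, config.interaction_l2fc_scale)
    has_covariate = rng.random(n) < config.frac_covariate
    beta_age = np.where(has_covariate, rng.normal(0, config.age_effect_scale, n), 0.0)
    beta_sex = np.where(has_covariate, rng.normal(0, config.sex_effect_scale, n), 0.0)
    alpha = np.exp(rng.normal(*config.dispersion_lognorm, size=n))
    baseline = np.exp(rng.uniform(*config.baseline_mean_log_range, size=n))
    depth = rng.uniform(*config.library_size_range, size=n_samples)

    # -- counts ------------------------------------------------------------
    log2_mu = (l2fc_disease[:, None] * disease[None, :]
               + l2fc_region[:, None] * region[None, :]
               + l2fc_interaction[:, None] * interaction[None, :]
               + beta_age[:, None] * (age_z * 15.0)[None, :]
               + beta_sex[:, None] * sex[None, :])
    mu = depth[None, :] * baseline[:, None] * np.exp2(log2_mu)
    # numpy's NB is (n_successes, p); mean mu, var mu + alpha mu^2
    size_param = 1.0 / np.maximum(alpha, 1e-12)
    p = size_param[:, None] / (size_param[:, None] + mu)
    counts = rng.negative_binomial(size_param[:, None], p)
    counts = pd.DataFrame(counts, index=gene_ids, columns=meta.index)

    truth = SimTruth(pd.DataFrame({
        "l2fc_disease": l2fc_disease,
        "l2fc_region": l2fc_region,
        "l2fc_interaction": l2fc_interaction,
        "beta_age_log2_per_year": beta_age,
        "beta_sex_log2": beta_sex,
        "alpha": alpha,
        "baseline_mean": baseline,
        "is_de": is_de,
        "is_region": is_region,
        "is_interaction": is_interaction,
    }, index=pd.Index(gene_ids, name="gene_id")))

    validate_counts(counts)
    validate_metadata(meta, counts)
    return counts, meta, truth


_FLAG_EFFECT = {"is_de": "l2fc_disease", "is_region": "l2fc_region",
                "is_interaction": "l2fc_interaction"}


def generate_gene_sets(truth: SimTruth, n_sets: int, set_size_range: tuple[int, int],
                       frac_enriched: float, seed: int, *,
                       target_flag: str = "is_de", enrich_rate: float = 0.8,
                       direction: int = 1, start_index: int = 0
                       ) -> dict[str, list[str]]:
    """Draw a gene-set collection; a fraction of sets over-sample true-effect genes.

    Enriched sets draw ``enrich_rate`` of their members from genes with
    ``target_flag`` set in the truth table (uniformly from the rest
    otherwise); non-enriched sets are uniform draws over all genes.
    ``direction`` restricts the over-sampled genes to positive (+1) or
    negative (-1) effects — real pathways move coherently, and a
    direction-agnostic set puts hits at both ends of a fold-change ranking,
    cancelling the enrichment walk; 0 ignores sign.  Set names encode
    enrichment status (``ENRSET``/``RNDSET``) so tests can score detection
    without a side table.
    """
    lo, hi = set_size_range
    if lo < 1:
        raise ValueError("set size lower bound must be >= 1")
    genes = truth.table.index.to_numpy()
    if hi > len(genes):
        raise ValueError("set sizes exceed the number of genes")
    if target_flag not in truth.table.columns:
        raise ValueError(f"unknown truth flag {target_flag!r}")
    flag = truth.table[target_flag].to_numpy(bool)
    if direction and target_flag in _FLAG_EFFECT:
        effect = truth.table[_FLAG_EFFECT[target_flag]].to_numpy()
        flag = flag & (np.sign(effect) == np.sign(direction))
    flagged = genes[flag]
    unflagged = genes[~flag]
    rng = np.random.default_rng(seed)
    n_enriched = int(round(frac_enriched * n_sets))
    tag = target_flag[3:].upper()
    collection: dict[str, list[str]] = {}
    for i in range(start_index, start_index + n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = (i - start_index) < n_enriched and len(flagged) > 0
        if enriched:
            k_flagged = min(int(round(enrich_rate * size)), len(flagged))
            members = list(rng.choice(flagged, size=k_flagged, replace=False))
            rest = size - k_flagged
            if rest:
                members += list(rng.choice(unflagged, size=min(rest, len(unflagged)),
                                           replace=False))
            name = f"ENRSET_{tag}_{i:04d}"
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            name = f"RNDSET_{i:04d}"
        collection[name] = sorted(members)
    return collection


def write_dataset(counts: pd.DataFrame, meta: pd.DataFrame, truth: SimTruth,
                  gene_sets: dict[str, list[str]] | None, outdir) -> None:
    """Write counts/metadata/truth TSVs (and the GMT, if given) under outdir."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")
    truth.write(outdir / "truth.tsv")
    if gene_sets is not None:
        write_gmt(gene_sets, outdir / "gene_sets.gmt")
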