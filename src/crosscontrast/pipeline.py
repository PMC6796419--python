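"""End-to-end orchestration of the five contrasts and downstream comparisons.

Stages: (simulate or load) -> normalize -> per-contrast NB Wald DE -> Welch
comparisons (3)vs(5) and (1)vs(2) with the early/late partition -> preranked
GSEA per ranking -> agreement classes + leading-edge graphs -> random-forest
consistency (three panel modes) -> JSON run manifest.

One global seed fans out to per-stage seeds through ``SeedSequence([seed,
stage_index])`` so any stage can be re-run individually and byte-identically
from cached upstream outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counts_io import (STUDY_CONTRASTS, ContrastSpec, compute_size_factors,
                        read_counts, read_metadata, validate_metadata)
from .diffexp import run_contrast, write_de_table
from .gene_sets import read_gmt
from .gsea import preranked_gsea, rank_by_score, write_gsea_table
from .lfc_ttest import partition_early_late, rank_by_t, welch_compare
from .rf_consistency import ForestProtocol, run_cv_forests
from .setspace import (assign_agreement_classes, build_leading_edge_graph,
                       nes_matrix, write_graph)
from .simdata import SimConfig, generate_dataset, generate_gene_sets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "FUNCTIONAL_CATEGORIES",
           "synthetic_category_map"]

#: The ten high-level functional category labels used to bin gene sets.
FUNCTIONAL_CATEGORIES = (
    "Angiogenesis/BBB", "Apoptosis", "Cell Cycle/Development",
    "Cytoskeleton/ECM", "Immune Response/Cancer", "Metabolism",
    "Neuron System", "Protein Folding/Other", "Signaling",
    "Transcription/Translation",
)


def synthetic_category_map(set_names) -> dict[str, str]:
    """Round-robin assignment of set names to the ten category labels.

    A stand-in for the manual biological curation, which is inherently a
    user-supplied mapping; patterns are exact set names.
    """
    return {name: FUNCTIONAL_CATEGORIES[i % len(FUNCTIONAL_CATEGORIES)]
            for i, name in enumerate(sorted(set_names))}


def stage_seed(base_seed: int, stage: int) -> int:
    """Deterministic per-stage integer seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence([base_seed, stage]).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Everything one run needs; paths may be None when simulating."""

    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    category_map_path: str | None = None
    sim: SimConfig | None = None
    n_gene_sets: int = 100
    gene_set_size_range: tuple[int, int] = (15, 80)
    frac_enriched_sets: float = 0.3
    contrasts: dict[str, ContrastSpec] = field(
        default_factory=lambda: dict(STUDY_CONTRASTS))
    alpha: float = 0.05
    overlap_threshold: float = 0.25
    gsea_n_perm: int = 1000
    gsea_size_bounds: tuple[int, int] = (15, 500)
    forest: ForestProtocol = field(default_factory=lambda: ForestProtocol(
        n_trees=1000, n_repetitions=50))
    seed: int = 0

    def __post_init__(self):
        names = [c.name for c in self.contrasts.values()]
        if len(names) != len(set(names)):
            raise ValueError("contrast names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "forest" in raw and raw["forest"] is not None:
            raw["forest"] = ForestProtocol(**raw["forest"])
        for key in ("gene_set_size_range", "gsea_size_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.counts_path is not None:
        counts = read_counts(config.counts_path)
        if config.metadata_path is None:
            raise ValueError("metadata_path required when counts_path is given")
        meta = read_metadata(config.metadata_path)
        truth = None
    else:
        sim = config.sim or SimConfig(seed=stage_seed(config.seed, 0))
        counts, meta, truth = generate_dataset(sim)
    validate_metadata(meta, counts)

    if config.gmt_path is not None:
        gene_sets = read_gmt(config.gmt_path)
    elif truth is not None:
        # two flavours of enriched sets: disease-responsive (show up in the
        # disease contrasts) and interaction-targeted (only in the
        # region-specific comparison), so all agreement classes can occur
        n_dis = (2 * config.n_gene_sets) // 3
        gene_sets = generate_gene_sets(
            truth, n_dis, config.gene_set_size_range,
            config.frac_enriched_sets, seed=stage_seed(config.seed, 1))
        gene_sets.update(generate_gene_sets(
            truth, config.n_gene_sets - n_dis, config.gene_set_size_range,
            config.frac_enriched_sets, seed=stage_seed(config.seed, 2),
            target_flag="is_interaction", start_index=n_dis))
    else:
        raise ValueError("gmt_path required when counts are loaded from disk")

    if config.category_map_path is not None:
        categories = yaml.safe_load(Path(config.category_map_path).read_text())
    else:
        categories = synthetic_category_map(gene_sets)
    return counts, meta, truth, gene_sets, categories


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; writes all tables under ``outdir`` and returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "overlap_threshold": config.overlap_threshold,
        "gsea_n_perm": config.gsea_n_perm,
        "forest": dataclasses.asdict(config.forest),
    }

    t0 = time.perf_counter()
    counts, meta, truth, gene_sets, categories = _load_inputs(config)
    (outdir / "inputs").mkdir(exist_ok=True)
    counts.to_csv(outdir / "inputs" / "counts.tsv", sep="\t", index_label="gene_id")
    meta.to_csv(outdir / "inputs" / "metadata.tsv", sep="\t", index_label="sample_id")
    if truth is not None:
        truth.write(outdir / "inputs" / "truth.tsv")
    timings["inputs"] = time.perf_counter() - t0

    # -- differential expression ------------------------------------------
    t0 = time.perf_counter()
    size_factors = compute_size_factors(counts)
    size_factors.to_csv(outdir / "inputs" / "size_factors.tsv", sep="\t",
                        index_label="sample_id", header=True)
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    de: dict[str, pd.DataFrame] = {}
    for label, spec in config.contrasts.items():
        logger.info("stage de: contrast %s", label)
        de[label] = run_contrast(counts, meta, spec, size_factors=size_factors)
        write_de_table(de[label], de_dir / f"analysis_{label}.tsv")
    manifest["contrasts"] = {l: {"n_total": int(d["n_total"].iloc[0]),
                                 "n_genes_tested": int(len(d))}
                             for l, d in de.items()}
    timings["diffexp"] = time.perf_counter() - t0

    # -- Welch comparisons -------------------------------------------------
    t0 = time.perf_counter()
    cmp_dir = outdir / "compare"
    cmp_dir.mkdir(exist_ok=True)
    welch: dict[str, pd.DataFrame] = {}
    for label, (a, b) in {"3v5": ("3", "5"), "1v2": ("1", "2")}.items():
        if a in de and b in de:
            welch[label] = welch_compare(de[a], de[b])
            welch[label].to_csv(cmp_dir / f"welch_{label}.tsv", sep="\t",
                                index_label="gene_id")
    if "1v2" in welch:
        part = partition_early_late(de["1"], de["2"], welch["1v2"],
                                    alpha=config.alpha)
        part["genes"].to_csv(cmp_dir / "early_late_genes.tsv", sep="\t",
                             index_label="gene_id")
        part["table"].to_csv(cmp_dir / "early_late_table.tsv", sep="\t", header=True)
        part["only_in_1"].to_csv(cmp_dir / "early_late_only_in_1.tsv", sep="\t",
                                 index_label="gene_id")
        part["only_in_2"].to_csv(cmp_dir / "early_late_only_in_2.tsv", sep="\t",
                                 index_label="gene_id")
    timings["lfc_ttest"] = time.perf_counter() - t0

    # -- GSEA --------------------------------------------------------------
    t0 = time.perf_counter()
    gsea_dir = outdir / "gsea"
    gsea_dir.mkdir(exist_ok=True)
    rankings: dict[str, pd.Series] = {}
    for label in ("1", "2", "4"):
        if label in de:
            scores = de[label]["log2FoldChange"].dropna()
            rankings[label] = rank_by_score(scores)
    if "3v5" in welch:
        rankings["3v5"] = rank_by_t(welch["3v5"])
    gsea_results: dict[str, pd.DataFrame] = {}
    for i, (label, ranking) in enumerate(rankings.items()):
        gsea_results[label] = preranked_gsea(
            ranking, gene_sets, n_perm=config.gsea_n_perm,
            size_bounds=config.gsea_size_bounds,
            seed=stage_seed(config.seed, 10 + i))
        write_gsea_table(gsea_results[label], gsea_dir / f"analysis_{label}.tsv")
    timings["gsea"] = time.perf_counter() - t0

    # -- agreement classes and graphs --------------------------------------
    t0 = time.perf_counter()
    set_dir = outdir / "setspace"
    set_dir.mkdir(exist_ok=True)
    records = assign_agreement_classes(gsea_results, alpha=config.alpha,
                                       categories=categories)
    records.to_csv(set_dir / "agreement_records.tsv", sep="\t",
                   index_label="set_name")
    nes_matrix(gsea_results).to_csv(set_dir / "nes_matrix.tsv", sep="\t")
    if len(records):
        # leading edges from the most CAU-specific analysis each set is
        # significant in (3v5 first, then 1, 2, 4)
        le_source = {}
        for name in records.index:
            for label in ("3v5", "1", "2", "4"):
                if (label in gsea_results and name in gsea_results[label].index
                        and records.loc[name, f"sig_{label}"]):
                    le_source[name] = gsea_results[label].loc[name, "leadingEdge"]
                    break
        le_df = pd.DataFrame({"leadingEdge": pd.Series(le_source)})
        le_df = le_df[le_df["leadingEdge"].apply(len) > 0]
        if len(le_df):
            graph = build_leading_edge_graph(le_df, config.overlap_threshold)
            write_graph(graph, set_dir / "leading_edge_graph_edges.tsv",
                        set_dir / "leading_edge_graph.graphml")
    manifest["agreement_class_counts"] = (
        records["agreement_class"].value_counts().to_dict() if len(records) else {})
    timings["setspace"] = time.perf_counter() - t0

    # -- random forest consistency ------------------------------------------
    t0 = time.perf_counter()
    rf_dir = outdir / "rf"
    rf_dir.mkdir(exist_ok=True)
    is_hd = (meta["group"] == "HD") & (meta["region"] == "BA9")
    is_c = (meta["group"] == "C") & (meta["region"] == "BA9")
    rf_samples = meta.index[is_hd | is_c]
    normalized = counts / size_factors
    labels = meta.loc[rf_samples, "group"]
    queries = normalized[meta.index[meta["group"] == "HD+"]]
    for k, mode in enumerate(("top_de", "random", "null")):
        protocol = dataclasses.replace(config.forest, panel_mode=mode,
                                       seed=stage_seed(config.seed, 20 + k))
        run = run_cv_forests(normalized[rf_samples], labels, protocol,
                             de_ranking=de.get("1"), queries=queries,
                             pos_label="HD")
        run.summary.to_csv(rf_dir / f"metrics_{mode}.tsv", sep="\t",
                           index_label="metric")
        if run.query_votes is not None:
            run.query_votes.to_csv(rf_dir / f"query_votes_{mode}.tsv", sep="\t",
                                   index_label="sample_id")
        manifest.setdefault("rf", {})[mode] = {
            "mean_test_accuracy": run.mean_test_accuracy}
    timings["rf"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
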