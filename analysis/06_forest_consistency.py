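"""Random-forest classification consistency for the asymptomatic samples.

Forests are trained to separate symptomatic-disease from control cortex
under three panel regimes (top DE genes, random genes, label-randomized
null), then the held-out asymptomatic carriers are pushed through every
forest: the fraction of trees voting each class is their classification
consistency.  Writes metric and vote tables under results/rf/.
"""

import argparse
import dataclasses
from pathlib import Path

from crosscontrast.counts_io import (compute_size_factors, read_counts,
                                     read_metadata)
from crosscontrast.diffexp import read_de_table
from crosscontrast.pipeline import stage_seed
from crosscontrast.rf_consistency import ForestProtocol, run_cv_forests


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-trees", type=int, default=1000)
    parser.add_argument("--n-reps", type=int, default=100)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/rf"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = read_counts(args.datadir / "counts.tsv")
    meta = read_metadata(args.datadir / "metadata.tsv")
    normalized = counts / compute_size_factors(counts)
    mask = ((meta["group"] == "HD") | (meta["group"] == "C")) \
        & (meta["region"] == "BA9")
    samples = meta.index[mask]
    labels = meta.loc[samples, "group"]
    queries = normalized[meta.index[meta["group"] == "HD+"]]
    de1 = read_de_table(args.dedir / "analysis_1.tsv")

    base = ForestProtocol(n_trees=args.n_trees, panel_size=250,
                          n_repetitions=args.n_reps)
    for k, mode in enumerate(("top_de", "random", "null")):
        protocol = dataclasses.replace(base, panel_mode=mode,
                                       seed=stage_seed(args.seed, 20 + k))
        run = run_cv_forests(normalized[samples], labels, protocol,
                             de_ranking=de1, queries=queries, pos_label="HD")
        run.summary.to_csv(args.outdir / f"metrics_{mode}.tsv", sep="\t",
                           index_label="metric")
        run.query_votes.to_csv(args.outdir / f"query_votes_{mode}.tsv",
                               sep="\t", index_label="sample_id")
        s = run.summary["mean"]
        print(f"{mode:7s}: train {s['train_accuracy']:.3f}, "
              f"test {s['test_accuracy']:.3f} "
              f"+-{run.summary.loc['test_accuracy', 'sd']:.3f}, "
              f"sens {s['sensitivity']:.3f}, spec {s['specificity']:.3f}")
        votes = run.query_votes["HD"]
        print("         HD-vote fractions: "
              + ", ".join(f"{i}={v:.3f}" for i, v in votes.items()))


if __name__ == "__main__":
    main()
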