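"""Generate the synthetic study: counts, metadata, ground truth, gene sets.

Emulates the seven-group post-mortem brain design (symptomatic disease,
asymptomatic gene-positive and control samples in two regions, plus the
large reference population) with negative-binomial counts carrying disease,
region, disease x region, age and sex effects.  Writes everything the later
steps read under results/data/.
"""

import argparse
from pathlib import Path

from crosscontrast.pipeline import stage_seed
from crosscontrast.simdata import (SimConfig, generate_dataset,
                                   generate_gene_sets, write_dataset)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-genes", type=int, default=2000)
    parser.add_argument("--n-sets", type=int, default=120)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = SimConfig(n_genes=args.n_genes, seed=stage_seed(args.seed, 0))
    counts, meta, truth = generate_dataset(config)

    n_dis = (2 * args.n_sets) // 3
    sets = generate_gene_sets(truth, n_dis, (15, 80), 0.3,
                              seed=stage_seed(args.seed, 1))
    sets.update(generate_gene_sets(truth, args.n_sets - n_dis, (15, 80), 0.3,
                                   seed=stage_seed(args.seed, 2),
                                   target_flag="is_interaction",
                                   start_index=n_dis))
    write_dataset(counts, meta, truth, sets, args.outdir)

    sizes = meta.groupby(["group", "region"]).size()
    print(f"wrote {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"to {args.outdir}")
    print(sizes.to_string())
    print(f"{int(truth.table.is_de.sum())} disease genes, "
          f"{int(truth.table.is_region.sum())} region genes, "
          f"{int(truth.table.is_interaction.sum())} interaction genes; "
          f"{len(sets)} gene sets")


if __name__ == "__main__":
    main()
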