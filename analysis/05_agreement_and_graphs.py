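"""Agreement classes across analyses and the leading-edge overlap graph.

Combines the four GSEA tables, labels every significant-anywhere set with
its agreement class (how specific its enrichment is to the asymptomatic
caudate), overlays the synthetic functional-category map, and casts the
sets as a graph whose edges join sets sharing >25% of their leading-edge
genes.  Writes tables and GraphML under results/setspace/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosscontrast.gsea import read_gsea_table
from crosscontrast.pipeline import synthetic_category_map
from crosscontrast.setspace import (assign_agreement_classes,
                                    build_leading_edge_graph, nes_matrix,
                                    write_graph)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--gseadir", type=Path, default=Path("results/gsea"))
    parser.add_argument("--outdir", type=Path, default=Path("results/setspace"))
    parser.add_argument("--overlap", type=float, default=0.25)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    results = {label: read_gsea_table(args.gseadir / f"analysis_{label}.tsv")
               for label in ("1", "2", "4", "3v5")}
    all_sets = set().union(*[set(r.index) for r in results.values()])
    records = assign_agreement_classes(results,
                                       categories=synthetic_category_map(all_sets))
    records.to_csv(args.outdir / "agreement_records.tsv", sep="\t",
                   index_label="set_name")
    nes_matrix(results).to_csv(args.outdir / "nes_matrix.tsv", sep="\t")
    print("agreement classes:",
          records["agreement_class"].value_counts().to_dict())

    # leading edges from the most caudate-specific analysis each set shows in
    le = {}
    for name in records.index:
        for label in ("3v5", "1", "2", "4"):
            if name in results[label].index and records.loc[name, f"sig_{label}"]:
                edge = results[label].loc[name, "leadingEdge"]
                if edge:
                    le[name] = edge
                break
    if le:
        graph = build_leading_edge_graph(
            pd.DataFrame({"leadingEdge": pd.Series(le)}), args.overlap)
        write_graph(graph, args.outdir / "leading_edge_graph_edges.tsv",
                    args.outdir / "leading_edge_graph.graphml")
        import networkx as nx
        n_comp = nx.number_connected_components(graph)
        print(f"leading-edge graph: {graph.number_of_nodes()} sets, "
              f"{graph.number_of_edges()} edges, {n_comp} components")


if __name__ == "__main__":
    main()
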