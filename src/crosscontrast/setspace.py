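"""Agreement classes and leading-edge-overlap graphs over GSEA results.

Combines per-analysis enrichment results into an ordinal "agreement class"
describing how specific each gene set's enrichment is to the caudate of
asymptomatic carriers, overlays user-supplied functional categories, and
casts sets within a category as a graph whose edges join sets sharing a
large fraction of their leading-edge genes.
"""

from __future__ import annotations

import fnmatch

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["assign_agreement_classes", "build_leading_edge_graph",
           "nes_matrix", "AGREEMENT_CLASSES", "ANALYSIS_LABELS"]

#: GSEA results are keyed by these analysis labels: the three disease
#: contrasts (1), (2), (4) plus the Welch-ranked (3)-vs-(5) comparison.
ANALYSIS_LABELS = ("1", "2", "4", "3v5")

AGREEMENT_CLASSES = ("CAU Unique", "CAU Enhanced", "BA9 Unique", "Unclassified")


def _classify(sig: dict[str, bool]) -> str:
    others = {k for k, v in sig.items() if v}
    if others == {"3v5"}:
        return "CAU Unique"
    if sig["1"] and (sig["4"] or sig["3v5"]):
        return "CAU Enhanced"
    if others == {"1"}:
        return "BA9 Unique"
    return "Unclassified"


def assign_agreement_classes(results: dict[str, pd.DataFrame], alpha: float = 0.05,
                             categories: dict[str, str] | None = None
                             ) -> pd.DataFrame:
    """Agreement-class records for every set significant in any analysis.

    ``results`` maps analysis label (see :data:`ANALYSIS_LABELS`) to a GSEA
    result table (``NES``/``padj`` columns, index = set name).  The class is
    a pure function of the significance-flag pattern:

    - significant only in (3)vs(5)  ->  CAU Unique
    - significant in (1) and in ((4) or (3)vs(5))  ->  CAU Enhanced
    - significant only in (1)  ->  BA9 Unique
    - anything else  ->  Unclassified

    ``categories`` maps set-name glob patterns to functional-category
    labels (first matching pattern wins); unmatched sets get
    ``"Uncategorized"``.
    """
    for label, df in results.items():
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"analysis {label!r}: duplicate set names {dupes[:5]}")
    labels = [l for l in ANALYSIS_LABELS if l in results]
    all_sets = sorted(set().union(*[set(results[l].index) for l in labels]))

    rows = []
    for name in all_sets:
        sig = {}
        nes = {}
        for l in ANALYSIS_LABELS:
            if l in results and name in results[l].index:
                padj = results[l].loc[name, "padj"]
                sig[l] = bool(np.isfinite(padj) and padj < alpha)
                nes[l] = float(results[l].loc[name, "NES"])
            else:
                sig[l] = False
                nes[l] = np.nan
        if not any(sig.values()):
            continue
        row = {"set_name": name, "agreement_class": _classify(sig)}
        for l in ANALYSIS_LABELS:
            row[f"NES_{l}"] = nes[l]
            row[f"sig_{l}"] = sig[l]
        rows.append(row)
    records = pd.DataFrame(rows).set_index("set_name") if rows else pd.DataFrame(
        columns=["agreement_class"], index=pd.Index([], name="set_name"))

    if categories is not None and len(records):
        def _category(name: str) -> str:
            for pattern, cat in categories.items():
                if fnmatch.fnmatch(name, pattern):
                    return cat
            return "Uncategorized"
        records["category"] = [_category(n) for n in records.index]
    return records


def nes_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Set x analysis NES matrix (heatmap-style table)."""
    cols = {l: df["NES"] for l, df in results.items()}
    return pd.DataFrame(cols).rename_axis(index="set_name")


def build_leading_edge_graph(results: pd.DataFrame, overlap_threshold: float = 0.25,
                             method: str = "overlap") -> nx.Graph:
    """Graph of gene sets sharing leading-edge genes.

    Nodes are set names (node attribute ``component`` labels connected
    components); an undirected edge joins A and B iff their leading-edge
    similarity strictly exceeds ``overlap_threshold``.  ``method='overlap'``
    uses the overlap coefficient |A∩B| / min(|A|,|B|) (protects the smaller
    set); ``method='jaccard'`` uses |A∩B| / |A∪B|.
    """
    if method not in ("overlap", "jaccard"):
        raise ValueError("method must be 'overlap' or 'jaccard'")
    edges_of = {name: set(le) for name, le in results["leadingEdge"].items()}
    for name, le in edges_of.items():
        if not le:
            raise ValueError(f"set {name!r} has an empty leading edge")
    graph = nx.Graph()
    names = sorted(edges_of)
    graph.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(edges_of[a] & edges_of[b])
            if inter == 0:
                continue
            if method == "overlap":
                sim = inter / min(len(edges_of[a]), len(edges_of[b]))
            else:
                sim = inter / len(edges_of[a] | edges_of[b])
            if sim > overlap_threshold:
                graph.add_edge(a, b, similarity=sim)
    for label, component in enumerate(sorted(nx.connected_components(graph),
                                             key=lambda c: sorted(c)[0])):
        for node in component:
            graph.nodes[node]["component"] = label
    return graph


def write_graph(graph: nx.Graph, edge_tsv, graphml) -> None:
    rows = [{"set_a": a, "set_b": b, "similarity": d["similarity"]}
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["set_a", "set_b", "similarity"]).to_csv(
        edge_tsv, sep="\t", index=False)
    nx.write_graphml(graph, graphml)
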