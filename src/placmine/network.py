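"""Feature-trait importance network.

A bipartite graph linking omics features to the four phenotypic traits,
with permutation-importance percentages as edge weights.  Features enter
the network when they reach at least ``include_threshold`` (default 10%)
importance for at least one trait; nodes reaching ``label_threshold``
(default 80%) for some trait are flagged for labelling in viewers.  A
supplementary table lists every feature at or above 50% for any trait.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["build_importance_network", "write_sif", "write_graphml", "supplementary_table"]

INCLUDE_THRESHOLD = 10.0
LABEL_THRESHOLD = 80.0
SUPPLEMENTARY_THRESHOLD = 50.0


def build_importance_network(
    importances: pd.DataFrame,
    include_threshold: float = INCLUDE_THRESHOLD,
    label_threshold: float = LABEL_THRESHOLD,
) -> nx.Graph:
    """Build the graph from a features x traits percent-importance table.

    Trait nodes are always present; a feature node appears iff it has an
    edge with importance >= ``include_threshold``, and carries
    ``labeled=True`` iff some edge reaches ``label_threshold``.
    """
    g = nx.Graph()
    for trait in importances.columns:
        g.add_node(str(trait), kind="trait", labeled=True)
    for feature, row in importances.iterrows():
        edges = {t: float(v) for t, v in row.items() if v >= include_threshold}
        if not edges:
            continue
        g.add_node(
            str(feature),
            kind="feature",
            labeled=bool(max(edges.values()) >= label_threshold),
        )
        for trait, v in edges.items():
            g.add_edge(str(feature), str(trait), importance_percent=v)
    return g


def supplementary_table(
    importances: pd.DataFrame,
    threshold: float = SUPPLEMENTARY_THRESHOLD,
) -> pd.DataFrame:
    """Long-format list of (feature, trait, percent) at or above the
    supplementary threshold, sorted by descending importance."""
    long = (
        importances.rename_axis("feature")
        .reset_index()
        .melt(id_vars="feature", var_name="trait", value_name="percent")
    )
    out = long[long["percent"] >= threshold].sort_values(
        ["percent", "feature"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "predicts") -> None:
    """Simple interaction format: feature <tab> predicts <tab> trait."""
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            a, b = (u, v) if g.nodes[u]["kind"] == "feature" else (v, u)
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for node in sorted(n for n in g.nodes if g.degree[n] == 0):
            fh.write(f"{node}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)
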